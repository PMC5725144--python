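"""Zygosity calling from read counts and carrier-frequency tables.

A sample *carries* a variant when its VAF reaches the het threshold; the
carrier frequency of a variant in a lesion group is (het + hom) / group
size, rounded half-up to two decimals — the convention used to report,
e.g., 7/30 carriers as 0.23.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .model import (
    DataValidationError,
    FunctionalClass,
    GENE_CHROMOSOMES,
    SampleMeta,
    Tissue,
    VariantKey,
    VariantObservation,
    Zygosity,
    ZygosityThresholds,
    round_half_up,
)

logger = logging.getLogger(__name__)

#: Canonical lesion-group column order (mirrors the cohort table layout).
GROUP_ORDER = (Tissue.NORMAL, Tissue.ADENOMA, Tissue.ADVANCED_ADENOMA, Tissue.CRC)


def compute_vaf(ref_reads: int, var_reads: int) -> float:
    """Variant allele fraction var / (ref + var); undefined at zero depth."""
    total = ref_reads + var_reads
    if total <= 0:
        raise DataValidationError("VAF undefined: zero total reads")
    if ref_reads < 0 or var_reads < 0:
        raise DataValidationError("negative read counts")
    return var_reads / total


def call_zygosity(vaf: float, thresholds: ZygosityThresholds = ZygosityThresholds()) -> Zygosity:
    if not (0.0 <= vaf <= 1.0):
        raise DataValidationError(f"VAF out of [0, 1]: {vaf}")
    if vaf < thresholds.het_low:
        return Zygosity.NOCALL
    if vaf < thresholds.hom_low:
        return Zygosity.HET
    return Zygosity.HOM


def annotate_zygosity(
    observations: list[VariantObservation],
    thresholds: ZygosityThresholds = ZygosityThresholds(),
) -> list[VariantObservation]:
    """Set the ``zygosity`` field on every observation, in place."""
    for obs in observations:
        obs.zygosity = call_zygosity(obs.vaf, thresholds)
    return observations


@dataclass
class FrequencyTable:
    """Per-variant het/hom carrier counts across lesion groups.

    ``df`` has one row per (variant, gene, functional class) with columns
    chromosome, position, ref, alt, gene, functional_class, novel and,
    per group g, ``het_<g>`` / ``hom_<g>``.  ``group_sizes`` holds the
    denominator for each group.
    """

    df: pd.DataFrame
    group_sizes: dict[Tissue, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in GROUP_ORDER:
            het, hom = f"het_{g.value}", f"hom_{g.value}"
            if het not in self.df.columns:
                self.df[het] = 0
                self.df[hom] = 0
            n = self.group_sizes.get(g, 0)
            bad = self.df[self.df[het] + self.df[hom] > n]
            if len(bad):
                raise DataValidationError(
                    f"het+hom exceeds group size {n} for group {g.value} at "
                    f"position(s) {bad['position'].tolist()}"
                )
        zero_cols = [c for c in self.df.columns if c.startswith(("het_", "hom_"))]
        all_zero = self.df[(self.df[zero_cols] == 0).all(axis=1)]
        for pos in all_zero["position"].tolist():
            warnings.warn(f"frequency table row at position {pos} has zero carriers in every group")

    def _row(self, key) -> pd.Series:
        if isinstance(key, VariantKey):
            mask = (
                (self.df["position"] == key.position)
                & (self.df["ref"] == key.ref)
                & (self.df["alt"] == key.alt)
            )
        else:  # bare position
            mask = self.df["position"] == int(key)
        hits = self.df[mask]
        if len(hits) == 0:
            raise KeyError(f"variant {key} not in frequency table")
        return hits.iloc[0]

    def counts(self, key, group: Tissue) -> tuple[int, int]:
        """(het, hom) carrier counts for a variant in one lesion group."""
        group = Tissue(group)
        row = self._row(key)
        return int(row[f"het_{group.value}"]), int(row[f"hom_{group.value}"])

    def carrier_frequency(self, key, group: Tissue) -> float:
        """(het + hom) / group size, rounded half-up to 2 decimals."""
        group = Tissue(group)
        n = self.group_sizes.get(group, 0)
        if n <= 0:
            raise DataValidationError(f"group {group.value} has size 0")
        het, hom = self.counts(key, group)
        return round_half_up((het + hom) / n, 2)

    def __len__(self) -> int:
        return len(self.df)


def carrier_frequency(table: FrequencyTable, key, group: Tissue) -> float:
    """Module-level convenience for ``FrequencyTable.carrier_frequency``."""
    return table.carrier_frequency(key, group)


def build_frequency_table(
    observations: list[VariantObservation],
    samples: list[SampleMeta],
    thresholds: ZygosityThresholds = ZygosityThresholds(),
) -> FrequencyTable:
    """Tabulate het/hom carriers per variant per lesion group.

    Each sample is counted at most once per variant (duplicate observations
    are collapsed to the first).  The denominator for each group is the full
    number of sheet samples with that tissue, whether or not they have
    coverage at a locus.
    """
    meta = {s.sample_id: s for s in samples}
    group_sizes = {g: sum(1 for s in samples if s.tissue == g) for g in GROUP_ORDER}

    seen: set[tuple[str, VariantKey]] = set()
    rows: dict[tuple, dict] = {}
    for obs in observations:
        if obs.sample_id not in meta:
            raise DataValidationError(f"sample {obs.sample_id} missing from sample sheet")
        tissue = meta[obs.sample_id].tissue
        if tissue is None:
            raise DataValidationError(f"sample {obs.sample_id} has no tissue assigned")
        if (obs.sample_id, obs.key) in seen:
            logger.debug("duplicate observation for %s at %s ignored", obs.sample_id, obs.key)
            continue
        seen.add((obs.sample_id, obs.key))
        zyg = obs.zygosity if obs.zygosity is not None else call_zygosity(obs.vaf, thresholds)
        if zyg == Zygosity.NOCALL:
            continue
        rkey = (obs.key, obs.gene)
        if rkey not in rows:
            rows[rkey] = {
                "chromosome": obs.key.chromosome,
                "position": obs.key.position,
                "ref": obs.key.ref,
                "alt": obs.key.alt,
                "gene": obs.gene,
                "functional_class": (obs.functional_class or FunctionalClass.OTHER).value,
                "novel": obs.novel,
            }
            for g in GROUP_ORDER:
                rows[rkey][f"het_{g.value}"] = 0
                rows[rkey][f"hom_{g.value}"] = 0
        rows[rkey][f"{zyg.value}_{tissue.value}"] += 1

    df = pd.DataFrame(list(rows.values()))
    if len(df) == 0:
        cols = ["chromosome", "position", "ref", "alt", "gene", "functional_class", "novel"]
        cols += [f"{z}_{g.value}" for g in GROUP_ORDER for z in ("het", "hom")]
        df = pd.DataFrame(columns=cols)
    else:
        df = df.sort_values(["gene", "position"]).reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-carrier rows cannot occur here by construction
        return FrequencyTable(df=df, group_sizes=group_sizes)
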