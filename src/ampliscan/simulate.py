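"""Synthetic tumor-normal cohorts with the read-count structure the
downstream analysis assumes.

The generator emulates a 3-gene targeted panel (APC, MSH3, MSH6) sequenced
to ~1000x mean depth over a lesion-staged cohort (defaults: 30 normal, 21
adenoma, 33 advanced adenoma, 56 CRC samples, 16 tumor-normal pairs).
Genotypes are drawn per patient per locus under Hardy-Weinberg from a
population alt-allele frequency; per-sample depth follows a negative
binomial around the mean; variant reads are binomial(depth, expected VAF)
with expected VAF 0.5 for het and 1.0 for hom-alt sites.  Planted CNV/LOH
events shift the expected VAF to ``target_vaf`` over a block of >= 3
consecutive panel loci: germline events in both members of a pair, somatic
events in the tumor only with the matched normal forced heterozygous.

Not modeled: sequencing error, mapping bias, FFPE artifacts, tumor-purity
mixtures (purity enters only through target_vaf).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    Catalog,
    DataValidationError,
    FunctionalClass,
    GENE_CHROMOSOMES,
    SampleMeta,
    Tissue,
    VariantKey,
    VariantObservation,
)

__all__ = [
    "PanelGene",
    "PlantedEvent",
    "SimConfig",
    "default_panel",
    "simulate_cohort",
    "simulate_catalog",
    "make_cnvloh_fixture",
]


@dataclass(frozen=True)
class PanelGene:
    gene: str
    chromosome: str
    positions: tuple[int, ...]


def default_panel(loci_per_gene: int = 40) -> tuple[PanelGene, ...]:
    """Ordered panel loci spread across the hg19 spans of the 3 genes.

    Spacing is arbitrary by design: run consecutiveness is rank order
    within a gene, so inter-locus distance never enters the scan.
    """
    spans = {
        "APC": ("chr5", 112_043_384, 112_179_909),
        "MSH3": ("chr5", 79_950_497, 80_168_937),
        "MSH6": ("chr2", 48_010_221, 48_033_700),
    }
    genes = []
    for gene, (chrom, start, end) in spans.items():
        step = max((end - start) // max(loci_per_gene - 1, 1), 1)
        positions = tuple(start + i * step for i in range(loci_per_gene))
        genes.append(PanelGene(gene=gene, chromosome=chrom, positions=positions))
    return tuple(genes)


#: Deterministic ref/alt assignment cycled over panel loci.
_ALLELE_CYCLE = (("G", "A"), ("C", "T"), ("T", "C"), ("A", "G"), ("G", "T"), ("C", "A"))
_CLASS_CYCLE = (
    FunctionalClass.INTRONIC,
    FunctionalClass.SYNONYMOUS,
    FunctionalClass.NONSYNONYMOUS,
    FunctionalClass.INTRONIC,
    FunctionalClass.SYNONYMOUS,
)


@dataclass(frozen=True)
class PlantedEvent:
    """A CNV/LOH event planted at a block of consecutive panel loci.

    ``locus_start``/``locus_end`` are inclusive indices into the gene's
    ordered position list; the block must span >= 3 loci.  Germline events
    shift both members of the patient's pair; somatic events shift the
    tumor only and force the matched normal heterozygous at those loci.
    """

    patient_id: str
    gene: str
    locus_start: int
    locus_end: int
    kind: str  # "germline" | "somatic"
    target_vaf: float = 0.8

    def __post_init__(self) -> None:
        if self.locus_end - self.locus_start + 1 < 3:
            raise DataValidationError("planted event must span >= 3 loci")
        if self.kind not in {"germline", "somatic"}:
            raise DataValidationError(f"unknown event kind {self.kind!r}")
        if not (0.6 <= self.target_vaf <= 1.0):
            raise DataValidationError("target_vaf must be in [0.6, 1.0]")

    @property
    def indices(self) -> range:
        return range(self.locus_start, self.locus_end + 1)


@dataclass
class SimConfig:
    """Cohort-simulation parameters; the defaults are the study conditions
    (group sizes 30/21/33/56, 16 matched pairs, ~1000x mean depth)."""

    seed: int = 0
    n_normal: int = 30
    n_adenoma: int = 21
    n_adv_adenoma: int = 33
    n_crc: int = 56
    n_pairs: int = 16
    panel: tuple[PanelGene, ...] = field(default_factory=default_panel)
    mean_depth: float = 1000.0
    depth_dispersion: float = 50.0  # negative-binomial size; larger = tighter
    alt_allele_freq: float = 0.10
    known_fraction: float = 0.7  # fraction of panel loci present in the catalog
    planted_events: tuple[PlantedEvent, ...] = ()

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_adenoma", "n_adv_adenoma", "n_crc"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{name} must be >= 0")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise DataValidationError("mean_depth and depth_dispersion must be > 0")
        if not (0.0 <= self.alt_allele_freq <= 1.0):
            raise DataValidationError("alt_allele_freq must be in [0, 1]")
        if self.n_pairs > min(self.n_normal, self.n_crc):
            raise DataValidationError("n_pairs cannot exceed n_normal or n_crc")
        self.planted_events = tuple(self.planted_events)


def _build_samples(config: SimConfig) -> list[SampleMeta]:
    samples: list[SampleMeta] = []
    for i in range(config.n_pairs):
        pid = f"P{i:03d}"
        samples.append(SampleMeta(f"{pid}N", pid, Tissue.NORMAL, paired_sample_id=f"{pid}T"))
        samples.append(SampleMeta(f"{pid}T", pid, Tissue.CRC, paired_sample_id=f"{pid}N"))
    counter = config.n_pairs
    blocks = [
        (Tissue.NORMAL, config.n_normal - config.n_pairs),
        (Tissue.ADENOMA, config.n_adenoma),
        (Tissue.ADVANCED_ADENOMA, config.n_adv_adenoma),
        (Tissue.CRC, config.n_crc - config.n_pairs),
    ]
    for tissue, n in blocks:
        for _ in range(n):
            pid = f"P{counter:03d}"
            suffix = {"normal": "N", "adenoma": "A", "advanced_adenoma": "AA", "crc": "T"}[tissue.value]
            samples.append(SampleMeta(f"{pid}{suffix}", pid, tissue))
            counter += 1
    return samples


def _locus_known_mask(config: SimConfig) -> dict[str, np.ndarray]:
    """Deterministic per-locus catalog membership, derived from the seed
    independently of the genotype stream so catalogs can be regenerated."""
    rng = np.random.default_rng([config.seed % (2**31), 17])
    return {
        pg.gene: rng.random(len(pg.positions)) < config.known_fraction
        for pg in config.panel
    }


def simulate_catalog(config: SimConfig, name: str = "dbSNP") -> Catalog:
    """The catalog of 'known' panel variants matching this configuration."""
    masks = _locus_known_mask(config)
    entries = set()
    for pg in config.panel:
        for idx, pos in enumerate(pg.positions):
            if masks[pg.gene][idx]:
                ref, alt = _ALLELE_CYCLE[idx % len(_ALLELE_CYCLE)]
                entries.add(VariantKey(pg.chromosome, pos, ref, alt))
    return Catalog(name=name, entries=frozenset(entries))


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[VariantObservation], list[SampleMeta], pd.DataFrame]:
    """Draw one cohort; returns (observations, sample sheet, truth table).

    The truth table lists planted events with their genomic extent and the
    affected sample ids.  Identical configuration (including seed) yields
    identical output.
    """
    rng = np.random.default_rng(config.seed % (2**31))
    samples = _build_samples(config)
    meta = {s.sample_id: s for s in samples}
    patients: dict[str, list[SampleMeta]] = {}
    for s in samples:
        patients.setdefault(s.patient_id, []).append(s)
    panel_by_gene = {pg.gene: pg for pg in config.panel}
    known = _locus_known_mask(config)

    # expected-VAF overrides and forced-het loci from planted events
    overrides: dict[tuple[str, str, int], float] = {}
    forced_het: set[tuple[str, str, int]] = set()
    truth_rows = []
    for ev in config.planted_events:
        if ev.patient_id not in patients:
            raise DataValidationError(f"planted event references unknown patient {ev.patient_id}")
        if ev.gene not in panel_by_gene:
            raise DataValidationError(f"planted event references unknown gene {ev.gene}")
        pg = panel_by_gene[ev.gene]
        if ev.locus_end >= len(pg.positions):
            raise DataValidationError(
                f"planted event indices {ev.locus_start}-{ev.locus_end} exceed "
                f"{ev.gene} panel size {len(pg.positions)}"
            )
        members = patients[ev.patient_id]
        tumors = [s for s in members if s.is_lesion]
        normals = [s for s in members if s.tissue == Tissue.NORMAL]
        for idx in ev.indices:
            if ev.kind == "germline":
                for s in members:
                    overrides[(s.sample_id, ev.gene, idx)] = ev.target_vaf
                    forced_het.add((s.sample_id, ev.gene, idx))
            else:  # somatic
                for s in tumors:
                    overrides[(s.sample_id, ev.gene, idx)] = ev.target_vaf
                    forced_het.add((s.sample_id, ev.gene, idx))
                for s in normals:
                    overrides[(s.sample_id, ev.gene, idx)] = 0.5
                    forced_het.add((s.sample_id, ev.gene, idx))
        truth_rows.append(
            {
                "patient_id": ev.patient_id,
                "gene": ev.gene,
                "kind": ev.kind,
                "locus_start": ev.locus_start,
                "locus_end": ev.locus_end,
                "start_pos": pg.positions[ev.locus_start],
                "end_pos": pg.positions[ev.locus_end],
                "target_vaf": ev.target_vaf,
                "tumor_samples": ",".join(s.sample_id for s in tumors),
                "normal_samples": ",".join(s.sample_id for s in normals),
            }
        )

    p = config.alt_allele_freq
    geno_probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.mean_depth)

    observations: list[VariantObservation] = []
    for pid in sorted(patients):
        members = sorted(patients[pid], key=lambda s: s.sample_id)
        for pg in config.panel:
            n_loci = len(pg.positions)
            germline_gt = rng.choice(3, size=n_loci, p=geno_probs)
            for s in members:
                for idx, pos in enumerate(pg.positions):
                    gt = germline_gt[idx]
                    loc = (s.sample_id, pg.gene, idx)
                    if loc in forced_het:
                        gt = 1
                    if gt == 0:
                        continue
                    depth = int(rng.negative_binomial(nb_n, nb_p)) + 1
                    evaf = overrides.get(loc, 0.5 if gt == 1 else 1.0)
                    var = int(rng.binomial(depth, evaf))
                    if var == 0:
                        continue
                    ref_allele, alt_allele = _ALLELE_CYCLE[idx % len(_ALLELE_CYCLE)]
                    observations.append(
                        VariantObservation(
                            key=VariantKey(pg.chromosome, pos, ref_allele, alt_allele),
                            sample_id=s.sample_id,
                            gene=pg.gene,
                            ref_reads=depth - var,
                            var_reads=var,
                            functional_class=_CLASS_CYCLE[idx % len(_CLASS_CYCLE)],
                            novel=not bool(known[pg.gene][idx]),
                        )
                    )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id", "gene", "kind", "locus_start", "locus_end",
            "start_pos", "end_pos", "target_vaf", "tumor_samples", "normal_samples",
        ],
    )
    return observations, samples, truth


def make_toy_transcript(
    gene: str = "TOY",
    n_codons: int = 30,
    strand: str = "+",
    seed: int = 7,
    ref_start: int = 1_000,
):
    """A small two-exon transcript with UTR flanks and an intron, for
    exercising the consequence classifier and protein mapping.

    The CDS starts with ATG, ends with TAA and contains no internal stop.
    The minus-strand variant encodes the same protein with the gene laid
    out on the reverse strand (reference is the plus-strand sequence).
    """
    from .annotate import TranscriptModel  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(bases, 3))
        if codon not in stops:
            codons.append(codon)
    codons.append("TAA")
    cds = "".join(codons)
    utr5 = "".join(rng.choice(bases, 10))
    utr3 = "".join(rng.choice(bases, 10))
    intron = "".join(rng.choice(bases, 20))
    half = (n_codons // 2) * 3
    layout = utr5 + cds[:half] + intron + cds[half:] + utr3
    total = len(layout)

    if strand == "+":
        reference = layout
        exon1 = (ref_start + 10, ref_start + 10 + half - 1)
        exon2_start = ref_start + 10 + half + 20
        exon2 = (exon2_start, exon2_start + (len(cds) - half) - 1)
        intervals = (exon1, exon2)
    else:
        comp = str.maketrans("ACGT", "TGCA")
        reference = layout.translate(comp)[::-1]

        def flip(i0: int, i1: int) -> tuple[int, int]:
            # transcript-layout [i0, i1] (0-based) -> ascending genomic coords
            return (ref_start + total - 1 - i1, ref_start + total - 1 - i0)

        part1 = flip(10, 10 + half - 1)
        part2 = flip(10 + half + 20, 10 + half + 20 + (len(cds) - half) - 1)
        intervals = tuple(sorted((part1, part2)))
    return TranscriptModel(
        gene=gene,
        strand=strand,
        cds_intervals=intervals,
        reference=reference,
        ref_start=ref_start,
    )


# ---------------------------------------------------------------------------
# Deterministic cohort fixture encoding the published event composition
# ---------------------------------------------------------------------------

#: Reference event plan for the deterministic cohort fixture.
#: Matched-pair germline event plan: gene -> pair indices, two events each.
_PAIR_GERMLINE = {
    "MSH6": (0, 1, 2, 3, 4, 5, 8, 9),
    "APC": (0, 1, 2),
    "MSH3": (4, 6, 7, 10),
}
#: Matched-pair somatic events: (pair index, gene), one event each.
_PAIR_SOMATIC = (
    (9, "APC"),
    (10, "MSH6"),
    (11, "APC"),
    (11, "MSH3"),
    (12, "APC"),
    (12, "MSH6"),
    (13, "APC"),
    (13, "MSH6"),
    (14, "APC"),
)
_N_PAIRS = 15
_N_UNPAIRED = 83
_N_UNPAIRED_ALTERED = 71
#: Unpaired-tumor gene coverage: one event per listed sample index.
_UNPAIRED_GENE_SAMPLES = {
    "MSH6": range(0, 48),
    "APC": range(30, 71),
    "MSH3": range(0, 28),
}

_EVENT_DEPTH = 1000
_EVENT_VAF = 0.75  # counts 250/750 at depth 1000
_HET_COUNTS = (500, 500)


def _event_obs(sample_id: str, gene: str, panel: dict[str, PanelGene],
               block: int, vaf: float) -> list[VariantObservation]:
    """Three imbalanced loci for event block b at indices 4b..4b+2."""
    pg = panel[gene]
    var = int(round(_EVENT_DEPTH * vaf))
    out = []
    for idx in range(4 * block, 4 * block + 3):
        pos = pg.positions[idx]
        ref_a, alt_a = _ALLELE_CYCLE[idx % len(_ALLELE_CYCLE)]
        out.append(
            VariantObservation(
                key=VariantKey(pg.chromosome, pos, ref_a, alt_a),
                sample_id=sample_id,
                gene=gene,
                ref_reads=_EVENT_DEPTH - var,
                var_reads=var,
            )
        )
    return out


def _separator_obs(sample_id: str, gene: str, panel: dict[str, PanelGene],
                   block: int) -> VariantObservation:
    """A balanced heterozygous locus at index 4b+3, breaking run adjacency."""
    pg = panel[gene]
    idx = 4 * block + 3
    ref_a, alt_a = _ALLELE_CYCLE[idx % len(_ALLELE_CYCLE)]
    return VariantObservation(
        key=VariantKey(pg.chromosome, pg.positions[idx], ref_a, alt_a),
        sample_id=sample_id,
        gene=gene,
        ref_reads=_HET_COUNTS[0],
        var_reads=_HET_COUNTS[1],
    )


def make_cnvloh_fixture() -> tuple[list[VariantObservation], list[SampleMeta]]:
    """A deterministic 98-tumor cohort with a reference CNV/LOH event
    composition: 15 matched pairs carrying 39 events (30 germline + 9
    somatic) and 83 unpaired tumors of which 71 carry 117 further events,
    with per-gene sample coverage MSH6 59 / APC 49 / MSH3 33 of 98.

    Read counts are exact (depth 1000, event VAF 0.75, het 0.5), so the run
    scan recovers the plan without stochastic slack.  Within one gene,
    consecutive planted events are separated by one balanced heterozygous
    locus so each stays a distinct maximal run.
    """
    panel = {pg.gene: pg for pg in default_panel(loci_per_gene=30)}
    observations: list[VariantObservation] = []
    samples: list[SampleMeta] = []

    for i in range(_N_PAIRS):
        pid = f"C{i:02d}"
        normal_id, tumor_id = f"{pid}N", f"{pid}T"
        samples.append(SampleMeta(normal_id, pid, Tissue.NORMAL, paired_sample_id=tumor_id))
        samples.append(SampleMeta(tumor_id, pid, Tissue.CRC, paired_sample_id=normal_id))
        for gene, pairs in _PAIR_GERMLINE.items():
            if i not in pairs:
                continue
            for block in (0, 1):  # two germline events per altered pair/gene
                for sid in (tumor_id, normal_id):
                    observations.extend(_event_obs(sid, gene, panel, block, _EVENT_VAF))
                    observations.append(_separator_obs(sid, gene, panel, block))
        for pair_idx, gene in _PAIR_SOMATIC:
            if pair_idx != i:
                continue
            block = 5  # clear of the germline blocks 0-1
            observations.extend(_event_obs(tumor_id, gene, panel, block, _EVENT_VAF))
            for obs in _event_obs(normal_id, gene, panel, block, 0.5):
                observations.append(obs)

    for j in range(_N_UNPAIRED):
        pid = f"U{j:02d}"
        sid = f"{pid}T"
        samples.append(SampleMeta(sid, pid, Tissue.CRC))
        altered_genes = [g for g, idxs in _UNPAIRED_GENE_SAMPLES.items() if j in idxs]
        if j >= _N_UNPAIRED_ALTERED or not altered_genes:
            # analyzed but unaltered: balanced het background only
            observations.append(_separator_obs(sid, "APC", panel, 0))
            observations.append(_separator_obs(sid, "APC", panel, 1))
            continue
        for gene in altered_genes:
            observations.extend(_event_obs(sid, gene, panel, 0, _EVENT_VAF))
    return observations, samples
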