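"""Allelic-imbalance run scanning and germline/somatic classification.

The CNV/LOH criterion: within one sample and one gene, variants are sorted
by genomic position, and any maximal stretch of at least ``k`` consecutive
variants whose VAF = var / (ref + var) is at least ``tau`` (defaults 3 and
0.6) is an imbalance run.  "Consecutive" means adjacent in the sample's
position-sorted variant list for that gene; genomic distance is not used,
and runs never span gene boundaries.

In a matched tumor-normal pair, a tumor run whose loci overlap a normal-
tissue run is a potential germline event (imbalance in both tissues); a
tumor run with no normal counterpart whose loci are heterozygous in the
normal is somatic (het in normal, shifted toward homozygous in tumor);
anything else is left unclassified.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    CnvLohEvent,
    DataValidationError,
    EventLabel,
    ImbalanceRun,
    LESION_TISSUES,
    SampleMeta,
    ScanParams,
    Tissue,
    VariantObservation,
    Zygosity,
    ZygosityThresholds,
    round_half_up,
)
from .zygosity import call_zygosity

__all__ = [
    "scan_sample",
    "classify_pair",
    "scan_cohort",
    "summarize",
    "CohortSummary",
]


def scan_sample(
    observations: Sequence[VariantObservation],
    params: ScanParams = ScanParams(),
) -> list[ImbalanceRun]:
    """Find all maximal imbalance runs in one sample.

    Observations must all belong to one sample; they are grouped by gene and
    sorted by position internally.  Every emitted run has length >= params.k,
    all member VAFs qualifying, and cannot be extended by an adjacent
    qualifying variant.
    """
    if not observations:
        return []
    sample_ids = {o.sample_id for o in observations}
    if len(sample_ids) > 1:
        raise DataValidationError(
            f"scan_sample expects one sample, got {sorted(sample_ids)}"
        )
    sample_id = observations[0].sample_id

    by_gene: dict[str, list[VariantObservation]] = defaultdict(list)
    for obs in observations:
        by_gene[obs.gene].append(obs)

    runs: list[ImbalanceRun] = []
    for gene in sorted(by_gene):
        ordered = sorted(by_gene[gene], key=lambda o: (o.key.chromosome, o.key.position))
        flags = [params.qualifies(o.vaf) for o in ordered]
        i = 0
        while i < len(ordered):
            if not flags[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(ordered) and flags[j + 1]:
                j += 1
            if j - i + 1 >= params.k:
                runs.append(
                    ImbalanceRun(
                        sample_id=sample_id,
                        gene=gene,
                        members=tuple(ordered[i : j + 1]),
                    )
                )
            i = j + 1
    return runs


def _run_contains_novel(run: ImbalanceRun) -> bool:
    return any(m.novel for m in run.members if m.novel is not None)


def classify_pair(
    tumor_runs: Sequence[ImbalanceRun],
    normal_observations: Sequence[VariantObservation],
    patient_id: str,
    *,
    normal_runs: Optional[Sequence[ImbalanceRun]] = None,
    params: ScanParams = ScanParams(),
    thresholds: ZygosityThresholds = ZygosityThresholds(),
    metas: Optional[dict[str, SampleMeta]] = None,
) -> list[CnvLohEvent]:
    """Label each tumor run germline / somatic / unclassified using the
    matched normal.

    Germline: a normal-tissue run shares at least one locus with the tumor
    run (imbalance in both tissues); this takes precedence.  Somatic: no
    overlapping normal run, and the normal is called heterozygous at >= 1
    member locus.  Otherwise (e.g. no normal coverage at the run's loci) the
    event stays tumor_only_unclassified.
    """
    if metas:
        patients = {
            metas[sid].patient_id
            for sid in (
                {r.sample_id for r in tumor_runs}
                | {o.sample_id for o in normal_observations}
            )
            if sid in metas
        }
        if len(patients) > 1:
            raise DataValidationError(
                f"classify_pair received samples from different patients: {sorted(patients)}"
            )
    if normal_runs is None:
        normal_runs = scan_sample(list(normal_observations), params)
    normal_at: dict[tuple[str, int], VariantObservation] = {
        (o.gene, o.key.position): o for o in normal_observations
    }

    events: list[CnvLohEvent] = []
    for run in tumor_runs:
        overlap = next((nr for nr in normal_runs if run.overlaps(nr)), None)
        if overlap is not None:
            label = EventLabel.GERMLINE
        else:
            normal_het = any(
                call_zygosity(normal_at[(run.gene, p)].vaf, thresholds) == Zygosity.HET
                for p in run.positions
                if (run.gene, p) in normal_at
            )
            label = EventLabel.SOMATIC if normal_het else EventLabel.TUMOR_ONLY_UNCLASSIFIED
        events.append(
            CnvLohEvent(
                patient_id=patient_id,
                gene=run.gene,
                tumor_run=run,
                normal_run=overlap,
                label=label,
                contains_novel=_run_contains_novel(run),
            )
        )
    return events


@dataclass
class CohortSummary:
    """Cohort-level CNV/LOH accounting.

    Percentages are rounded half-up to integers; averages to one decimal.
    ``germline_pct`` / ``somatic_pct`` are shares of the classified
    (germline + somatic) matched-pair events only.
    """

    n_samples: int
    n_altered: int
    total_events: int
    germline_events: int
    somatic_events: int
    unclassified_events: int
    gene_sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def altered_pct(self) -> int:
        return int(round_half_up(100 * self.n_altered / self.n_samples)) if self.n_samples else 0

    @property
    def classified_events(self) -> int:
        return self.germline_events + self.somatic_events

    @property
    def germline_pct(self) -> Optional[int]:
        if self.classified_events == 0:
            return None
        return int(round_half_up(100 * self.germline_events / self.classified_events))

    @property
    def somatic_pct(self) -> Optional[int]:
        if self.classified_events == 0:
            return None
        return int(round_half_up(100 * self.somatic_events / self.classified_events))

    @property
    def events_per_sample(self) -> float:
        return round_half_up(self.total_events / self.n_samples, 1) if self.n_samples else 0.0

    @property
    def events_per_altered_sample(self) -> float:
        return round_half_up(self.total_events / self.n_altered, 1) if self.n_altered else 0.0

    def gene_sample_pct(self, gene: str) -> int:
        if not self.n_samples:
            return 0
        return int(round_half_up(100 * self.gene_sample_counts.get(gene, 0) / self.n_samples))

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_altered": self.n_altered,
            "altered_pct": self.altered_pct,
            "total_events": self.total_events,
            "germline_events": self.germline_events,
            "somatic_events": self.somatic_events,
            "unclassified_events": self.unclassified_events,
            "germline_pct": self.germline_pct,
            "somatic_pct": self.somatic_pct,
            "events_per_sample": self.events_per_sample,
            "events_per_altered_sample": self.events_per_altered_sample,
            "genes": {
                g: {"n_samples_altered": n, "pct_samples_altered": self.gene_sample_pct(g)}
                for g, n in sorted(self.gene_sample_counts.items())
            },
        }


def summarize(events: Sequence[CnvLohEvent], n_samples: int) -> CohortSummary:
    """Aggregate events into the cohort summary; ``n_samples`` is the number
    of lesion samples scanned (the denominator for altered fractions)."""
    altered = {e.sample_id for e in events}
    gene_samples: dict[str, set[str]] = defaultdict(set)
    counts = {label: 0 for label in EventLabel}
    for e in events:
        counts[e.label] += 1
        gene_samples[e.gene].add(e.sample_id)
    return CohortSummary(
        n_samples=n_samples,
        n_altered=len(altered),
        total_events=len(events),
        germline_events=counts[EventLabel.GERMLINE],
        somatic_events=counts[EventLabel.SOMATIC],
        unclassified_events=counts[EventLabel.TUMOR_ONLY_UNCLASSIFIED],
        gene_sample_counts={g: len(s) for g, s in gene_samples.items()},
    )


def scan_cohort(
    observations: Sequence[VariantObservation],
    samples: Sequence[SampleMeta],
    params: ScanParams = ScanParams(),
    thresholds: ZygosityThresholds = ZygosityThresholds(),
) -> tuple[list[CnvLohEvent], CohortSummary]:
    """Scan every lesion sample; classify through the matched normal where
    the sample sheet pairs one, otherwise emit tumor-only events.

    Normal-tissue samples are never scanned on their own (normal-only runs
    are not counted as events).  The summary denominator is the number of
    lesion samples in the sheet.
    """
    meta = {s.sample_id: s for s in samples}
    by_sample: dict[str, list[VariantObservation]] = defaultdict(list)
    for obs in observations:
        if obs.sample_id not in meta:
            raise DataValidationError(f"sample {obs.sample_id} missing from sample sheet")
        by_sample[obs.sample_id].append(obs)

    # pairing: explicit field on either member of the pair
    normal_of: dict[str, str] = {}
    for s in samples:
        if s.paired_sample_id is None or s.paired_sample_id not in meta:
            continue
        other = meta[s.paired_sample_id]
        if s.patient_id != other.patient_id:
            raise DataValidationError(
                f"paired samples {s.sample_id}/{other.sample_id} belong to different patients"
            )
        if s.is_lesion and other.tissue == Tissue.NORMAL:
            normal_of[s.sample_id] = other.sample_id
        elif other.is_lesion and s.tissue == Tissue.NORMAL:
            normal_of[other.sample_id] = s.sample_id

    lesions = [s for s in samples if s.is_lesion]
    events: list[CnvLohEvent] = []
    for lesion in lesions:
        tumor_runs = scan_sample(by_sample.get(lesion.sample_id, []), params)
        if not tumor_runs:
            continue
        normal_id = normal_of.get(lesion.sample_id)
        if normal_id is not None:
            events.extend(
                classify_pair(
                    tumor_runs,
                    by_sample.get(normal_id, []),
                    lesion.patient_id,
                    params=params,
                    thresholds=thresholds,
                )
            )
        else:
            events.extend(
                CnvLohEvent(
                    patient_id=lesion.patient_id,
                    gene=run.gene,
                    tumor_run=run,
                    label=EventLabel.TUMOR_ONLY_UNCLASSIFIED,
                    contains_novel=_run_contains_novel(run),
                )
                for run in tumor_runs
            )
    return events, summarize(events, n_samples=len(lesions))
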