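"""Domain types shared by every pipeline stage.

Coordinates are 1-based, fully closed, on hg19 chromosome labels throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "Tissue",
    "LESION_TISSUES",
    "GENE_CHROMOSOMES",
    "DEFAULT_GENE_REGIONS",
    "FunctionalClass",
    "Zygosity",
    "VariantKey",
    "VariantObservation",
    "SampleMeta",
    "Catalog",
    "ZygosityThresholds",
    "ScanParams",
    "ImbalanceRun",
    "EventLabel",
    "CnvLohEvent",
    "DataValidationError",
    "round_half_up",
]


class DataValidationError(ValueError):
    """Malformed or inconsistent input data."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.025 -> 0.03), matching the
    reporting convention used for carrier frequencies and percentages."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


class Tissue(str, Enum):
    NORMAL = "normal"
    ADENOMA = "adenoma"
    ADVANCED_ADENOMA = "advanced_adenoma"
    CRC = "crc"


LESION_TISSUES = frozenset({Tissue.ADENOMA, Tissue.ADVANCED_ADENOMA, Tissue.CRC})

#: Panel genes and the chromosome each maps to (hg19).  DHFR shares the
#: MSH3 promoter region on chr5 and appears in co-annotated loci.
GENE_CHROMOSOMES = {
    "APC": "chr5",
    "MSH3": "chr5",
    "DHFR": "chr5",
    "DHFR, MSH3": "chr5",
    "MSH6": "chr2",
}

#: Approximate hg19 gene spans of the panel, used to resolve a gene from a
#: coordinate when an input carries no gene annotation.
DEFAULT_GENE_REGIONS = {
    "MSH6": ("chr2", 47_990_000, 48_040_000),
    "MSH3": ("chr5", 79_940_000, 80_180_000),
    "APC": ("chr5", 112_040_000, 112_190_000),
}


class FunctionalClass(str, Enum):
    INTRONIC = "intronic"
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    STOPGAIN = "stopgain"
    FRAMESHIFT = "frameshift"
    UTR = "UTR"
    OTHER = "other"


_FUNC_ALIASES = {
    "intronic": FunctionalClass.INTRONIC,
    "intron": FunctionalClass.INTRONIC,
    "synonymous snv": FunctionalClass.SYNONYMOUS,
    "synonymous": FunctionalClass.SYNONYMOUS,
    "non-synonymous snv": FunctionalClass.NONSYNONYMOUS,
    "nonsynonymous snv": FunctionalClass.NONSYNONYMOUS,
    "nonsynonymous": FunctionalClass.NONSYNONYMOUS,
    "non-synonymous": FunctionalClass.NONSYNONYMOUS,
    "missense": FunctionalClass.NONSYNONYMOUS,
    "stopgain": FunctionalClass.STOPGAIN,
    "stopgain snv": FunctionalClass.STOPGAIN,
    "frameshift": FunctionalClass.FRAMESHIFT,
    "frameshift deletion": FunctionalClass.FRAMESHIFT,
    "frameshift insertion": FunctionalClass.FRAMESHIFT,
    "utr": FunctionalClass.UTR,
    "utr3": FunctionalClass.UTR,
    "utr5": FunctionalClass.UTR,
    "other": FunctionalClass.OTHER,
}


def parse_functional_class(label: str) -> FunctionalClass:
    """Map an annotation label (ANNOVAR style or our own) to the enum."""
    return _FUNC_ALIASES.get(str(label).strip().lower(), FunctionalClass.OTHER)


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"
    NOCALL = "nocall"


_DNA = set("ACGT")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: (chromosome, 1-based position, ref, alt)."""

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataValidationError(f"position must be >= 1, got {self.position}")
        if not self.ref or not self.alt:
            raise DataValidationError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise DataValidationError(f"ref == alt ({self.ref}) at {self.chromosome}:{self.position}")
        for allele in (self.ref, self.alt):
            if allele != "-" and not set(allele.upper()) <= _DNA:
                raise DataValidationError(f"allele {allele!r} is not a DNA string")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref != "-" and self.alt != "-"


@dataclass
class VariantObservation:
    """One variant observed in one sample, with its supporting read counts."""

    key: VariantKey
    sample_id: str
    gene: str
    ref_reads: int
    var_reads: int
    functional_class: Optional[FunctionalClass] = None
    exon: Optional[int] = None
    novel: Optional[bool] = None
    zygosity: Optional[Zygosity] = None

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.var_reads < 0:
            raise DataValidationError(
                f"negative read counts for {self.sample_id} at "
                f"{self.key.chromosome}:{self.key.position}"
            )

    @property
    def depth(self) -> int:
        return self.ref_reads + self.var_reads

    @property
    def vaf(self) -> float:
        """Variant allele fraction: var / (ref + var)."""
        if self.depth == 0:
            raise DataValidationError(
                f"VAF undefined at zero depth ({self.sample_id}, "
                f"{self.key.chromosome}:{self.key.position})"
            )
        return self.var_reads / self.depth


@dataclass
class SampleMeta:
    sample_id: str
    patient_id: str
    tissue: Optional[Tissue] = None
    paired_sample_id: Optional[str] = None
    stage: Optional[str] = None

    @property
    def is_lesion(self) -> bool:
        return self.tissue in LESION_TISSUES


@dataclass
class Catalog:
    """A local variant catalog (dbSNP / 1000 Genomes / COSMIC stand-in).

    Membership is exact on (chromosome, position, ref, alt).
    """

    name: str
    entries: frozenset[VariantKey] = field(default_factory=frozenset)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ZygosityThresholds:
    """VAF cut points for zygosity calls.

    vaf < het_low -> nocall (variant not carried); het_low <= vaf < hom_low
    -> het; vaf >= hom_low -> hom.  Defaults leave wide margins so binomial
    noise at ~1000x depth essentially never flips a true het/hom call.
    """

    het_low: float = 0.20
    hom_low: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 < self.het_low < self.hom_low < 1.0):
            raise DataValidationError(
                f"require 0 < het_low < hom_low < 1, got {self.het_low}, {self.hom_low}"
            )


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the allelic-imbalance run scan.

    tau: minimum VAF for a variant to count as imbalanced (default 0.6).
    k: minimum number of consecutive imbalanced variants (default 3).
    symmetric: also flag reference-allele excess (VAF <= 1 - tau); off by
        default, matching the one-sided published criterion.
    max_vaf: optional cap excluding near-homozygous variants (VAF > cap)
        from runs, to suppress germline homozygous stretches.
    """

    tau: float = 0.6
    k: int = 3
    symmetric: bool = False
    max_vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.5 <= self.tau <= 1.0):
            raise DataValidationError(f"tau must be in [0.5, 1], got {self.tau}")
        if self.k < 1:
            raise DataValidationError(f"k must be >= 1, got {self.k}")
        if self.max_vaf is not None and not (self.tau <= self.max_vaf <= 1.0):
            raise DataValidationError("max_vaf must lie in [tau, 1]")

    def qualifies(self, vaf: float) -> bool:
        if self.max_vaf is not None and vaf > self.max_vaf:
            return False
        if vaf >= self.tau:
            return True
        return self.symmetric and vaf <= 1.0 - self.tau


@dataclass
class ImbalanceRun:
    """A maximal run of consecutive imbalanced variants in one sample/gene."""

    sample_id: str
    gene: str
    members: tuple[VariantObservation, ...]

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m.key.position for m in self.members)

    @property
    def vafs(self) -> tuple[float, ...]:
        return tuple(m.vaf for m in self.members)

    @property
    def start(self) -> int:
        return self.members[0].key.position

    @property
    def end(self) -> int:
        return self.members[-1].key.position

    def __len__(self) -> int:
        return len(self.members)

    def overlaps(self, other: "ImbalanceRun") -> bool:
        """Share at least one locus with another run in the same gene."""
        if self.gene != other.gene:
            return False
        return bool(set(self.positions) & set(other.positions))


class EventLabel(str, Enum):
    GERMLINE = "germline"
    SOMATIC = "somatic"
    TUMOR_ONLY_UNCLASSIFIED = "tumor_only_unclassified"


@dataclass
class CnvLohEvent:
    """A CNV/LOH call: a tumor imbalance run with its germline/somatic label."""

    patient_id: str
    gene: str
    tumor_run: ImbalanceRun
    normal_run: Optional[ImbalanceRun] = None
    label: EventLabel = EventLabel.TUMOR_ONLY_UNCLASSIFIED
    contains_novel: bool = False

    @property
    def sample_id(self) -> str:
        return self.tumor_run.sample_id

    @property
    def start(self) -> int:
        return self.tumor_run.start

    @property
    def end(self) -> int:
        return self.tumor_run.end

    @property
    def n_variants(self) -> int:
        return len(self.tumor_run)
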