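"""Protein-domain models for the panel genes and mapping of coding variants
onto them (the lollipop-style per-domain tallies).

Default interval boundaries are editable approximations drawn from standard
protein annotations (Pfam/UniProt-style): the MutS domains of the MutS-
homolog mismatch-repair proteins MSH3 (1137 aa) and MSH6 (1360 aa, with its
N-terminal PWWP domain, P-loop NTPase core and C-terminal MSH2-binding
region), and the APC (2843 aa) Armadillo repeats, 15-amino-acid (15R) and
20-amino-acid (20R) beta-catenin-binding repeats and basic region.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import yaml

from .model import DataValidationError, FunctionalClass, VariantKey
from .annotate import TranscriptModel

__all__ = [
    "DomainModel",
    "ProteinVariant",
    "DEFAULT_DOMAIN_MODELS",
    "genomic_to_protein",
    "map_to_domain",
    "tally_domains",
    "load_domain_config",
]


@dataclass(frozen=True)
class DomainInterval:
    label: str
    start: int  # 1-based aa, closed
    end: int


@dataclass
class DomainModel:
    """Ordered, disjoint protein-coordinate intervals for one gene."""

    gene: str
    protein_length: int
    intervals: tuple[DomainInterval, ...]

    def __post_init__(self) -> None:
        ivals = tuple(
            iv if isinstance(iv, DomainInterval) else DomainInterval(*iv)
            for iv in self.intervals
        )
        prev_end = 0
        for iv in ivals:
            if not (1 <= iv.start <= iv.end <= self.protein_length):
                raise DataValidationError(
                    f"{self.gene} interval {iv.label} ({iv.start}-{iv.end}) "
                    f"outside 1..{self.protein_length}"
                )
            if iv.start <= prev_end:
                raise DataValidationError(
                    f"{self.gene} intervals must be sorted and disjoint ({iv.label})"
                )
            prev_end = iv.end
        self.intervals = ivals

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(iv.label for iv in self.intervals)


@dataclass(frozen=True)
class ProteinVariant:
    key: VariantKey
    gene: str
    protein_position: int
    functional_class: Optional[FunctionalClass] = None

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise DataValidationError("protein position must be >= 1")


DEFAULT_DOMAIN_MODELS: dict[str, DomainModel] = {
    "MSH3": DomainModel(
        gene="MSH3",
        protein_length=1137,
        intervals=(
            DomainInterval("EXO1-interaction", 25, 124),
            DomainInterval("MutS_I", 287, 396),
            DomainInterval("MutS_II", 421, 520),
            DomainInterval("MutS_III", 538, 790),
            DomainInterval("MutS_IV", 796, 875),
            DomainInterval("MutS_V", 896, 1113),
        ),
    ),
    "MSH6": DomainModel(
        gene="MSH6",
        protein_length=1360,
        intervals=(
            DomainInterval("PWWP", 92, 152),
            DomainInterval("MutS_I", 362, 518),
            DomainInterval("MutS_II", 540, 650),
            DomainInterval("MutS_III", 676, 934),
            DomainInterval("MutS_IV", 954, 1075),
            DomainInterval("P-loop_NTPase", 1096, 1305),
            DomainInterval("MSH2-binding", 1306, 1355),
        ),
    ),
    "APC": DomainModel(
        gene="APC",
        protein_length=2843,
        intervals=(
            DomainInterval("ARM", 453, 767),
            DomainInterval("15R", 1020, 1169),
            DomainInterval("20R", 1262, 2033),
            DomainInterval("basic region", 2200, 2400),
        ),
    ),
}


def genomic_to_protein(key: VariantKey, transcript: TranscriptModel) -> Optional[int]:
    """1-based amino-acid index of a genomic position, or None outside the
    CDS.  CDS offset o maps to residue ceil(o / 3), consistent with the
    codon indexing of the consequence classifier."""
    if not transcript._in_span(key.position):
        raise DataValidationError(
            f"position {key.position} outside the {transcript.gene} gene span"
        )
    offset = transcript.cds_offset(key.position)
    if offset is None:
        return None
    return math.ceil(offset / 3)


def map_to_domain(pv: ProteinVariant, model: DomainModel) -> str:
    """Label of the domain containing the variant; inter-domain positions
    are reported relative to the next downstream domain ("prior to X")."""
    if model.gene != pv.gene:
        raise DataValidationError(f"domain model is for {model.gene}, variant for {pv.gene}")
    if pv.protein_position > model.protein_length:
        raise DataValidationError(
            f"protein position {pv.protein_position} exceeds {model.gene} "
            f"length {model.protein_length}"
        )
    for iv in model.intervals:
        if iv.start <= pv.protein_position <= iv.end:
            return iv.label
        if pv.protein_position < iv.start:
            return f"prior to {iv.label}"
    return f"after {model.intervals[-1].label}" if model.intervals else "unassigned"


def tally_domains(pvs: Sequence[ProteinVariant], model: DomainModel) -> dict[str, int]:
    """Count variants per domain label (including inter-domain labels).

    Label order is deterministic: domain order first, then inter-domain
    labels in protein-coordinate order.  Counts sum to len(pvs).
    """
    order: list[str] = []
    for iv in model.intervals:
        order.append(f"prior to {iv.label}")
        order.append(iv.label)
    if model.intervals:
        order.append(f"after {model.intervals[-1].label}")
    tally = {label: 0 for label in order}
    for pv in pvs:
        tally[map_to_domain(pv, model)] += 1
    return tally


def load_domain_config(path: str) -> dict[str, DomainModel]:
    """Read domain models from YAML/JSON: {gene: {length: int,
    domains: [[label, start, end], ...]}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    models = {}
    for gene, spec in raw.items():
        models[gene] = DomainModel(
            gene=gene,
            protein_length=int(spec["length"]),
            intervals=tuple(DomainInterval(str(l), int(s), int(e)) for l, s, e in spec["domains"]),
        )
    return models
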