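"""Depth filtering, novelty classification against local variant catalogs,
and a minimal codon-level consequence classifier for panel transcripts.

The novelty rule is the catalog-union rule: a variant present in any
catalog (dbSNP / 1000 Genomes / COSMIC stand-ins alike) is non-novel;
matching is exact on (chromosome, position, ref, alt).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .model import (
    Catalog,
    DataValidationError,
    FunctionalClass,
    VariantKey,
    VariantObservation,
)

DEFAULT_MIN_READS = 10


class ReferenceMismatchError(DataValidationError):
    """The observed ref allele disagrees with the transcript sequence."""


def depth_filter(
    observations: Iterable[VariantObservation], min_reads: int = DEFAULT_MIN_READS
) -> list[VariantObservation]:
    """Keep observations with strictly more than ``min_reads`` total reads.

    The cutoff is exclusive: at the default of 10, a site covered by exactly
    10 reads is dropped and one covered by 11 is retained.
    """
    if min_reads < 0:
        raise DataValidationError(f"min_reads must be >= 0, got {min_reads}")
    return [obs for obs in observations if obs.depth > min_reads]


def classify_novelty(key: VariantKey, catalogs: Sequence[Catalog]) -> bool:
    """True (novel) iff the variant appears in none of the catalogs."""
    return not any(key in catalog for catalog in catalogs)


def annotate_novelty(
    observations: Iterable[VariantObservation], catalogs: Sequence[Catalog]
) -> list[VariantObservation]:
    """Set the ``novel`` flag on every observation, in place."""
    cache: dict[VariantKey, bool] = {}
    out = []
    for obs in observations:
        if obs.key not in cache:
            cache[obs.key] = classify_novelty(obs.key, catalogs)
        obs.novel = cache[obs.key]
        out.append(obs)
    return out


@dataclass
class TranscriptModel:
    """A minimal transcript: ordered CDS intervals on genomic coordinates
    plus the plus-strand reference sequence covering the gene span.

    Intervals are 1-based, fully closed, sorted ascending, non-overlapping,
    and their total length must be a multiple of 3.  For minus-strand genes
    the coding sequence is the reverse complement of the concatenated
    intervals, and variant alleles are complemented before codon lookup.
    """

    gene: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    reference: str
    ref_start: int  # genomic position of reference[0]
    span: Optional[tuple[int, int]] = None  # gene span; defaults to reference extent

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise DataValidationError(f"strand must be + or -, got {self.strand!r}")
        ivals = tuple(tuple(iv) for iv in self.cds_intervals)
        prev_end = 0
        total = 0
        for start, end in ivals:
            if start > end:
                raise DataValidationError(f"CDS interval {start}-{end} is inverted")
            if start <= prev_end:
                raise DataValidationError("CDS intervals must be sorted and non-overlapping")
            prev_end = end
            total += end - start + 1
        if total % 3 != 0:
            raise DataValidationError(f"CDS length {total} not divisible by 3")
        self.cds_intervals = ivals
        if self.span is None:
            self.span = (self.ref_start, self.ref_start + len(self.reference) - 1)
        ref_end = self.ref_start + len(self.reference) - 1
        if ivals and (ivals[0][0] < self.ref_start or ivals[-1][1] > ref_end):
            raise DataValidationError("reference sequence does not cover the CDS")
        self.reference = self.reference.upper()

    # -- coordinate helpers -------------------------------------------------

    def base_at(self, position: int) -> str:
        """Plus-strand reference base at a genomic position."""
        idx = position - self.ref_start
        if idx < 0 or idx >= len(self.reference):
            raise DataValidationError(
                f"position {position} outside reference for {self.gene}"
            )
        return self.reference[idx]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def cds_offset(self, position: int) -> Optional[int]:
        """1-based offset of a genomic position within the spliced CDS, in
        transcript (translation) orientation; None outside the CDS."""
        plus_offset = 0
        for start, end in self.cds_intervals:
            if start <= position <= end:
                plus_offset += position - start + 1
                if self.strand == "+":
                    return plus_offset
                return self.cds_length - plus_offset + 1
            if position < start:
                return None
            plus_offset += end - start + 1
        return None

    def cds_sequence(self) -> str:
        """Spliced coding sequence in translation orientation."""
        seq = "".join(
            self.reference[s - self.ref_start : e - self.ref_start + 1]
            for s, e in self.cds_intervals
        )
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def _noncoding_class(self, position: int) -> FunctionalClass:
        """UTR outside the CDS extent, intronic between CDS intervals."""
        cds_start, cds_end = self.cds_intervals[0][0], self.cds_intervals[-1][1]
        if position < cds_start or position > cds_end:
            return FunctionalClass.UTR
        return FunctionalClass.INTRONIC

    def _in_span(self, position: int) -> bool:
        return self.span[0] <= position <= self.span[1]


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def classify_consequence(key: VariantKey, transcript: TranscriptModel) -> FunctionalClass:
    """Coding consequence of a variant on one transcript.

    SNVs in the CDS are classified by codon comparison (synonymous /
    nonsynonymous / stopgain; loss of the native stop falls into ``other``).
    Indels overlapping the CDS are frameshift when the length change is not
    a multiple of 3, otherwise ``other``.  Positions inside the gene span
    but outside the CDS are intronic (between CDS intervals) or UTR.
    """
    pos = key.position
    if not transcript._in_span(pos):
        raise DataValidationError(
            f"position {pos} outside the {transcript.gene} gene span"
        )
    if key.is_snv:
        offset = transcript.cds_offset(pos)
        if offset is None:
            return transcript._noncoding_class(pos)
        if transcript.base_at(pos) != key.ref.upper():
            raise ReferenceMismatchError(
                f"ref allele {key.ref} does not match transcript base "
                f"{transcript.base_at(pos)} at {key.chromosome}:{pos}"
            )
        cds = transcript.cds_sequence()
        codon_idx = (offset - 1) // 3
        within = (offset - 1) % 3
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        alt = key.alt.upper()
        if transcript.strand == "-":
            alt = alt.translate(_COMPLEMENT)
        mutant = codon[:within] + alt + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutant).translate())
        if aa_ref == aa_alt:
            return FunctionalClass.SYNONYMOUS
        if aa_alt == "*":
            return FunctionalClass.STOPGAIN
        if aa_ref == "*":
            return FunctionalClass.OTHER  # stop-loss: outside the panel's classes
        return FunctionalClass.NONSYNONYMOUS

    # indel: affected reference footprint
    ref_len = 0 if key.ref == "-" else len(key.ref)
    alt_len = 0 if key.alt == "-" else len(key.alt)
    foot_start, foot_end = pos, pos + max(ref_len - 1, 0)
    touches_cds = any(
        not (foot_end < s or foot_start > e) for s, e in transcript.cds_intervals
    )
    if touches_cds:
        if (ref_len - alt_len) % 3 != 0:
            return FunctionalClass.FRAMESHIFT
        return FunctionalClass.OTHER
    return transcript._noncoding_class(pos)


def annotate_consequences(
    observations: Iterable[VariantObservation],
    transcripts: dict[str, TranscriptModel],
) -> list[VariantObservation]:
    """Set functional_class from the gene's transcript where one is known."""
    out = []
    for obs in observations:
        tx = transcripts.get(obs.gene)
        if tx is not None:
            obs.functional_class = classify_consequence(obs.key, tx)
        out.append(obs)
    return out
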