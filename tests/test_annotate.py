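"""Depth filtering, novelty against catalogs, and the consequence classifier."""
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from ampliscan.annotate import (
    ReferenceMismatchError,
    classify_consequence,
    classify_novelty,
    depth_filter,
)
from ampliscan.model import Catalog, DataValidationError, FunctionalClass, VariantKey
from ampliscan.simulate import make_toy_transcript
from conftest import make_obs


@pytest.mark.parametrize(
    "total,min_reads,kept",
    [(10, 10, False), (11, 10, True), (1, 0, True), (0, 0, False)],
)
def test_depth_filter_is_strictly_greater_than(total, min_reads, kept):
    obs = [make_obs("s1", 100, 0.5, depth=total)] if total else []
    if total == 0:
        from ampliscan.model import VariantObservation

        obs = [VariantObservation(VariantKey("chr5", 100, "G", "A"), "s1", "APC", 0, 0)]
    assert bool(depth_filter(obs, min_reads)) is kept


def test_depth_filter_min_zero_keeps_all_covered():
    obs = [make_obs("s1", 100 + i, 0.5, depth=d) for i, d in enumerate([1, 5, 2000])]
    assert depth_filter(obs, 0) == obs


KEY = VariantKey("chr5", 79966029, "G", "A")
OTHER = VariantKey("chr2", 48033545, "A", "C")


def test_novelty_union_rule():
    dbsnp = Catalog("dbSNP", frozenset({KEY}))
    cosmic = Catalog("cosmic", frozenset())
    assert classify_novelty(KEY, [dbsnp, cosmic]) is False  # in any catalog
    assert classify_novelty(OTHER, [dbsnp, cosmic]) is True
    assert classify_novelty(KEY, []) is True  # vacuous union


@settings(max_examples=50, deadline=None)
@given(st.sets(st.integers(min_value=1, max_value=50), max_size=8))
def test_novelty_is_monotone_in_catalog_content(extra_positions):
    """Adding catalog entries never turns a non-novel variant novel."""
    base = Catalog("dbSNP", frozenset({KEY}))
    grown = Catalog(
        "dbSNP",
        base.entries | {VariantKey("chr5", p, "G", "A") for p in extra_positions},
    )
    for key in [KEY, OTHER]:
        if not classify_novelty(key, [base]):
            assert not classify_novelty(key, [grown])


class TestConsequence:
    def test_synonymous_third_position(self):
        # codon GCT (Ala) -> GCC (Ala) via a T>C at CDS offset 6
        tx = make_toy_transcript(seed=7)
        cds = tx.cds_sequence()
        # find any third-position SNV that is synonymous by construction
        for pos in range(tx.ref_start, tx.ref_start + len(tx.reference)):
            off = tx.cds_offset(pos)
            if off is None or off % 3 != 0:
                continue
            codon = cds[off - 3 : off]
            for alt in "ACGT":
                if alt == codon[2]:
                    continue
                if str(Seq(codon[:2] + alt).translate()) == str(Seq(codon).translate()):
                    key = VariantKey("chr1", pos, tx.base_at(pos), alt)
                    assert classify_consequence(key, tx) == FunctionalClass.SYNONYMOUS
                    return
        pytest.fail("toy transcript unexpectedly has no synonymous third-position change")

    def test_stopgain_from_gln_codon(self, toy_tx_plus):
        """A C>T making TAA from CAA (Gln -> stop) is a stopgain."""
        tx = toy_tx_plus
        cds = tx.cds_sequence()
        idx = cds.find("CAA", 3)
        while idx != -1 and idx % 3 != 0:
            idx = cds.find("CAA", idx + 1)
        assert idx > 0, "toy CDS lacks an in-frame CAA codon"
        # genomic position of that first codon base
        pos = [p for p in range(tx.ref_start, tx.ref_start + len(tx.reference))
               if tx.cds_offset(p) == idx + 1][0]
        got = classify_consequence(VariantKey("chr1", pos, "C", "T"), tx)
        assert got == FunctionalClass.STOPGAIN

    def test_two_bp_deletion_is_frameshift(self, toy_tx_plus):
        tx = toy_tx_plus
        start, _ = tx.cds_intervals[0]
        ref = tx.reference[start - tx.ref_start : start - tx.ref_start + 3]
        key = VariantKey("chr1", start, ref, ref[0])  # 2-bp deletion
        assert classify_consequence(key, tx) == FunctionalClass.FRAMESHIFT

    def test_inframe_deletion_is_other(self, toy_tx_plus):
        tx = toy_tx_plus
        start, _ = tx.cds_intervals[0]
        ref = tx.reference[start - tx.ref_start : start - tx.ref_start + 4]
        key = VariantKey("chr1", start, ref, ref[0])  # 3-bp deletion
        assert classify_consequence(key, tx) == FunctionalClass.OTHER

    def test_intronic_and_utr_positions(self, toy_tx_plus):
        tx = toy_tx_plus
        utr_pos = tx.ref_start  # before the CDS
        intron_pos = tx.cds_intervals[0][1] + 5
        ref_u = tx.base_at(utr_pos)
        ref_i = tx.base_at(intron_pos)
        alt_u = "A" if ref_u != "A" else "C"
        alt_i = "A" if ref_i != "A" else "C"
        assert classify_consequence(VariantKey("chr1", utr_pos, ref_u, alt_u), tx) \
            == FunctionalClass.UTR
        assert classify_consequence(VariantKey("chr1", intron_pos, ref_i, alt_i), tx) \
            == FunctionalClass.INTRONIC

    def test_reference_mismatch_is_an_error(self, toy_tx_plus):
        tx = toy_tx_plus
        pos = tx.cds_intervals[0][0]
        wrong_ref = "A" if tx.base_at(pos) != "A" else "C"
        alt = "G" if wrong_ref != "G" else "T"
        with pytest.raises(ReferenceMismatchError):
            classify_consequence(VariantKey("chr1", pos, wrong_ref, alt), tx)

    def test_position_outside_span_rejected(self, toy_tx_plus):
        tx = toy_tx_plus
        with pytest.raises(DataValidationError):
            classify_consequence(VariantKey("chr1", tx.ref_start - 10, "G", "A"), tx)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_classifier_agrees_with_full_translation_oracle(strand):
    """Every SNV of the 30-codon toy transcript, classified codon-locally,
    matches a brute-force oracle that translates the whole mutant CDS."""
    tx = make_toy_transcript(strand=strand)
    cds = tx.cds_sequence()
    prot_ref = str(Seq(cds).translate())
    comp = str.maketrans("ACGT", "TGCA")
    n_checked = 0
    for pos in range(tx.ref_start, tx.ref_start + len(tx.reference)):
        off = tx.cds_offset(pos)
        if off is None:
            continue
        ref = tx.base_at(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            tx_alt = alt.translate(comp) if strand == "-" else alt
            mutant = cds[: off - 1] + tx_alt + cds[off:]
            prot_alt = str(Seq(mutant).translate())
            codon_i = (off - 1) // 3
            if prot_ref == prot_alt:
                want = FunctionalClass.SYNONYMOUS
            elif prot_alt[codon_i] == "*":
                want = FunctionalClass.STOPGAIN
            elif prot_ref[codon_i] == "*":
                want = FunctionalClass.OTHER
            else:
                want = FunctionalClass.NONSYNONYMOUS
            assert classify_consequence(VariantKey("chr1", pos, ref, alt), tx) == want
            n_checked += 1
    assert n_checked == 270  # 90 CDS positions x 3 alternate bases
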