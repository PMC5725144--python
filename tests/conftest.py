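import warnings

import pytest

from ampliscan.model import (
    SampleMeta,
    Tissue,
    VariantKey,
    VariantObservation,
)
from ampliscan.simulate import make_toy_transcript
from ampliscan.tables import make_table2_fixture


def make_obs(sample_id, position, vaf, gene="APC", chrom="chr5", depth=1000,
             ref="G", alt="A", **kwargs):
    """Observation with exact read counts for a requested VAF."""
    var = int(round(depth * vaf))
    return VariantObservation(
        key=VariantKey(chrom, position, ref, alt),
        sample_id=sample_id,
        gene=gene,
        ref_reads=depth - var,
        var_reads=var,
        **kwargs,
    )


@pytest.fixture(scope="session")
def table2():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the packaged all-zero row
        return make_table2_fixture()


@pytest.fixture(scope="session")
def toy_tx_plus():
    return make_toy_transcript(strand="+")


@pytest.fixture(scope="session")
def toy_tx_minus():
    return make_toy_transcript(strand="-")


@pytest.fixture
def tiny_cohort():
    """One tumor-normal pair plus one unpaired adenoma."""
    samples = [
        SampleMeta("p1N", "p1", Tissue.NORMAL, paired_sample_id="p1T"),
        SampleMeta("p1T", "p1", Tissue.CRC, paired_sample_id="p1N"),
        SampleMeta("p2A", "p2", Tissue.ADENOMA),
    ]
    return samples
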