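"""Imbalance-run scanning: brute-force equivalence, maximality, pair
classification and cohort summaries."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampliscan.model import (
    DataValidationError,
    EventLabel,
    SampleMeta,
    ScanParams,
    Tissue,
)
from ampliscan.scan import classify_pair, scan_cohort, scan_sample, summarize
from conftest import make_obs


def brute_force_runs(vafs, params: ScanParams):
    """Oracle: enumerate all maximal qualifying windows of length >= k."""
    n = len(vafs)
    qual = [params.qualifies(v) for v in vafs]
    runs = []
    for i in range(n):
        for j in range(i, n):
            if all(qual[i : j + 1]) and j - i + 1 >= params.k:
                left_ext = i > 0 and qual[i - 1]
                right_ext = j < n - 1 and qual[j + 1]
                if not left_ext and not right_ext:
                    runs.append((i, j))
    return runs


def obs_from_vafs(vafs, sample_id="s1", gene="APC"):
    return [make_obs(sample_id, 1000 + 10 * i, v, gene=gene) for i, v in enumerate(vafs)]


def run_indices(run, vafs):
    positions = [1000 + 10 * i for i in range(len(vafs))]
    return (positions.index(run.start), positions.index(run.end))


def test_minimal_qualifying_run():
    runs = scan_sample(obs_from_vafs([0.7, 0.75, 0.9]))
    assert len(runs) == 1 and len(runs[0]) == 3


def test_interruption_breaks_consecutiveness():
    assert scan_sample(obs_from_vafs([0.7, 0.5, 0.7, 0.7])) == []


def test_empty_input_gives_no_runs():
    assert scan_sample([]) == []


def test_runs_do_not_span_genes():
    obs = obs_from_vafs([0.7, 0.8], gene="APC") + obs_from_vafs([0.9, 0.7], gene="MSH3")
    assert scan_sample(obs) == []
    obs = obs_from_vafs([0.7, 0.8, 0.9], gene="APC") + obs_from_vafs([0.9] * 3, gene="MSH3")
    runs = scan_sample(obs)
    assert sorted(r.gene for r in runs) == ["APC", "MSH3"]


def test_mixed_samples_rejected():
    obs = obs_from_vafs([0.7] * 3, sample_id="a") + obs_from_vafs([0.7] * 3, sample_id="b")
    with pytest.raises(DataValidationError):
        scan_sample(obs)


def test_symmetric_flags_reference_excess():
    vafs = [0.3, 0.35, 0.4]
    assert scan_sample(obs_from_vafs(vafs)) == []
    runs = scan_sample(obs_from_vafs(vafs), ScanParams(symmetric=True))
    assert len(runs) == 1


def test_max_vaf_cap_excludes_homozygous_stretch():
    vafs = [1.0, 1.0, 1.0]
    assert len(scan_sample(obs_from_vafs(vafs))) == 1
    assert scan_sample(obs_from_vafs(vafs), ScanParams(max_vaf=0.9)) == []


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    vafs=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=0, max_size=12),
    tau=st.sampled_from([0.6, 0.7, 0.8]),
    k=st.integers(min_value=1, max_value=4),
)
def test_scan_equals_brute_force(vafs, tau, k):
    params = ScanParams(tau=tau, k=k)
    vafs = [round(v, 3) for v in vafs]
    runs = scan_sample(obs_from_vafs(vafs), params)
    assert [run_indices(r, vafs) for r in runs] == brute_force_runs(vafs, params)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(vafs=st.lists(st.floats(min_value=0.0, max_value=1.0), max_size=12))
def test_monotonicity_in_tau_and_k(vafs):
    """Raising k never increases the number of runs; raising tau never
    increases the number of run-covered variants (a stricter tau can split
    one long run in two, so the run count itself is not the monotone
    quantity for tau)."""
    vafs = [round(v, 3) for v in vafs]
    covered_tau = [
        sum(len(r) for r in scan_sample(obs_from_vafs(vafs), ScanParams(tau=t)))
        for t in (0.6, 0.7, 0.8, 0.9)
    ]
    assert covered_tau == sorted(covered_tau, reverse=True)
    counts_k = [
        len(scan_sample(obs_from_vafs(vafs), ScanParams(k=k))) for k in (1, 2, 3, 4)
    ]
    assert counts_k == sorted(counts_k, reverse=True)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(vafs=st.lists(st.floats(min_value=0.0, max_value=1.0), max_size=12))
def test_runs_are_maximal_and_disjoint(vafs):
    params = ScanParams()
    vafs = [round(v, 3) for v in vafs]
    runs = scan_sample(obs_from_vafs(vafs), params)
    claimed = set()
    for r in runs:
        i, j = run_indices(r, vafs)
        assert all(params.qualifies(v) for v in vafs[i : j + 1])
        if i > 0:
            assert not params.qualifies(vafs[i - 1])
        if j < len(vafs) - 1:
            assert not params.qualifies(vafs[j + 1])
        members = set(range(i, j + 1))
        assert not members & claimed  # each variant in at most one run
        claimed |= members


class TestClassifyPair:
    def _tumor_runs(self):
        return scan_sample(obs_from_vafs([0.72, 0.75, 0.8], sample_id="p1T"))

    def test_normal_imbalance_means_germline(self):
        normal = obs_from_vafs([0.72, 0.72, 0.72], sample_id="p1N")
        events = classify_pair(self._tumor_runs(), normal, "p1")
        assert [e.label for e in events] == [EventLabel.GERMLINE]
        assert events[0].normal_run is not None

    def test_normal_heterozygous_means_somatic(self):
        normal = obs_from_vafs([0.5, 0.5, 0.5], sample_id="p1N")
        events = classify_pair(self._tumor_runs(), normal, "p1")
        assert [e.label for e in events] == [EventLabel.SOMATIC]

    def test_no_normal_coverage_stays_unclassified(self):
        events = classify_pair(self._tumor_runs(), [], "p1")
        assert [e.label for e in events] == [EventLabel.TUMOR_ONLY_UNCLASSIFIED]

    def test_different_patients_rejected(self):
        metas = {
            "p1T": SampleMeta("p1T", "p1", Tissue.CRC),
            "p9N": SampleMeta("p9N", "p9", Tissue.NORMAL),
        }
        normal = obs_from_vafs([0.5] * 3, sample_id="p9N")
        with pytest.raises(DataValidationError, match="different patients"):
            classify_pair(self._tumor_runs(), normal, "p1", metas=metas)

    def test_contains_novel_propagates(self):
        obs = obs_from_vafs([0.72, 0.75, 0.8], sample_id="p1T")
        obs[1].novel = True
        runs = scan_sample(obs)
        events = classify_pair(runs, [], "p1")
        assert events[0].contains_novel is True


def test_scan_cohort_empty():
    events, summary = scan_cohort([], [])
    assert events == [] and summary.total_events == 0
    assert summary.altered_pct == 0 and summary.germline_pct is None


def test_scan_cohort_pairs_and_unpaired(tiny_cohort):
    obs = obs_from_vafs([0.75] * 3, sample_id="p1T")
    obs += obs_from_vafs([0.5] * 3, sample_id="p1N")
    obs += obs_from_vafs([0.9] * 4, sample_id="p2A", gene="MSH6")
    events, summary = scan_cohort(obs, tiny_cohort)
    labels = {e.sample_id: e.label for e in events}
    assert labels == {
        "p1T": EventLabel.SOMATIC,
        "p2A": EventLabel.TUMOR_ONLY_UNCLASSIFIED,
    }
    assert summary.n_samples == 2  # two lesion samples; the normal is not scanned
    assert summary.n_altered == 2
    assert summary.germline_events + summary.somatic_events + summary.unclassified_events \
        == summary.total_events


def test_summary_arithmetic_fixture():
    """30 germline + 9 somatic matched-pair events give the 77% / 23% split."""
    from ampliscan.model import CnvLohEvent, ImbalanceRun

    def fake_event(i, label):
        run = ImbalanceRun("s%d" % i, "APC", tuple(obs_from_vafs([0.7] * 3, f"s{i}")))
        return CnvLohEvent(f"p{i}", "APC", run, label=label)

    events = [fake_event(i, EventLabel.GERMLINE) for i in range(30)]
    events += [fake_event(30 + i, EventLabel.SOMATIC) for i in range(9)]
    summary = summarize(events, n_samples=39)
    assert summary.germline_pct == 77
    assert summary.somatic_pct == 23
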