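"""UMI normalization, length distributions and kinetics fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spacerseq.models import BarcodeSpec
from spacerseq.simulate import simulate_acquisition_reads
from spacerseq.stats import (
    KineticsSeries,
    expected_umi_collisions,
    fit_processing_rate,
    length_distribution,
    normalize_counts,
    summarize_mapping,
)


def calls_df(rows):
    return pd.DataFrame(rows, columns=["sample_id", "umi", "sequence", "length"])


class TestNormalizeCounts:
    def test_duplicates_collapse_to_one_umi(self):
        rows = [("S1", "AAAAA", "ACGT" * 8, 32)] * 5
        out = normalize_counts(calls_df(rows))
        assert out.iloc[0]["raw_reads"] == 5
        assert out.iloc[0]["distinct_umis"] == 1

    def test_distinct_tags_count_separately(self):
        umis = ["AAAAA", "CCCCC", "GGGGG", "TTTTT", "ACGTA"]
        rows = [("S1", u, "ACGT" * 8, 32) for u in umis]
        out = normalize_counts(calls_df(rows))
        assert out.iloc[0]["distinct_umis"] == 5

    def test_invariance_to_global_duplication_factor(self, parent_model,
                                                     genome, barcodes):
        tables = []
        for dup in (1, 4):
            reads, _ = simulate_acquisition_reads(
                parent_model, genome, barcodes, 200, {30: 1.0}, pcr_bias=dup,
                seed=23)
            from spacerseq.calling import call_all, demultiplex
            assigned, _ = demultiplex(reads, barcodes)
            calls, _ = call_all(assigned, parent_model)
            t = normalize_counts(calls)
            tables.append(t.set_index(["sample_id", "sequence"])["distinct_umis"])
        # same events (same seed) at 1x and 4x duplication: identical UMIs
        assert tables[0].equals(tables[1])

    def test_matches_truth_event_counts_up_to_collisions(self, parent_model,
                                                         genome, barcodes):
        reads, truth = simulate_acquisition_reads(
            parent_model, genome, barcodes, 400, {30: 1.0}, seed=29)
        from spacerseq.calling import call_all, demultiplex
        assigned, _ = demultiplex(reads, barcodes)
        calls, _ = call_all(assigned, parent_model)
        out = normalize_counts(calls).set_index(["sample_id", "sequence"])
        want = (truth.drop_duplicates(["sample_id", "spacer", "umi"])
                .groupby(["sample_id", "spacer"]).size())
        got = out["distinct_umis"]
        got.index.names = want.index.names
        assert got.sort_index().equals(want.sort_index())

    def test_empty_input(self):
        out = normalize_counts(calls_df([]))
        assert out.empty


class TestLengthDistribution:
    def test_single_class_is_100_percent(self):
        t = pd.DataFrame([dict(sample_id="S1", sequence=f"seq{i}", length=30,
                               raw_reads=1, distinct_umis=1) for i in range(10)])
        d = length_distribution(t)
        assert d.percent_by_length == {30: 100.0}
        assert d.n_unique == 10

    def test_symmetric_split(self):
        t = pd.DataFrame([dict(sample_id="S1", sequence=f"seq{i}",
                               length=30 + (i % 2), raw_reads=1,
                               distinct_umis=1 + i) for i in range(10)])
        d = length_distribution(t)
        assert d.percent_by_length == {30: 50.0, 31: 50.0}
        assert d.n_unique == 10

    def test_unique_sequences_count_once_regardless_of_abundance(self):
        t = pd.DataFrame([
            dict(sample_id="S1", sequence="A" * 30, length=30,
                 raw_reads=100, distinct_umis=50),
            dict(sample_id="S1", sequence="C" * 31, length=31,
                 raw_reads=1, distinct_umis=1)])
        d = length_distribution(t)
        assert d.percent_by_length == {30: 50.0, 31: 50.0}
        dw = length_distribution(t, abundance_weighted=True)
        assert dw.percent_by_length[30] == pytest.approx(100 * 50 / 51)

    def test_empty_table_gives_empty_distribution(self):
        d = length_distribution(pd.DataFrame(columns=["sample_id", "sequence",
                                                      "length", "distinct_umis"]))
        assert d.n_unique == 0 and d.percent_by_length == {}

    @given(st.lists(st.integers(25, 40), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=50)
    def test_percents_sum_to_100(self, lengths):
        t = pd.DataFrame([dict(sample_id="S1", sequence=f"seq{i}", length=l,
                               raw_reads=1, distinct_umis=1)
                          for i, l in enumerate(lengths)])
        d = length_distribution(t)
        assert sum(d.percent_by_length.values()) == pytest.approx(100.0)

    def test_recovers_generator_weights_within_3se(self, parent_model):
        # unique-sequence percentages estimate the event-length weights
        # only when duplicate protospacer draws are rare, so give the
        # sampler a large site pool (big genome, unconstrained sites)
        from spacerseq.simulate import make_phage_genome
        big = make_phage_genome(100000, gc=0.4, seed=131)
        weights = {30: 0.6, 31: 0.3, 32: 0.1}
        bcs = [BarcodeSpec("S1", "ACG")]
        reads, _ = simulate_acquisition_reads(
            parent_model, big, bcs, 2000, weights, pcr_bias=1,
            require_pam=False, seed=31)
        from spacerseq.calling import call_all, demultiplex
        assigned, _ = demultiplex(reads, bcs)
        calls, _ = call_all(assigned, parent_model)
        d = length_distribution(normalize_counts(calls))
        n = d.n_unique
        for l, w in weights.items():
            se = 100 * (w * (1 - w) / n) ** 0.5
            assert abs(d.percent_by_length[l] - 100 * w) <= 3 * se


def test_summarize_mapping_empty_is_all_zero():
    s = summarize_mapping(pd.DataFrame())
    assert s["n_spacers"] == 0 and s["percent_pam_valid"] == 0.0


def test_expected_umi_collisions_closed_form():
    # n=2 events over M tags collide with probability exactly 1/M
    m = 4 ** 5
    assert expected_umi_collisions(2) == pytest.approx(1 / m)
    assert expected_umi_collisions(0) == pytest.approx(0.0)


class TestKinetics:
    def test_exact_line_recovered(self):
        t = (5, 10, 20, 40, 60, 120)
        series = KineticsSeries(t, (tuple(0.005 * x for x in t),))
        fit = fit_processing_rate(series)
        assert fit["slope_mean"] == pytest.approx(0.005)
        assert fit["intercept_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_flat_series_has_zero_slope(self):
        series = KineticsSeries((5, 10, 20), ((0.4, 0.4, 0.4),))
        assert fit_processing_rate(series)["slope_mean"] == pytest.approx(0.0)

    def test_slope_equals_normal_equations_closed_form(self):
        rng = np.random.default_rng(37)
        t = np.array([5.0, 10, 20, 40, 60, 120])
        reps = tuple(tuple(np.clip(0.004 * t + rng.normal(0, 0.02, t.size),
                                   0, 1)) for _ in range(3))
        fit = fit_processing_rate(KineticsSeries(tuple(t), reps))
        slopes = []
        for y in np.array(reps):
            # closed form from the normal equations
            slopes.append(((t - t.mean()) * (y - y.mean())).sum()
                          / ((t - t.mean()) ** 2).sum())
        assert fit["slope_mean"] == pytest.approx(np.mean(slopes))
        assert fit["slope_sd"] == pytest.approx(np.std(slopes, ddof=1))

    def test_requires_two_timepoints(self):
        with pytest.raises(ValueError):
            fit_processing_rate(KineticsSeries((5,), ((0.1,),)))

    def test_validates_monotone_timepoints_and_fraction_range(self):
        with pytest.raises(ValueError):
            KineticsSeries((10, 5), ((0.1, 0.2),))
        with pytest.raises(ValueError):
            KineticsSeries((5, 10), ((0.1, 1.2),))
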