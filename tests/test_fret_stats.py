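"""FRET efficiencies, bleach QC, Yuen/Holm statistics."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from boxbind.errors import ConfigError, StatError
from boxbind.fret_stats import (
    FretRoi,
    bleach_qc,
    compare_groups,
    fret_efficiency,
    holm_bonferroni,
    trimmed_mean,
    yuen_test,
)
from boxbind.synthetic_data import gen_fret_rois


def roi(dpre, dpost, apre=100.0, apost=5.0, group="WT", rid="r1"):
    return FretRoi(rid, group, dpre, dpost, apre, apost)


class TestEfficiency:
    @pytest.mark.parametrize(
        "dpre, dpost, expected", [(80.0, 100.0, 20.0), (100.0, 100.0, 0.0),
                                  (92.0, 100.0, 8.0), (105.0, 100.0, -5.0)]
    )
    def test_donor_dequenching(self, dpre, dpost, expected):
        assert fret_efficiency(roi(dpre, dpost)) == pytest.approx(expected)

    def test_scale_invariance(self):
        assert fret_efficiency(roi(80.0, 100.0)) == pytest.approx(
            fret_efficiency(roi(80.0 * 7.3, 100.0 * 7.3))
        )

    def test_undefined_without_donor_signal(self):
        with pytest.raises(StatError):
            fret_efficiency(roi(80.0, 0.0))


class TestBleachQc:
    @pytest.mark.parametrize(
        "apost, keep", [(10.0, True), (20.0, False), (15.0, True)]
    )
    def test_threshold_is_inclusive(self, apost, keep):
        assert bleach_qc(roi(80, 100, apre=100.0, apost=apost)) is keep

    def test_monotone_in_threshold(self):
        r = roi(80, 100, apre=100.0, apost=12.0)
        kept = [bleach_qc(r, m) for m in (0.95, 0.88, 0.85, 0.5)]
        # once kept at a strict threshold, always kept at looser ones
        assert kept == sorted(kept)


class TestTrimmedMean:
    def test_by_definition(self):
        assert trimmed_mean([1, 2, 3, 4, 100], 0.2) == pytest.approx(3.0)

    def test_zero_trim_is_arithmetic_mean(self, rng):
        x = rng.normal(size=31)
        assert trimmed_mean(x, 0.0) == pytest.approx(x.mean())

    def test_symmetric_data_unchanged_by_trimming(self):
        x = np.concatenate([np.arange(-10, 11)] * 2).astype(float)
        for g in (0.0, 0.1, 0.2, 0.4):
            assert trimmed_mean(x, g) == pytest.approx(0.0, abs=1e-12)


class TestYuen:
    def test_identical_samples(self, rng):
        x = rng.normal(size=20)
        res = yuen_test(x, x.copy(), 0.2)
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_zero_trim_equals_welch(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(5, 60))
            y = rng.normal(0.3, 2, rng.integers(5, 60))
            ours = yuen_test(x, y, 0.0)
            welch = stats.ttest_ind(x, y, equal_var=False)
            assert ours.t_statistic == pytest.approx(welch.statistic, abs=1e-10)
            assert ours.p_value == pytest.approx(welch.pvalue, abs=1e-10)

    def test_matches_trimmed_ttest_oracle(self, rng):
        for gamma in (0.1, 0.2):
            x = rng.normal(0, 1, 37)
            y = rng.normal(0.5, 2, 52)
            ours = yuen_test(x, y, gamma)
            ref = stats.ttest_ind(x, y, trim=gamma, equal_var=False)
            assert ours.t_statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_antisymmetric_in_sample_order(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(1, 1, 18)
        ab = yuen_test(x, y, 0.2)
        ba = yuen_test(y, x, 0.2)
        assert ab.t_statistic == pytest.approx(-ba.t_statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_robust_to_gross_outlier(self, rng):
        x = rng.normal(0.0, 1.0, 10)
        y = rng.normal(0.5, 1.0, 10)
        y_out = y.copy()
        y_out[0] = 500.0
        shift_yuen = abs(
            yuen_test(x, y, 0.2).p_value - yuen_test(x, y_out, 0.2).p_value
        )
        shift_welch = abs(
            yuen_test(x, y, 0.0).p_value - yuen_test(x, y_out, 0.0).p_value
        )
        assert shift_yuen < shift_welch

    def test_group_size_precondition(self, rng):
        with pytest.raises(StatError):
            yuen_test(rng.normal(size=4), rng.normal(size=10), 0.2)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03]) == pytest.approx([0.03])

    def test_step_down_hand_example(self):
        # sorted p: 0.01, 0.03, 0.04; multipliers 3, 2, 1; cumulative max
        got = holm_bonferroni([0.01, 0.04, 0.03])
        assert got == pytest.approx([0.03, 0.06, 0.06])
        assert got == pytest.approx(
            multipletests([0.01, 0.04, 0.03], method="holm")[1]
        )

    def test_all_ones(self):
        assert holm_bonferroni([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_dominates_raw_and_idempotent(self, rng):
        p = rng.uniform(size=12)
        adj = holm_bonferroni(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert holm_bonferroni(adj) == pytest.approx(adj)

    def test_rejects_invalid_p(self):
        with pytest.raises(StatError):
            holm_bonferroni([0.1, 1.5])


class TestCompareGroups:
    def test_recovers_group_difference(self):
        ds = gen_fret_rois(
            [("WT", 8.0, 116, 3.0), ("Cla", 5.0, 98, 3.0)], seed=42
        )
        comp = compare_groups(ds.table, "WT")
        t = comp.table.set_index("group")
        assert t.loc["WT", "trimmed_mean_pct"] == pytest.approx(8.0, abs=1.0)
        assert t.loc["Cla", "trimmed_mean_pct"] == pytest.approx(5.0, abs=1.0)
        assert t.loc["Cla", "p_adj_vs_reference"] < 0.001
        assert "*" in t.loc["Cla", "stars"]

    def test_qc_drops_underbleached_rois(self):
        ds = gen_fret_rois(
            [("WT", 8.0, 50, 3.0), ("Mut", 8.0, 50, 3.0)],
            bleach_mean=0.86, bleach_sd=0.05, seed=3,
        )
        comp = compare_groups(ds.table, "WT")
        assert len(comp.dropped) > 0
        assert int(comp.table["n_kept"].sum()) + len(comp.dropped) == 100

    def test_missing_reference_group(self):
        ds = gen_fret_rois([("A", 8.0, 20, 3.0)], seed=0)
        with pytest.raises(ConfigError):
            compare_groups(ds.table, "WT")
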