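"""Population-level analyses: z-medians, group contrasts, tallies, radius
standardization, covariate correlations."""

import numpy as np
import pytest

import followerkit as fk
from followerkit.exceptions import InvalidParameterError
from followerkit.follower_stats import MeanZResult
from followerkit.population import PopulationSummary, display_percent


def _result(mean_z, label="neutral", cell=0):
    return MeanZResult(
        cell=cell, z_values=np.array([mean_z]), mean_z=mean_z, label=label,
        thresholds=fk.REFERENCE_THRESHOLDS, null_median=0.0, n_trials=10,
    )


class TestFovZMedian:
    def test_small_examples(self):
        assert fk.fov_zmedian([_result(0.0)] * 3) == 0.0
        assert fk.fov_zmedian([_result(m) for m in (-0.2, 0.1, 0.3)]) == \
            pytest.approx(0.1)

    def test_invariant_to_cell_order_and_robust_to_outlier(self):
        vals = [-0.4, -0.1, 0.0, 0.2, 0.5]
        base = fk.fov_zmedian([_result(m) for m in vals])
        shuffled = fk.fov_zmedian([_result(m) for m in reversed(vals)])
        outlier = fk.fov_zmedian([_result(m) for m in vals[:-1] + [50.0]])
        assert base == shuffled == outlier

    def test_mean_available_as_option(self):
        res = [_result(m) for m in (0.0, 0.0, 3.0)]
        assert fk.fov_zmedian(res, statistic="mean") == pytest.approx(1.0)

    def test_empty_fov_rejected(self):
        with pytest.raises(InvalidParameterError):
            fk.fov_zmedian([])


class TestCompareZMedians:
    def test_identical_groups_p_near_one(self):
        g = np.array([-0.1, 0.0, 0.2, 0.4])
        stat, p = fk.compare_zmedians(g, g)
        assert p == pytest.approx(1.0)

    def test_fully_separated_19_vs_47_extreme_tail(self):
        sham = np.linspace(-1.0, -0.5, 19)
        stim = np.linspace(0.5, 1.0, 47)
        stat, p = fk.compare_zmedians(sham, stim)
        assert stat > 0  # stim stochastically larger
        assert p < 1e-9

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            fk.compare_zmedians([], [0.1])


class TestChi2:
    def test_effective_stimulator_table_reproduces_printed_p(self):
        chi2, p = fk.chi2_2x2(4, 19, 5, 14)
        assert round(p, 2) == 0.35
        # hand-evaluated Pearson value from expected counts
        assert chi2 == pytest.approx(0.874, abs=2e-3)

    def test_equal_proportions_give_zero_statistic(self):
        chi2, p = fk.chi2_2x2(5, 10, 5, 10)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidParameterError):
            fk.chi2_2x2(0, 10, 0, 20)
        with pytest.raises(InvalidParameterError):
            fk.chi2_2x2(10, 10, 20, 20)


class TestTally:
    def _summary(self, group, n_cells, n_exc, n_inh=0):
        return PopulationSummary(
            z_median=0.0, group=group, n_cells=n_cells, n_excited=n_exc,
            n_inhibited=n_inh,
        )

    def test_display_matches_printed_precision(self):
        assert display_percent(4, 796) == "0.5"
        assert display_percent(8, 832) == "0.96"
        assert display_percent(4, 19) == "21.1"
        assert display_percent(5, 14) == "35.7"

    def test_pooled_percentages(self):
        fovs = [self._summary("anesthetized", 400, 2, 1),
                self._summary("anesthetized", 396, 1, 0),
                self._summary("awake", 832, 6, 2)]
        df = fk.tally_study(fovs)
        an = df.loc["anesthetized"]
        assert an["n_cells"] == 796 and an["n_followers"] == 4
        assert an["percent_followers_display"] == "0.5"
        assert an["n_effective_stimulators"] == 2
        aw = df.loc["awake"]
        assert aw["percent_followers_display"] == "0.96"
        assert aw["percent_followers"] == pytest.approx(100 * 8 / 832)

    def test_no_followers_anywhere(self):
        df = fk.tally_study([self._summary("sham", 100, 0)])
        assert df.loc["sham", "percent_followers"] == 0.0
        assert df.loc["sham", "n_effective_stimulators"] == 0

    def test_effective_stimulator_flag(self):
        assert self._summary("g", 10, 1).effective_stimulator
        assert not self._summary("g", 10, 0).effective_stimulator


class TestRadiusFilter:
    def _rec(self, distances):
        n = len(distances) + 1
        pos = np.zeros((n, 2))
        pos[1:, 0] = distances
        sched = fk.make_schedule(n_trials=2)
        traces = np.ones((n, int(sched.end * 10) + 20))
        return fk.FovRecording(
            traces=traces, frame_rate=10.0, schedule=sched, patched_cell=0,
            cell_positions=pos,
        )

    def test_drops_cells_beyond_cutoff(self):
        rec = self._rec([100.0, 160.0])
        filtered, ok = fk.radius_filter(rec, 150.0)
        assert filtered.n_cells == 2  # patched cell + the 100 um cell
        assert ok  # FOV extends beyond 150 um
        assert filtered.patched_cell == 0

    def test_small_fov_flagged_for_exclusion(self):
        rec = self._rec([50.0, 80.0])
        filtered, ok = fk.radius_filter(rec, 150.0)
        assert filtered.n_cells == 3 and not ok

    def test_infinite_cutoff_is_identity(self):
        rec = self._rec([100.0, 160.0])
        filtered, ok = fk.radius_filter(rec, np.inf)
        assert filtered.n_cells == rec.n_cells and ok

    def test_missing_positions_rejected(self, small_fov):
        with pytest.raises(InvalidParameterError):
            fk.radius_filter(small_fov, 150.0)


class TestCovariateCorrelation:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r, p = fk.covariate_correlation(x, 2 * x)
        assert r == pytest.approx(1.0)

    def test_independent_draws_near_zero(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        r, p = fk.covariate_correlation(x, y)
        assert abs(r) < 0.08

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            fk.covariate_correlation(np.ones(5), np.arange(5.0))
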