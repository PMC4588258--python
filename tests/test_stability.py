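"""Stability curves, sliding-window slopes, inflection detection, baselines."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from mbratools.beta_diversity import DistanceMatrix, distance_matrix
from mbratools.errors import InsufficientDataError
from mbratools import stability as st


def _dm_from_sim(sim_matrix, ids):
    return DistanceMatrix(ids, 1.0 - np.asarray(sim_matrix), "bray_curtis")


def _identical_days_dm(n):
    d = np.zeros((n, n))
    ids = [f"d{i}" for i in range(1, n + 1)]
    return DistanceMatrix(ids, d, "bray_curtis"), {i + 1: ids[i] for i in range(n)}


class TestSimilarityCurve:
    def test_identical_samples_give_flat_curve_at_one(self):
        dm, day_map = _identical_days_dm(5)
        curve = st.similarity_curve(dm, day_map, "v")
        assert np.allclose(curve.mean_similarity, 1.0)

    def test_aberrant_day_scores_lowest(self):
        n = 5
        d = np.zeros((n, n))
        d[2, :] = d[:, 2] = 0.8
        d[2, 2] = 0.0
        ids = [f"d{i}" for i in range(n)]
        dm = DistanceMatrix(ids, d, "bray_curtis")
        curve = st.similarity_curve(dm, {i + 1: ids[i] for i in range(n)}, "v")
        assert np.argmin(curve.mean_similarity) == 2

    def test_too_few_days_raises(self):
        dm, day_map = _identical_days_dm(2)
        with pytest.raises(InsufficientDataError):
            st.similarity_curve(dm, day_map, "v")

    def test_values_bounded_by_pairwise_extremes(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.1, 0.9, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"d{i}" for i in range(6)]
        dm = DistanceMatrix(ids, d, "bray_curtis")
        curve = st.similarity_curve(dm, {i + 1: ids[i] for i in range(6)}, "v")
        sims = 1 - d[np.triu_indices(6, 1)]
        assert curve.mean_similarity.min() >= sims.min() - 1e-12
        assert curve.mean_similarity.max() <= sims.max() + 1e-12


class TestWindowSlopes:
    def _curve(self, days, values):
        return st.StabilityCurve("v", np.asarray(days), np.asarray(values, float))

    def test_linear_curve_recovers_slope_everywhere(self):
        days = np.arange(1, 9)
        curve = self._curve(days, 0.1 + 0.13 * days)
        st.window_slopes(curve)
        valid = ~np.isnan(curve.window_slopes)
        assert np.allclose(curve.window_slopes[valid], 0.13)

    def test_flat_curve_has_zero_slopes(self):
        curve = self._curve(range(1, 7), [0.5] * 6)
        st.window_slopes(curve)
        valid = ~np.isnan(curve.window_slopes)
        assert np.allclose(curve.window_slopes[valid], 0.0)

    def test_three_point_hand_ols(self):
        curve = self._curve([1, 2, 3], [0.2, 0.4, 0.6])
        st.window_slopes(curve)
        assert curve.window_slopes[1] == pytest.approx(0.2)

    def test_window_must_fit(self):
        curve = self._curve([1, 2], [0.1, 0.2])
        with pytest.raises(InsufficientDataError):
            st.window_slopes(curve)
        with pytest.raises(ValueError):
            st.window_slopes(self._curve([1, 2, 3, 4], [0.1] * 4), window=4)


class TestInflectionDay:
    def _with_slopes(self, days, slopes):
        curve = st.StabilityCurve(
            "v", np.asarray(days), np.zeros(len(days)),
            window_slopes=np.asarray(slopes, float),
        )
        return curve

    def test_first_positive_to_nonpositive_transition(self):
        curve = self._with_slopes([4, 5, 6, 7, 8], [0.1, 0.2, 0.1, -0.05, -0.1])
        assert st.inflection_day(curve) == 7

    def test_zero_slope_counts_as_nonpositive(self):
        curve = self._with_slopes([2, 3, 4, 5], [0.1, 0.2, 0.0, -0.1])
        assert st.inflection_day(curve) == 4

    def test_strictly_increasing_curve_has_none(self):
        curve = self._with_slopes([1, 2, 3, 4], [0.1, 0.2, 0.1, 0.3])
        assert st.inflection_day(curve) is None

    def test_requires_positive_run_before_crossing(self):
        # a lone positive window before the dip does not qualify
        curve = self._with_slopes([1, 2, 3, 4, 5, 6],
                                  [0.1, -0.1, 0.1, 0.2, -0.1, 0.0])
        assert st.inflection_day(curve) == 5
        assert curve.all_crossings == [5]


class TestIntervalSimilarity:
    def test_identical_samples_every_gap_is_one(self):
        dm, day_map = _identical_days_dm(6)
        res = st.interval_similarity(dm, {"v": day_map}, range(1, 7), "w")
        assert np.allclose(res.means, 1.0)
        assert np.allclose(res.sds, 0.0)

    def test_day_window_gap_combinatorics(self):
        dm, day_map = _identical_days_dm(13)
        res = st.interval_similarity(dm, {"v": day_map}, range(8, 14), "stable")
        assert list(res.gaps) == [1, 2, 3, 4, 5]

    def test_window_needs_two_days(self):
        dm, day_map = _identical_days_dm(6)
        with pytest.raises(InsufficientDataError):
            st.interval_similarity(dm, {"v": day_map}, [3], "w")


class TestCompareWindows:
    def _interval(self, label, values_by_gap):
        gaps = np.asarray(sorted(values_by_gap))
        vals = {g: np.asarray(values_by_gap[g], float) for g in gaps}
        means = np.asarray([vals[g].mean() for g in gaps])
        sds = np.asarray([vals[g].std(ddof=1) for g in gaps])
        return st.IntervalSimilarity(label, gaps, means, sds, vals)

    def test_matches_scipy_on_toy(self):
        a = [0.5, 0.6, 0.7]
        b = [0.8, 0.9, 1.0]
        res = st.compare_windows(
            self._interval("transitioning", {1: a}),
            self._interval("stable", {1: b}),
        )
        t_ref, p_ref = scipy_stats.ttest_ind(a, b, equal_var=True)
        assert res.loc[0, "t"] == pytest.approx(t_ref)
        assert res.loc[0, "p"] == pytest.approx(p_ref)
        # hand value: pooled sd 0.1, se = 0.1*sqrt(2/3)
        assert res.loc[0, "t"] == pytest.approx(-0.3 / (0.1 * np.sqrt(2 / 3)))

    def test_shifted_means_tiny_variance_significant(self):
        rng = np.random.default_rng(1)
        a = 0.5 + rng.normal(0, 0.001, 10)
        b = 0.9 + rng.normal(0, 0.001, 10)
        res = st.compare_windows(
            self._interval("transitioning", {1: list(a)}),
            self._interval("stable", {1: list(b)}),
        )
        assert res.loc[0, "p"] < 1e-3

    def test_underpowered_gap_skipped(self):
        res = st.compare_windows(
            self._interval("transitioning", {1: [0.5, 0.6], 2: [0.4]}),
            self._interval("stable", {1: [0.8, 0.9], 2: [0.7, 0.8]}),
        )
        assert list(res["gap"]) == [1]


class TestTechnicalBaseline:
    def test_identical_pairs_give_one(self):
        dm, _ = _identical_days_dm(4)
        mean, sd = st.technical_baseline(dm, [("d1", "d2"), ("d3", "d4")])
        assert (mean, sd) == (1.0, 0.0)

    def test_hand_arithmetic(self):
        ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
        d = np.zeros((6, 6))
        pairs = {(0, 1): 0.10, (2, 3): 0.15, (4, 5): 0.14}
        for (i, j), v in pairs.items():
            d[i, j] = d[j, i] = v
        # fill remaining off-diagonal entries arbitrarily but symmetrically
        for i in range(6):
            for j in range(i + 1, 6):
                if d[i, j] == 0:
                    d[i, j] = d[j, i] = 0.5
        dm = DistanceMatrix(ids, d, "bray_curtis")
        mean, sd = st.technical_baseline(
            dm, [("a1", "a2"), ("b1", "b2"), ("c1", "c2")]
        )
        assert mean == pytest.approx(0.87)
        assert sd == pytest.approx(0.02646, abs=1e-4)

    def test_no_pairs_raises(self):
        dm, _ = _identical_days_dm(3)
        with pytest.raises(InsufficientDataError):
            st.technical_baseline(dm, [])


@pytest.mark.parametrize("tau", [6, 8, 10])
def test_inflection_recovers_planted_stabilization_day(tau):
    """Median detected inflection lies within one day of planted tau,
    across 50 independent default-size simulated studies."""
    from mbratools import synthetic_data as sd

    detected = []
    for seed in range(50):
        study = sd.simulate_study(sd.SimConfig(seed=1000 * tau + seed, tau=tau))
        dm = distance_matrix(study.table, "bray_curtis", 10_000,
                             seed=2_000_000 + seed)
        for vessel, day_map in sorted(
            st.vessel_day_samples(study.table.metadata).items()
        ):
            curve = st.similarity_curve(dm, day_map, vessel)
            st.window_slopes(curve)
            day = st.inflection_day(curve)
            if day is not None:
                detected.append(day)
    assert abs(np.median(detected) - tau) <= 1


class TestOnSimulatedStudy:
    def test_curve_rises_then_plateaus(self, small_study):
        dm = distance_matrix(small_study.table, "bray_curtis", 2_000, seed=5)
        vm = st.vessel_day_samples(small_study.table.metadata)
        vessel, day_map = sorted(vm.items())[0]
        curve = st.similarity_curve(dm, day_map, vessel)
        early = curve.mean_similarity[:3].mean()
        late = curve.mean_similarity[-8:].mean()
        assert late > early

    def test_stable_window_beats_transitioning_at_every_gap(self, default_study):
        dm = distance_matrix(default_study.table, "bray_curtis", 10_000, seed=6)
        vm = st.vessel_day_samples(default_study.table.metadata)
        trans = st.interval_similarity(dm, vm, range(2, 8), "transitioning")
        stable = st.interval_similarity(dm, vm, range(8, 14), "stable")
        common = sorted(set(trans.values) & set(stable.values))
        for gap in common:
            assert stable.values[gap].mean() > trans.values[gap].mean()

    def test_technical_noise_below_day_to_day_variation(self, default_study):
        # resequencing the same latent state must look more similar than
        # consecutive stable days, which add biological fluctuation
        from mbratools import synthetic_data as sd
        from mbratools.beta_diversity import bray_curtis

        latent = default_study.latent["A1"][10]
        tech = [
            1 - bray_curtis(
                sd.sequence_sample(latent, 10_000, 2 * k),
                sd.sequence_sample(latent, 10_000, 2 * k + 1),
            )
            for k in range(5)
        ]
        dm = distance_matrix(default_study.table, "bray_curtis", 10_000, seed=7)
        vm = st.vessel_day_samples(default_study.table.metadata)
        stable = st.interval_similarity(dm, vm, range(8, 22), "stable")
        stable_mean = np.concatenate(list(stable.values.values())).mean()
        assert np.mean(tech) > stable_mean
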