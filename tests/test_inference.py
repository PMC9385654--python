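import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import paleoveg as pv
from paleoveg.bnn import forward

from conftest import make_trace


@pytest.fixture()
def small_setup():
    cfg = pv.BNNConfig(n_taxa=2, n_stages=3, hidden_layout=(4,))
    rng = np.random.default_rng(0)
    n = 12
    data = pv.ModelData(
        tensor=pv.BioticDistanceTensor(
            delta_s=rng.uniform(0, 1, (n, 2, 3)),
            delta_t=rng.uniform(0, 1, (n, 2, 3)),
            taxa=["a", "b"],
            groups=["mammal", "plant"],
        ),
        abiotic=pv.FeatureMatrix(
            values=rng.uniform(0, 1, (n, 8)),
            feature_names=list(pv.ABIOTIC_FEATURE_NAMES),
        ),
    )
    return cfg, data, rng


class TestPosteriorProbs:
    def test_single_sample_trace_equals_that_samples_softmax(self, small_setup):
        cfg, data, rng = small_setup
        vec = rng.normal(size=cfg.n_weights)
        trace = make_trace(cfg, [vec])
        result = pv.posterior_probs(trace, data)
        np.testing.assert_allclose(
            result.pp, forward(pv.WeightSample(cfg, vec), data), atol=1e-12
        )

    def test_mean_of_two_samples(self, small_setup):
        cfg, data, rng = small_setup
        v1, v2 = rng.normal(size=(2, cfg.n_weights))
        trace = make_trace(cfg, [v1, v2])
        result = pv.posterior_probs(trace, data)
        expected = 0.5 * (
            forward(pv.WeightSample(cfg, v1), data)
            + forward(pv.WeightSample(cfg, v2), data)
        )
        np.testing.assert_allclose(result.pp, expected, atol=1e-12)

    def test_matches_loop_over_samples_oracle(self, small_setup):
        cfg, data, rng = small_setup
        vectors = rng.normal(size=(7, cfg.n_weights))
        trace = make_trace(cfg, vectors)
        result = pv.posterior_probs(trace, data)
        probs = [forward(pv.WeightSample(cfg, v), data) for v in vectors]
        np.testing.assert_allclose(result.pp, np.mean(probs, axis=0), atol=1e-12)
        expected_classes = np.stack([p.argmax(axis=1) for p in probs], axis=1)
        np.testing.assert_array_equal(result.per_sample_class, expected_classes)

    def test_empty_post_burnin_is_an_error(self, small_setup):
        cfg, data, rng = small_setup
        trace = make_trace(cfg, [rng.normal(size=cfg.n_weights)])
        trace.burnin_cutoff = 10**9
        with pytest.raises(ValueError, match="post-burn-in"):
            pv.posterior_probs(trace, data)


def brute_force_threshold(pp_open, labels, target, step=0.01):
    """Exhaustive grid scan, kept deliberately naive."""
    pp_open = np.asarray(pp_open)
    labels = np.asarray(labels)
    winning = np.maximum(pp_open, 1 - pp_open)
    correct = (pp_open >= 0.5).astype(int) == labels
    grid = [round(0.5 + k * step, 10) for k in range(int(round(0.5 / step)) + 1)]
    for t in grid:
        kept = winning >= t
        if kept.sum() and correct[kept].mean() >= target:
            return t, kept.mean()
    return 1.0, 0.0


class TestCalibration:
    def test_perfectly_classified_set_keeps_everything(self):
        pp = np.array([0.9, 0.8, 0.1, 0.05])
        labels = np.array([1, 1, 0, 0])
        assert pv.calibrate_threshold(pp, labels) == (0.5, 1.0)

    def test_unattainable_target_sets_threshold_to_one(self):
        pp = np.array([0.9, 0.9])
        labels = np.array([0, 0])  # every prediction wrong
        assert pv.calibrate_threshold(pp, labels) == (1.0, 0.0)

    def test_worked_three_instance_example(self):
        # winning PPs {0.95 correct, 0.91 correct, 0.65 wrong}, target 0.9
        pp_open = np.array([0.95, 0.09, 0.65])
        labels = np.array([1, 0, 0])
        threshold, retained = pv.calibrate_threshold(pp_open, labels, 0.9)
        assert threshold == pytest.approx(0.66)
        assert retained == pytest.approx(2 / 3)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 40)
        pp = rng.uniform(0, 1, n)
        labels = rng.integers(0, 2, n)
        target = rng.uniform(0.6, 0.99)
        assert pv.calibrate_threshold(pp, labels, target) == pytest.approx(
            brute_force_threshold(pp, labels, target)
        )

    def test_retained_accuracy_meets_target_when_threshold_below_one(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            pp = rng.uniform(0, 1, 25)
            labels = rng.integers(0, 2, 25)
            threshold, _ = pv.calibrate_threshold(pp, labels, 0.85)
            if threshold < 1.0:
                kept = np.maximum(pp, 1 - pp) >= threshold
                correct = (pp >= 0.5).astype(int) == labels
                assert correct[kept].mean() >= 0.85

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            pv.calibrate_threshold(np.array([]), np.array([]))


class TestPredictGrid:
    def make_prediction(self, threshold, small_setup):
        cfg, data, _ = small_setup
        data.scaling = object()  # marks the features as scaled
        vectors = np.random.default_rng(123).normal(size=(5, cfg.n_weights))
        trace = make_trace(cfg, vectors)
        grid_table = pd.DataFrame(
            {
                "lon": np.arange(data.n_instances, dtype=float),
                "lat": np.zeros(data.n_instances),
                "age_ma": np.zeros(data.n_instances),
            }
        )
        return pv.predict_grid(trace, data, grid_table, threshold=threshold)

    def test_threshold_half_leaves_no_unknowns(self, small_setup):
        frame, _ = self.make_prediction(0.5, small_setup)
        assert not (frame["class"] == "unknown").any()

    def test_threshold_one_makes_everything_unknown(self, small_setup):
        frame, result = self.make_prediction(1.0, small_setup)
        if (result.winning_pp < 1.0).all():
            assert (frame["class"] == "unknown").all()

    def test_unknown_count_is_monotone_in_the_threshold(self, small_setup):
        counts = []
        for threshold in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0):
            frame, _ = self.make_prediction(threshold, small_setup)
            counts.append(int((frame["class"] == "unknown").sum()))
        assert counts == sorted(counts)

    def test_identical_samples_equal_single_sample_prediction(self, small_setup):
        cfg, data, rng = small_setup
        data.scaling = object()
        vec = rng.normal(size=cfg.n_weights)
        trace5 = make_trace(cfg, np.tile(vec, (5, 1)))
        trace1 = make_trace(cfg, [vec])
        grid_table = pd.DataFrame(
            {"lon": np.zeros(data.n_instances),
             "lat": np.zeros(data.n_instances),
             "age_ma": np.zeros(data.n_instances)}
        )
        f5, _ = pv.predict_grid(trace5, data, grid_table, 0.7)
        f1, _ = pv.predict_grid(trace1, data, grid_table, 0.7)
        pd.testing.assert_frame_equal(f5, f1)

    def test_unscaled_features_are_refused(self, small_setup):
        cfg, data, rng = small_setup
        trace = make_trace(cfg, [rng.normal(size=cfg.n_weights)])
        grid_table = pd.DataFrame({"lon": [0.0], "lat": [0.0], "age_ma": [0.0]})
        with pytest.raises(ValueError, match="unscaled"):
            pv.predict_grid(trace, data, grid_table, 0.5)


def brute_force_hpd(samples, mass):
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = int(np.ceil(mass * n))
    best = None
    for start in range(n - m + 1):
        width = x[start + m - 1] - x[start]
        if best is None or width < best[0]:
            best = (width, (x[start], x[start + m - 1]))
    return best[1]


class TestHPD:
    def test_identical_samples_give_a_point_interval(self):
        assert pv.hpd_interval([3.0] * 10) == (3.0, 3.0)

    def test_uniform_grid_spans_95_consecutive_values(self):
        lo, hi = pv.hpd_interval(np.arange(100.0), 0.95)
        assert hi - lo == 94.0

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        assert pv.hpd_interval(x) == pv.hpd_interval(rng.permutation(x))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_exhaustive_shortest_window(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 60)
        x = rng.normal(size=n)
        mass = rng.uniform(0.5, 0.99)
        assert pv.hpd_interval(x, mass) == pytest.approx(brute_force_hpd(x, mass))

    def test_single_sample_degenerates(self):
        assert pv.hpd_interval([1.5]) == (1.5, 1.5)


class TestOpenFractionSeries:
    def test_all_open_everywhere(self):
        classes = {0.0: np.ones((10, 4), dtype=int), 1.0: np.ones((10, 4), dtype=int)}
        series = pv.open_fraction_series(classes)
        np.testing.assert_array_equal(series.mean_fraction, [1.0, 1.0])
        np.testing.assert_array_equal(series.hpd_low, [1.0, 1.0])
        np.testing.assert_array_equal(series.hpd_high, [1.0, 1.0])

    def test_half_open_gives_exactly_half_with_zero_width_band(self):
        block = np.zeros((10, 6), dtype=int)
        block[:5] = 1
        series = pv.open_fraction_series({0.0: block})
        assert series.mean_fraction[0] == 0.5
        assert series.hpd_low[0] == series.hpd_high[0] == 0.5

    def test_matches_per_sample_cell_counting(self):
        rng = np.random.default_rng(6)
        classes = {a: rng.integers(0, 2, (30, 8)) for a in (0.0, 1.0, 2.0)}
        series = pv.open_fraction_series(classes)
        for k, age in enumerate(series.ages):
            per_sample = [
                np.mean([classes[age][c, s] == 1 for c in range(30)])
                for s in range(8)
            ]
            assert series.mean_fraction[k] == pytest.approx(np.mean(per_sample))
            assert (series.hpd_low[k], series.hpd_high[k]) == pytest.approx(
                brute_force_hpd(per_sample, 0.95)
            )

    def test_land_mask_restricts_the_denominator(self):
        block = np.ones((4, 3), dtype=int)
        block[2:] = 0  # two open cells, two closed cells
        mask = np.array([True, True, True, False])
        series = pv.open_fraction_series({0.0: block}, {0.0: mask})
        assert series.mean_fraction[0] == pytest.approx(2 / 3)

    def test_empty_land_mask_is_an_error(self):
        with pytest.raises(ValueError, match="land mask"):
            pv.open_fraction_series(
                {0.0: np.ones((3, 2), dtype=int)}, {0.0: np.zeros(3, dtype=bool)}
            )

    def test_fraction_is_invariant_to_cell_order(self):
        rng = np.random.default_rng(7)
        block = rng.integers(0, 2, (20, 5))
        s1 = pv.open_fraction_series({0.0: block})
        s2 = pv.open_fraction_series({0.0: block[rng.permutation(20)]})
        np.testing.assert_array_equal(s1.mean_fraction, s2.mean_fraction)


class TestExpansionRate:
    def make_series(self, ages, means):
        n = len(ages)
        return pv.OpenFractionSeries(
            ages=np.asarray(ages, dtype=float),
            mean_fraction=np.asarray(means, dtype=float),
            hpd_low=np.zeros(n),
            hpd_high=np.ones(n),
            fractions=np.zeros((n, 1)),
        )

    def test_constant_series_has_zero_rate(self):
        series = self.make_series([0, 1, 2, 3], [0.4] * 4)
        rate = pv.expansion_rate(series)
        np.testing.assert_array_equal(rate[:-1], np.zeros(3))
        assert np.isnan(rate[-1])

    def test_worked_two_point_example(self):
        # fraction 0.1 at 2 Ma grows to 0.3 at 1 Ma: rate at 1 Ma = 0.2/Myr
        series = self.make_series([1.0, 2.0], [0.3, 0.1])
        rate = pv.expansion_rate(series)
        assert rate[0] == pytest.approx(0.2)

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(8)
        means = rng.uniform(0, 1, 10)
        series = self.make_series(np.arange(10), means)
        rate = pv.expansion_rate(series)
        for k in range(9):
            assert rate[k] == pytest.approx(means[k] - means[k + 1])

    def test_single_age_has_no_rate(self):
        series = self.make_series([0.0], [0.5])
        assert np.isnan(pv.expansion_rate(series)).all()


class TestHabitatAssociation:
    def make_maps(self):
        cells = pd.DataFrame(
            {
                "lon": [-110.5, -109.5, -108.5],
                "lat": [40.5, 40.5, 40.5],
                "class": ["open", "closed", "unknown"],
            }
        )
        return {0.0: cells, 5.0: cells}

    def occ(self, rows):
        return pd.DataFrame(
            rows, columns=["taxon", "group", "lon", "lat", "age_ma", "source"]
        )

    def test_all_open_occurrences_give_fraction_one(self):
        occ = self.occ([("a", "mammal", -110.5, 40.5, 0.0, "current")] * 3)
        out = pv.habitat_association(occ, self.make_maps())
        assert out.loc["a", "fraction_open"] == 1.0

    def test_no_open_occurrences_give_zero(self):
        occ = self.occ([("b", "mammal", -109.5, 40.5, 4.9, "fossil")] * 2)
        out = pv.habitat_association(occ, self.make_maps())
        assert out.loc["b", "fraction_open"] == 0.0

    def test_unknown_cells_are_excluded_from_the_denominator(self):
        occ = self.occ(
            [
                ("c", "mammal", -110.5, 40.5, 0.0, "current"),  # open
                ("c", "mammal", -108.5, 40.5, 0.0, "current"),  # unknown
            ]
        )
        out = pv.habitat_association(occ, self.make_maps())
        assert out.loc["c", "fraction_open"] == 1.0
        assert out.loc["c", "n_unknown"] == 1

    def test_mixed_set_matches_cell_lookup_counting(self):
        occ = self.occ(
            [
                ("d", "plant", -110.4, 40.6, 0.1, "current"),  # open cell
                ("d", "plant", -109.6, 40.4, 5.2, "fossil"),  # closed cell
                ("d", "plant", -110.6, 40.5, 4.8, "fossil"),  # open cell
            ]
        )
        out = pv.habitat_association(occ, self.make_maps())
        assert out.loc["d", "n_open"] == 2
        assert out.loc["d", "n_closed"] == 1
        assert out.loc["d", "fraction_open"] == pytest.approx(2 / 3)

    def test_unresolvable_taxon_has_undefined_fraction(self):
        occ = self.occ([("e", "mammal", -108.5, 40.5, 0.0, "current")])
        out = pv.habitat_association(occ, self.make_maps())
        assert np.isnan(out.loc["e", "fraction_open"])
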