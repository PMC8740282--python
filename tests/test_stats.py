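"""Firing rates, ISI CV, correlation coefficients, KS scores, surrogates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from synquant.datasets import make_periodic_train, make_poisson_trains
from synquant.stats import (
    SpikeTrainSet,
    cc_discretization_level,
    coincidence_cc,
    correlation_coefficients,
    firing_rates,
    freedman_diaconis_edges,
    isi_cv,
    ks_score,
    spike_count_vectors,
    surrogate_randomize,
)


def train_set(trains, duration=10_000.0, t_start=0.0, pop="P"):
    return SpikeTrainSet(
        trains=[np.asarray(t, float) for t in trains],
        t_start=t_start,
        t_stop=t_start + duration,
        population=np.full(len(trains), pop, dtype=object),
    )


def brute_force_ks(a, b):
    """Independent oracle: scan the pooled support for the max CDF gap."""
    grid = np.concatenate([a, b])
    pa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
    pb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
    return np.max(np.abs(pa - pb))


class TestFiringRates:
    def test_simple_count_over_duration(self):
        ts = train_set([np.linspace(10, 9990, 90)], duration=10_000.0)
        assert firing_rates(ts)[0] == pytest.approx(9.0)

    def test_silent_neuron_has_zero_rate(self):
        ts = train_set([[], [100.0, 200.0, 300.0]])
        np.testing.assert_allclose(firing_rates(ts), [0.0, 0.3])

    def test_rates_are_multiples_of_inverse_duration(self, rng):
        ts = make_poisson_trains(7.0, 10_000.0, 50, rng)
        fr = firing_rates(ts)
        steps = fr * 10.0  # 1/D = 0.1 per second
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)


class TestIsiCv:
    def test_periodic_train_has_zero_cv(self):
        t = make_periodic_train(10.0, 10_000.0)
        cv, kept, _ = isi_cv(train_set([t]))
        assert cv[0] == 0.0

    def test_two_isis_hand_arithmetic(self):
        # ISIs {1, 3} ms: mu=2, population sigma=1 -> CV = 0.5
        cv, _, _ = isi_cv(train_set([[1.0, 2.0, 5.0]]))
        assert cv[0] == pytest.approx(0.5)

    def test_long_poisson_train_cv_near_one(self, rng):
        ts = make_poisson_trains(50.0, 200_000.0, 1, rng)
        cv, _, _ = isi_cv(ts)
        n = len(ts.trains[0])
        assert abs(cv[0] - 1.0) <= 4 / math.sqrt(n)

    def test_sparse_trains_excluded_and_reported(self):
        cv, kept, excluded = isi_cv(train_set([[1.0, 2.0], [1, 2, 3, 4]]))
        assert list(excluded) == [0] and list(kept) == [1]

    def test_all_excluded_warns(self):
        with pytest.warns(UserWarning, match="enough spikes"):
            cv, kept, _ = isi_cv(train_set([[1.0], [2.0]]))
        assert len(cv) == 0


class TestSpikeCounts:
    def test_single_spike_lands_in_one_bin(self):
        ts = train_set([[0.5]], duration=10.0)
        x = spike_count_vectors(ts, 2.0)
        assert x.shape == (1, 5)
        assert x.sum() == 1 and x[0, 0] == 1

    def test_vector_length_is_duration_over_bin(self):
        ts = train_set([[]], duration=10_000.0)
        assert spike_count_vectors(ts, 2.0).shape[1] == 5000

    def test_count_conservation_under_surrogate(self, rng):
        ts = make_poisson_trains(20.0, 5000.0, 10, rng)
        sur = surrogate_randomize(ts, rng)
        a = spike_count_vectors(ts, 2.0).sum(axis=1)
        b = spike_count_vectors(sur, 2.0).sum(axis=1)
        np.testing.assert_array_equal(a, b)


class TestCorrelation:
    def test_identical_trains_fully_correlated(self, rng):
        t = np.sort(rng.uniform(0, 10_000, 400))
        cc, _ = correlation_coefficients(train_set([t, t.copy()]), 2.0)
        assert cc["P"][0] == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self, rng):
        ts = make_poisson_trains(10.0, 100_000.0, 30, rng)
        cc, _ = correlation_coefficients(ts, 2.0)
        m = 50_000
        assert abs(np.mean(cc["P"])) <= 4 / math.sqrt(m)

    def test_covariance_and_coincidence_formulas_agree(self, rng):
        """Dual-route check on random binary vectors (1e-12)."""
        for _ in range(20):
            x = (rng.random(500) < 0.07).astype(float)
            y = (rng.random(500) < 0.12).astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            pearson = np.corrcoef(x, y)[0, 1]
            assert abs(coincidence_cc(x, y) - pearson) <= 1e-12

    def test_zero_variance_pairs_excluded(self, rng):
        t = np.sort(rng.uniform(0, 10_000, 200))
        ts = train_set([t, [], np.sort(rng.uniform(0, 10_000, 150))])
        with pytest.warns(UserWarning, match="smaller than sample_size"):
            cc, excluded = correlation_coefficients(ts, 2.0)
        assert len(cc["P"]) == 1  # only the pair of active neurons
        assert excluded["P"] == 2  # two pairs involved the silent neuron

    def test_small_population_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            correlation_coefficients(train_set([[1.0, 2.0]]), 2.0)


class TestCcDiscretization:
    def test_paper_scale_example(self):
        # 1/s over 15 minutes with 2 ms bins
        level = cc_discretization_level(900, 900, 450_000)
        assert level == pytest.approx(0.001, abs=0.0005)
        assert float(f"{level:.1g}") == 0.001

    def test_half_full_vectors(self):
        m = 1000
        assert cc_discretization_level(m // 2, m // 2, m) == pytest.approx(4 / m)

    def test_lattice_spacing_matches_coincidence_increment(self):
        """Brute force: bumping the coincidence count G by one moves the CC
        by exactly the predicted discretization level."""
        m, n_i, n_j, g = 2000, 60, 45, 7
        x = np.zeros(m)
        y = np.zeros(m)
        x[:n_i] = 1
        y[:g] = 1
        y[n_i : n_i + (n_j - g)] = 1  # overlap g
        y2 = y.copy()
        y2[n_i] = 0
        y2[g] = 1  # overlap g+1, same counts
        delta = coincidence_cc(x, y2) - coincidence_cc(x, y)
        assert delta == pytest.approx(
            cc_discretization_level(n_i, n_j, m), rel=1e-12
        )

    def test_counts_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cc_discretization_level(0, 10, 100)
        with pytest.raises(ValueError):
            cc_discretization_level(100, 10, 100)


class TestFreedmanDiaconis:
    def test_width_matches_independent_iqr(self):
        x = np.arange(1.0, 9.0)
        edges = freedman_diaconis_edges(x)
        width = edges[1] - edges[0]
        assert width == pytest.approx(2 * sps.iqr(x) / len(x) ** (1 / 3))

    def test_width_shrinks_with_sample_size(self, rng):
        small = freedman_diaconis_edges(rng.normal(size=100))
        large = freedman_diaconis_edges(rng.normal(size=100_000))
        assert (large[1] - large[0]) < (small[1] - small[0])

    def test_edges_span_reference_range(self, rng):
        x = rng.normal(size=500)
        edges = freedman_diaconis_edges(x)
        assert edges[0] <= x.min() and edges[-1] >= x.max()

    def test_zero_iqr_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="zero IQR"):
            edges = freedman_diaconis_edges(np.ones(50) * 3.0)
        assert len(edges) > 2


class TestKsScore:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=100)
        assert ks_score(x, x.copy()) == 0.0

    def test_disjoint_supports_one(self, rng):
        assert ks_score(rng.uniform(0, 1, 50), rng.uniform(5, 6, 70)) == 1.0

    def test_matches_brute_force_cdf_scan(self, rng):
        for _ in range(25):
            a = rng.normal(size=rng.integers(3, 40))
            b = rng.normal(0.3, 1.2, size=rng.integers(3, 40))
            assert abs(ks_score(a, b) - brute_force_ks(a, b)) <= 1e-15

    @given(
        a=hst.lists(hst.floats(-50, 50), min_size=2, max_size=30),
        b=hst.lists(hst.floats(-50, 50), min_size=2, max_size=30),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_monotone_invariant(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        d = ks_score(a, b)
        assert d == ks_score(b, a)
        assert 0 <= d <= 1
        # strictly monotone (and floating-point-exact) transform of both
        # samples leaves the score alone
        f = lambda x: 2.0 * x
        assert ks_score(f(a), f(b)) == pytest.approx(d, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_score([], [1.0])


class TestSurrogate:
    def test_spike_counts_preserved_exactly(self, rng):
        ts = make_poisson_trains(5.0, 20_000.0, 40, rng)
        sur = surrogate_randomize(ts, rng)
        before = firing_rates(ts)
        after = firing_rates(sur)
        np.testing.assert_array_equal(before, after)

    def test_surrogate_cc_consistent_with_null(self, rng):
        t = np.sort(rng.uniform(0, 50_000, 500))
        base = train_set([t, t.copy(), t.copy()], duration=50_000.0)
        sur = surrogate_randomize(base, rng)
        cc, _ = correlation_coefficients(sur, 2.0)
        m = 25_000
        assert np.all(np.abs(cc["P"]) <= 6 / math.sqrt(m))

    def test_surrogate_cv_near_one(self, rng):
        ts = train_set([np.linspace(5, 99_995, 2000)], duration=100_000.0)
        sur = surrogate_randomize(ts, rng)
        cv, _, _ = isi_cv(sur)
        assert abs(cv[0] - 1.0) <= 4 / math.sqrt(2000)

    def test_surrogate_cc_comb_on_predicted_lattice(self, rng):
        """Homogeneous-rate surrogates: attainable CC values sit on a lattice
        whose spacing follows from the spike counts and bin count."""
        n_spikes, d, delta = 80, 40_000.0, 2.0
        m_bins = int(d / delta)
        # one spike per occupied bin keeps the count vectors binary, the
        # regime in which the lattice spacing is exact
        trains = [
            (np.sort(rng.choice(m_bins, n_spikes, replace=False)) + 0.5) * delta
            for _ in range(12)
        ]
        ts = train_set(trains, duration=d)
        cc, _ = correlation_coefficients(ts, delta)
        m = int(d / delta)
        level = cc_discretization_level(n_spikes, n_spikes, m)
        # offset of the lattice: CC at zero coincidences
        base = -n_spikes * n_spikes / m / (
            math.sqrt(n_spikes * n_spikes * (1 - n_spikes / m) ** 2)
        )
        residues = (cc["P"] - base) / level
        np.testing.assert_allclose(residues, np.round(residues), atol=1e-9)


class TestWindowHandling:
    def test_statistics_exclude_pre_transient_data(self):
        # build a record-like train set directly: the window starts at 1 s
        ts = SpikeTrainSet(
            trains=[np.array([1500.0, 2500.0, 3500.0])],
            t_start=1000.0,
            t_stop=11_000.0,
            population=np.array(["P"], object),
        )
        assert firing_rates(ts)[0] == pytest.approx(0.3)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrainSet([np.array([1.0])], 10.0, 10.0, np.array(["P"], object))
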