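"""Cluster permutation test, correlations and reliability statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from predtend.decoding import DecisionValueSeries, TendencyCurve, transition_evidence
from predtend.stats import (
    ClusterTestConfig,
    cluster_permutation_test,
    cronbach_alpha,
    disattenuated_correlation,
    paired_difference_test,
    pearson_correlation,
    reliability_report,
    spearman_brown,
    split_half_scores,
    time_by_time_reliability,
)


def _exact_sign_flip_null(data, cluster_alpha=0.025):
    """Brute-force oracle: enumerate all 2^n sign patterns, return observed
    cluster (start, stop, mass) list and exact max-mass null distribution."""
    n, _ = data.shape
    thr = sps.t.ppf(1 - cluster_alpha, df=n - 1)

    def t_of(x):
        return x.mean(axis=0) / (x.std(axis=0, ddof=1) / np.sqrt(n))

    def clusters_of(t):
        out = []
        for sign in (1, -1):
            run = None
            for i, v in enumerate(sign * t > thr):
                if v and run is None:
                    run = i
                if not v and run is not None:
                    out.append((run, i, float(t[run:i].sum())))
                    run = None
            if run is not None:
                out.append((run, len(t), float(t[run:].sum())))
        return sorted(out)

    obs = clusters_of(t_of(data))
    null = []
    for signs in itertools.product([-1.0, 1.0], repeat=n):
        t = t_of(data * np.array(signs)[:, None])
        cl = clusters_of(t)
        null.append(max((abs(m) for _, _, m in cl), default=0.0))
    return obs, np.array(null)


class TestClusterTest:
    def test_all_zero_data_has_no_clusters(self):
        res = cluster_permutation_test(
            np.zeros((6, 20)), config=ClusterTestConfig(n_permutations=100, seed=0)
        )
        assert res.clusters == []

    def test_constructed_positive_control_recovers_window(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20, 40)) * 0.1
        data[:, 10:20] += 1.0  # strong offset on a contiguous window
        res = cluster_permutation_test(
            data, config=ClusterTestConfig(n_permutations=500, seed=2)
        )
        sig = res.significant
        assert len(sig) == 1
        assert sig[0].start == 10 and sig[0].stop == 20
        assert sig[0].mass > 0

    def test_masses_and_p_match_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((6, 15))
        data[:, 5:9] += 0.9
        obs_oracle, null = _exact_sign_flip_null(data)
        res = cluster_permutation_test(
            data, config=ClusterTestConfig(n_permutations=4000, seed=4)
        )
        got = sorted((c.start, c.stop, c.mass) for c in res.clusters)
        assert len(got) == len(obs_oracle)
        for (a, b, m), (a2, b2, m2) in zip(got, obs_oracle):
            assert (a, b) == (a2, b2)
            assert m == pytest.approx(m2, abs=1e-10)
        # Monte-Carlo p within sampling tolerance of the exact enumeration p
        for c in res.clusters:
            p_exact = np.mean(null >= abs(c.mass))
            tol = 3 * np.sqrt(max(p_exact * (1 - p_exact), 0.001) / 4000) + 2 / 4000
            assert abs(c.p - p_exact) < tol + 0.01

    def test_agrees_with_independent_cluster_implementation(self):
        # cross-check observed clustering against mne's implementation
        from mne.stats import permutation_cluster_1samp_test

        rng = np.random.default_rng(5)
        data = rng.standard_normal((12, 30))
        data[:, 8:14] += 0.8
        thr = sps.t.ppf(1 - 0.025, df=11)
        t_mne, clusters, pvals, _ = permutation_cluster_1samp_test(
            data, threshold=thr, n_permutations=2000, tail=0, seed=6, verbose="error"
        )
        res = cluster_permutation_test(
            data, config=ClusterTestConfig(n_permutations=2000, seed=7)
        )
        np.testing.assert_allclose(res.t_values, t_mne, atol=1e-10)
        def window(cl):  # mne may return slices, masks or index arrays
            if isinstance(cl, tuple):
                cl = cl[0]
            if isinstance(cl, slice):
                return cl.start, cl.stop
            idx = np.flatnonzero(np.asarray(cl)) if np.asarray(cl).dtype == bool else np.asarray(cl)
            return int(idx.min()), int(idx.max()) + 1

        mne_windows = sorted(window(cl) for cl in clusters)
        got_windows = sorted((c.start, c.stop) for c in res.clusters)
        assert got_windows == mne_windows
        # significance decisions agree on the strong cluster
        strong = [c for c in res.clusters if (c.start, c.stop) == (8, 14)]
        assert strong and strong[0].p < 0.025
        assert pvals.min() < 0.025

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((8, 25))
        cfg = ClusterTestConfig(n_permutations=300, seed=9)
        a = cluster_permutation_test(data, config=cfg)
        b = cluster_permutation_test(data, config=cfg)
        assert [(c.start, c.stop, c.p) for c in a.clusters] == [
            (c.start, c.stop, c.p) for c in b.clusters
        ]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(np.zeros((2, 10)))


class TestCorrelations:
    def test_identity_and_antiidentity(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_five_point_arithmetic_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        r_direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson_correlation(x, y)[0] == pytest.approx(r_direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


def _two_items_with_exact_moments(n, sd1, sd2, r, seed=0):
    """Construct an n x 2 sample whose sample SDs and correlation are exact."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    z -= z.mean(axis=0)
    q, _ = np.linalg.qr(z)
    z = q * np.sqrt(n - 1)  # exactly unit sample variance, zero correlation
    x1 = sd1 * z[:, 0]
    x2 = sd2 * (r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1])
    return np.column_stack([x1, x2])


class TestCronbach:
    def test_reconstruction_from_printed_moments(self):
        # two-item scale with SDs 0.164 / 0.127 and r = .18: alpha ~ .297,
        # matching the published .298 within printed-input rounding
        items = _two_items_with_exact_moments(35, 0.164, 0.127, 0.18)
        alpha = cronbach_alpha(items)
        v1, v2 = 0.164**2, 0.127**2
        c = 0.18 * 0.164 * 0.127
        assert alpha == pytest.approx(4 * c / (v1 + v2 + 2 * c), abs=1e-10)
        assert alpha == pytest.approx(0.298, abs=0.005)

    def test_identical_items_give_one(self):
        x = np.arange(10.0)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_independent_items_approach_zero(self):
        rng = np.random.default_rng(10)
        items = rng.standard_normal((4000, 2))
        assert abs(cronbach_alpha(items)) < 3 / np.sqrt(4000) * 2

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.column_stack([np.ones(5), -np.ones(5)]))


class TestSpearmanBrown:
    def test_published_split_half_value(self):
        assert spearman_brown(0.74) == pytest.approx(0.851, abs=5e-4)

    def test_fixed_points(self):
        assert spearman_brown(0.0) == 0.0
        assert spearman_brown(1.0) == 1.0

    def test_cross_modal_value_up_to_rounding(self):
        # 2*.18/1.18 = .305; the published .306 reflects rounding of r
        assert spearman_brown(0.18) == pytest.approx(0.305, abs=5e-4)
        assert abs(spearman_brown(0.18) - 0.306) < 0.002

    def test_minus_one_rejected(self):
        with pytest.raises(ValueError):
            spearman_brown(-1.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-0.99, 0.999), st.floats(0.0005, 0.01))
    def test_strictly_increasing(self, r, eps):
        assert spearman_brown(r + eps) > spearman_brown(r)


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 1000))
def test_cronbach_two_item_identity(seed):
    rng = np.random.default_rng(seed)
    items = rng.standard_normal((12, 2)) * [1.0, 2.5] + [0.3, -1.0]
    v1, v2 = items.var(axis=0, ddof=1)
    c = np.cov(items.T, ddof=1)[0, 1]
    assert cronbach_alpha(items) == pytest.approx(
        4 * c / (v1 + v2 + 2 * c), abs=1e-10
    )


class TestDisattenuation:
    def test_perfect_reliability_is_identity(self):
        assert disattenuated_correlation(0.4, 1.0, 1.0) == pytest.approx(0.4)

    def test_attenuated_observation_recovers_latent_scale(self):
        assert disattenuated_correlation(0.4, 0.5, 0.8) == pytest.approx(
            0.4 / np.sqrt(0.4), abs=1e-12
        )

    def test_clipped_to_unit_interval(self):
        assert disattenuated_correlation(0.9, 0.5, 0.5) == 1.0

    def test_nonpositive_reliability_rejected(self):
        with pytest.raises(ValueError):
            disattenuated_correlation(0.5, 0.0, 1.0)


def _series_for_split(rng, n_per_cond=12, n_times=8, offset=0.0):
    dvals = rng.standard_normal((2 * n_per_cond, 4, n_times))
    dvals[:n_per_cond, 1] += offset  # forward evidence for prev=1 sits in d2
    cond = ["ordered"] * n_per_cond + ["random"] * n_per_cond
    s = DecisionValueSeries(
        dvals=dvals,
        times=np.linspace(-0.3, 0.4, n_times),
        labels=np.ones(2 * n_per_cond, dtype=int),
        prev_stimulus=np.ones(2 * n_per_cond, dtype=int),
        condition=np.array(cond),
    )
    return transition_evidence(s)


class TestSplitHalf:
    def test_noise_free_halves_agree(self):
        rng = np.random.default_rng(11)
        s = _series_for_split(rng, offset=2.0)
        s.dvals[: 12] = s.dvals[0]  # identical ordered trials
        s.dvals[12:] = s.dvals[12]  # identical random trials
        s = transition_evidence(s)
        a, b = split_half_scores(s, seed=0)
        assert a == pytest.approx(b, abs=1e-10)

    def test_halves_are_condition_balanced(self):
        rng = np.random.default_rng(12)
        s = _series_for_split(rng)
        a, b = split_half_scores(s, seed=1)
        assert np.isfinite(a) and np.isfinite(b)

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(13)
        s = _series_for_split(rng, n_per_cond=2)
        with pytest.raises(ValueError):
            split_half_scores(s, seed=0)


class TestTimeByTime:
    def test_identical_curve_sets_have_unit_diagonal(self):
        rng = np.random.default_rng(14)
        times = np.arange(-30, 31) / 100.0
        curves = TendencyCurve(values=rng.standard_normal((10, len(times))), times=times)
        rho, taxis = time_by_time_reliability(curves, curves)
        assert rho.shape == (30, 30)
        np.testing.assert_allclose(np.diag(rho), 1.0, atol=1e-10)
        assert taxis[0] == pytest.approx(-0.3)

    def test_independent_null_scatters_about_zero(self):
        rng = np.random.default_rng(15)
        times = np.arange(-30, 31) / 100.0
        a = TendencyCurve(values=rng.standard_normal((200, len(times))), times=times)
        b = TendencyCurve(values=rng.standard_normal((200, len(times))), times=times)
        rho, _ = time_by_time_reliability(a, b)
        assert abs(np.mean(rho)) < 0.05

    def test_subject_mismatch_rejected(self):
        times = np.arange(-5, 1) / 100.0
        a = TendencyCurve(values=np.random.randn(5, 6), times=times)
        b = TendencyCurve(values=np.random.randn(6, 6), times=times)
        with pytest.raises(ValueError):
            time_by_time_reliability(a, b)


class TestPairedDifference:
    def test_identical_vectors_give_zero(self):
        x = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        t, ci = paired_difference_test(x, x)
        assert t == 0
        assert ci[0] == pytest.approx(0) and ci[1] == pytest.approx(0)

    def test_five_subject_formula_oracle(self):
        a = np.array([0.3, 0.1, 0.6, 0.2, 0.5])
        b = np.array([0.1, 0.2, 0.3, 0.1, 0.2])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        t, ci = paired_difference_test(a, b)
        assert t == pytest.approx(t_hand, abs=1e-10)
        tcrit = sps.t.ppf(0.975, 4)
        assert ci[0] == pytest.approx(d.mean() - tcrit * d.std(ddof=1) / np.sqrt(5), abs=1e-10)

    def test_null_calibration(self):
        rng = np.random.default_rng(16)
        crit = sps.t.ppf(0.975, 19)
        rejections = 0
        runs = 400
        for _ in range(runs):
            d = rng.standard_normal(20)
            t, _ = paired_difference_test(d, np.zeros(20))
            rejections += abs(t) > crit
        assert rejections / runs < 0.05 + 3 * np.sqrt(0.05 * 0.95 / runs)


class TestReliabilityReport:
    def test_table_contains_consistent_statistics(self):
        rng = np.random.default_rng(17)
        aud = rng.standard_normal(35)
        vis = 0.5 * aud + rng.standard_normal(35)
        halves = np.column_stack([aud + rng.standard_normal(35) * 0.2, aud])
        rep = reliability_report(aud, vis, halves_aud=halves)
        row = rep.table.loc["cross_modal"]
        r = pearson_correlation(aud, vis)[0]
        assert row["pearson_r"] == pytest.approx(r)
        assert row["spearman_brown_rho"] == pytest.approx(spearman_brown(r))
        assert row["cronbach_alpha"] == pytest.approx(
            cronbach_alpha(np.column_stack([aud, vis]))
        )
        assert "auditory_split_half" in rep.table.index
        assert "visual_split_half" not in rep.table.index
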