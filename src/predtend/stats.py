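"""Group-level inference and reliability statistics.

Covers the nonparametric cluster-based permutation t-test over time (sign-flip
null on paired difference curves), Pearson correlation, Cronbach's alpha, the
Spearman-Brown two-part reliability correction rho = 2r/(1+r), split-half
reliability of the tendency score, and the prestimulus time-by-time
cross-modal reliability matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decoding import DecisionValueSeries, TendencyCurve, _forward_evidence, tendency_score
from .sequence import ORDERED, RANDOM

__all__ = [
    "ClusterTestConfig",
    "Cluster",
    "ClusterResult",
    "ReliabilityReport",
    "cluster_permutation_test",
    "pearson_correlation",
    "cronbach_alpha",
    "spearman_brown",
    "disattenuated_correlation",
    "split_half_scores",
    "split_half_reliability",
    "time_by_time_reliability",
    "paired_difference_test",
    "reliability_report",
]


@dataclass(frozen=True)
class ClusterTestConfig:
    """Settings of the cluster-based permutation t-test.

    ``cluster_alpha`` sets the per-tail cluster-forming t threshold;
    ``critical_alpha`` is the Monte-Carlo significance level for cluster
    p-values.
    """

    n_permutations: int = 10_000
    cluster_alpha: float = 0.025
    critical_alpha: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cluster_alpha < 0.5 and 0 < self.critical_alpha < 0.5):
            raise ValueError("alphas must lie in (0, 0.5)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


@dataclass(frozen=True)
class Cluster:
    start: int  # sample index, inclusive
    stop: int  # sample index, exclusive
    t_interval: tuple[float, float]
    mass: float  # summed t-values
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    times: np.ndarray
    config: ClusterTestConfig

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.config.critical_alpha]


def _one_sample_t(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.nan_to_num(t)


def _cluster_masses(t: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    """Maximal contiguous runs above +thr or below -thr, with summed t mass."""
    out = []
    for sign in (1.0, -1.0):
        supra = sign * t > thr
        if not supra.any():
            continue
        edges = np.diff(np.r_[False, supra, False].astype(int))
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)
        for a, b in zip(starts, stops):
            out.append((int(a), int(b), float(t[a:b].sum())))
    return sorted(out)


def _max_mass(t: np.ndarray, thr: float) -> float:
    runs = _cluster_masses(t, thr)
    return max((abs(m) for _, _, m in runs), default=0.0)


def cluster_permutation_test(
    data: np.ndarray,
    times: np.ndarray | None = None,
    config: ClusterTestConfig = ClusterTestConfig(),
) -> ClusterResult:
    """One-sample cluster-based permutation t-test over time.

    ``data`` is subjects x time of paired differences tested against zero.
    Clusters are maximal contiguous runs of samples whose one-sample t exceeds
    the two-sided ``cluster_alpha`` threshold (per tail); the null is the
    distribution of the maximum absolute cluster mass over seeded random
    sign-flips of whole subject curves. Cluster p-values use the
    (1 + exceedances) / (1 + n_permutations) estimator.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValueError("need a subjects x time array with >= 3 subjects")
    n_sub, n_time = data.shape
    if times is None:
        times = np.arange(n_time, dtype=float)
    thr = sps.t.ppf(1 - config.cluster_alpha, df=n_sub - 1)

    t_obs = _one_sample_t(data)
    observed = _cluster_masses(t_obs, thr)

    rng = np.random.default_rng(config.seed)
    sq_sum = (data**2).sum(axis=0)
    null_max = np.empty(config.n_permutations)
    chunk = 256
    done = 0
    while done < config.n_permutations:
        k = min(chunk, config.n_permutations - done)
        flips = rng.choice([-1.0, 1.0], size=(k, n_sub))
        means = flips @ data / n_sub
        var = (sq_sum / n_sub - means**2) * n_sub / (n_sub - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = means / np.sqrt(var / n_sub)
        t_perm = np.nan_to_num(t_perm)
        for j in range(k):
            null_max[done + j] = _max_mass(t_perm[j], thr)
        done += k
    clusters = [
        Cluster(
            start=a,
            stop=b,
            t_interval=(float(times[a]), float(times[b - 1])),
            mass=m,
            p=float((1 + np.sum(null_max >= abs(m))) / (1 + config.n_permutations)),
        )
        for a, b, m in observed
    ]
    return ClusterResult(clusters=clusters, t_values=t_obs, times=times, config=config)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def cronbach_alpha(items: np.ndarray) -> float:
    """Covariance-based Cronbach's alpha for a subjects x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the item sum).
    For two items this reduces to 4*cov / (var1 + var2 + 2*cov).
    """
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2 or items.shape[0] < 3:
        raise ValueError("need a subjects x items matrix, k >= 2, >= 3 subjects")
    k = items.shape[1]
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    item_var = items.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def spearman_brown(r: float) -> float:
    """Predicted full-length reliability of a two-part measure: 2r/(1+r)."""
    if r <= -1:
        raise ValueError("undefined for r <= -1")
    return 2 * r / (1 + r)


def disattenuated_correlation(r: float, rel_a: float, rel_b: float) -> float:
    """Classical correction for attenuation: r / sqrt(rel_a * rel_b).

    Estimates the correlation of the latent quantities from the observed
    correlation ``r`` of two noisy measures with reliabilities ``rel_a`` and
    ``rel_b``. The result is clipped to [-1, 1]; reliabilities must be
    positive.
    """
    if rel_a <= 0 or rel_b <= 0:
        raise ValueError("reliabilities must be positive to disattenuate")
    return float(np.clip(r / np.sqrt(rel_a * rel_b), -1.0, 1.0))


def split_half_scores(
    series: DecisionValueSeries,
    seed: int,
    contrast: str = "forward",
    prestim: tuple[float, float] = (-0.3, 0.0),
) -> tuple[float, float]:
    """Tendency scores from two random condition-balanced halves of the
    matched test trials of one subject (training is shared)."""
    rng = np.random.default_rng(seed)
    halves: dict[int, dict[str, np.ndarray]] = {0: {}, 1: {}}
    for cond in (ORDERED, RANDOM):
        ev = _forward_evidence(series, cond)
        n = ev.shape[0]
        if n < 4:
            raise ValueError("need >= 4 matched test trials per condition to split")
        perm = rng.permutation(n)
        halves[0][cond] = ev[perm[: n // 2]]
        halves[1][cond] = ev[perm[n // 2 :]]
    scores = []
    for h in (0, 1):
        if contrast == "forward":
            stat = {c: halves[h][c][:, 0] for c in (ORDERED, RANDOM)}
        elif contrast == "forward_minus_repetition":
            stat = {c: halves[h][c][:, 0] - halves[h][c][:, 1] for c in (ORDERED, RANDOM)}
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
        curve = TendencyCurve(
            values=stat[ORDERED].mean(axis=0) - stat[RANDOM].mean(axis=0),
            times=series.times,
        )
        scores.append(tendency_score(curve, prestim))
    return scores[0], scores[1]


def split_half_reliability(
    series_per_subject: list[DecisionValueSeries],
    seed: int,
    contrast: str = "forward",
    prestim: tuple[float, float] = (-0.3, 0.0),
    return_halves: bool = False,
):
    """Across-subject split-half reliability of the tendency score.

    Returns the Pearson r between half-scores and its Spearman-Brown
    corrected rho (optionally also the subjects x 2 half-score matrix).
    """
    rng = np.random.default_rng(seed)
    halves = np.array(
        [
            split_half_scores(series, int(rng.integers(2**31)), contrast, prestim)
            for series in series_per_subject
        ]
    )
    r, _ = pearson_correlation(halves[:, 0], halves[:, 1])
    if return_halves:
        return r, spearman_brown(r), halves
    return r, spearman_brown(r)


def time_by_time_reliability(
    curves_aud: TendencyCurve,
    curves_vis: TendencyCurve,
    prestim: tuple[float, float] = (-0.3, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman-Brown-transformed across-subject correlation for every pair of
    prestimulus time samples (auditory sample i vs visual sample j).

    Returns (rho matrix, prestimulus time axis).
    """
    va = np.atleast_2d(curves_aud.values)
    vv = np.atleast_2d(curves_vis.values)
    if va.shape[0] != vv.shape[0]:
        raise ValueError("curve sets must share the subject axis")
    lo, hi = prestim
    eps = 1e-9
    mask_a = (curves_aud.times >= lo - eps) & (curves_aud.times < hi - eps)
    mask_v = (curves_vis.times >= lo - eps) & (curves_vis.times < hi - eps)
    va, vv = va[:, mask_a], vv[:, mask_v]
    rho = np.empty((va.shape[1], vv.shape[1]))
    for i in range(va.shape[1]):
        for j in range(vv.shape[1]):
            r = np.corrcoef(va[:, i], vv[:, j])[0, 1]
            rho[i, j] = spearman_brown(r)
    return rho, curves_aud.times[mask_a]


def paired_difference_test(scores_a, scores_b) -> tuple[float, tuple[float, float]]:
    """One-sample t-test on paired differences, with the 95% CI of the mean
    difference."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need paired vectors with >= 3 subjects")
    d = a - b
    n = len(d)
    se = d.std(ddof=1) / np.sqrt(n)
    if se == 0:
        # degenerate case: identical pairs carry no evidence of a difference
        t_stat = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t_stat = float(sps.ttest_1samp(d, 0.0).statistic)
    tcrit = sps.t.ppf(0.975, df=n - 1)
    ci = (float(d.mean() - tcrit * se), float(d.mean() + tcrit * se))
    return float(t_stat), ci


@dataclass
class ReliabilityReport:
    """Cross-modal and split-half reliability of the tendency score."""

    scores: pd.DataFrame  # columns: subject, auditory, visual
    table: pd.DataFrame  # rows: cross-modal / auditory split-half / visual split-half

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True)


def reliability_report(
    scores_aud: np.ndarray,
    scores_vis: np.ndarray,
    halves_aud: np.ndarray | None = None,
    halves_vis: np.ndarray | None = None,
) -> ReliabilityReport:
    """Assemble the three reliability statistics into one table.

    Rows mirror the standard layout: cross-modal reliability of the two-item
    (auditory, visual) scale, then the within-modality split-half rows when
    subjects x 2 half-score matrices are supplied.
    """
    r, _ = pearson_correlation(scores_aud, scores_vis)
    rows = {
        "cross_modal": {
            "pearson_r": r,
            "cronbach_alpha": cronbach_alpha(np.column_stack([scores_aud, scores_vis])),
            "spearman_brown_rho": spearman_brown(r),
        }
    }
    for name, halves in (
        ("auditory_split_half", halves_aud),
        ("visual_split_half", halves_vis),
    ):
        if halves is not None:
            r_h, _ = pearson_correlation(halves[:, 0], halves[:, 1])
            rows[name] = {
                "pearson_r": r_h,
                "cronbach_alpha": cronbach_alpha(halves),
                "spearman_brown_rho": spearman_brown(r_h),
            }
    scores = pd.DataFrame(
        {
            "subject": np.arange(len(scores_aud)),
            "auditory": scores_aud,
            "visual": scores_vis,
        }
    )
    return ReliabilityReport(scores=scores, table=pd.DataFrame(rows).T)
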