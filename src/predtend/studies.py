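"""Simulation studies that validate the measurement pipeline.

Three self-contained studies, each running the full simulate -> preprocess ->
decode -> score chain (or, for the cluster calibration, the group statistic
on synthetic null cohorts):

* :func:`beta_recovery_study` - does the recovered tendency score track the
  simulator's ground-truth pre-activation amplitude across subjects?
* :func:`rho_recovery_study` - is the cross-modal correlation of recovered
  scores an unbiased estimate of the generating latent correlation, once the
  classical correction for attenuation is applied?
* :func:`null_decoding_accuracy` - does label-shuffled training produce
  chance-level (0.25) four-class accuracy?
* :func:`cluster_type1_study` - does the cluster permutation test hold its
  nominal false-positive rate on Gaussian null cohorts?
"""

from __future__ import annotations

import numpy as np

from .decoding import (
    decoding_accuracy,
    select_test_trials,
    select_training_trials,
    time_resolved_decode,
)
from .pipeline import RunConfig, make_design, subject_analysis
from .preprocessing import preprocess
from .simulate import (
    SubjectParams,
    draw_cohort_betas,
    make_forward_model,
    simulate_cohort,
    simulate_subject,
)
from .stats import (
    ClusterTestConfig,
    cluster_permutation_test,
    disattenuated_correlation,
    pearson_correlation,
    spearman_brown,
    split_half_reliability,
)

__all__ = [
    "recovery_config",
    "scaled_config",
    "beta_recovery_study",
    "rho_recovery_study",
    "null_decoding_accuracy",
    "cluster_type1_study",
]


def recovery_config(seed: int = 0, **overrides) -> RunConfig:
    """Reduced geometry (1 block of 4 x 700, 32 channels), prestimulus-only
    decoding window - the setting for the beta-recovery study."""
    base = dict(decode_window=(-0.3, 0.0), seed=seed)
    base.update(overrides)
    return RunConfig.reduced(**base)


def scaled_config(seed: int = 0, **overrides) -> RunConfig:
    """Desk-scale design (1 block of 4 x 250, 16 channels) for replicated
    studies where many cohorts must be simulated."""
    base = dict(
        segment_length=250,
        n_channels=16,
        decode_window=(-0.3, 0.0),
        seed=seed,
    )
    base.update(overrides)
    return RunConfig.reduced(**base)


def beta_recovery_study(
    n_subjects: int = 35, seed: int = 0, cfg: RunConfig | None = None
) -> dict:
    """Simulate a cohort (one modality) and correlate true beta with the
    recovered prediction-tendency score."""
    if cfg is None:
        cfg = recovery_config(seed=seed)
    rng = np.random.default_rng(seed)
    betas = draw_cohort_betas(
        n_subjects, 0.0, mean=cfg.beta_mean, sd=cfg.beta_sd, seed=int(rng.integers(2**31))
    )[:, 0]
    scores = []
    for b in betas:
        seq = make_design(cfg, rng)
        fm = make_forward_model(cfg.n_channels, seed=int(rng.integers(2**31)))
        p = SubjectParams(
            beta_aud=float(b), beta_vis=float(b), noise_sd=cfg.noise_sd,
            seed=int(rng.integers(2**31)),
        )
        rec = simulate_subject(seq, fm, p, sampling_rate=cfg.native_rate)
        _, _, score = subject_analysis(rec, cfg, seed=int(rng.integers(2**31)))
        scores.append(score)
    r, p_val = pearson_correlation(betas, scores)
    return {
        "betas": betas,
        "scores": np.asarray(scores),
        "recovery_r": r,
        "p": p_val,
        "n_subjects": n_subjects,
    }


def _one_rho_replicate(rho: float, n_subjects: int, seed: int, cfg: RunConfig) -> dict:
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(
        n_subjects,
        rho,
        schedule_fn=lambda r: make_design(cfg, r),
        seed=int(rng.integers(2**31)),
        n_channels=cfg.n_channels,
        sampling_rate=cfg.native_rate,
        beta_mean=cfg.beta_mean,
        beta_sd=cfg.beta_sd,
        noise_sd=cfg.noise_sd,
    )
    scores = {"aud": [], "vis": []}
    series = {"aud": [], "vis": []}
    for rec_a, rec_v, _ in cohort:
        for key, rec in (("aud", rec_a), ("vis", rec_v)):
            s, _, sc = subject_analysis(rec, cfg, seed=int(rng.integers(2**31)))
            scores[key].append(sc)
            series[key].append(s)
    r_obs, _ = pearson_correlation(scores["aud"], scores["vis"])
    rel = {
        key: spearman_brown(
            split_half_reliability(series[key], seed=int(rng.integers(2**31)))[0]
        )
        for key in ("aud", "vis")
    }
    return {"r_obs": r_obs, "rel_aud": rel["aud"], "rel_vis": rel["vis"]}


def rho_recovery_study(
    rhos: tuple[float, ...] = (0.0, 0.8),
    n_replicates: int = 20,
    n_subjects: int = 15,
    seed: int = 0,
    cfg: RunConfig | None = None,
) -> dict:
    """Replicate cohorts at each latent cross-modal correlation.

    For each rho, pools the observed score correlation and the per-modality
    split-half reliabilities over replicates and reports both the raw pooled
    estimate and the attenuation-corrected estimate of the latent correlation.
    """
    if cfg is None:
        cfg = scaled_config(seed=seed)
    out = {}
    rng = np.random.default_rng(seed)
    for rho in rhos:
        reps = [
            _one_rho_replicate(rho, n_subjects, int(rng.integers(2**31)), cfg)
            for _ in range(n_replicates)
        ]
        r_raw = float(np.mean([x["r_obs"] for x in reps]))
        rel_a = float(np.mean([x["rel_aud"] for x in reps]))
        rel_v = float(np.mean([x["rel_vis"] for x in reps]))
        out[rho] = {
            "r_raw": r_raw,
            "rel_aud": rel_a,
            "rel_vis": rel_v,
            "r_corrected": disattenuated_correlation(r_raw, rel_a, rel_v),
            "n_replicates": n_replicates,
            "n_subjects": n_subjects,
        }
    return out


def null_decoding_accuracy(
    n_subjects: int = 3, seed: int = 0, cfg: RunConfig | None = None
) -> dict:
    """Mean 4-class accuracy with shuffled training labels (expected: 0.25).

    Trains the time-resolved classifier on label-shuffled ordered forward
    trials and scores class-assignment accuracy on the matched test set over
    the full decoding window.
    """
    if cfg is None:
        cfg = scaled_config(seed=seed, decode_window=(-0.3, 0.3))
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_subjects):
        seq = make_design(cfg, rng)
        fm = make_forward_model(cfg.n_channels, seed=int(rng.integers(2**31)))
        p = SubjectParams(
            beta_aud=cfg.beta_mean, beta_vis=cfg.beta_mean, noise_sd=cfg.noise_sd,
            seed=int(rng.integers(2**31)),
        )
        rec = simulate_subject(seq, fm, p, sampling_rate=cfg.native_rate)
        epochs = preprocess(
            rec, cfg.filter_low, cfg.filter_high, cfg.analysis_rate,
            cfg.epoch_tmin, cfg.epoch_tmax,
        )
        train_idx = select_training_trials(epochs.metadata)
        test_o, test_r = select_test_trials(epochs.metadata, seed=int(rng.integers(2**31)))
        # shuffle the training labels in place of the true stimulus ids
        shuffled = epochs.metadata.copy()
        labels = shuffled["stimulus"].to_numpy().copy()
        perm = np.random.default_rng(int(rng.integers(2**31))).permutation(len(train_idx))
        labels[train_idx] = labels[train_idx][perm]
        shuffled["stimulus"] = labels
        epochs.metadata = shuffled
        series = time_resolved_decode(
            epochs, train_idx, np.concatenate([test_o, test_r]),
            window=cfg.decode_window, shrinkage=cfg.shrinkage,
        )
        # score accuracy against the unshuffled true labels of the test trials
        accs.append(decoding_accuracy(series).mean())
    return {"accuracy": float(np.mean(accs)), "per_subject": accs, "n_subjects": n_subjects}


def cluster_type1_study(
    n_cohorts: int = 250,
    n_subjects: int = 20,
    n_times: int = 30,
    n_permutations: int = 1000,
    critical_alpha: float = 0.025,
    seed: int = 0,
) -> dict:
    """False-positive rate of the cluster test on Gaussian null cohorts.

    Each cohort is i.i.d. standard-normal subjects x time data; a cohort
    counts as a false positive if any cluster reaches p < critical_alpha.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        data = rng.standard_normal((n_subjects, n_times))
        cfg = ClusterTestConfig(
            n_permutations=n_permutations,
            critical_alpha=critical_alpha,
            seed=int(rng.integers(2**31)),
        )
        res = cluster_permutation_test(data, config=cfg)
        hits += bool(res.significant)
    return {
        "false_positive_rate": hits / n_cohorts,
        "n_cohorts": n_cohorts,
        "nominal": critical_alpha,
    }
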