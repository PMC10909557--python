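"""Time-resolved decoding and the per-subject prediction-tendency score.

The logic of the measurement:

* **Training** uses only *ordered forward* trials, so the classifier can pick
  up both the evoked response to a stimulus and any prediction-related
  pattern that precedes a foreseeable stimulus.
* **Testing** uses only *self-repetition* trials whose predecessor transition
  (t-2 -> t-1) was forward, in both entropy contexts. Repetitions occur with
  the same probability (25%) in both contexts and carry identical bottom-up
  history once matched at t-1 and t-2, so any ordered-vs-random difference in
  prestimulus forward-transition evidence isolates context-dependent
  anticipation rather than carry-over processing.
* Per test trial and time point, the four class decision values d1-d4 are
  relabelled as transition evidence (forward / repetition / backward / other)
  given the stimulus at t-1.
* The **tendency curve** is the mean forward-transition evidence, ordered
  minus random, per time point; the **prediction tendency score** is its sum
  over prestimulus time (-0.3-0 s): one signed scalar per subject and
  modality.

A multiclass shrinkage LDA (pooled covariance shrunk toward a scaled
identity, Ledoit-Wolf analytic intensity by default) is trained independently
at every time sample (diagonal decoding); temporal generalization (train at
one time, test at all) is a separate operation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .preprocessing import SensorEpochs
from .sequence import N_STIMULI, ORDERED, RANDOM, classify_transition, forward_successor

__all__ = [
    "TRANSITION_LABELS",
    "DecisionValueSeries",
    "TendencyCurve",
    "select_training_trials",
    "select_test_trials",
    "train_lda",
    "time_resolved_decode",
    "transition_evidence",
    "tendency_curve",
    "tendency_score",
    "decoding_accuracy",
    "temporal_generalization",
]

TRANSITION_LABELS = ("forward", "repetition", "backward", "other")


@dataclass
class DecisionValueSeries:
    """Per-trial, per-class, per-time classifier decision values.

    ``dvals`` has shape (trials, 4, times) ordered by stimulus class 1-4;
    ``transition_evidence`` (same shape) is the per-trial permutation of the
    class axis into (forward, repetition, backward, other) given the previous
    stimulus, filled by :func:`transition_evidence`.
    """

    dvals: np.ndarray
    times: np.ndarray
    labels: np.ndarray  # true stimulus id per test trial
    prev_stimulus: np.ndarray
    condition: np.ndarray  # entropy label per test trial
    transition_evidence: np.ndarray | None = None


@dataclass
class TendencyCurve:
    """Ordered-minus-random forward-transition evidence over time."""

    values: np.ndarray  # (times,) for one subject, or (subjects, times)
    times: np.ndarray


class TrialSelectionError(ValueError):
    """Raised when a selection step yields no usable trials."""


def _transitions(meta: pd.DataFrame) -> np.ndarray:
    prev = meta["prev_stimulus"].to_numpy()
    curr = meta["stimulus"].to_numpy()
    out = np.array(
        [
            classify_transition(int(p), int(c)) if p > 0 else "none"
            for p, c in zip(prev, curr)
        ],
        dtype=object,
    )
    return out


def select_training_trials(meta: pd.DataFrame) -> np.ndarray:
    """Indices of ordered forward trials with clean history.

    Keeps trials in an ordered context whose t-1 -> t transition is forward,
    with both the trial and its predecessor non-omitted and the trial outside
    the burn-in window.
    """
    trans = _transitions(meta)
    mask = (
        (meta["entropy"].to_numpy() == ORDERED)
        & (trans == "forward")
        & ~meta["omitted"].to_numpy()
        & ~meta["prev_omitted"].to_numpy()
        & ~meta["burn_in"].to_numpy()
    )
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        counts = {
            "n_trials": len(meta),
            "n_ordered": int((meta["entropy"] == ORDERED).sum()),
            "n_forward": int((trans == "forward").sum()),
        }
        raise TrialSelectionError(f"no ordered forward training trials; {counts}")
    return idx


def select_test_trials(
    meta: pd.DataFrame, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Matched (ordered, random) sets of repetition test trials.

    A test trial must be a self-repetition at t-1 -> t preceded by a forward
    transition at t-2 -> t-1, with t, t-1 and t-2 all non-omitted and t
    outside burn-in. Within each stimulus-identity stratum the larger
    condition is randomly subselected to the size of the smaller (in the full
    design the ordered set is the larger one), so the joint distribution of
    the stimuli at t-1 and t-2 is identical across conditions by construction.
    """
    prev = meta["prev_stimulus"].to_numpy()
    prev2 = meta["prev2_stimulus"].to_numpy()
    curr = meta["stimulus"].to_numpy()
    valid_hist = (prev > 0) & (prev2 > 0)
    rep = valid_hist & (curr == prev)
    fwd_before = np.zeros(len(meta), dtype=bool)
    ok = valid_hist.nonzero()[0]
    fwd_before[ok] = [
        int(prev[i]) == forward_successor(int(prev2[i])) for i in ok
    ]
    clean = (
        ~meta["omitted"].to_numpy()
        & ~meta["prev_omitted"].to_numpy()
        & ~meta["prev2_omitted"].to_numpy()
        & ~meta["burn_in"].to_numpy()
    )
    eligible = rep & fwd_before & clean
    entropy = meta["entropy"].to_numpy()
    ordered_idx = np.flatnonzero(eligible & (entropy == ORDERED))
    random_idx = np.flatnonzero(eligible & (entropy == RANDOM))
    if len(ordered_idx) == 0 or len(random_idx) == 0:
        raise TrialSelectionError(
            f"empty test condition (ordered={len(ordered_idx)}, random={len(random_idx)})"
        )

    rng = np.random.default_rng(seed)
    keep_ord, keep_rand = [], []
    for s in range(1, N_STIMULI + 1):
        o = ordered_idx[curr[ordered_idx] == s]
        r = random_idx[curr[random_idx] == s]
        n = min(len(o), len(r))
        if n == 0:
            continue
        keep_ord.append(np.sort(rng.choice(o, size=n, replace=False)))
        keep_rand.append(np.sort(rng.choice(r, size=n, replace=False)))
    if not keep_ord:
        raise TrialSelectionError("no stimulus stratum present in both conditions")
    return np.concatenate(keep_ord), np.concatenate(keep_rand)


def train_lda(
    X: np.ndarray, labels: np.ndarray, shrinkage: float | str | None = "auto"
) -> LinearDiscriminantAnalysis:
    """Fit a multiclass shrinkage LDA on trials x channels data.

    ``shrinkage='auto'`` uses the Ledoit-Wolf analytic intensity; a float in
    [0, 1] fixes it (1 reduces the pooled covariance to a scaled identity,
    i.e. nearest-class-mean scoring); ``0``/``None`` uses the empirical
    covariance and fails loudly if it is singular.
    """
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 trials each")
    if shrinkage == 0:
        shrinkage = None
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    with np.errstate(all="ignore"):
        clf.fit(X, labels)
    if not np.all(np.isfinite(clf.coef_)):
        raise np.linalg.LinAlgError(
            "singular covariance; use shrinkage='auto' or a positive intensity"
        )
    return clf


def _window_indices(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    eps = 1e-9
    idx = np.flatnonzero((times >= lo - eps) & (times <= hi + eps))
    if len(idx) == 0:
        raise ValueError(f"window {window} outside epoch grid")
    return idx


def time_resolved_decode(
    epochs: SensorEpochs,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    window: tuple[float, float] = (-0.3, 0.3),
    shrinkage: float | str | None = "auto",
) -> DecisionValueSeries:
    """Diagonal decoding: train and test at each time sample of ``window``.

    Emits decision values d1-d4 for every test trial at every sample
    (endpoints inclusive). Training and test sets must be disjoint.
    """
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("training and test trials overlap")
    tsel = _window_indices(epochs.times, window)
    meta = epochs.metadata
    y_train = meta["stimulus"].to_numpy()[train_idx]
    dvals = np.empty((len(test_idx), N_STIMULI, len(tsel)))
    for k, ti in enumerate(tsel):
        clf = train_lda(epochs.data[train_idx, :, ti], y_train, shrinkage)
        dvals[:, :, k] = clf.decision_function(epochs.data[test_idx, :, ti])
    return DecisionValueSeries(
        dvals=dvals,
        times=epochs.times[tsel],
        labels=meta["stimulus"].to_numpy()[test_idx],
        prev_stimulus=meta["prev_stimulus"].to_numpy()[test_idx],
        condition=meta["entropy"].to_numpy()[test_idx],
    )


def transition_evidence(series: DecisionValueSeries) -> DecisionValueSeries:
    """Relabel class decision values as transition evidence per trial.

    Class c's decision value becomes evidence for the transition
    ``classify_transition(prev_stimulus, c)`` - a pure permutation of the
    class axis, trial by trial.
    """
    if np.any(series.prev_stimulus <= 0):
        raise ValueError("previous stimulus unknown for some test trials")
    ev = np.empty_like(series.dvals)
    lab_pos = {lab: i for i, lab in enumerate(TRANSITION_LABELS)}
    for prev in range(1, N_STIMULI + 1):
        rows = np.flatnonzero(series.prev_stimulus == prev)
        if len(rows) == 0:
            continue
        perm = [lab_pos[classify_transition(prev, c)] for c in range(1, N_STIMULI + 1)]
        for c, p in enumerate(perm):
            ev[np.ix_(rows, [p])] = series.dvals[np.ix_(rows, [c])]
    series.transition_evidence = ev
    return series


def _forward_evidence(series: DecisionValueSeries, condition: str) -> np.ndarray:
    if series.transition_evidence is None:
        raise ValueError("call transition_evidence() first")
    rows = series.condition == condition
    if not rows.any():
        raise ValueError(f"no test trials in condition {condition!r}")
    return series.transition_evidence[rows]  # (trials, 4, times)


def tendency_curve(
    series: DecisionValueSeries, contrast: str = "forward"
) -> TendencyCurve:
    """Ordered-minus-random mean transition evidence per time sample.

    ``contrast='forward'`` (default) contrasts the forward-transition decision
    value; ``'forward_minus_repetition'`` first takes forward minus repetition
    evidence within each trial.
    """
    ev_ord = _forward_evidence(series, ORDERED)
    ev_rand = _forward_evidence(series, RANDOM)
    if contrast == "forward":
        stat_ord, stat_rand = ev_ord[:, 0], ev_rand[:, 0]
    elif contrast == "forward_minus_repetition":
        stat_ord = ev_ord[:, 0] - ev_ord[:, 1]
        stat_rand = ev_rand[:, 0] - ev_rand[:, 1]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return TendencyCurve(
        values=stat_ord.mean(axis=0) - stat_rand.mean(axis=0), times=series.times
    )


def tendency_score(
    curve: TendencyCurve, prestim: tuple[float, float] = (-0.3, 0.0)
) -> float:
    """Summed curve value over prestimulus samples [prestim[0], prestim[1])."""
    lo, hi = prestim
    eps = 1e-9
    mask = (curve.times >= lo - eps) & (curve.times < hi - eps)
    if not mask.any():
        raise ValueError("empty prestimulus grid")
    return float(np.sum(np.atleast_2d(curve.values)[..., mask]))


def decoding_accuracy(series: DecisionValueSeries) -> np.ndarray:
    """Fraction of test trials whose top decision value is the true class, per time."""
    pred = series.dvals.argmax(axis=1) + 1
    return (pred == series.labels[:, None]).mean(axis=0)


def temporal_generalization(
    epochs: SensorEpochs,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    train_window: tuple[float, float] = (0.0, 0.3),
    test_window: tuple[float, float] = (-0.3, 0.3),
    shrinkage: float | str | None = "auto",
) -> dict:
    """Train at every sample of ``train_window``, test at every sample of
    ``test_window``; returns forward-transition evidence and accuracy matrices
    (train-time x test-time) for each entropy condition.
    """
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("training and test trials overlap")
    tr_sel = _window_indices(epochs.times, train_window)
    te_sel = _window_indices(epochs.times, test_window)
    meta = epochs.metadata
    y_train = meta["stimulus"].to_numpy()[train_idx]
    labels = meta["stimulus"].to_numpy()[test_idx]
    prev = meta["prev_stimulus"].to_numpy()[test_idx]
    cond = meta["entropy"].to_numpy()[test_idx]
    fwd_class = np.array([forward_successor(int(p)) for p in prev])

    out = {
        c: {
            "forward_evidence": np.empty((len(tr_sel), len(te_sel))),
            "accuracy": np.empty((len(tr_sel), len(te_sel))),
        }
        for c in (ORDERED, RANDOM)
    }
    rows = {c: cond == c for c in (ORDERED, RANDOM)}
    trial_ix = np.arange(len(test_idx))
    for a, ti in enumerate(tr_sel):
        clf = train_lda(epochs.data[train_idx, :, ti], y_train, shrinkage)
        for b, tj in enumerate(te_sel):
            d = clf.decision_function(epochs.data[test_idx, :, tj])
            fwd_ev = d[trial_ix, fwd_class - 1]
            acc = (d.argmax(axis=1) + 1) == labels
            for c in (ORDERED, RANDOM):
                out[c]["forward_evidence"][a, b] = fwd_ev[rows[c]].mean()
                out[c]["accuracy"][a, b] = acc[rows[c]].mean()
    out["train_times"] = epochs.times[tr_sel]
    out["test_times"] = epochs.times[te_sel]
    return out
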