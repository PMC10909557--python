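"""Entropy-conditioned Markov stimulus sequences.

The experimental design presents four stimulus identities (1-4) at a fixed
rate, with next-stimulus probabilities set by the current *entropy level*:

* ``ordered`` (low entropy): the cyclic forward transition (1→2, 2→3, 3→4,
  4→1) occurs with probability 0.75 and a self-repetition with 0.25; all
  other transitions never occur.
* ``random`` (high entropy): all 16 transitions are equally likely (0.25).

Entropy alternates between balanced segments within each block, a stratified
10% of trials is omitted (no stimulus delivered), and the first trials of
each segment are flagged as burn-in, reflecting the time an ideal Bayesian
observer needs to infer the new transition regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ORDERED",
    "RANDOM",
    "N_STIMULI",
    "TransitionModel",
    "SequenceTiming",
    "StimulusSequence",
    "build_transition_matrix",
    "forward_successor",
    "classify_transition",
    "generate_entropy_schedule",
    "generate_sequence",
    "apply_omissions",
    "mark_burn_in",
    "ideal_observer",
]

ORDERED = "ordered"
RANDOM = "random"
N_STIMULI = 4

FORWARD = "forward"
REPETITION = "repetition"
BACKWARD = "backward"
OTHER = "other"


class EntropyError(ValueError):
    """Raised for entropy labels other than 'ordered'/'random'."""


class StimulusIdError(ValueError):
    """Raised for stimulus identities outside 1..4."""


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic 4x4 next-stimulus probability matrix for one entropy level."""

    entropy: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (N_STIMULI, N_STIMULI):
            raise ValueError(f"transition matrix must be 4x4, got {probs.shape}")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        object.__setattr__(self, "probs", probs)


@dataclass(frozen=True)
class SequenceTiming:
    """Presentation timing: 3 Hz stimulation, 100 ms stimuli."""

    stimulation_rate: float = 3.0
    stimulus_duration: float = 0.1

    @property
    def onset_asynchrony(self) -> float:
        return 1.0 / self.stimulation_rate


@dataclass
class StimulusSequence:
    """Per-trial design arrays for one modality.

    ``stimulus`` holds identities 1..4 for every scheduled trial, including
    omitted ones (the identity is retained for bookkeeping; no stimulus is
    delivered on omitted trials).
    """

    stimulus: np.ndarray
    entropy: np.ndarray
    block: np.ndarray
    segment: np.ndarray
    omitted: np.ndarray = field(default=None)  # type: ignore[assignment]
    burn_in: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.stimulus)
        if self.omitted is None:
            self.omitted = np.zeros(n, dtype=bool)
        if self.burn_in is None:
            self.burn_in = np.zeros(n, dtype=bool)
        for name in ("entropy", "block", "segment", "omitted", "burn_in"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field '{name}' length mismatch")

    def __len__(self) -> int:
        return len(self.stimulus)

    def to_frame(self) -> pd.DataFrame:
        """One row per trial; serializable as TSV."""
        return pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "block": self.block,
                "segment": self.segment,
                "entropy": self.entropy,
                "stimulus": self.stimulus,
                "omitted": self.omitted,
                "burn_in": self.burn_in,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_transition_matrix(entropy: str) -> TransitionModel:
    """Transition model for one entropy level.

    ordered: P(forward) = 0.75, P(repetition) = 0.25, rest 0.
    random: all entries 0.25.
    """
    if entropy == ORDERED:
        probs = np.zeros((N_STIMULI, N_STIMULI))
        for s in range(1, N_STIMULI + 1):
            probs[s - 1, forward_successor(s) - 1] = 0.75
            probs[s - 1, s - 1] = 0.25
    elif entropy == RANDOM:
        probs = np.full((N_STIMULI, N_STIMULI), 0.25)
    else:
        raise EntropyError(f"unknown entropy level: {entropy!r}")
    return TransitionModel(entropy=entropy, probs=probs)


def _check_stimulus(s: int) -> None:
    if s not in (1, 2, 3, 4):
        raise StimulusIdError(f"stimulus id must be in 1..4, got {s!r}")


def forward_successor(s: int) -> int:
    """Cyclic successor: 1→2, 2→3, 3→4, 4→1."""
    _check_stimulus(s)
    return s % N_STIMULI + 1


def classify_transition(prev: int, curr: int) -> str:
    """Label the transition prev→curr as forward, repetition, backward or other."""
    _check_stimulus(prev)
    _check_stimulus(curr)
    if curr == forward_successor(prev):
        return FORWARD
    if curr == prev:
        return REPETITION
    if prev == forward_successor(curr):
        return BACKWARD
    return OTHER


def generate_entropy_schedule(
    n_blocks: int, segments_per_block: int, seed: int
) -> pd.DataFrame:
    """Balanced pseudorandom entropy labels, one row per segment.

    Each block receives an independent random permutation of an equal number
    of ordered and random segments.
    """
    if segments_per_block % 2 != 0:
        raise ValueError("segments_per_block must be even to balance entropy levels")
    if n_blocks < 1 or segments_per_block < 2:
        raise ValueError("need at least 1 block of 2 segments")
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_blocks):
        labels = np.array(
            [ORDERED] * (segments_per_block // 2) + [RANDOM] * (segments_per_block // 2)
        )
        rng.shuffle(labels)
        for s, lab in enumerate(labels):
            rows.append({"block": b, "segment": b * segments_per_block + s, "entropy": lab})
    return pd.DataFrame(rows)


def generate_sequence(
    schedule: pd.DataFrame,
    segment_length: int,
    seed: int,
    models: dict[str, TransitionModel] | None = None,
) -> StimulusSequence:
    """Sample a stimulus sequence following the scheduled entropy regimes.

    The first trial is uniform over 1..4; every later trial is drawn from the
    active entropy's transition row given the previous trial's stimulus.
    Transitions continue across segment boundaries under the new model (no
    restart at an entropy change).
    """
    if len(schedule) == 0:
        raise ValueError("empty entropy schedule")
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    if models is None:
        models = {e: build_transition_matrix(e) for e in (ORDERED, RANDOM)}
    cum = {e: np.cumsum(models[e].probs, axis=1) for e in models}

    rng = np.random.default_rng(seed)
    n_trials = len(schedule) * segment_length
    entropy = np.repeat(schedule["entropy"].to_numpy(), segment_length)
    block = np.repeat(schedule["block"].to_numpy(), segment_length)
    segment = np.repeat(schedule["segment"].to_numpy(), segment_length)

    u = rng.random(n_trials)
    stimulus = np.empty(n_trials, dtype=np.int64)
    stimulus[0] = rng.integers(1, N_STIMULI + 1)
    for t in range(1, n_trials):
        row = cum[entropy[t]][stimulus[t - 1] - 1]
        stimulus[t] = int(np.searchsorted(row, u[t], side="right")) + 1
    return StimulusSequence(stimulus=stimulus, entropy=entropy, block=block, segment=segment)


def apply_omissions(seq: StimulusSequence, rate: float, seed: int) -> StimulusSequence:
    """Flag an exact stratified fraction of trials as omitted.

    Within each (stimulus x entropy) stratum, exactly ``round(rate * size)``
    trials are flagged, at pseudorandom positions. Returns a new sequence;
    stimulus identities are retained on omitted trials.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"omission rate must be in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    omitted = np.zeros(len(seq), dtype=bool)
    for ent in np.unique(seq.entropy):
        for s in range(1, N_STIMULI + 1):
            idx = np.flatnonzero((seq.entropy == ent) & (seq.stimulus == s))
            n_omit = round(rate * len(idx))
            if n_omit:
                omitted[rng.choice(idx, size=n_omit, replace=False)] = True
    return StimulusSequence(
        stimulus=seq.stimulus.copy(),
        entropy=seq.entropy.copy(),
        block=seq.block.copy(),
        segment=seq.segment.copy(),
        omitted=omitted,
        burn_in=seq.burn_in.copy(),
    )


def mark_burn_in(seq: StimulusSequence, n_exclude: int = 20) -> StimulusSequence:
    """Flag the first ``n_exclude`` trials of every segment as burn-in."""
    if n_exclude < 0:
        raise ValueError("n_exclude must be >= 0")
    burn_in = np.zeros(len(seq), dtype=bool)
    for seg in np.unique(seq.segment):
        idx = np.flatnonzero(seq.segment == seg)
        if n_exclude >= len(idx):
            raise ValueError(
                f"n_exclude={n_exclude} >= segment length {len(idx)} (segment {seg})"
            )
        burn_in[idx[:n_exclude]] = True
    return StimulusSequence(
        stimulus=seq.stimulus.copy(),
        entropy=seq.entropy.copy(),
        block=seq.block.copy(),
        segment=seq.segment.copy(),
        omitted=seq.omitted.copy(),
        burn_in=burn_in,
    )


def ideal_observer(
    stimuli: np.ndarray, prior_strength: float = 1.0
) -> tuple[np.ndarray, int | None]:
    """Dirichlet-count learner of next-stimulus probabilities.

    Maintains, per current stimulus, Dirichlet(``prior_strength``) pseudo-counts
    over the four next-stimulus outcomes. For each trial t >= 1 the returned
    trajectory holds the posterior predictive probability of the *forward
    successor* of the stimulus at t-1, evaluated before observing trial t
    (trial 0 has no prediction and is NaN). Also returns the first trial index
    at which that probability exceeds 0.5, or None if it never does.

    This is a simplified rational-observer device that reproduces the
    qualitative rationale for excluding early post-regime-change trials; it is
    not a hierarchical Gaussian filter.
    """
    stimuli = np.asarray(stimuli)
    if len(stimuli) == 0:
        raise ValueError("empty sequence")
    if prior_strength <= 0:
        raise ValueError("prior_strength must be positive")
    counts = np.zeros((N_STIMULI, N_STIMULI))
    traj = np.full(len(stimuli), np.nan)
    first_cross: int | None = None
    for t in range(1, len(stimuli)):
        prev = int(stimuli[t - 1])
        fwd = forward_successor(prev)
        row = counts[prev - 1]
        traj[t] = (row[fwd - 1] + prior_strength) / (row.sum() + N_STIMULI * prior_strength)
        if first_cross is None and traj[t] > 0.5:
            first_cross = t
        counts[prev - 1, int(stimuli[t]) - 1] += 1
    return traj, first_cross
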