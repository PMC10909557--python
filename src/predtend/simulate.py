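"""Synthetic multi-channel recordings with controllable prediction tendency.

Each of the four stimulus identities projects to the sensors through a fixed
unit-norm spatial pattern (a stand-in for the sensor projection of a
stimulus-specific cortical source). A recording is the superposition of

* an evoked response per non-omitted trial: amplitude x pattern(stimulus) x a
  smooth unimodal kernel supported on roughly [0, 0.7] s post-onset;
* a prestimulus *pre-activation* in ordered segments only: for every trial
  whose predecessor was stimulus s, the pattern of the forward successor of s
  ramps up linearly over [-0.3, 0) s before onset, scaled by the subject's
  tendency parameter beta (omitted trials still carry this prediction - there
  is simply no bottom-up input afterwards);
* i.i.d. Gaussian sensor noise.

beta is the simulator's ground truth for the individual prediction tendency
that the decoding pipeline is asked to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .sequence import ORDERED, SequenceTiming, StimulusSequence, forward_successor

__all__ = [
    "ForwardModel",
    "SubjectParams",
    "SensorRecording",
    "make_forward_model",
    "evoked_waveform",
    "evoked_waveform_integral",
    "prediction_ramp",
    "simulate_subject",
    "simulate_cohort",
]

EVOKED_SUPPORT = 0.7  # s; stimulus identity is decodable out to ~0.7 s post-onset
PRESTIM_RAMP = 0.3  # s; prediction builds up over the 300 ms before onset


@dataclass(frozen=True)
class ForwardModel:
    """Four unit-norm sensor patterns, one per stimulus identity."""

    topographies: np.ndarray  # 4 x n_channels

    @property
    def n_channels(self) -> int:
        return self.topographies.shape[1]


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth simulation parameters for one subject."""

    beta_aud: float
    beta_vis: float
    evoked_amplitude: float = 1.0
    evoked_latency: float = 0.17
    evoked_width: float = 0.12
    noise_sd: float = 0.7
    seed: int = 0


@dataclass
class SensorRecording:
    """Continuous channels x samples array with an event list."""

    data: np.ndarray
    sampling_rate: float
    events: np.ndarray  # columns: sample index, stimulus id, omitted flag
    sequence: StimulusSequence | None = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def make_forward_model(
    n_channels: int, seed: int, max_abs_corr: float = 0.3, max_tries: int = 10_000
) -> ForwardModel:
    """Draw 4 random unit-norm patterns with bounded pairwise correlation.

    Rejection-samples standard-normal patterns until all pairwise Pearson
    correlations satisfy ``|r| <= max_abs_corr``, so the four stimulus classes
    are linearly separable at the sensor level.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels for 4 separable patterns")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        pats = rng.standard_normal((4, n_channels))
        pats /= np.linalg.norm(pats, axis=1, keepdims=True)
        r = np.corrcoef(pats)
        if np.all(np.abs(r[np.triu_indices(4, k=1)]) <= max_abs_corr):
            return ForwardModel(topographies=pats)
    raise RuntimeError("could not satisfy the pattern-correlation bound")


def evoked_waveform(
    t: np.ndarray | float,
    latency: float = 0.17,
    width: float = 0.12,
    support: float = EVOKED_SUPPORT,
) -> np.ndarray:
    """Gaussian-windowed half-sine evoked kernel.

    ``sin(pi * t / support) * exp(-(t - latency)^2 / (2 width^2))`` on
    ``[0, support]``, zero elsewhere. Smooth, unimodal, causal, with its peak
    pulled toward ``latency`` by the Gaussian window.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    inside = (t >= 0) & (t <= support)
    ti = t[inside]
    out[inside] = np.sin(np.pi * ti / support) * np.exp(
        -((ti - latency) ** 2) / (2 * width**2)
    )
    return out


def evoked_waveform_integral(
    latency: float = 0.17, width: float = 0.12, support: float = EVOKED_SUPPORT
) -> float:
    """Closed-form integral of the evoked kernel over its support.

    Uses Im[ integral of exp(i a t) * Gaussian ], which reduces to the error
    function of a complex argument.
    """
    a = np.pi / support
    s = width
    mu = latency
    z0 = (0 - mu) / (s * np.sqrt(2)) - 1j * a * s / np.sqrt(2)
    z1 = (support - mu) / (s * np.sqrt(2)) - 1j * a * s / np.sqrt(2)
    val = (
        s
        * np.sqrt(np.pi / 2)
        * np.exp(1j * a * mu - a**2 * s**2 / 2)
        * (erf(z1) - erf(z0))
    )
    return float(np.imag(val))


def prediction_ramp(t: np.ndarray, ramp: float = PRESTIM_RAMP) -> np.ndarray:
    """Linear ramp from 0 at -ramp to 1 just before onset, supported on [-ramp, 0)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    inside = (t >= -ramp) & (t < 0)
    out[inside] = (t[inside] + ramp) / ramp
    return out


def simulate_subject(
    seq: StimulusSequence,
    fm: ForwardModel,
    params: SubjectParams,
    timing: SequenceTiming = SequenceTiming(),
    sampling_rate: float = 300.0,
    beta: float | None = None,
    pad: float = 1.0,
) -> SensorRecording:
    """Render one continuous recording for one modality.

    ``beta`` overrides the modality-specific tendency amplitude (defaults to
    ``params.beta_aud``). ``pad`` seconds of noise-only signal are prepended
    and appended so that full epochs exist around every event.
    """
    if beta is None:
        beta = params.beta_aud
    rng = np.random.default_rng(params.seed)
    soa_samples = sampling_rate / timing.stimulation_rate
    if abs(soa_samples - round(soa_samples)) > 1e-9:
        raise ValueError("sampling_rate must be an integer multiple of the stimulation rate")
    soa_samples = int(round(soa_samples))

    n_trials = len(seq)
    pad_samples = int(round(pad * sampling_rate))
    n_samples = pad_samples * 2 + n_trials * soa_samples
    n_ch = fm.n_channels

    if params.noise_sd > 0:
        data = rng.standard_normal((n_ch, n_samples)) * params.noise_sd
    else:
        data = np.zeros((n_ch, n_samples))

    onsets = pad_samples + np.arange(n_trials) * soa_samples

    t_ev = np.arange(int(round(EVOKED_SUPPORT * sampling_rate)) + 1) / sampling_rate
    kernel = evoked_waveform(t_ev, params.evoked_latency, params.evoked_width)
    ramp_len = int(round(PRESTIM_RAMP * sampling_rate))
    t_ramp = np.arange(-ramp_len, 0) / sampling_rate
    ramp = prediction_ramp(t_ramp)

    topo = fm.topographies
    for i in range(n_trials):
        on = onsets[i]
        if not seq.omitted[i]:
            data[:, on : on + len(kernel)] += params.evoked_amplitude * np.outer(
                topo[seq.stimulus[i] - 1], kernel
            )
        # pre-activation of the predicted (forward) stimulus, ordered context only
        if i > 0 and beta != 0 and seq.entropy[i] == ORDERED:
            pred = forward_successor(int(seq.stimulus[i - 1]))
            data[:, on - ramp_len : on] += beta * np.outer(topo[pred - 1], ramp)

    events = np.column_stack(
        [onsets, seq.stimulus, seq.omitted.astype(np.int64)]
    ).astype(np.int64)
    return SensorRecording(
        data=data, sampling_rate=sampling_rate, events=events, sequence=seq
    )


def draw_cohort_betas(
    n_subjects: int,
    rho: float,
    mean: float = 0.4,
    sd: float = 0.15,
    seed: int = 0,
    truncate: bool = True,
) -> np.ndarray:
    """Per-subject (beta_aud, beta_vis) pairs from a bivariate Gaussian.

    With ``truncate`` (default), pairs with any negative component are
    redrawn, keeping tendencies non-negative.
    """
    if not -1 <= rho <= 1:
        raise ValueError("rho must lie in [-1, 1]")
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    betas = np.empty((n_subjects, 2))
    for i in range(n_subjects):
        pair = rng.multivariate_normal([mean, mean], cov, method="svd")
        if truncate:
            while pair.min() < 0:
                pair = rng.multivariate_normal([mean, mean], cov, method="svd")
        betas[i] = pair
    return betas


def simulate_cohort(
    n_subjects: int,
    rho: float,
    schedule_fn,
    seed: int = 0,
    n_channels: int = 32,
    sampling_rate: float = 300.0,
    beta_mean: float = 0.4,
    beta_sd: float = 0.15,
    truncate: bool = True,
    noise_sd: float = 0.7,
    timing: SequenceTiming = SequenceTiming(),
):
    """Yield per-subject (recording_aud, recording_vis, SubjectParams).

    ``schedule_fn(rng)`` must return a fully prepared
    :class:`~predtend.sequence.StimulusSequence` (omissions and burn-in
    applied); it is called twice per subject so the two modalities use
    independent sequences, and each modality gets an independent forward
    model, mirroring separate sensory systems.
    """
    betas = draw_cohort_betas(
        n_subjects, rho, mean=beta_mean, sd=beta_sd, seed=seed, truncate=truncate
    )
    rng = np.random.default_rng(seed + 1)
    for i in range(n_subjects):
        p = SubjectParams(
            beta_aud=betas[i, 0],
            beta_vis=betas[i, 1],
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        fm_aud = make_forward_model(n_channels, seed=int(rng.integers(2**31)))
        fm_vis = make_forward_model(n_channels, seed=int(rng.integers(2**31)))
        seq_aud = schedule_fn(np.random.default_rng(int(rng.integers(2**31))))
        seq_vis = schedule_fn(np.random.default_rng(int(rng.integers(2**31))))
        rec_aud = simulate_subject(
            seq_aud, fm_aud, p, timing, sampling_rate, beta=p.beta_aud
        )
        p_vis = SubjectParams(
            beta_aud=p.beta_aud,
            beta_vis=p.beta_vis,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        rec_vis = simulate_subject(
            seq_vis, fm_vis, p_vis, timing, sampling_rate, beta=p.beta_vis
        )
        yield rec_aud, rec_vis, p
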