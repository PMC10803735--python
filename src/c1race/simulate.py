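"""Synthetic EEG epochs and reaction-time tables with known ground truth.

The EEG generator injects a retinotopic early visual component (the C1
source) at occipital/parietal channels.  Its defining property — the one the
downstream difference wave exploits — is the polarity flip between upper and
lower visual field stimulation caused by the opposing banks of the calcarine
sulcus.  The component can be suppressed per condition (multiplicative factor
in [0, 1]) to emulate a crossmodal suppression of the earliest visual
cortical response.  On top of the signal the generator adds 1/f-shaped
background noise (independent per channel plus a shared component), and
blink, saccade and motor artifacts with amplitudes that exceed the rejection
thresholds of the ERP pipeline.

The reaction-time generator produces redundant-target data from either a
race architecture (response = faster of two ex-Gaussian channel finishing
times, optionally correlated) or a coactivation architecture (race minimum
sped up by a fixed shift), with rare targets embedded among standards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy import stats

from .epochs import EpochSet
from .montage import CHANNELS_32, DEFAULT_MIRROR_MAP, MontageMirrorMap

# --------------------------------------------------------------------------
# EEG simulation
# --------------------------------------------------------------------------

#: Scalp projection of the C1 source for a *right*-hemifield stimulus
#: (strongest at O1, decaying toward parietal sites).  Channels not listed
#: get a small negative weight after mean removal, giving a dipolar
#: occipital-positive / frontal-negative topography.
_C1_BASE_WEIGHTS: dict[str, float] = {
    "O1": 1.0, "O2": 0.6, "Pz": 0.5, "P3": 0.45, "P4": 0.35,
    "P7": 0.3, "P8": 0.2, "CP1": 0.15, "CP2": 0.1, "CP5": 0.1, "CP6": 0.05,
}

#: Temporal envelope of the C1 source: Gaussian peaking at 75 ms (unit peak).
_C1_PEAK_MS = 75.0
_C1_WIDTH_MS = 12.0

_BLINK_WEIGHTS: dict[str, float] = {
    "FP1": 1.0, "FP2": 1.0, "F3": 0.5, "F4": 0.5, "Fz": 0.5,
    "F7": 0.35, "F8": 0.35, "FC1": 0.25, "FC2": 0.25, "F9": 0.3, "F10": 0.3,
}
_BLINK_DURATION_MS = 400.0

_SACCADE_WEIGHTS: dict[str, float] = {
    "F9": 1.0, "F10": -1.0, "F7": 0.3, "F8": -0.3, "FP1": 0.2, "FP2": -0.2,
}

#: Fraction of noise variance shared across channels.
_SHARED_NOISE_FRAC = 0.25


def c1_weight_vector(channels=CHANNELS_32) -> np.ndarray:
    """Zero-mean forward-projection weights for a right-hemifield stimulus.

    The mean over channels is removed so the injected topography is exactly
    invariant under common-average re-referencing.
    """
    w = np.array([_C1_BASE_WEIGHTS.get(c, 0.0) for c in channels], dtype=float)
    return w - w.mean()


def c1_envelope(times_ms: np.ndarray) -> np.ndarray:
    """Unit-peak temporal envelope of the simulated C1 source."""
    t = np.asarray(times_ms, dtype=float)
    return np.exp(-0.5 * ((t - _C1_PEAK_MS) / _C1_WIDTH_MS) ** 2)


@dataclass
class EEGSimConfig:
    """Parameters of the synthetic EEG study.

    ``trials_per_cell`` counts *standard* (non-target) trials per collapsed
    (condition × visual field) cell, split evenly over left/right stimulus
    sides; rare targets are added on top at ``target_prob``.
    ``suppression`` maps each visual condition to a multiplicative factor in
    [0, 1] on the C1 source strength ({"V": 1, "AV_i": 0.5, "AV_c": 0}
    emulates a spatially graded crossmodal suppression; all ones emulate an
    unaffected control group).
    """

    n_participants: int = 14
    trials_per_cell: int = 200
    channels: tuple[str, ...] = CHANNELS_32
    srate: float = 500.0
    epoch_window: tuple[float, float] = (-100.0, 300.0)
    c1_amplitude: float = 2.0
    polarity_flip: bool = True
    suppression: dict[str, float] = field(
        default_factory=lambda: {"V": 1.0, "AV_i": 1.0, "AV_c": 1.0}
    )
    noise_sd: float = 5.0
    pink_exponent: float = 1.0
    blink_rate: float = 0.05
    saccade_rate: float = 0.05
    participant_sd: float = 0.4
    target_prob: float = 0.2
    miss_rate: float = 0.05
    include_auditory: bool = True
    group: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        unknown = set(self.suppression) - {"V", "AV_i", "AV_c"}
        if unknown:
            raise ValueError(f"unknown condition key(s) in suppression: {sorted(unknown)}")
        for cond, s in self.suppression.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"suppression[{cond!r}] must lie in [0, 1]")
        lo, hi = self.epoch_window
        if lo > -100.0 or hi < 100.0:
            raise ValueError(
                "epoch window must contain [-100, 100] ms "
                "(baseline plus the C1 latency range)"
            )
        if not 0.0 < self.target_prob < 1.0:
            raise ValueError("target_prob must lie in (0, 1)")

    @property
    def times(self) -> np.ndarray:
        lo, hi = self.epoch_window
        n = int(round((hi - lo) * self.srate / 1000.0)) + 1
        return lo + np.arange(n) * 1000.0 / self.srate


def expected_delta_c1(
    config: EEGSimConfig,
    electrode: str,
    condition: str = "V",
    window: tuple[float, float] = (50.0, 100.0),
) -> float:
    """Analytic expectation of the ΔC1 statistic for the simulated signal.

    ΔC1 is the LVF−UVF difference averaged over ``window``; with the polarity
    flip the signed source contributes twice, scaled by the projection weight
    of ``electrode`` and the window mean of the temporal envelope.
    """
    w = c1_weight_vector(config.channels)[list(config.channels).index(electrode)]
    times = config.times
    lo, hi = window
    tol = 500.0 / config.srate
    mask = (times >= lo - tol) & (times <= hi + tol)
    env = c1_envelope(times[mask]).mean()
    flip = 2.0 if config.polarity_flip else 0.0
    return flip * config.c1_amplitude * config.suppression.get(condition, 1.0) * w * env


def _pink_filter(n_samples: int, srate: float, exponent: float, sd: float) -> np.ndarray:
    """rfft-domain gain giving 1/f^exponent noise with variance ``sd**2``."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    # Parseval: output variance of unit white noise through this filter
    weights = np.full_like(freqs, 2.0)
    weights[0] = 1.0
    if n_samples % 2 == 0:
        weights[-1] = 1.0
    var = float(np.sum(weights * gain**2) / n_samples)
    if var > 0:
        gain *= sd / math.sqrt(var)
    return gain


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                gain: np.ndarray, n_samples: int, n_fft: int) -> np.ndarray:
    """Stationary 1/f noise synthesized directly in the frequency domain.

    The rfft of unit white noise has independent complex-Gaussian bins with
    E|W_k|² = n (DC and Nyquist real); drawing that spectrum directly and
    shaping it with ``gain`` (already variance-normalized for ``n_fft``)
    skips the forward transform.  ``n_fft`` is a fast transform length; the
    leading ``n_samples`` of the circular noise are returned (stationarity
    keeps the variance exact).
    """
    n_bins = n_fft // 2 + 1
    re = rng.standard_normal(shape + (n_bins,), dtype=np.float32)
    im = rng.standard_normal(shape + (n_bins,), dtype=np.float32)
    im[..., 0] = 0.0
    scale = np.full(n_bins, math.sqrt(n_fft / 2.0), dtype=np.float32)
    scale[0] = math.sqrt(n_fft)
    if n_fft % 2 == 0:
        scale[-1] = math.sqrt(n_fft)
        im[..., -1] = 0.0
    spec = (re + 1j * im) * (scale * gain.astype(np.float32))
    out = sfft.irfft(spec, n=n_fft, axis=-1)
    return out[..., :n_samples]


def _exgauss(rng: np.random.Generator, mu: float, sigma: float, tau: float,
             size) -> np.ndarray:
    return mu + sigma * rng.standard_normal(size) + tau * rng.standard_exponential(size)


def _participant_trial_table(config: EEGSimConfig, participant: str,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Lay out the trial list for one participant (balanced cells)."""
    rows: list[dict] = []
    n_std = config.trials_per_cell
    n_tgt = int(round(n_std * config.target_prob / (1.0 - config.target_prob)))

    def add(condition: str, vf: str, side: str, sound: str, n: int, target: bool):
        for _ in range(n):
            rows.append(dict(
                participant=participant, condition=condition, visual_field=vf,
                visual_side=side, sound_side=sound, is_target=target,
            ))

    half = n_std // 2
    half_t = n_tgt // 2
    for cond in ("V", "AV_c", "AV_i"):
        for vf in ("UVF", "LVF"):
            for side, ns, nt in (("left", n_std - half, n_tgt - half_t),
                                 ("right", half, half_t)):
                if cond == "V":
                    sound = "none"
                elif cond == "AV_c":
                    sound = side
                else:
                    sound = "right" if side == "left" else "left"
                add(cond, vf, side, sound, ns, target=False)
                add(cond, vf, side, sound, nt, target=True)
    if config.include_auditory:
        for sound in ("left", "right"):
            add("A", "none", "none", sound, n_std, target=False)
            add("A", "none", "none", sound, n_tgt, target=True)

    table = pd.DataFrame(rows)
    # unspeeded responses to targets; a fraction lands within 500 ms of onset
    n = len(table)
    latency = _exgauss(rng, 450.0, 80.0, 150.0, n)
    responded = table["is_target"].to_numpy() & (rng.random(n) >= config.miss_rate)
    table["response_latency_ms"] = np.where(responded, latency, np.nan)
    return table


def simulate_eeg_participant(config: EEGSimConfig, index: int,
                             mirror_map: MontageMirrorMap = DEFAULT_MIRROR_MAP,
                             ) -> EpochSet:
    """Simulate one participant's epoched EEG (deterministic in config.seed)."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
    rng = np.random.Generator(np.random.PCG64(ss))
    participant = f"{config.group}{index + 1:02d}"

    table = _participant_trial_table(config, participant, rng)
    times = config.times
    n_trials, n_ch, n_samp = len(table), len(config.channels), times.size

    # --- background noise: independent + shared 1/f components
    if config.noise_sd > 0:
        n_fft = sfft.next_fast_len(n_samp)
        gain = _pink_filter(n_fft, config.srate, config.pink_exponent, config.noise_sd)
        data = np.float32(math.sqrt(1.0 - _SHARED_NOISE_FRAC)) * _pink_noise(
            rng, (n_trials, n_ch), gain, n_samp, n_fft)
        shared = _pink_noise(rng, (n_trials,), gain, n_samp, n_fft)
        data += np.float32(math.sqrt(_SHARED_NOISE_FRAC)) * shared[:, None, :]
        data = data.astype(np.float64)
    else:
        data = np.zeros((n_trials, n_ch, n_samp))

    # --- retinotopic component with UVF/LVF polarity flip
    w_right = c1_weight_vector(config.channels)
    perm = mirror_map.permutation(config.channels)
    w_left = w_right[perm]
    env = c1_envelope(times)
    amp_p = config.c1_amplitude + config.participant_sd * rng.standard_normal()
    cond = table["condition"].to_numpy()
    vf = table["visual_field"].to_numpy()
    side = table["visual_side"].to_numpy()
    sign = np.where(vf == "LVF", 1.0, np.where(vf == "UVF", -1.0, 0.0))
    if not config.polarity_flip:
        sign = np.abs(sign)
    supp = np.array([config.suppression.get(c, 0.0) if c != "A" else 0.0
                     for c in cond])
    scale = amp_p * sign * supp  # per trial
    is_left = side == "left"
    weights = np.where(is_left[:, None], w_left[None, :], w_right[None, :])
    data += (scale[:, None] * weights)[:, :, None] * env[None, None, :]

    # --- artifacts (ground truth recorded for audit)
    ch_index = {c: i for i, c in enumerate(config.channels)}
    has_blink = rng.random(n_trials) < config.blink_rate
    has_saccade = rng.random(n_trials) < config.saccade_rate
    for t in np.flatnonzero(has_blink):
        peak = rng.normal(250.0, 30.0)
        center = rng.uniform(-25.0, 175.0)
        span = (times >= center - _BLINK_DURATION_MS / 2) & (
            times <= center + _BLINK_DURATION_MS / 2)
        shape = 0.5 * (1.0 + np.cos(
            2.0 * np.pi * (times[span] - center) / _BLINK_DURATION_MS))
        for c, wgt in _BLINK_WEIGHTS.items():
            if c in ch_index:
                data[t, ch_index[c], span] += peak * wgt * shape
    for t in np.flatnonzero(has_saccade):
        step = rng.normal(120.0, 20.0) * rng.choice([-1.0, 1.0])
        onset = rng.uniform(-25.0, 150.0)
        span = times >= onset
        for c, wgt in _SACCADE_WEIGHTS.items():
            if c in ch_index:
                data[t, ch_index[c], span] += step * wgt
    table["sim_blink"] = has_blink
    table["sim_saccade"] = has_saccade

    return EpochSet(
        data=data.astype(np.float32),
        times=times,
        channel_names=config.channels,
        trial_table=table,
        srate=config.srate,
    )


def simulate_eeg_dataset(config: EEGSimConfig,
                         mirror_map: MontageMirrorMap = DEFAULT_MIRROR_MAP,
                         ) -> list[EpochSet]:
    """Simulate all participants; element ``i`` equals
    :func:`simulate_eeg_participant` called with index ``i``."""
    return [simulate_eeg_participant(config, i, mirror_map)
            for i in range(config.n_participants)]


# --------------------------------------------------------------------------
# Reaction-time simulation
# --------------------------------------------------------------------------

RT_MODELS = ("race_independent", "race_correlated", "coactivation")

#: Stimulus classes: unimodal targets, bimodal single-target, bimodal double
#: target.  ``A_T``/``AT_V0`` respond via the auditory channel, ``V_T``/
#: ``A0_VT`` via the visual channel, ``AT_VT`` via the race/coactivation rule.
STIMULUS_CLASSES = ("A_T", "AT_V0", "V_T", "A0_VT", "AT_VT")

_TARGET_CLASS = {
    "A_T": "A_only", "AT_V0": "A_only",
    "V_T": "V_only", "A0_VT": "V_only",
    "AT_VT": "AV_double",
}


@dataclass
class RTSimConfig:
    """Parameters of the synthetic redundant-target detection task.

    ``channel_params`` gives ex-Gaussian (µ, σ, τ) finishing-time parameters
    in ms per modality.  ``n_trials`` counts target trials per stimulus class
    and congruence cell; standards are added so targets make up
    ``target_prob`` of all trials.
    """

    model: str = "race_independent"
    channel_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"A": (350.0, 60.0, 120.0), "V": (400.0, 60.0, 120.0)}
    )
    rho: float = 0.0
    coactivation_shift: float = 0.0
    target_prob: float = 0.2
    miss_rate: float = 0.05
    false_alarm_rate: float = 0.01
    n_trials: int = 100
    n_participants: int = 12
    participant_jitter: float = 20.0
    min_rt: float = 100.0
    group: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in RT_MODELS:
            raise ValueError(f"invalid model {self.model!r}; choose from {RT_MODELS}")
        if self.coactivation_shift < 0:
            raise ValueError("coactivation_shift must be nonnegative")
        if not 0.0 < self.target_prob < 1.0:
            raise ValueError("target_prob must lie in (0, 1)")
        for mod, (mu, sigma, tau) in self.channel_params.items():
            if sigma < 0 or tau < 0:
                raise ValueError(f"sigma and tau must be nonnegative for {mod!r}")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")


def simulate_rt_dataset(config: RTSimConfig) -> pd.DataFrame:
    """Simulate the trial-level reaction-time table.

    Returns a DataFrame with columns participant, group, stimulus,
    target_class, congruence, is_target, rt_ms, correct.  Misses delete the
    response (rt_ms = NaN) rather than censoring it.
    """
    mu_a, sg_a, tau_a = config.channel_params["A"]
    mu_v, sg_v, tau_v = config.channel_params["V"]
    rho = config.rho if config.model == "race_correlated" else 0.0
    shift = config.coactivation_shift if config.model == "coactivation" else 0.0

    frames: list[pd.DataFrame] = []
    for p in range(config.n_participants):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(1000 + p,))
        rng = np.random.Generator(np.random.PCG64(ss))
        pid = f"{config.group}{p + 1:02d}"
        offset = config.participant_jitter * rng.standard_normal()

        rows: list[dict] = []
        for stim in STIMULUS_CLASSES:
            congruences = ("congruent", "incongruent") if stim != "A_T" and stim != "V_T" \
                else ("none",)
            for cong in congruences:
                n = config.n_trials
                z = rng.standard_normal((n, 2))
                z_v = rho * z[:, 0] + math.sqrt(1.0 - rho**2) * z[:, 1]
                t_a = mu_a + offset + sg_a * z[:, 0] + tau_a * rng.standard_exponential(n)
                t_v = mu_v + offset + sg_v * z_v + tau_v * rng.standard_exponential(n)
                if stim in ("A_T", "AT_V0"):
                    rt = t_a
                elif stim in ("V_T", "A0_VT"):
                    rt = t_v
                else:
                    rt = np.maximum(np.minimum(t_a, t_v) - shift, config.min_rt)
                miss = rng.random(n) < config.miss_rate
                for i in range(n):
                    rows.append(dict(
                        participant=pid, group=config.group, stimulus=stim,
                        target_class=_TARGET_CLASS[stim], congruence=cong,
                        is_target=True,
                        rt_ms=np.nan if miss[i] else float(rt[i]),
                        correct=not miss[i],
                    ))
        n_targets = len(rows)
        n_standards = int(round(n_targets * (1.0 - config.target_prob)
                                / config.target_prob))
        fa = rng.random(n_standards) < config.false_alarm_rate
        fa_rt = rng.uniform(250.0, 900.0, n_standards)
        for i in range(n_standards):
            rows.append(dict(
                participant=pid, group=config.group, stimulus="standard",
                target_class="standard", congruence="none", is_target=False,
                rt_ms=float(fa_rt[i]) if fa[i] else np.nan,
                correct=not fa[i],
            ))
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Analytic distribution helpers (used by tests and oracles)
# --------------------------------------------------------------------------

def exgauss_cdf(t, mu: float, sigma: float, tau: float):
    """Ex-Gaussian CDF (normal(mu, sigma) + exponential(tau))."""
    if tau <= 0:
        return stats.norm.cdf(t, loc=mu, scale=sigma)
    return stats.exponnorm.cdf(t, K=tau / sigma, loc=mu, scale=sigma)


def race_min_cdf(t, params_a, params_v):
    """CDF of min of two independent ex-Gaussian finishing times."""
    fa = exgauss_cdf(t, *params_a)
    fv = exgauss_cdf(t, *params_v)
    return fa + fv - fa * fv
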