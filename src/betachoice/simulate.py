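"""Seeded synthetic cohorts: observer-driven choices, RTs, and response-locked EEG.

The generator produces desk-scale datasets carrying the statistical
structure the analysis pipeline assumes:

* choices drawn from the contraction-bias observer (:mod:`betachoice.observer`),
  with a configurable response bias toward "f2 > f1";
* shifted-lognormal response times that are faster for "f2 > f1" choices,
  for correct and incorrect trials alike;
* EEG epochs locked to saccade onset containing 1/f background noise, a
  steady-state component at the trial's f2 frequency during the second
  stimulus (placed via the trial's RT, so the stimulus-frequency confound of
  the real experiment is present), and a choice-selective band-limited
  24-32 Hz component in right-frontal channels in a pre-response window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochArray, n_samples_for_window
from .montage import standard_64_montage
from .observer import ObserverParams, choice_probability
from .stimuli import schedule_session

#: Observer defaults emulating the published cohort's accuracy pattern
#: (~74% correct overall, harder 2 Hz pairs worse, positive differences
#: judged slightly better, mild response bias toward "f2 > f1").
DEFAULT_OBSERVER = ObserverParams(sigma_like=0.145, sigma_prior=0.26, bias=0.02)

#: Duration of each flutter stimulus, ms.
STIM_DURATION_MS = 250.0


@dataclass(frozen=True)
class RTModel:
    """Shifted-lognormal response times with a choice-dependent location shift.

    ``rt = location * exp(sigma * Z - sigma^2 / 2)`` with
    ``location = base_ms + choice_shift_ms`` for "f2 > f1" choices and
    ``base_ms`` otherwise; a negative ``choice_shift_ms`` makes the
    preferred "f2 > f1" choice faster regardless of correctness.
    """

    base_ms: float = 600.0
    choice_shift_ms: float = -50.0
    sigma: float = 0.15

    def __post_init__(self) -> None:
        if self.base_ms + min(0.0, self.choice_shift_ms) <= 0:
            raise ValueError("RT location must stay positive")


@dataclass(frozen=True)
class BetaEffect:
    """Choice-selective band-limited amplitude effect injected before the response."""

    channels: tuple[str, ...] = ("FC2", "FC4")
    band: tuple[float, float] = (24.0, 32.0)
    window_ms: tuple[float, float] = (-750.0, -450.0)
    base_amp: float = 1.5  # uV RMS common to both choices
    amp_diff: float = 1.0  # extra uV RMS for "f2 > f1" choices
    ramp_ms: float = 100.0  # cosine on/off ramps outside the flat window


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic subject's session and EEG."""

    n_blocks: int = 7
    trials_per_block: int = 160
    observer: ObserverParams = DEFAULT_OBSERVER
    rt_model: RTModel = field(default_factory=RTModel)
    mapping: str = "right_means_greater"
    channels: tuple[str, ...] = tuple(standard_64_montage()[0])
    fs: float = 512.0
    window_ms: tuple[float, float] = (-2500.0, 1000.0)
    beta_effect: BetaEffect = field(default_factory=BetaEffect)
    ssep_gain: float = 3.0
    ssep_channels: tuple[str, ...] = ("C4", "CP4")  # contralateral to the left finger
    noise_exponent: float = 1.0  # 1/f spectral slope of the background
    noise_level: float = 10.0  # broadband RMS in uV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ssep_gain < 0 or self.beta_effect.base_amp < 0 or self.beta_effect.amp_diff < 0:
            raise ValueError("all gains must be non-negative")
        lo, hi = self.beta_effect.band
        if not (4.0 <= lo < hi <= 48.0):
            raise ValueError("effect band must lie within 4-48 Hz")
        w0, w1 = self.beta_effect.window_ms
        t0, t1 = self.window_ms
        if not (t0 <= w0 < w1 <= t1):
            raise ValueError("effect window must lie inside the epoch window")
        known = set(standard_64_montage()[0])
        unknown = [c for c in self.channels if c not in known]
        if unknown:
            raise ValueError(f"unknown channel label(s): {sorted(set(unknown))}")
        missing = [c for c in (*self.beta_effect.channels, *self.ssep_channels)
                   if c not in self.channels]
        if missing:
            raise ValueError(f"effect/SSEP channel(s) not simulated: {sorted(set(missing))}")


def simulate_behavior(
    trials: pd.DataFrame,
    observer: ObserverParams = DEFAULT_OBSERVER,
    rt_model: RTModel = RTModel(),
    mapping: str = "right_means_greater",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill choice, correctness, RT and saccade direction into a trial-table stub.

    Choices are Bernoulli draws from the observer's choice probability per
    pair; saccade direction follows the choice under ``mapping``.
    """
    if mapping not in ("right_means_greater", "right_means_smaller"):
        raise ValueError("unknown mapping")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = trials.copy()
    p = choice_probability(out["f1"].to_numpy(float), out["f2"].to_numpy(float), observer)
    chose_greater = rng.random(len(out)) < p
    out["choice"] = np.where(chose_greater, "f2>f1", "f2<f1")
    out["correct"] = chose_greater == (out["delta"].to_numpy() > 0)
    loc = rt_model.base_ms + np.where(chose_greater, rt_model.choice_shift_ms, 0.0)
    z = rng.standard_normal(len(out))
    out["rt_ms"] = loc * np.exp(rt_model.sigma * z - rt_model.sigma**2 / 2.0)
    right_for_greater = mapping == "right_means_greater"
    out["saccade_dir"] = np.where(chose_greater == right_for_greater, "right", "left")
    out["mapping"] = mapping
    return out


def _one_over_f_noise(shape: tuple[int, ...], fs: float, exponent: float,
                      rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ~ f^(-exponent/2), unit-free RMS scaling."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0:
        x = white
    else:
        spec = np.fft.rfft(white, axis=-1)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        gain = np.ones_like(f)
        nz = f > 0
        gain[nz] = f[nz] ** (-exponent / 2.0)
        gain[0] = 0.0  # no DC drift
        x = np.fft.irfft(spec * gain, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


def _effect_envelope(times_ms: np.ndarray, window_ms: tuple[float, float], ramp_ms: float) -> np.ndarray:
    """Flat envelope over the effect window with raised-cosine ramps outside it."""
    w0, w1 = window_ms
    env = np.zeros_like(times_ms)
    env[(times_ms >= w0) & (times_ms <= w1)] = 1.0
    if ramp_ms > 0:
        up = (times_ms >= w0 - ramp_ms) & (times_ms < w0)
        env[up] = 0.5 * (1 + np.cos(np.pi * (w0 - times_ms[up]) / ramp_ms))
        dn = (times_ms > w1) & (times_ms <= w1 + ramp_ms)
        env[dn] = 0.5 * (1 + np.cos(np.pi * (times_ms[dn] - w1) / ramp_ms))
    return env


def simulate_eeg(
    trials: pd.DataFrame,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> EpochArray:
    """Generate response-locked epochs for completed trials.

    Each epoch is the sum of 1/f background noise (all channels), a
    steady-state sinusoid at the trial's f2 frequency during the second
    stimulus interval ``[-rt, -rt + 250] ms`` in the contralateral
    somatosensory channels, and the choice-selective 24-32 Hz component in
    the configured right-frontal channels. Reproducible for a fixed seed.
    """
    if trials["choice"].isna().any():
        raise ValueError("trials must be completed (run simulate_behavior first)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    channels = list(config.channels)
    n_ch = len(channels)
    n_samp = n_samples_for_window(config.window_ms, config.fs)
    n_tr = len(trials)
    times = config.window_ms[0] + np.arange(n_samp) / config.fs * 1000.0

    data = np.empty((n_ch, n_samp, n_tr))
    for t in range(n_tr):  # per-trial loop keeps memory flat for full-size sessions
        data[:, :, t] = _one_over_f_noise(
            (n_ch, n_samp), config.fs, config.noise_exponent, config.noise_level, rng
        )

    # steady-state evoked component at f2, placed via the trial's RT
    if config.ssep_gain > 0:
        ssep_idx = [channels.index(c) for c in config.ssep_channels if c in channels]
        f2 = trials["f2"].to_numpy(float)
        rt = trials["rt_ms"].to_numpy(float)
        for t in range(n_tr):
            on, off = -rt[t], -rt[t] + STIM_DURATION_MS
            m = (times >= on) & (times < off)
            if not m.any():
                continue
            wave = np.sin(2 * np.pi * f2[t] * (times[m] - on) / 1000.0)
            wave *= signal.windows.tukey(m.sum(), alpha=0.2)
            for c in ssep_idx:
                data[c, m, t] += config.ssep_gain * np.sqrt(2.0) * wave

    # choice-selective band-limited component
    eff = config.beta_effect
    if eff.base_amp > 0 or eff.amp_diff > 0:
        eff_idx = [channels.index(c) for c in eff.channels]
        env = _effect_envelope(times, eff.window_ms, eff.ramp_ms)
        sos = signal.butter(4, eff.band, btype="bandpass", fs=config.fs, output="sos")
        chose_greater = (trials["choice"] == "f2>f1").to_numpy()
        core = (times >= eff.window_ms[0]) & (times <= eff.window_ms[1])
        for t in range(n_tr):
            amp = eff.base_amp + (eff.amp_diff if chose_greater[t] else 0.0)
            if amp == 0:
                continue
            for c in eff_idx:
                x = signal.sosfiltfilt(sos, rng.standard_normal(n_samp))
                x /= x[core].std()  # unit RMS inside the effect window
                data[c, :, t] += amp * env * x

    return EpochArray(
        data=data, channel_names=channels, fs=config.fs,
        window_ms=config.window_ms,
        trial_ids=trials["trial_index"].to_numpy() if "trial_index" in trials else None,
    )


def simulate_subject(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, EpochArray]:
    """Schedule, behave and record one synthetic subject; fully seeded."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trials = schedule_session(config.n_blocks, config.trials_per_block, rng)
    trials = simulate_behavior(trials, config.observer, config.rt_model, config.mapping, rng)
    epochs = simulate_eeg(trials, config, rng)
    return trials, epochs


def simulate_cohort(
    n_subjects: int, config: SimConfig, base_seed: int = 0,
    counterbalance_mapping: bool = True,
) -> list[tuple[pd.DataFrame, EpochArray]]:
    """Simulate ``n_subjects`` independent subjects.

    Seeds are derived from ``base_seed`` via a spawned bit generator, and
    the saccade-to-choice mapping is counterbalanced across subjects unless
    disabled.
    """
    out = []
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n_subjects)
    for i, child in enumerate(children):
        mapping = config.mapping
        if counterbalance_mapping:
            mapping = "right_means_greater" if i % 2 == 0 else "right_means_smaller"
        cfg = replace(config, mapping=mapping)
        rng = np.random.default_rng(child)
        trials = schedule_session(cfg.n_blocks, cfg.trials_per_block, rng)
        trials = simulate_behavior(trials, cfg.observer, cfg.rt_model, cfg.mapping, rng)
        trials["subject"] = i
        epochs = simulate_eeg(trials, cfg, rng)
        out.append((trials, epochs))
    return out


def detect_saccade_onset(
    heog_trace: np.ndarray,
    fs: float,
    threshold: float | None = None,
    smooth_ms: float = 10.0,
    sustain_ms: float = 10.0,
) -> int | None:
    """First sample where the smoothed hEOG derivative exceeds a threshold, sustained.

    The derivative (units of the trace per second) is smoothed with a
    ``smooth_ms`` moving average; an onset requires ``|derivative| >
    threshold`` for ``sustain_ms`` consecutive milliseconds. With
    ``threshold=None`` a robust default of 10 median absolute deviations of
    the smoothed derivative is used. Returns ``None`` when no event is found.
    """
    x = np.asarray(heog_trace, float)
    n_smooth = max(1, int(round(smooth_ms / 1000.0 * fs)))
    if x.size < n_smooth + 1:
        raise ValueError("trace shorter than the smoothing window")
    deriv = np.gradient(x) * fs
    kernel = np.ones(n_smooth) / n_smooth
    sm = np.convolve(deriv, kernel, mode="same")
    a = np.abs(sm)
    if threshold is None:
        mad = np.median(np.abs(a - np.median(a)))
        threshold = 10.0 * mad / 0.6745 + 1e-12
    above = a > threshold
    n_sustain = max(1, int(round(sustain_ms / 1000.0 * fs)))
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= n_sustain:
            # compensate the acausal spread of the centred smoothing kernel
            return min(i, i - n_sustain + 1 + (n_smooth - 1) // 2)
    return None
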