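"""Morlet time-frequency amplitude maps and band-limited time courses.

The transform follows the response-locked analysis convention of the task:
4-48 Hz in 1 Hz steps, a seven-cycle Morlet wavelet per frequency (segment
length ``n_cycles / f``: 700 ms at 10 Hz, 350 ms at 20 Hz), power sampled
every 50 ms, square-root transformed to spectral amplitude, and finally
smoothed with a 3 Hz x 300 ms FWHM Gaussian kernel. Amplitude (not power)
maps are what enter the statistics, and the square root is applied once,
before smoothing.

Wavelets are normalised to unit total energy so that white noise yields a
flat amplitude profile across frequencies; bins whose wavelet support
extends past the epoch edges are marked invalid (NaN) and excluded from all
downstream statistics rather than zero-padded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .epochs import EpochArray

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # = 1/2.3548


@dataclass(frozen=True)
class TFRConfig:
    freqs: tuple[float, ...] = tuple(range(4, 49))  # Hz, 1 Hz step
    n_cycles: float = 7.0
    time_step_ms: float = 50.0
    smoothing_fwhm: tuple[float, float] = (3.0, 300.0)  # (Hz, ms)
    band: tuple[float, float] = (24.0, 32.0)  # upper beta, for time courses

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.time_step_ms <= 0:
            raise ValueError("time_step_ms must be positive")
        lo, hi = self.band
        if not (min(self.freqs) <= lo <= hi <= max(self.freqs)):
            raise ValueError("band must lie within the analysed frequencies")


def segment_length(freq: float, n_cycles: float = 7.0) -> float:
    """Wavelet segment length in seconds: ``n_cycles / freq``."""
    return n_cycles / freq


@dataclass
class TFR:
    """Per-trial amplitude maps: ``values`` is trials x channels x freqs x times.

    ``valid`` marks (freq, time) bins whose wavelet support fits inside the
    epoch; invalid bins are NaN in ``values``.
    """

    values: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    channel_names: list[str]
    valid: np.ndarray | None = None  # (n_freqs, n_times) bool

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.all(np.isfinite(self.values), axis=tuple(range(self.values.ndim - 2)))
        if np.any(self.values < 0):  # NaN (invalid) bins compare False
            raise ValueError("amplitudes must be non-negative")

    def band_freq_indices(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return np.flatnonzero((self.freqs >= lo) & (self.freqs <= hi))


def preprocess(epochs: EpochArray, l_freq: float = 0.5, h_freq: float = 48.0,
               order: int = 6) -> EpochArray:
    """Common-average re-reference followed by a zero-phase band-pass filter.

    The band-pass is a forward-backward Butterworth (``order`` poles per
    pass) with the stated cut-offs. After re-referencing the per-sample mean
    across channels is zero by construction.
    """
    if epochs.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    out = epochs.copy()
    out.data -= out.data.mean(axis=0, keepdims=True)
    sos = signal.butter(order, (l_freq, h_freq), btype="bandpass", fs=epochs.fs,
                        output="sos")
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def _morlet_wavelet(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet on a support of exactly ``n_cycles / freq`` seconds.

    Gaussian envelope with sigma = support/6 (support truncates at +/-3
    sigma); normalised to unit total energy (sum |w|^2 / fs = 1).
    """
    support = segment_length(freq, n_cycles)
    half = int(np.floor(support * fs / 2.0))
    t = np.arange(-half, half + 1) / fs
    sigma_t = support / 6.0
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / fs)
    return w


def morlet_tfr(epochs: EpochArray, config: TFRConfig = TFRConfig()) -> TFR:
    """Single-trial spectral amplitude maps on the 50 ms x 1 Hz grid.

    Power is |wavelet convolution|^2 sampled at the bin times; amplitude is
    its square root. Raises when the epoch is shorter than the longest
    (lowest-frequency) wavelet.
    """
    freqs = np.asarray(config.freqs, float)
    longest = segment_length(freqs.min(), config.n_cycles)
    if epochs.n_samples / epochs.fs < longest:
        raise ValueError("epoch shorter than the longest wavelet")

    t0, t1 = epochs.window_ms
    bin_times = np.arange(t0, t1 + 1e-9, config.time_step_ms)
    bin_idx = np.round((bin_times - t0) / 1000.0 * epochs.fs).astype(int)
    n_f, n_t = len(freqs), len(bin_times)

    # data as (trials*channels, samples); each bin is a windowed projection
    # onto the wavelet, so only the 50 ms grid is ever computed
    x = np.moveaxis(epochs.data, -1, 0).reshape(-1, epochs.n_samples)
    # float32 keeps large cohorts light; well above amplitude precision needs
    values = np.full((x.shape[0], n_f, n_t), np.nan, dtype=np.float32)
    valid = np.zeros((n_f, n_t), dtype=bool)
    for i, f in enumerate(freqs):
        w = np.conj(_morlet_wavelet(f, config.n_cycles, epochs.fs))
        wr, wi = np.ascontiguousarray(w.real), np.ascontiguousarray(w.imag)
        n_w = len(w)
        half = n_w // 2
        for j, b in enumerate(bin_idx):
            a = b - half
            if a < 0 or a + n_w > epochs.n_samples:
                continue  # wavelet support exceeds the epoch: bin invalid
            seg = x[:, a:a + n_w]
            values[:, i, j] = np.hypot(seg @ wr, seg @ wi)  # sqrt of power
            valid[i, j] = True
    values = values.reshape(epochs.n_trials, epochs.n_channels, n_f, n_t)
    return TFR(values=values, freqs=freqs, times_ms=bin_times,
               channel_names=list(epochs.channel_names), valid=valid)


def _gaussian_operator(n: int, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Dense 1-D Gaussian smoothing matrix (unit-sum kernel, zero padding)."""
    radius = int(truncate * sigma + 0.5)
    k = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (k / sigma) ** 2)
    kernel /= kernel.sum()
    m = np.zeros((n, n))
    for off, wgt in zip(k, kernel):
        rows = np.arange(max(0, -off), min(n, n - off))
        m[rows, rows + off] = wgt
    return m


def smooth_tfr(tfr: TFR, fwhm: tuple[float, float] | None = None) -> TFR:
    """Separable Gaussian smoothing over (frequency, time) with renormalised edges.

    ``fwhm`` is (Hz, ms); the kernel has unit sum, and near invalid bins or
    map edges the kernel is renormalised over the available bins so a
    constant map stays constant. Invalid bins remain NaN.
    """
    if fwhm is None:
        fwhm = (3.0, 300.0)
    f_fwhm, t_fwhm = fwhm
    if f_fwhm <= 0 or t_fwhm <= 0:
        raise ValueError("FWHM values must be positive")
    df = np.diff(tfr.freqs).mean() if len(tfr.freqs) > 1 else 1.0
    dt = np.diff(tfr.times_ms).mean() if len(tfr.times_ms) > 1 else 1.0
    sigma = (f_fwhm / df * FWHM_TO_SIGMA, t_fwhm / dt * FWHM_TO_SIGMA)

    vals = tfr.values
    mask = np.isfinite(vals)
    filled = np.where(mask, vals, vals.dtype.type(0))
    # separable smoothing as dense operator matrices (fast for short axes)
    mf = _gaussian_operator(vals.shape[-2], sigma[0]).astype(vals.dtype)
    mt = _gaussian_operator(vals.shape[-1], sigma[1]).astype(vals.dtype)

    def smooth2d(a, out=None):
        tmp = np.matmul(mf, a)
        return np.matmul(tmp, mt.T, out=out)

    num = smooth2d(filled, out=filled)  # filled is consumed: reuse its buffer
    grid = mask.reshape(-1, *vals.shape[-2:])[0]
    if np.all(mask == grid):
        # one validity grid shared by all leading axes: renormalise once
        den = smooth2d(grid.astype(vals.dtype))
    else:
        den = smooth2d(mask.astype(vals.dtype))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~mask] = np.nan
    return TFR(values=out, freqs=tfr.freqs, times_ms=tfr.times_ms,
               channel_names=list(tfr.channel_names), valid=tfr.valid)


def band_timecourse(
    tfr: TFR,
    trial_groups: dict[str, np.ndarray],
    band: tuple[float, float] = (24.0, 32.0),
    channels: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Mean amplitude time course per trial group, averaged over band and channels.

    ``trial_groups`` maps a label (e.g. an SPFD level) to trial indices or a
    boolean mask. Invalid (edge) bins propagate as NaN in the output.
    """
    fi = tfr.band_freq_indices(band)
    if fi.size == 0:
        raise ValueError("band contains no analysed frequencies")
    if channels is None:
        ci = np.arange(len(tfr.channel_names))
    else:
        ci = np.array([tfr.channel_names.index(c) for c in channels])
    out = {}
    for name, sel in trial_groups.items():
        sel = np.asarray(sel)
        sub = tfr.values[sel][:, ci][:, :, fi, :]
        if sub.shape[0] == 0:
            raise ValueError(f"trial group {name!r} is empty")
        with warnings.catch_warnings():
            # edge bins are all-NaN by design and stay NaN in the time course
            warnings.filterwarnings("ignore", "Mean of empty slice")
            out[name] = np.nanmean(sub, axis=(0, 1, 2))
    return out
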