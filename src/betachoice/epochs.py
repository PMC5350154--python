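"""Response-locked EEG epoch container and its HDF5 representation."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np


def n_samples_for_window(window_ms: tuple[float, float], fs: float) -> int:
    """Sample count for an epoch window, rounded consistently everywhere."""
    t0, t1 = window_ms
    return int(round((t1 - t0) / 1000.0 * fs))


@dataclass
class EpochArray:
    """Multichannel epoched EEG: ``data`` is channels x samples x trials (uV-scale).

    Time zero of each epoch is the saccade onset (the response); the window
    extends from ``window_ms[0]`` to ``window_ms[1]`` relative to it.
    """

    data: np.ndarray
    channel_names: list[str]
    fs: float
    window_ms: tuple[float, float] = (-2500.0, 1000.0)
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x samples x trials")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        expected = n_samples_for_window(self.window_ms, self.fs)
        if self.data.shape[1] != expected:
            raise ValueError(
                f"sample count {self.data.shape[1]} inconsistent with window "
                f"{self.window_ms} at fs={self.fs} (expected {expected})"
            )
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[2])
        self.trial_ids = np.asarray(self.trial_ids)
        if len(self.trial_ids) != self.data.shape[2]:
            raise ValueError("trial_ids must align one-to-one with trials")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Per-sample times in ms relative to saccade onset."""
        return self.window_ms[0] + np.arange(self.n_samples) / self.fs * 1000.0

    def pick(self, channels: list[str]) -> "EpochArray":
        idx = [self.channel_names.index(c) for c in channels]
        return EpochArray(self.data[idx], list(channels), self.fs, self.window_ms, self.trial_ids)

    def copy(self) -> "EpochArray":
        return EpochArray(
            self.data.copy(), list(self.channel_names), self.fs, self.window_ms,
            None if self.trial_ids is None else self.trial_ids.copy(),
        )


def reject_artifacts(
    epochs: EpochArray, peak_to_peak: float = 200.0
) -> tuple[EpochArray, np.ndarray]:
    """Drop trials whose peak-to-peak amplitude exceeds a threshold on any channel.

    A reproducible stand-in for visual trial screening: returns the cleaned
    epochs and the boolean keep-mask (aligned with the input trial axis) so
    the trial table can be subset identically. ``peak_to_peak`` is in the
    data's amplitude units (uV-scale).
    """
    if peak_to_peak <= 0:
        raise ValueError("peak_to_peak must be positive")
    ptp = epochs.data.max(axis=1) - epochs.data.min(axis=1)  # channels x trials
    keep = np.all(ptp <= peak_to_peak, axis=0)
    if not keep.any():
        raise ValueError("threshold rejects every trial")
    out = EpochArray(
        epochs.data[:, :, keep], list(epochs.channel_names), epochs.fs,
        epochs.window_ms, epochs.trial_ids[keep],
    )
    return out, keep


def save_epochs(path, epochs: EpochArray) -> None:
    """Write an :class:`EpochArray` to HDF5 (datasets: data, channel_names, fs, window_ms, trial_ids)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "channel_names", data=np.array(epochs.channel_names, dtype="S16")
        )
        f.create_dataset("fs", data=float(epochs.fs))
        f.create_dataset("window_ms", data=np.asarray(epochs.window_ms, float))
        f.create_dataset("trial_ids", data=np.asarray(epochs.trial_ids))


def load_epochs(path) -> EpochArray:
    """Read an :class:`EpochArray` written by :func:`save_epochs`."""
    with h5py.File(path, "r") as f:
        return EpochArray(
            data=f["data"][()],
            channel_names=[n.decode() for n in f["channel_names"][()]],
            fs=float(f["fs"][()]),
            window_ms=tuple(f["window_ms"][()]),
            trial_ids=f["trial_ids"][()],
        )
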