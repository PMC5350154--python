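"""Trial-table round-trips and optional import of continuous BioSemi BDF/EDF recordings.

Trial tables are plain CSV/TSV files, one row per trial. The documented
columns are::

    subject       optional subject identifier
    block         1-based block number
    trial_index   0-based trial counter within the session
    f1, f2        flutter frequencies in Hz
    delta         f2 - f1 in Hz
    choice        "f2>f1" or "f2<f1"
    correct       boolean
    rt_ms         response time from f2 onset, ms
    saccade_dir   "left" or "right"
    mapping       "right_means_greater" or "right_means_smaller"
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epochs import EpochArray, n_samples_for_window

TRIAL_COLUMNS = [
    "block", "trial_index", "f1", "f2", "delta",
    "choice", "correct", "rt_ms", "saccade_dir", "mapping",
]


def write_trials(path, trials: pd.DataFrame, sep: str = ",") -> None:
    """Write a trial table to CSV (default) or TSV (``sep='\\t'``)."""
    trials.to_csv(path, sep=sep, index=False)


def read_trials(path, sep: str | None = None) -> pd.DataFrame:
    """Read a trial table; the delimiter is sniffed unless given.

    Restores the boolean dtype of ``correct`` so tables round-trip exactly.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if "correct" in df.columns and df["correct"].dtype == object:
        df["correct"] = df["correct"].map({"True": True, "False": False}).astype(bool)
    return df


def epochs_from_raw(
    path,
    onset_samples,
    window_ms: tuple[float, float] = (-2500.0, 1000.0),
    channels: list[str] | None = None,
) -> EpochArray:
    """Epoch a continuous BioSemi BDF or EDF recording around event samples.

    ``onset_samples`` are saccade-onset sample indices in the continuous
    recording (e.g. from an event channel or :func:`betachoice.simulate.detect_saccade_onset`
    applied to the hEOG trace). Requires the optional ``mne`` dependency;
    everything downstream is independent of it.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - exercised only without mne
        raise ImportError(
            "BDF/EDF import requires the optional 'mne' dependency "
            "(pip install betachoice[edf])"
        ) from exc

    path = str(path)
    reader = mne.io.read_raw_bdf if path.lower().endswith(".bdf") else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    if channels is not None:
        raw.pick(channels)
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne returns volts; the package works in uV
    n_samp = n_samples_for_window(window_ms, fs)
    start_off = int(round(window_ms[0] / 1000.0 * fs))
    segs = []
    kept = []
    for i, onset in enumerate(np.asarray(onset_samples, int)):
        a = onset + start_off
        b = a + n_samp
        if a < 0 or b > data.shape[1]:
            continue  # epoch falls outside the recording
        segs.append(data[:, a:b])
        kept.append(i)
    if not segs:
        raise ValueError("no epoch fits inside the recording")
    return EpochArray(
        data=np.stack(segs, axis=-1),
        channel_names=list(raw.ch_names),
        fs=fs,
        window_ms=window_ms,
        trial_ids=np.asarray(kept),
    )
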