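"""Subject-level pipeline glue: epochs -> smoothed TFR -> contrast images.

These helpers chain the standard stages (common-average reference and
band-pass, Morlet amplitude maps, Gaussian smoothing, 2x2 condition means,
choice contrasts) for one subject, so group scripts and tests stay short.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import CELL_ORDER, ContrastSpec, apply_contrast, condition_means
from .epochs import EpochArray
from .tfr import TFR, TFRConfig, band_timecourse, morlet_tfr, preprocess, smooth_tfr


@dataclass
class SubjectMaps:
    """Per-subject outputs of the TF pipeline."""

    tfr: TFR  # smoothed single-trial amplitude maps
    cell_means: dict
    cell_counts: dict
    images: dict[str, np.ndarray]  # contrast name -> channels x freqs x times
    band_amplitude: np.ndarray  # one value per trial (band x window x channels mean)


def subject_maps(
    trials: pd.DataFrame,
    epochs: EpochArray,
    config: TFRConfig = TFRConfig(),
    contrasts: tuple[str, ...] = ("interaction", "correct_only", "incorrect_only"),
    amplitude_window_ms: tuple[float, float] = (-750.0, -450.0),
    amplitude_channels: tuple[str, ...] = ("FC2", "FC4"),
) -> SubjectMaps:
    """Run preprocessing, TFR, smoothing and contrasts for one subject.

    ``band_amplitude`` is the single-trial mean amplitude in the configured
    band over ``amplitude_window_ms`` and ``amplitude_channels`` (the
    quantity used for the RT-correlation control analysis).
    """
    ep = preprocess(epochs)
    t = smooth_tfr(morlet_tfr(ep, config), config.smoothing_fwhm)
    sign = np.where(trials["delta"].to_numpy() > 0, "positive", "negative")
    correct = trials["correct"].to_numpy(bool)
    means, counts = condition_means(t.values, sign, correct)
    images = {name: apply_contrast(means, ContrastSpec.preset(name)) for name in contrasts}

    fi = t.band_freq_indices(config.band)
    ci = [t.channel_names.index(c) for c in amplitude_channels]
    wi = (t.times_ms >= amplitude_window_ms[0]) & (t.times_ms <= amplitude_window_ms[1])
    band_amp = np.nanmean(t.values[:, ci][:, :, fi][:, :, :, wi], axis=(1, 2, 3))
    return SubjectMaps(tfr=t, cell_means=means, cell_counts=counts,
                       images=images, band_amplitude=band_amp)


def spfd_level_timecourses(
    trials: pd.DataFrame,
    tfr: TFR,
    band: tuple[float, float] = (24.0, 32.0),
    channels: tuple[str, ...] = ("FC2", "FC4"),
) -> dict:
    """Upper-beta time courses for the six SPFD levels (correct trials) and
    the two choice classes (incorrect trials).

    ``trials`` must carry an ``spfd_level`` column (see
    :func:`betachoice.observer.assign_spfd_levels`). Levels without trials
    are skipped (small sessions may not populate all six).
    """
    correct = trials["correct"].to_numpy(bool)
    levels = trials["spfd_level"].to_numpy()
    groups = {}
    for lv in range(1, 7):
        sel = correct & (levels == lv)
        if sel.any():
            groups[f"correct_level_{lv}"] = sel
    for ch, name in (("f2>f1", "incorrect_chose_greater"), ("f2<f1", "incorrect_chose_smaller")):
        sel = ~correct & (trials["choice"].to_numpy() == ch)
        if sel.any():
            groups[name] = sel
    return band_timecourse(tfr, groups, band=band, channels=list(channels))
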