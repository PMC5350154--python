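"""Template 64-channel extended 10-20 montage and channel adjacency.

Individual digitised electrode positions are not part of synthetic data, so
the package ships a schematic 2-D template layout (anterior-posterior rows
by lateral columns, unit spacing) for the standard 64-channel set. The
layout is only used to define sensor neighbourhoods for clustering, where
approximate relative geometry is what matters.
"""

from __future__ import annotations

import numpy as np

# rows front (positive y) to back; within a row left (negative x) to right
_ROWS: list[tuple[float, list[tuple[str, float]]]] = [
    (4.0, [("Fp1", -1), ("Fpz", 0), ("Fp2", 1)]),
    (3.0, [("AF7", -3), ("AF3", -1.5), ("AFz", 0), ("AF4", 1.5), ("AF8", 3)]),
    (2.0, [("F7", -4), ("F5", -3), ("F3", -2), ("F1", -1), ("Fz", 0),
           ("F2", 1), ("F4", 2), ("F6", 3), ("F8", 4)]),
    (1.0, [("FT7", -4), ("FC5", -3), ("FC3", -2), ("FC1", -1), ("FCz", 0),
           ("FC2", 1), ("FC4", 2), ("FC6", 3), ("FT8", 4)]),
    (0.0, [("T7", -4), ("C5", -3), ("C3", -2), ("C1", -1), ("Cz", 0),
           ("C2", 1), ("C4", 2), ("C6", 3), ("T8", 4)]),
    (-1.0, [("TP7", -4), ("CP5", -3), ("CP3", -2), ("CP1", -1), ("CPz", 0),
            ("CP2", 1), ("CP4", 2), ("CP6", 3), ("TP8", 4)]),
    (-2.0, [("P7", -4), ("P5", -3), ("P3", -2), ("P1", -1), ("Pz", 0),
            ("P2", 1), ("P4", 2), ("P6", 3), ("P8", 4)]),
    (-2.5, [("P9", -5), ("P10", 5)]),
    (-3.0, [("PO7", -3), ("PO3", -1.5), ("POz", 0), ("PO4", 1.5), ("PO8", 3)]),
    (-4.0, [("O1", -1), ("Oz", 0), ("O2", 1)]),
    (-5.0, [("Iz", 0)]),
]

#: Default distance (in grid units) below which two channels are neighbours.
NEIGHBOR_DISTANCE = 1.6


def standard_64_montage() -> tuple[list[str], np.ndarray]:
    """Return the 64 channel labels and their template 2-D positions (n, 2)."""
    labels, pos = [], []
    for y, row in _ROWS:
        for name, x in row:
            labels.append(name)
            pos.append((x, y))
    return labels, np.asarray(pos, float)


def channel_positions(channels: list[str]) -> np.ndarray:
    """Template positions for a channel subset, in the given order."""
    labels, pos = standard_64_montage()
    lookup = {name: p for name, p in zip(labels, pos)}
    missing = [c for c in channels if c not in lookup]
    if missing:
        raise KeyError(f"unknown channel label(s): {missing}")
    return np.asarray([lookup[c] for c in channels])


def channel_adjacency(
    channels: list[str], max_distance: float = NEIGHBOR_DISTANCE
) -> np.ndarray:
    """Symmetric, irreflexive boolean neighbour matrix for ``channels``.

    Two channels are neighbours when their template distance is below
    ``max_distance``; the default captures lateral, anterior-posterior and
    diagonal grid neighbours (median degree ~7 on the full montage).
    """
    pos = channel_positions(channels)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d < max_distance) & (d > 0)
    return adj
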