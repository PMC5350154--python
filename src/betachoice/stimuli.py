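"""Stimulus set and session scheduling for the vibrotactile comparison task.

Two flutter frequencies f1 and f2 are presented per trial; the subject
reports whether f2 > f1. The base frequencies f1 are 16, 20, 24 and 28 Hz,
and f2 differs from f1 by +/-2 or +/-4 Hz, so f2 spans 12-32 Hz and the
full design has 16 distinct pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

F1_VALUES: tuple[int, ...] = (16, 20, 24, 28)
DELTAS: tuple[int, ...] = (-4, -2, 2, 4)

#: Columns of a trial table before responses are simulated or recorded.
STUB_COLUMNS = ["block", "trial_index", "f1", "f2", "delta"]


@dataclass(frozen=True)
class StimulusPair:
    """One (f1, f2) flutter-frequency combination."""

    f1: float
    f2: float

    def __post_init__(self) -> None:
        if self.f1 not in F1_VALUES:
            raise ValueError(f"f1 must be one of {F1_VALUES}, got {self.f1}")
        if round(self.f2 - self.f1) not in DELTAS:
            raise ValueError(f"f2 - f1 must be one of {DELTAS}")

    @property
    def delta(self) -> float:
        return self.f2 - self.f1

    @property
    def sign(self) -> str:
        return "positive" if self.delta > 0 else "negative"

    @property
    def difficulty(self) -> str:
        """'easy' for 4 Hz differences, 'hard' for 2 Hz differences."""
        return "easy" if abs(self.delta) == 4 else "hard"


def build_stimulus_set() -> list[StimulusPair]:
    """All 16 stimulus pairs in deterministic (f1 ascending, delta ascending) order.

    The set is exactly balanced: each f1 appears in four pairs, f2 covers
    12-32 Hz, and the mean f2 is 25 Hz among f2 > f1 pairs and 19 Hz among
    f2 < f1 pairs (the asymmetry that makes steady-state responses a
    potential confound for choice decoding).
    """
    return [StimulusPair(f1, f1 + d) for f1 in F1_VALUES for d in DELTAS]


def schedule_session(
    n_blocks: int = 7,
    trials_per_block: int = 160,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign stimulus pairs to a session of ``n_blocks`` x ``trials_per_block`` trials.

    Pair counts are balanced over the session: when the session length is a
    multiple of 16 every pair occurs equally often; otherwise the remainder
    pairs are drawn once without replacement, so per-session counts differ
    by at most one from perfect balance. Trial order is then shuffled.

    Returns a trial-table stub with columns ``block, trial_index, f1, f2,
    delta`` and no response fields.
    """
    if n_blocks <= 0 or trials_per_block <= 0:
        raise ValueError("n_blocks and trials_per_block must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pairs = build_stimulus_set()
    n_pairs = len(pairs)
    total = n_blocks * trials_per_block
    reps, rem = divmod(total, n_pairs)
    idx = np.repeat(np.arange(n_pairs), reps)
    if rem:  # remainder pairs drawn once per session, without replacement
        idx = np.concatenate([idx, rng.choice(n_pairs, size=rem, replace=False)])
    rng.shuffle(idx)
    rows = []
    for trial_index, i in enumerate(idx):
        p = pairs[i]
        rows.append((trial_index // trials_per_block + 1, trial_index, p.f1, p.f2, p.delta))
    return pd.DataFrame(rows, columns=STUB_COLUMNS)


def pair_labels(trials: pd.DataFrame) -> pd.DataFrame:
    """Add ``sign`` and ``difficulty`` factor columns derived from ``delta``."""
    out = trials.copy()
    out["sign"] = np.where(out["delta"] > 0, "positive", "negative")
    out["difficulty"] = np.where(np.abs(out["delta"]) == 4, "easy", "hard")
    return out
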