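"""Behavioral summaries and control analyses.

Covers proportions correct with within-subject factorial tests (logit
transform available), signal-detection criterion shifts with an RT median
split, single-trial RT-amplitude correlations, and subgroup re-runs of the
group-level cluster analysis (low-bias subjects; saccade-mapping split).

Sign conventions. "f2 > f1" stimuli are treated as the signal class, so the
hit rate is P(choose "f2>f1" | f2 > f1) and the false-alarm rate is
P(choose "f2>f1" | f2 < f1). The criterion is c = -(z(hit) + z(fa)) / 2:
negative c means a liberal bias toward "f2 > f1" answers. A positive
*criterion shift toward "f2 > f1"* as conventionally reported is therefore
``-c``, exposed as :attr:`SDTResult.shift_toward_greater`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import (
    Adjacency,
    ClusterResult,
    cluster_permutation,
    two_sample_cluster_permutation,
)


def logit(p, n: int | None = None):
    """log(p / (1-p)); with ``n`` given, extreme rates are corrected first.

    The log-linear rule replaces a rate k/n by (k + 0.5) / (n + 1), which
    keeps the transform finite for empty and full cells.
    """
    p = np.asarray(p, float)
    if n is not None:
        p = (p * n + 0.5) / (n + 1)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("rate outside (0, 1); pass n for the log-linear correction")
    return np.log(p / (1.0 - p))


def pcr_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Proportions correct per physical frequency difference and per margin.

    One row per condition: the four f2-f1 levels (-4, -2, +2, +4 Hz), the
    sign margins, the difficulty margins and the overall rate; columns are
    ``n``, ``pcr`` and ``pcr_logit`` (log-linear corrected).
    """
    t = trials
    rows = {}
    for d in (-4, -2, 2, 4):
        sel = t[t["delta"] == d]
        if len(sel) == 0:
            raise ValueError(f"no trials with delta {d}")
        rows[f"delta_{d:+d}"] = sel["correct"]
    rows["sign_negative"] = t.loc[t["delta"] < 0, "correct"]
    rows["sign_positive"] = t.loc[t["delta"] > 0, "correct"]
    rows["difficulty_easy"] = t.loc[t["delta"].abs() == 4, "correct"]
    rows["difficulty_hard"] = t.loc[t["delta"].abs() == 2, "correct"]
    rows["all"] = t["correct"]
    out = pd.DataFrame(
        {
            "n": {k: len(v) for k, v in rows.items()},
            "pcr": {k: v.mean() for k, v in rows.items()},
        }
    )
    out["pcr_logit"] = [logit(p, n) for p, n in zip(out["pcr"], out["n"])]
    return out


@dataclass
class FactorialBehaviorResult:
    """Within-subject factorial effects via difference-score contrasts.

    ``effects`` has one row per main effect / interaction with the mean
    difference score, paired t, F = t^2, df and p-value; ``cell_means`` are
    the grand means per cell.
    """

    effects: pd.DataFrame
    cell_means: pd.Series
    n_subjects: int


def within_factorial_test(cell_values: pd.DataFrame, factors: dict[str, dict]) -> FactorialBehaviorResult:
    """Repeated-measures ANOVA for 2^k within designs from per-subject cell values.

    ``cell_values``: one row per subject, one column per cell.
    ``factors`` maps a factor name to a {cell_column: level_code} dict with
    level codes +/-1. Every effect (each non-empty subset of factors) is
    tested by a paired t-test on the per-subject contrast score whose
    weights are the products of the involved factors' codes; for 2-level
    factors this F = t^2 is the classical repeated-measures F.
    """
    cells = list(cell_values.columns)
    if cell_values.isna().any().any():
        raise ValueError("incomplete cells")
    if cell_values.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    for fac, codes in factors.items():
        if set(codes) != set(cells) or set(codes.values()) != {-1, 1}:
            raise ValueError(f"factor {fac!r} must code every cell as +1/-1")
    rows = []
    names = list(factors)
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            w = np.array([np.prod([factors[f][c] for f in combo]) for c in cells], float)
            w /= np.sum(w == 1)  # difference of cell means, not sums
            scores = cell_values.to_numpy(float) @ w
            n = len(scores)
            if np.ptp(scores) == 0:  # zero-variance difference scores
                tval, p = (0.0, 1.0) if scores[0] == 0 else (np.inf * np.sign(scores[0]), 0.0)
            else:
                tval, p = stats.ttest_1samp(scores, 0.0)
            rows.append({
                "effect": " x ".join(combo),
                "estimate": float(scores.mean()),
                "t": float(tval),
                "F": float(tval**2),
                "df": n - 1,
                "p": float(p),
            })
    return FactorialBehaviorResult(
        effects=pd.DataFrame(rows).set_index("effect"),
        cell_means=cell_values.mean(axis=0),
        n_subjects=cell_values.shape[0],
    )


@dataclass(frozen=True)
class SDTResult:
    """Signal-detection summary with "f2>f1" stimuli as the signal class."""

    hit_rate: float
    fa_rate: float
    criterion_c: float
    corrected: bool  # log-linear correction applied to the rates

    @property
    def shift_toward_greater(self) -> float:
        """Positive values = bias toward "f2 > f1" answers (equals -c)."""
        return -self.criterion_c


def sdt_criterion(hit_rate: float, fa_rate: float) -> float:
    """c = -(z(hit) + z(fa)) / 2 from already-corrected rates in (0, 1)."""
    if not (0 < hit_rate < 1 and 0 < fa_rate < 1):
        raise ValueError("rates must lie strictly inside (0, 1)")
    return float(-(stats.norm.ppf(hit_rate) + stats.norm.ppf(fa_rate)) / 2.0)


def _sdt_from_trials(trials: pd.DataFrame) -> SDTResult:
    pos = trials[trials["delta"] > 0]
    neg = trials[trials["delta"] < 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both stimulus classes must be present")
    hit = (np.sum(pos["choice"] == "f2>f1") + 0.5) / (len(pos) + 1)
    fa = (np.sum(neg["choice"] == "f2>f1") + 0.5) / (len(neg) + 1)
    return SDTResult(float(hit), float(fa), sdt_criterion(hit, fa), corrected=True)


def criterion_shift(trials: pd.DataFrame, split: str | None = None):
    """SDT criterion for one subject's trials; log-linear corrected rates.

    ``split='rt_median'`` returns a (fast, slow) pair of results from a
    median split of RTs, mirroring the fast/slow bias dissociation analysis.
    """
    if split is None:
        return _sdt_from_trials(trials)
    if split != "rt_median":
        raise ValueError("split must be None or 'rt_median'")
    med = trials["rt_ms"].median()
    fast = trials[trials["rt_ms"] <= med]
    slow = trials[trials["rt_ms"] > med]
    return _sdt_from_trials(fast), _sdt_from_trials(slow)


@dataclass
class CorrelationResult:
    """Per-subject RT-amplitude correlations and their group-level test."""

    coefficients: pd.Series  # rho per subject
    t: float
    p: float
    method: str
    scope: str


def rt_amplitude_correlation(
    data: pd.DataFrame,
    scope: str = "all",
    method: str = "spearman",
) -> CorrelationResult | dict[str, CorrelationResult]:
    """Correlate single-trial RT with band amplitude, per subject, then test at group level.

    ``data`` needs columns ``subject``, ``rt_ms``, ``amplitude`` and (for
    ``scope='per_choice'``) ``choice``. The per-subject coefficient is
    Spearman's rho by default (Pearson via ``method``); the group test is a
    one-sample t-test of the coefficients against zero.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    if scope == "per_choice":
        return {
            ch: rt_amplitude_correlation(
                data[data["choice"] == ch], scope=f"choice:{ch}", method=method
            )
            for ch in ("f2>f1", "f2<f1")
        }
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    coeffs = {}
    for subj, g in data.groupby("subject"):
        if len(g) < 3:
            raise ValueError(f"fewer than 3 trials in scope for subject {subj}")
        coeffs[subj] = float(corr(g["rt_ms"], g["amplitude"])[0])
    coeffs = pd.Series(coeffs, name="rho")
    tval, p = stats.ttest_1samp(coeffs.to_numpy(), 0.0)
    return CorrelationResult(coeffs, float(tval), float(p), method, scope)


def subgroup_rerun(
    subject_trials: list[pd.DataFrame],
    contrast_images: np.ndarray,
    adjacency: Adjacency,
    selector: str = "all",
    bias_cutoff: float = 0.1,
    **cluster_kw,
) -> dict:
    """Re-run the group cluster analysis on a subject subset.

    Selectors:

    * ``'all'``: identical to the main run;
    * ``'low_bias'``: subjects whose criterion shift toward "f2>f1" is below
      ``bias_cutoff`` (the no-bias control);
    * ``'mapping'``: split by saccade-to-choice mapping, run each group and
      additionally the between-group two-sample cluster test.

    Returns ``{'groups': {name: (subject_indices, ClusterResult)}, 'between':
    ClusterResult | None}``.
    """
    n = len(subject_trials)
    if contrast_images.shape[0] != n:
        raise ValueError("one contrast image per subject required")

    def run(idx: list[int]) -> tuple[list[int], ClusterResult]:
        if len(idx) < 2:
            raise ValueError("subgroup too small (need >= 2 subjects)")
        return idx, cluster_permutation(contrast_images[idx], adjacency, **cluster_kw)

    if selector == "all":
        return {"groups": {"all": run(list(range(n)))}, "between": None}
    if selector == "low_bias":
        idx = [
            i for i, t in enumerate(subject_trials)
            if criterion_shift(t).shift_toward_greater < bias_cutoff
        ]
        return {"groups": {"low_bias": run(idx)}, "between": None}
    if selector == "mapping":
        groups = {}
        split = {}
        for name in ("right_means_greater", "right_means_smaller"):
            idx = [i for i, t in enumerate(subject_trials) if t["mapping"].iloc[0] == name]
            split[name] = idx
            groups[name] = run(idx)
        between = two_sample_cluster_permutation(
            contrast_images[split["right_means_greater"]],
            contrast_images[split["right_means_smaller"]],
            adjacency, **cluster_kw,
        )
        return {"groups": groups, "between": between}
    raise ValueError("selector must be 'all', 'low_bias' or 'mapping'")
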