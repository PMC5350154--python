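"""Factorial contrasts and sign-flip cluster-based permutation inference.

The group analysis works on per-subject contrast images over a channel x
frequency x time grid. For each bin a one-sample t-test across subjects is
computed; bins exceeding a cluster-defining threshold are grouped into
clusters by adjacency (neighbouring channels at the same TF bin, or +/-1
frequency / time step within a channel), and each cluster's mass (sum of
t-values) is compared with the permutation distribution of the maximum
cluster mass obtained by randomly sign-flipping whole subject images. The
max-statistic null pools positive and negative clusters, so the family-wise
error rate over both tails is controlled at ``alpha``.

The conjunction analysis runs the same machinery separately for correct-
and incorrect-trial choice contrasts on a restricted channel set and
reports the overlap of significant clusters together with the element-wise
minimum of the two t maps (a test of the conjunction null: the effect is
absent in at least one contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .montage import channel_adjacency

# 2x2 cell order: (stimulus sign, correctness)
CELL_ORDER = (
    ("negative", True),   # f2<f1, correct  -> chose "f2<f1"
    ("positive", True),   # f2>f1, correct  -> chose "f2>f1"
    ("negative", False),  # f2<f1, incorrect -> chose "f2>f1"
    ("positive", False),  # f2>f1, incorrect -> chose "f2<f1"
)

#: Named contrast presets over the cells in :data:`CELL_ORDER`. The
#: interaction contrast equals "chose f2>f1 minus chose f2<f1" pooled over
#: correctness; the correct-/incorrect-only contrasts are its two halves.
CONTRASTS = {
    "interaction": (-1.0, 1.0, 1.0, -1.0),
    "correct_only": (-1.0, 1.0, 0.0, 0.0),
    "incorrect_only": (0.0, 0.0, 1.0, -1.0),
}


@dataclass(frozen=True)
class ContrastSpec:
    weights: tuple[float, float, float, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.weights) != len(CELL_ORDER) or not np.all(np.isfinite(self.weights)):
            raise ValueError("need one finite weight per 2x2 cell")

    @classmethod
    def preset(cls, name: str) -> "ContrastSpec":
        return cls(CONTRASTS[name], name=name)


@dataclass(frozen=True)
class Adjacency:
    """Neighbourhood structure: channel graph plus +/-1-bin frequency/time steps."""

    channel_names: tuple[str, ...]
    channel_neighbors: np.ndarray  # boolean (n_ch, n_ch), symmetric, irreflexive

    def __post_init__(self) -> None:
        a = self.channel_neighbors
        if a.shape != (len(self.channel_names),) * 2:
            raise ValueError("adjacency matrix shape must match channel count")
        if np.any(a != a.T) or np.any(np.diag(a)):
            raise ValueError("channel adjacency must be symmetric and irreflexive")

    @classmethod
    def from_montage(cls, channels: list[str], max_distance: float | None = None) -> "Adjacency":
        kw = {} if max_distance is None else {"max_distance": max_distance}
        return cls(tuple(channels), channel_adjacency(list(channels), **kw))

    def restrict(self, channels: list[str]) -> "Adjacency":
        idx = [self.channel_names.index(c) for c in channels]
        return Adjacency(tuple(channels), self.channel_neighbors[np.ix_(idx, idx)])


def condition_means(
    trial_values: np.ndarray, sign: np.ndarray, correct: np.ndarray,
    require: tuple | None = None,
) -> tuple[dict, dict]:
    """Per-cell mean maps over trials for the 2x2 (sign x correctness) design.

    ``trial_values`` has trials on the first axis. Returns (means, counts)
    keyed by the :data:`CELL_ORDER` cells; cells in ``require`` (default:
    all four) must be non-empty or a ValueError is raised, others are
    flagged by a None entry.
    """
    sign = np.asarray(sign)
    correct = np.asarray(correct, bool)
    if len(sign) != trial_values.shape[0] or len(correct) != trial_values.shape[0]:
        raise ValueError("every trial needs a sign and correctness label")
    require = CELL_ORDER if require is None else require
    means, counts = {}, {}
    for cell in CELL_ORDER:
        s, c = cell
        m = (sign == s) & (correct == c)
        counts[cell] = int(m.sum())
        if counts[cell] == 0:
            if cell in require:
                raise ValueError(f"required cell {cell} has no trials")
            means[cell] = None
        else:
            with warnings.catch_warnings():
                # all-NaN (edge) bins are NaN in the mean by design
                warnings.filterwarnings("ignore", "Mean of empty slice")
                means[cell] = np.nanmean(trial_values[m], axis=0)
    return means, counts


def apply_contrast(means: dict, spec: ContrastSpec) -> np.ndarray:
    """Weighted sum of cell-mean maps; errors if a weighted cell is missing."""
    out = None
    for w, cell in zip(spec.weights, CELL_ORDER):
        if w == 0:
            continue
        if means.get(cell) is None:
            raise ValueError(f"contrast {spec.name!r} needs cell {cell}, which is missing")
        term = w * means[cell]
        out = term if out is None else out + term
    if out is None:
        raise ValueError("contrast has no non-zero weights")
    return out


def group_t_map(contrast_images: np.ndarray) -> np.ndarray:
    """One-sample t across subjects per bin (df = n-1); NaN where undefined.

    Bins invalid (NaN) for any subject, or with zero variance and non-zero
    mean, are NaN in the output; zero-variance zero-mean bins give t = 0.
    """
    x = np.asarray(contrast_images, float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    n = x.shape[0]
    m = x.mean(axis=0)
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / se
    t[(se == 0) & (m == 0)] = 0.0
    t[(se == 0) & (m != 0)] = np.nan
    return t


@dataclass
class Cluster:
    bins: np.ndarray  # (k, 3) int array of (channel, freq, time) indices
    mass: float  # sum of t over member bins (signed)
    p: float  # FWE-corrected permutation p
    sign: int  # +1 or -1

    @property
    def significant(self) -> bool:
        return self.p < 0.05

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, bool)
        m[tuple(self.bins.T)] = True
        return m


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    t_crit: float
    threshold_p: float
    alpha: float
    n_permutations: int
    null_max_mass: np.ndarray  # max |cluster mass| per permutation

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p < a]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _cluster_masses(
    supra_flat: np.ndarray, t_flat: np.ndarray, shape: tuple[int, int, int],
    neighbor_lists: list[np.ndarray],
) -> tuple[list[np.ndarray], list[float]]:
    """Connected components (and their t-mass) of suprathreshold bins.

    Works on the sparse set of suprathreshold flat indices: adjacency is
    same-channel +/-1 frequency or time step, or a neighbouring channel at
    the same (frequency, time) bin — no diagonal steps in the TF plane.
    """
    idx = np.flatnonzero(supra_flat)
    if idx.size == 0:
        return [], []
    n_ch, n_f, n_t = shape
    pos = {int(i): k for k, i in enumerate(idx)}
    uf = _UnionFind(idx.size)
    c, rem = np.divmod(idx, n_f * n_t)
    f, t = np.divmod(rem, n_t)
    for k, i in enumerate(idx):
        i = int(i)
        if t[k] + 1 < n_t and (j := i + 1) in pos:
            uf.union(k, pos[j])
        if f[k] + 1 < n_f and (j := i + n_t) in pos:
            uf.union(k, pos[j])
        for cn in neighbor_lists[c[k]]:
            if cn > c[k] and (j := int(i + (cn - c[k]) * n_f * n_t)) in pos:
                uf.union(k, pos[j])
    roots = np.array([uf.find(k) for k in range(idx.size)])
    members: dict[int, list[int]] = {}
    for k, r in enumerate(roots):
        members.setdefault(int(r), []).append(k)
    bins, masses = [], []
    for ks in members.values():
        ii = idx[ks]
        bins.append(np.column_stack([c[ks], f[ks], t[ks]]))
        masses.append(float(t_flat[ii].sum()))
    return bins, masses


def _sign_flip_t(x_flat: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t maps for many sign-flip assignments at once.

    ``x_flat`` is subjects x bins, ``flips`` is permutations x subjects of
    +/-1. Uses the identity that the per-bin sum of squares is invariant
    under sign flips.
    """
    n = x_flat.shape[0]
    ssq = np.einsum("ij,ij->j", x_flat, x_flat)
    mean = flips @ x_flat / n
    var = (ssq[None, :] - n * mean**2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return mean / np.sqrt(var / n)


def cluster_permutation(
    contrast_images: np.ndarray,
    adjacency: Adjacency,
    threshold_p: float = 0.001,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ClusterResult:
    """Group-level sign-flip cluster test on subjects x channels x freqs x times images.

    Bins with |t| above the two-sided cluster-defining threshold are grouped
    into clusters (positive and negative families separately); each
    cluster's |mass| is referred to the permutation distribution of the
    maximum |cluster mass| over both families under whole-image subject
    sign flips. ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0.0 < threshold_p < 1.0):
        raise ValueError("threshold_p must be in (0, 1)")
    x = np.asarray(contrast_images, float)
    n_subj = x.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    shape = x.shape[1:]
    if len(shape) != 3:
        raise ValueError("images must be channels x freqs x times")
    if len(adjacency.channel_names) != shape[0]:
        raise ValueError("adjacency must cover all channels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    valid = np.all(np.isfinite(x), axis=0)
    xv = np.where(valid[None], x, 0.0)
    x_flat = xv.reshape(n_subj, -1)
    valid_flat = valid.ravel()

    df = n_subj - 1
    t_crit = float(stats.t.isf(threshold_p / 2.0, df))
    neighbor_lists = [np.flatnonzero(row) for row in adjacency.channel_neighbors]

    def max_mass(t_flat: np.ndarray) -> float:
        supra = valid_flat & (np.abs(t_flat) > t_crit)
        _, masses = _cluster_masses(supra, t_flat, shape, neighbor_lists)
        return max((abs(m) for m in masses), default=0.0)

    t_obs_flat = _sign_flip_t(x_flat, np.ones((1, n_subj)))[0]
    t_obs_flat[~valid_flat] = 0.0

    null = np.empty(n_perm)
    block = 100
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        flips = rng.choice([-1.0, 1.0], size=(k, n_subj))
        t_perm = _sign_flip_t(x_flat, flips)
        t_perm[:, ~valid_flat] = 0.0
        for j in range(k):
            null[done + j] = max_mass(t_perm[j])
        done += k

    clusters = []
    for sgn in (1, -1):
        supra = valid_flat & (sgn * t_obs_flat > t_crit)
        bins_list, masses = _cluster_masses(supra, t_obs_flat, shape, neighbor_lists)
        for bins, mass in zip(bins_list, masses):
            p = float((1 + np.sum(null >= abs(mass))) / (1 + n_perm))
            clusters.append(Cluster(bins=bins, mass=mass, p=p, sign=sgn))
    clusters.sort(key=lambda c: c.p)

    t_map = t_obs_flat.reshape(shape).copy()
    t_map[~valid] = np.nan
    return ClusterResult(
        clusters=clusters, t_map=t_map, t_crit=t_crit, threshold_p=threshold_p,
        alpha=alpha, n_permutations=n_perm, null_max_mass=null,
    )


@dataclass
class ConjunctionResult:
    correct: ClusterResult
    incorrect: ClusterResult
    min_t_map: np.ndarray
    overlap_bins: np.ndarray  # (k, 3) indices common to significant clusters of both classes
    channel_names: tuple[str, ...]

    @property
    def conjunction_positive(self) -> bool:
        """True when significant same-sign clusters of both classes overlap."""
        return self.overlap_bins.shape[0] > 0


def conjunction(
    correct_images: np.ndarray,
    incorrect_images: np.ndarray,
    adjacency: Adjacency,
    channel_restriction: list[str],
    threshold_p: float = 0.01,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ConjunctionResult:
    """Conjunction of the choice contrast across correct and incorrect trials.

    Cluster permutation runs separately per trial class, restricted to (and
    corrected over) ``channel_restriction``; the result reports per-class
    clusters, the bins where significant positive clusters of both classes
    overlap, and the element-wise minimum of the two t maps.
    """
    if len(channel_restriction) == 0:
        raise ValueError("channel restriction must not be empty")
    if correct_images.shape != incorrect_images.shape:
        raise ValueError("both image sets must come from the same subjects and grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = [adjacency.channel_names.index(c) for c in channel_restriction]
    sub_adj = adjacency.restrict(channel_restriction)
    res_c = cluster_permutation(correct_images[:, idx], sub_adj, threshold_p,
                                n_perm, alpha, rng)
    res_i = cluster_permutation(incorrect_images[:, idx], sub_adj, threshold_p,
                                n_perm, alpha, rng)
    min_t = np.minimum(res_c.t_map, res_i.t_map)

    shape = res_c.t_map.shape
    mask_c = np.zeros(shape, bool)
    for c in res_c.significant(alpha):
        if c.sign > 0:
            mask_c |= c.mask(shape)
    mask_i = np.zeros(shape, bool)
    for c in res_i.significant(alpha):
        if c.sign > 0:
            mask_i |= c.mask(shape)
    overlap = np.argwhere(mask_c & mask_i)
    return ConjunctionResult(
        correct=res_c, incorrect=res_i, min_t_map=min_t,
        overlap_bins=overlap, channel_names=tuple(channel_restriction),
    )


def independent_t_map(images_a: np.ndarray, images_b: np.ndarray) -> np.ndarray:
    """Two-sample (pooled-variance) t map comparing two subject groups per bin."""
    a, b = np.asarray(images_a, float), np.asarray(images_b, float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a.mean(axis=0) - b.mean(axis=0)) / (sp * np.sqrt(1 / na + 1 / nb))


def two_sample_cluster_permutation(
    images_a: np.ndarray,
    images_b: np.ndarray,
    adjacency: Adjacency,
    threshold_p: float = 0.001,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ClusterResult:
    """Between-group cluster test by permuting group labels (used for mapping splits)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = np.asarray(images_a, float), np.asarray(images_b, float)
    na, nb = a.shape[0], b.shape[0]
    x = np.concatenate([a, b], axis=0)
    shape = x.shape[1:]
    valid = np.all(np.isfinite(x), axis=0)
    x = np.where(valid[None], x, 0.0)
    df = na + nb - 2
    t_crit = float(stats.t.isf(threshold_p / 2.0, df))
    neighbor_lists = [np.flatnonzero(row) for row in adjacency.channel_neighbors]
    valid_flat = valid.ravel()

    def stat(order: np.ndarray) -> np.ndarray:
        t = independent_t_map(x[order[:na]], x[order[na:]]).ravel()
        t[~valid_flat] = 0.0
        return np.nan_to_num(t)

    def max_mass(t_flat: np.ndarray) -> float:
        supra = valid_flat & (np.abs(t_flat) > t_crit)
        _, masses = _cluster_masses(supra, t_flat, shape, neighbor_lists)
        return max((abs(m) for m in masses), default=0.0)

    t_obs = stat(np.arange(na + nb))
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = max_mass(stat(rng.permutation(na + nb)))

    clusters = []
    for sgn in (1, -1):
        supra = valid_flat & (sgn * t_obs > t_crit)
        bins_list, masses = _cluster_masses(supra, t_obs, shape, neighbor_lists)
        for bins, mass in zip(bins_list, masses):
            pval = float((1 + np.sum(null >= abs(mass))) / (1 + n_perm))
            clusters.append(Cluster(bins=bins, mass=mass, p=pval, sign=sgn))
    clusters.sort(key=lambda c: c.p)
    t_map = t_obs.reshape(shape).copy()
    t_map[~valid] = np.nan
    return ClusterResult(clusters, t_map, t_crit, threshold_p, alpha, n_perm, null)
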