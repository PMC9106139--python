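"""Channel-space statistics: cluster-based permutation, Wilcoxon, Spearman+FDR.

The cluster-based permutation test controls the family-wise error of a
paired channel-wise comparison: per-channel paired t statistics are
thresholded per tail at the 95th quantile of the t distribution, connected
same-sign suprathreshold channels (under a montage-derived spatial
adjacency) form clusters whose mass is the sum of member t values, and a
null distribution of the maximum absolute cluster mass is built by random
within-subject sign flips of the paired differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class ChannelAdjacency:
    """Symmetric, irreflexive channel neighbourhood from montage distances."""

    labels: list[str]
    neighbors: np.ndarray  # (n, n) bool

    def __post_init__(self) -> None:
        nb = np.asarray(self.neighbors, dtype=bool)
        if not np.array_equal(nb, nb.T):
            raise ValueError("adjacency must be symmetric")
        if nb.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        self.neighbors = nb

    @property
    def mean_neighbor_count(self) -> float:
        return float(self.neighbors.sum(axis=1).mean())

    def subset(self, keep: np.ndarray) -> "ChannelAdjacency":
        """Adjacency restricted to the channels selected by boolean mask ``keep``."""
        labels = [ch for ch, k in zip(self.labels, keep) if k]
        return ChannelAdjacency(labels=labels, neighbors=self.neighbors[np.ix_(keep, keep)])


def build_adjacency(
    coords: np.ndarray, labels: list[str], distance_quantile: float = 0.15
) -> ChannelAdjacency:
    """Channels are neighbours iff their Euclidean montage distance is at
    or below the stated quantile of all pairwise distances."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    dvec = pdist(coords)
    if np.any(dvec == 0):
        raise ValueError("coincident channel coordinates: adjacency is degenerate")
    thr = np.quantile(dvec, distance_quantile)
    d = squareform(dvec)
    nb = d <= thr
    np.fill_diagonal(nb, False)
    return ChannelAdjacency(labels=list(labels), neighbors=nb)


@dataclass
class Cluster:
    channels: tuple[str, ...]
    indices: np.ndarray
    sign: int  # +1: condition A > B on members, -1: A < B
    mass: float  # sum of member t values
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray  # (n_channels,) observed paired t statistics
    threshold: float  # per-tail clustering threshold on |t|
    null_distribution: np.ndarray  # (n_permutations,) max |cluster mass|
    n_permutations: int
    alpha: float
    labels: list[str]

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": k,
                "sign": c.sign,
                "n_channels": len(c.channels),
                "channels": ",".join(c.channels),
                "mass": c.mass,
                "p_value": c.p_value,
            }
            for k, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows, columns=["cluster", "sign", "n_channels", "channels", "mass", "p_value"]
        )


def _paired_t(diffs: np.ndarray, warn: bool = True) -> np.ndarray:
    """Per-channel one-sample t on paired differences; zero variance -> t = 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero = sd == 0
    if warn and np.any(zero):
        warnings.warn(
            "zero-variance paired differences on some channels; their t set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero, 0.0, mean / np.where(zero, 1.0, sd / np.sqrt(n)))
    return t


def _components(mask: np.ndarray, neighbors: np.ndarray) -> list[np.ndarray]:
    """Connected components of the suprathreshold channel set."""
    idx = np.flatnonzero(mask)
    comps: list[np.ndarray] = []
    unvisited = set(idx.tolist())
    while unvisited:
        start = unvisited.pop()
        comp = [start]
        stack = [start]
        while stack:
            node = stack.pop()
            nbrs = np.flatnonzero(neighbors[node] & mask)
            for nb in nbrs:
                if nb in unvisited:
                    unvisited.remove(nb)
                    comp.append(nb)
                    stack.append(nb)
        comps.append(np.sort(np.array(comp)))
    return comps


def _max_cluster_mass(t: np.ndarray, thr: float, neighbors: np.ndarray) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        mask = sign * t > thr
        if not mask.any():
            continue
        st = sign * t
        if mask.sum() == 1:
            best = max(best, float(st[mask][0]))
            continue
        for comp in _components(mask, neighbors):
            best = max(best, float(st[comp].sum()))
    return best


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    adjacency: ChannelAdjacency,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterResult:
    """Paired two-condition cluster-based permutation test over channels.

    ``a`` and ``b`` are (n_subjects, n_channels) matrices of the same
    subjects under two conditions; the statistic per channel is the paired
    t of ``a - b``.  Channels exceeding the per-tail t-distribution
    quantile at ``cluster_alpha`` enter clustering; each observed cluster's
    p-value is the smoothed proportion of sign-flip permutations whose
    maximum absolute cluster mass reaches its own.  Two-tailed significance
    at ``p < alpha``.  Deterministic given ``seed``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition matrices must have identical shape")
    n_subj, n_ch = a.shape
    if n_subj < 3:
        raise ValueError("cluster permutation test needs at least 3 subjects")
    if n_ch != len(adjacency.labels):
        raise ValueError("channel count does not match adjacency")
    if n_permutations < 100:
        warnings.warn(
            f"{n_permutations} permutations gives a coarse null; use >= 100",
            RuntimeWarning,
            stacklevel=2,
        )
    diffs = a - b
    t_obs = _paired_t(diffs)
    thr = float(stats.t.ppf(1.0 - cluster_alpha, df=n_subj - 1))

    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = sign * t_obs > thr
        if not mask.any():
            continue
        for comp in _components(mask, adjacency.neighbors):
            clusters.append(
                Cluster(
                    channels=tuple(adjacency.labels[i] for i in comp),
                    indices=comp,
                    sign=sign,
                    mass=float(t_obs[comp].sum()),
                    p_value=np.nan,
                )
            )

    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_permutations, n_subj)) * 2 - 1
    null = np.empty(n_permutations)
    sqrt_n = np.sqrt(n_subj)
    for p in range(n_permutations):
        d = flips[p][:, None] * diffs
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_p = np.where(sd == 0, 0.0, mean / np.where(sd == 0, 1.0, sd / sqrt_n))
        null[p] = _max_cluster_mass(t_p, thr, adjacency.neighbors)

    for c in clusters:
        c.p_value = float((1 + np.sum(null >= abs(c.mass))) / (1 + n_permutations))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters,
        t_values=t_obs,
        threshold=thr,
        null_distribution=null,
        n_permutations=n_permutations,
        alpha=alpha,
        labels=list(adjacency.labels),
    )


def wilcoxon_signed_rank(diffs: np.ndarray) -> float:
    """Two-tailed Wilcoxon signed-rank p-value on paired differences.

    Zeros are dropped; tied absolute differences receive mid-ranks.  For
    n <= 25 the p-value is exact, computed from the full sign-flip
    distribution of the rank sum (a convolution over the doubled mid-ranks,
    equivalent to enumerating all 2^n sign patterns); above that a normal
    approximation with tie correction and continuity correction is used.
    The two-tailed p is twice the smaller tail, capped at 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        r2 = np.rint(2 * ranks).astype(np.int64)  # doubled mid-ranks are integers
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: total + 1 - r].copy()
        w2 = int(np.rint(2 * w_pos))
        n_patterns = 2.0**n
        p_ge = counts[w2:].sum() / n_patterns
        p_le = counts[: w2 + 1].sum() / n_patterns
        return float(min(1.0, 2.0 * min(p_ge, p_le)))
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    delta = w_pos - mu
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def spearman_fdr(
    x_matrix: np.ndarray,
    y: np.ndarray,
    q: float = 0.05,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-channel Spearman correlation with Benjamini-Hochberg correction.

    ``x_matrix`` is (n_subjects, n_channels); ``y`` is a per-subject
    vector.  Channels with constant values have undefined rho: they are
    flagged (rho = NaN) and excluded from the FDR family with a warning.
    Returns a DataFrame with columns channel, rho, p, p_fdr, significant.
    """
    x = np.asarray(x_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.size:
        raise ValueError("x_matrix must be (n_subjects, n_channels), y (n_subjects,)")
    if x.shape[0] < 5:
        raise ValueError("Spearman correlation needs at least 5 subjects")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    n_ch = x.shape[1]
    if labels is None:
        labels = [f"ch{i:02d}" for i in range(n_ch)]
    rho = np.full(n_ch, np.nan)
    pval = np.full(n_ch, np.nan)
    const_y = np.ptp(y) == 0
    for c in range(n_ch):
        if const_y or np.ptp(x[:, c]) == 0:
            continue
        r, p = stats.spearmanr(x[:, c], y)
        rho[c], pval[c] = r, p
    valid = ~np.isnan(pval)
    if valid.sum() < n_ch:
        warnings.warn(
            "constant input on some channels: rho undefined, excluded from FDR family",
            RuntimeWarning,
            stacklevel=2,
        )
    significant = np.zeros(n_ch, dtype=bool)
    p_fdr = np.full(n_ch, np.nan)
    if valid.any():
        reject, p_adj, *_ = multipletests(pval[valid], alpha=q, method="fdr_bh")
        significant[valid] = reject
        p_fdr[valid] = p_adj
    return pd.DataFrame(
        {"channel": labels, "rho": rho, "p": pval, "p_fdr": p_fdr, "significant": significant}
    )
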