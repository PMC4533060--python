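"""Nonparametric cluster-based permutation inference.

Bin-wise statistics (independent-samples t, simple-regression t, or paired
one-sample t) are thresholded at a two-sided ``cluster_alpha``; connected
supra-threshold bins (separately for positive and negative t) form
clusters whose mass is the sum of member t-values.  The observed masses
are compared with the permutation distribution of the maximum cluster
mass — pooled across all supplied maps (e.g. both hemispheres), which is
how correction across hemispheres is achieved.  The identity permutation
is always a member of the null, so p-values are strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as spstats

__all__ = [
    "PermutationConfig",
    "Cluster",
    "ClusterResult",
    "bin_statistic",
    "form_clusters",
    "permutation_test",
    "T_SENTINEL",
]

T_SENTINEL = 1e6  # cap for infinite t at perfect fits


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1000
    cluster_alpha: float = 0.05  # bin-thresholding level (liberal scan: 0.1)
    test_alpha: float = 0.05  # cluster-level significance
    channel_adjacency: bool = True  # connect neighboring bipolar channels
    no_adjacency: bool = False  # every bin its own cluster (max-|t| correction)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cluster_alpha < 0.5:
            raise ValueError("cluster_alpha must lie in (0, 0.5)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


@dataclass
class Cluster:
    map_index: int  # which supplied map (hemisphere) the cluster lives in
    sign: str  # "positive" | "negative"
    mass: float
    p_value: float
    bins: tuple  # arrays of member indices, one per map axis

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        return {
            "map_index": self.map_index,
            "sign": self.sign,
            "mass": self.mass,
            "p_value": self.p_value,
            "extents": [
                (int(np.min(ax)), int(np.max(ax))) for ax in self.bins
            ],
        }


@dataclass
class ClusterResult:
    clusters: list  # of Cluster, all maps pooled
    t_maps: list  # observed t-map per supplied map
    kind: str
    df: int
    null_positive: np.ndarray
    null_negative: np.ndarray
    config: PermutationConfig

    def significant(self, alpha: float | None = None) -> list:
        alpha = self.config.test_alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_value < alpha]


# ---------------------------------------------------------------- t-maps


def _t_indep(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """labels (P, n) of 0/1; X (n, B).  Pooled-variance two-sample t."""
    labels = np.asarray(labels, float)
    n = X.shape[0]
    n1 = labels[0].sum()
    n0 = n - n1
    if n1 < 3 or n0 < 3:
        raise ValueError("need at least 3 trials per condition")
    S = X.sum(axis=0)
    Q = (X**2).sum(axis=0)
    S1 = labels @ X
    Q1 = labels @ X**2
    m1 = S1 / n1
    m0 = (S - S1) / n0
    ss1 = Q1 - S1**2 / n1
    ss0 = (Q - Q1) - (S - S1) ** 2 / n0
    sp2 = (ss1 + ss0) / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / denom
    return _capped(t, m1 - m0)


def _t_regression(X: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """regressors (P, n); X (n, B).  Simple-linear-regression slope t."""
    xr = np.asarray(regressors, float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("regression needs at least 4 trials")
    if np.ptp(xr[0]) == 0:
        raise ValueError("regressor has zero variance")
    xc = xr - xr.mean(axis=1, keepdims=True)
    sxx = (xc[0] ** 2).sum()
    yc = X - X.mean(axis=0, keepdims=True)
    syy = (yc**2).sum(axis=0)
    sxy = xc @ yc  # (P, B)
    resid = sxx * syy[None, :] - sxy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = sxy * np.sqrt((n - 2) / resid)
    return _capped(t, sxy)


def _t_paired(X: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """signs (P, n) of +/-1; X (n, B) of per-trial differences vs 0."""
    sg = np.asarray(signs, float)
    n = X.shape[0]
    m = (sg @ X) / n
    q = (X**2).sum(axis=0)
    var = (q[None, :] - n * m**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    return _capped(t, m)


def _capped(t: np.ndarray, direction: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(t)
    if bad.any():
        t = np.where(bad, np.sign(np.where(direction == 0, 0.0, direction)) * T_SENTINEL, t)
        t = np.where(bad & (direction == 0), 0.0, t)
    return t


_KIND_FUNCS = {"indep_t": _t_indep, "regression_t": _t_regression, "dep_t": _t_paired}


def bin_statistic(data: np.ndarray, design: np.ndarray | None, kind: str) -> np.ndarray:
    """Observed bin-wise t-map of ``data`` (trials x bins...) for a design.

    ``design`` is 0/1 condition labels for ``indep_t``, regressor values
    for ``regression_t`` and is ignored (vs-zero) for ``dep_t``.  Returns
    a map with the trial axis removed.
    """
    X = np.asarray(data, float)
    shape = X.shape[1:]
    X = X.reshape(X.shape[0], -1)
    if kind == "dep_t":
        d = np.ones((1, X.shape[0]))
    else:
        if design is None:
            raise ValueError(f"{kind} requires a design vector")
        d = np.asarray(design, float)[None, :]
    t = _KIND_FUNCS[kind](X, d)[0]
    return t.reshape(shape)


def _dof(kind: str, n: int) -> int:
    return n - 1 if kind == "dep_t" else n - 2


# ------------------------------------------------------------- clustering


def _label_map(mask: np.ndarray, channel_axis: bool, channel_adjacency: bool):
    """Connected components; axis 0 is channels when ``channel_axis``."""
    if mask.ndim == 0:
        return (mask.astype(int), 1 if mask else 0)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    if channel_axis and not channel_adjacency and mask.ndim > 1:
        labels = np.zeros(mask.shape, dtype=np.int32)
        count = 0
        sub = ndimage.generate_binary_structure(mask.ndim - 1, 1)
        for c in range(mask.shape[0]):
            lab, k = ndimage.label(mask[c], structure=sub)
            labels[c] = np.where(lab > 0, lab + count, 0)
            count += k
        return labels, count
    return ndimage.label(mask, structure=structure)


def form_clusters(
    t_map: np.ndarray,
    cluster_alpha: float,
    df: int,
    channel_axis: bool = False,
    channel_adjacency: bool = True,
    no_adjacency: bool = False,
) -> list[tuple[tuple, float, str]]:
    """Group supra-threshold bins into sign-separated connected clusters.

    Returns ``(member_indices, mass, sign)`` triples; the threshold is the
    two-sided critical t at ``cluster_alpha`` with ``df`` degrees of
    freedom.
    """
    crit = spstats.t.ppf(1.0 - cluster_alpha / 2.0, df)
    out = []
    for sign, mask in (("positive", t_map > crit), ("negative", t_map < -crit)):
        if not mask.any():
            continue
        if no_adjacency:
            for idx in zip(*np.nonzero(mask)):
                out.append((tuple(np.array([i]) for i in idx), float(t_map[idx]), sign))
            continue
        labels, n_lab = _label_map(mask, channel_axis, channel_adjacency)
        for lab in range(1, n_lab + 1):
            members = np.nonzero(labels == lab)
            out.append((members, float(t_map[members].sum()), sign))
    return out


def _max_masses(t_map, cluster_alpha, df, channel_axis, channel_adjacency, no_adjacency):
    clusters = form_clusters(
        t_map, cluster_alpha, df, channel_axis, channel_adjacency, no_adjacency
    )
    pos = max((m for _, m, s in clusters if s == "positive"), default=0.0)
    neg = max((-m for _, m, s in clusters if s == "negative"), default=0.0)
    return pos, neg


# -------------------------------------------------------- permutation test


def _permutation_designs(kind, design, n, n_perm, rng):
    if kind == "dep_t":
        mat = rng.choice([-1.0, 1.0], size=(n_perm, n))
        mat[0] = 1.0
    else:
        base = np.asarray(design, float)
        mat = np.empty((n_perm, n))
        mat[0] = base
        for p in range(1, n_perm):
            mat[p] = base[rng.permutation(n)]
    return mat


def permutation_test(
    data,
    design: np.ndarray | None,
    kind: str,
    config: PermutationConfig = PermutationConfig(),
    channel_axis: bool = False,
) -> ClusterResult:
    """Cluster-based permutation test over one or several maps.

    Parameters
    ----------
    data
        One array or a list of arrays (e.g. one per hemisphere), each
        ``trials x bins...`` with identical trial ordering.  When several
        maps are given, the null pools the maximum cluster mass across
        all of them, which corrects inference across hemispheres.
    design
        Condition labels (0/1, ``indep_t``), regressor (``regression_t``)
        or None (``dep_t``: per-trial values tested against zero with
        sign-flipping permutations).
    kind
        ``indep_t`` | ``regression_t`` | ``dep_t``.
    channel_axis
        Whether axis 1 of each data array is a channel axis (clusters may
        then span same-electrode neighboring channels if
        ``config.channel_adjacency``).
    """
    maps = data if isinstance(data, (list, tuple)) else [data]
    maps = [np.asarray(m, float) for m in maps]
    n = maps[0].shape[0]
    if any(m.shape[0] != n for m in maps):
        raise ValueError("all maps must share the trial axis")
    shapes = [m.shape[1:] for m in maps]
    flats = [m.reshape(n, -1) for m in maps]

    rng = np.random.default_rng(config.seed)
    n_perm = config.n_permutations
    if kind == "indep_t":
        d = np.asarray(design, float)
        dmat = np.empty((n_perm, n))
        dmat[0] = d
        for p in range(1, n_perm):
            dmat[p] = d[rng.permutation(n)]
    else:
        dmat = _permutation_designs(kind, design, n, n_perm, rng)

    func = _KIND_FUNCS[kind]
    df = _dof(kind, n)

    null_pos = np.zeros(n_perm)
    null_neg = np.zeros(n_perm)
    observed = []
    for h, (flat, shape) in enumerate(zip(flats, shapes)):
        tall = func(flat, dmat)  # (n_perm, B)
        t_obs = tall[0].reshape(shape)
        observed.append(t_obs)
        for p in range(n_perm):
            pos, neg = _max_masses(
                tall[p].reshape(shape), config.cluster_alpha, df,
                channel_axis, config.channel_adjacency, config.no_adjacency,
            )
            null_pos[p] = max(null_pos[p], pos)
            null_neg[p] = max(null_neg[p], neg)

    clusters = []
    for h, t_obs in enumerate(observed):
        for members, mass, sign in form_clusters(
            t_obs, config.cluster_alpha, df,
            channel_axis, config.channel_adjacency, config.no_adjacency,
        ):
            null = null_pos if sign == "positive" else null_neg
            p_val = float(np.mean(null >= abs(mass)))
            clusters.append(
                Cluster(map_index=h, sign=sign, mass=mass, p_value=p_val, bins=members)
            )
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters, t_maps=observed, kind=kind, df=df,
        null_positive=null_pos, null_negative=null_neg, config=config,
    )
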