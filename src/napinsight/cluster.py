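"""Cluster-based permutation inference over channel x frequency data.

Element-wise statistics (Welch t for two groups, one-way F for three) are
thresholded at the parametric critical value of ``cluster_alpha``;
supra-threshold elements are clustered over spatial channel neighbours
and, within a channel, adjacent frequency bins (no diagonal hops; t
clusters are sign-separated). Cluster mass is the sum of statistics, and
its significance comes from the permutation null of the maximum cluster
mass over random relabelings, with the (+1)/(+1) exact-test correction.
Channel-only data (e.g. slope maps) are handled as a single frequency bin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .montage import DEFAULT_ADJACENCY_RADIUS, DEFAULT_MONTAGE


@dataclass
class AdjacencyGraph:
    channels: list[str]
    neighbours: np.ndarray  # boolean (n_ch, n_ch), symmetric, no self-loops
    radius: float

    def pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.channels)):
            for j in range(i + 1, len(self.channels)):
                if self.neighbours[i, j]:
                    out.append((self.channels[i], self.channels[j]))
        return out


@dataclass
class Cluster:
    members: list[tuple[str, int]]  # (channel, frequency-bin index)
    sign: str                       # "+", "-" or "F"
    mass: float
    p: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    stat_map: np.ndarray            # (n_ch, n_bins) element statistics
    threshold: float | np.ndarray
    n_permutations: int
    alpha: float
    cluster_alpha: float
    frequencies: np.ndarray | None = None
    channels: list[str] = field(default_factory=list)

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= self.alpha]


def build_adjacency(
    montage: dict[str, tuple[float, float]] | None = None,
    radius: float = DEFAULT_ADJACENCY_RADIUS,
) -> AdjacencyGraph:
    """Channels within Euclidean ``radius`` of each other are neighbours."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    montage = DEFAULT_MONTAGE if montage is None else montage
    if len(montage) < 2:
        raise ValueError("need at least two channels with positions")
    names = list(montage)
    pos = np.array([montage[n] for n in names], dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d <= radius) & ~np.eye(len(names), dtype=bool)
    return AdjacencyGraph(channels=names, neighbours=adj, radius=radius)


# ---------------------------------------------------------------------------
# element statistics
# ---------------------------------------------------------------------------

def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t and df over the first (subject) axis."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = np.where(se2 > 0, t, 0.0)
    df = np.where(np.isfinite(df), df, na + nb - 2)
    return t, df


def _oneway_f(groups: list[np.ndarray]) -> np.ndarray:
    """Vectorized one-way F over the first (subject) axis."""
    k = len(groups)
    ns = np.array([g.shape[0] for g in groups])
    n = ns.sum()
    means = np.stack([g.mean(axis=0) for g in groups])
    grand = (means * ns[:, None, None]).sum(axis=0) / n
    ssb = ((means - grand) ** 2 * ns[:, None, None]).sum(axis=0)
    ssw = sum(((g - means[i]) ** 2).sum(axis=0) for i, g in enumerate(groups))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    return np.where(np.isfinite(f), f, 0.0)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _element_graph(mask: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """Connected-component labels over supra-threshold (channel, bin) cells."""
    n_ch, n_bins = mask.shape
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        return np.full(mask.shape, -1, dtype=int)
    pos = {v: i for i, v in enumerate(idx)}
    rows, cols = [], []
    for v in idx:
        c, b = divmod(v, n_bins)
        if b + 1 < n_bins and mask[c, b + 1]:
            w = v + 1
            rows.append(pos[v]); cols.append(pos[w])
        for c2 in np.flatnonzero(adj[c]):
            if c2 > c and mask[c2, b]:
                w = c2 * n_bins + b
                rows.append(pos[v]); cols.append(pos[w])
    g = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(idx.size, idx.size)
    )
    _, comp = connected_components(g, directed=False)
    labels = np.full(mask.shape, -1, dtype=int)
    labels.ravel()[idx] = comp
    return labels


def _cluster_masses(
    stat: np.ndarray, threshold, adj: np.ndarray, signed: bool
) -> tuple[list[float], list[np.ndarray], list[str]]:
    masses, members, signs = [], [], []
    if signed:
        variants = [(stat > threshold, "+"), (stat < -threshold, "-")]
    else:
        variants = [(stat > threshold, "F")]
    for mask, sign in variants:
        labels = _element_graph(mask, adj)
        for lab in range(labels.max() + 1):
            sel = labels == lab
            masses.append(float(stat[sel].sum()))
            members.append(sel)
            signs.append(sign)
    return masses, members, signs


def _stat_and_threshold(
    data_groups: list[np.ndarray], stat: str, cluster_alpha: float
):
    if stat == "t":
        t, df = _welch_t(data_groups[0], data_groups[1])
        crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
        return t, crit, True
    f = _oneway_f(data_groups)
    k = len(data_groups)
    n = sum(g.shape[0] for g in data_groups)
    crit = float(stats.f.ppf(1.0 - cluster_alpha, k - 1, n - k))
    return f, crit, False


def _max_mass(data: np.ndarray, sizes: list[int], stat: str,
              cluster_alpha: float, adj: np.ndarray) -> float:
    groups, at = [], 0
    for n in sizes:
        groups.append(data[at : at + n])
        at += n
    s, crit, signed = _stat_and_threshold(groups, stat, cluster_alpha)
    masses, _, _ = _cluster_masses(s, crit, adj, signed)
    return max((abs(m) for m in masses), default=0.0)


def cluster_permutation_test(
    data: np.ndarray,
    groups: np.ndarray | list,
    stat: str = "F",
    adjacency: AdjacencyGraph | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
    frequencies: np.ndarray | None = None,
    exact: bool = False,
) -> ClusterTestResult:
    """Cluster-based permutation test on (subjects, channels[, bins]) data.

    ``stat`` is "t" (exactly two groups, two-tailed with ``alpha`` per
    tail applied to cluster p) or "F" (exactly three groups). ``exact``
    enumerates every distinct relabeling instead of sampling ``n_perm``
    of them (feasible only for small cohorts).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError("data must be (subjects, channels) or (subjects, channels, bins)")
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups.tolist()))
    if stat == "t" and len(levels) != 2:
        raise ValueError("t statistic requires exactly two groups")
    if stat == "F" and len(levels) != 3:
        raise ValueError("F statistic requires exactly three groups")
    if any((groups == g).sum() < 2 for g in levels):
        raise ValueError("each group needs at least two subjects")
    adjacency = build_adjacency() if adjacency is None else adjacency
    if len(adjacency.channels) != data.shape[1]:
        raise ValueError("adjacency channel count does not match data")

    order = np.concatenate([np.flatnonzero(groups == g) for g in levels])
    sizes = [int((groups == g).sum()) for g in levels]
    stacked = data[order]

    grp_arrays, at = [], 0
    for n in sizes:
        grp_arrays.append(stacked[at : at + n])
        at += n
    s, crit, signed = _stat_and_threshold(grp_arrays, stat, cluster_alpha)
    masses, members, signs = _cluster_masses(s, crit, adjacency.neighbours, signed)

    n_total = stacked.shape[0]
    if exact:
        perms = [np.array(p) for p in _enumerate_assignments(n_total, sizes)]
        null = np.array([
            _max_mass(stacked[p], sizes, stat, cluster_alpha, adjacency.neighbours)
            for p in perms
        ])
        n_eff = len(perms)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        idx = np.arange(n_total)
        for i in range(n_perm):
            rng.shuffle(idx)
            null[i] = _max_mass(
                stacked[idx], sizes, stat, cluster_alpha, adjacency.neighbours
            )
        n_eff = n_perm

    clusters = []
    for mass, sel, sign in zip(masses, members, signs):
        p = (np.sum(null >= abs(mass)) + 1.0) / (n_eff + 1.0)
        mem = [
            (adjacency.channels[c], int(b))
            for c, b in zip(*np.nonzero(sel))
        ]
        clusters.append(Cluster(members=mem, sign=sign, mass=mass, p=float(p)))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterTestResult(
        clusters=clusters,
        stat_map=s,
        threshold=crit,
        n_permutations=n_eff,
        alpha=alpha,
        cluster_alpha=cluster_alpha,
        frequencies=frequencies,
        channels=list(adjacency.channels),
    )


def _enumerate_assignments(n: int, sizes: list[int]):
    """All distinct orderings of subjects into consecutive group slots."""
    if len(sizes) == 2:
        all_idx = set(range(n))
        for combo in itertools.combinations(range(n), sizes[0]):
            rest = sorted(all_idx - set(combo))
            yield list(combo) + rest
    else:
        idx = set(range(n))
        for g1 in itertools.combinations(range(n), sizes[0]):
            rem = idx - set(g1)
            for g2 in itertools.combinations(sorted(rem), sizes[1]):
                g3 = sorted(rem - set(g2))
                yield list(g1) + list(g2) + g3


def posthoc_pairwise(
    data: np.ndarray,
    groups: np.ndarray | list,
    pairs: list[tuple[str, str]],
    adjacency: AdjacencyGraph | None = None,
    n_perm: int = 1000,
    alpha: float = 0.025,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
    frequencies: np.ndarray | None = None,
) -> dict[tuple[str, str], ClusterTestResult]:
    """Run the two-group t variant for each requested pair of groups."""
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    out = {}
    for a, b in pairs:
        sel = (groups == a) | (groups == b)
        if not sel.any() or a == b:
            raise ValueError(f"invalid pair ({a}, {b})")
        sub_groups = np.where(groups[sel] == a, a, b)
        # keep requested order so positive clusters mean a > b
        order = np.concatenate(
            [np.flatnonzero(sub_groups == a), np.flatnonzero(sub_groups == b)]
        )
        out[(a, b)] = cluster_permutation_test(
            data[sel][order],
            sub_groups[order],
            stat="t",
            adjacency=adjacency,
            n_perm=n_perm,
            alpha=alpha,
            cluster_alpha=cluster_alpha,
            seed=seed,
            frequencies=frequencies,
        )
    return out
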