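"""Fine clustering of reflection data sets by structure-factor correlation.

Similarity between two crystals is the Pearson correlation coefficient (CC)
of their amplitudes over the Miller indices they share; it is converted to a
distance d(i,j) = sqrt(1 - CC(i,j)) and fed to Ward minimum-variance
agglomeration. Cutting the resulting dendrogram at a height k yields the
fine clusters. The combined two-factor workflow first groups crystals by
unit-cell similarity (coarse stage, see :mod:`polyclust.cell_cluster`) and
then refines each coarse cluster with the CC stage.

Crystals must be reasonably complete for the CC stage: pairs are compared
only on common reflections, so sparse sets correlate on too few amplitudes.
By default sets below 70% completeness are excluded; with the penalty
variant (which down-weights CC by the matched fraction) much lower
completeness becomes usable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .reflection_model import ReflectionSet, completeness, encode_hkl

__all__ = [
    "CCMatrix",
    "LinkageTree",
    "ClusterConfig",
    "ClusterAssignment",
    "pairwise_cc",
    "cc_matrix",
    "cc_distance",
    "penalized_distance",
    "distance_matrix_from_cc",
    "ward_linkage",
    "cut_tree",
    "cut_tree_n",
    "cluster_count",
    "two_factor_cluster",
]

#: tolerance when clamping numerically out-of-range correlations
CC_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class ClusterConfig:
    """Knobs of the CC clustering stage.

    min_completeness:
        completeness gate for admission to the CC stage (default 0.70).
    min_common:
        minimum number of shared unique reflections for a CC to be trusted;
        pairs below it are flagged instead of scored (Pearson on a handful
        of points is noise).
    cut_height:
        dendrogram height cutoff k; lower k means tighter clusters.
    use_penalty:
        score pairs with the unmatched-reflection penalty variant.
    cc_on:
        correlate amplitudes (default) or their squares (intensities).
    """

    min_completeness: float = 0.70
    min_common: int = 30
    cut_height: float = 1.0
    use_penalty: bool = False
    cc_on: Literal["amplitudes", "intensities"] = "amplitudes"

    def __post_init__(self) -> None:
        if not 0.0 < self.min_completeness <= 1.0:
            raise ValueError("min_completeness must lie in (0, 1]")
        if self.min_common < 2:
            raise ValueError("min_common must be at least 2")
        if self.cut_height < 0:
            raise ValueError("cut_height must be non-negative")
        if self.cc_on not in ("amplitudes", "intensities"):
            raise ValueError("cc_on must be 'amplitudes' or 'intensities'")


@dataclass
class CCMatrix:
    """Pairwise correlation structure for a list of data sets.

    ``cc[i, j]`` is NaN where a pair had fewer than ``min_common`` shared
    reflections; ``n_common`` always carries the overlap count.
    """

    ids: list[str]
    cc: np.ndarray
    n_common: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.cc.shape != (n, n) or self.n_common.shape != (n, n):
            raise ValueError("matrix shapes must match the id list")


@dataclass
class LinkageTree:
    """Agglomeration history: n-1 merge records over n leaves.

    Internal nodes are numbered scipy-style: leaves are 0..n-1 in the order
    of ``leaf_ids``; merge i creates node n+i. Heights are on the same scale
    as the input distances (square root of the Ward objective).
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]]  # (left, right, height, size)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix in scipy.cluster.hierarchy format."""
        return np.array([[l, r, h, s] for l, r, h, s in self.merges], dtype=float).reshape(-1, 4)

    def members(self, node: int) -> list[int]:
        """Leaf indices under a node (a leaf is its own member)."""
        n = self.n_leaves
        if node < n:
            return [node]
        left, right, _, _ = self.merges[node - n]
        return self.members(left) + self.members(right)


@dataclass
class ClusterAssignment:
    """Flat partition of data sets, with provenance of how it was cut.

    ``labels`` maps id -> integer cluster label; ``status`` is "assigned" or
    an "unassigned:<reason>" marker for sets excluded by gating (those carry
    label -1). ``coarse_of`` records the parent coarse cluster for fine
    assignments.
    """

    labels: dict[str, int]
    stage: Literal["coarse", "fine"]
    cut_height: float | None = None
    n_clusters_requested: int | None = None
    status: dict[str, str] = field(default_factory=dict)
    coarse_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid in self.labels:
            self.status.setdefault(sid, "assigned")

    @property
    def n_clusters(self) -> int:
        return len({v for v in self.labels.values() if v >= 0})

    def assigned_ids(self) -> list[str]:
        return [i for i, s in self.status.items() if s == "assigned"]

    def labels_for(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids])


# --------------------------------------------------------------------------
# pairwise correlation
# --------------------------------------------------------------------------

def _common_values(a: ReflectionSet, b: ReflectionSet) -> tuple[np.ndarray, np.ndarray]:
    """Amplitudes of the two sets at the intersection of their indices."""
    both = np.concatenate([encode_hkl(a.hkl), encode_hkl(b.hkl)])
    uniq, inverse = np.unique(both, return_inverse=True)
    ia = np.full(len(uniq), -1, dtype=np.int64)
    ib = np.full(len(uniq), -1, dtype=np.int64)
    ia[inverse[: len(a.hkl)]] = np.arange(len(a.hkl))
    ib[inverse[len(a.hkl):]] = np.arange(len(b.hkl))
    shared = (ia >= 0) & (ib >= 0)
    return a.amplitude[ia[shared]], b.amplitude[ib[shared]]


def pairwise_cc(
    a: ReflectionSet, b: ReflectionSet, cfg: ClusterConfig = ClusterConfig()
) -> tuple[float, int]:
    """Pearson CC of two ASU-merged sets over their common Miller indices.

    Returns ``(cc, n_common)``; ``cc`` is NaN when the overlap is below
    ``cfg.min_common`` (the pair is "insufficient overlap", not dissimilar).
    Scale-invariant: multiplying either set's amplitudes by a positive
    constant leaves the CC unchanged.
    """
    x, y = _common_values(a, b)
    n = len(x)
    if n < cfg.min_common:
        return math.nan, n
    if cfg.cc_on == "intensities":
        x, y = x * x, y * y
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"constant amplitudes in pair ({a.id}, {b.id})")
    cc = float(np.corrcoef(x, y)[0, 1])
    return cc, n


def cc_matrix(sets: Sequence[ReflectionSet], cfg: ClusterConfig = ClusterConfig()) -> CCMatrix:
    """All pairwise CCs, computed in one pass.

    Sets are aligned on the union of their Miller indices; sums needed by
    the Pearson formula restricted to each pairwise intersection are then
    obtained with masked matrix products, which keeps the cost at
    O(n² · n_reflections) flops instead of a Python loop over pairs.
    """
    n = len(sets)
    all_keys = np.concatenate([encode_hkl(s.hkl) for s in sets])
    uniq, inverse = np.unique(all_keys, return_inverse=True)
    m = len(uniq)
    X = np.zeros((n, m))
    W = np.zeros((n, m))
    pos = 0
    for i, s in enumerate(sets):
        rows = inverse[pos: pos + len(s.hkl)]
        vals = s.amplitude if cfg.cc_on == "amplitudes" else s.amplitude**2
        X[i, rows] = vals
        W[i, rows] = 1.0
        pos += len(s.hkl)
    n_common = (W @ W.T).astype(np.int64)
    sx = X @ W.T          # Σ xᵢ over the (i,j) intersection
    sxx = (X * X) @ W.T
    sxy = X @ X.T
    nc = n_common.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / nc
        varx = sxx - sx**2 / nc
        cc = cov / np.sqrt(varx * varx.T)
    cc[n_common < cfg.min_common] = np.nan
    np.fill_diagonal(cc, 1.0)
    cc = np.clip(cc, -1.0, 1.0, out=cc, where=~np.isnan(cc))
    return CCMatrix(ids=[s.id for s in sets], cc=cc, n_common=n_common)


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

def cc_distance(cc: float | np.ndarray) -> float | np.ndarray:
    """d = sqrt(1 - CC): 0 for perfect correlation, sqrt(2) at CC = -1."""
    cc_arr = np.asarray(cc, dtype=float)
    if np.any(np.abs(cc_arr) > 1.0 + CC_CLAMP_TOL):
        raise ValueError("correlation outside [-1, 1]")
    out = np.sqrt(1.0 - np.clip(cc_arr, -1.0, 1.0))
    return float(out) if np.isscalar(cc) or out.ndim == 0 else out


def penalized_distance(
    cc: float, n_common: int, n_a: int, n_b: int, cfg: ClusterConfig
) -> float:
    """Distance with a penalty for unmatched structure factors.

    The CC is down-weighted by the matched fraction w = 2·n_common/(n_a+n_b)
    inside the radical, d = sqrt(1 - cc·w), so incomplete overlap pushes
    pairs apart even when the shared amplitudes agree. Reduces to
    :func:`cc_distance` at w = 1.
    """
    if not cfg.use_penalty:
        raise ValueError("penalized_distance requires cfg.use_penalty")
    if abs(cc) > 1.0 + CC_CLAMP_TOL:
        raise ValueError("correlation outside [-1, 1]")
    if n_a <= 0 or n_b <= 0 or n_common < 0:
        raise ValueError("reflection counts must be positive")
    w = 2.0 * n_common / (n_a + n_b)
    return float(math.sqrt(1.0 - np.clip(cc, -1.0, 1.0) * w))


def distance_matrix_from_cc(
    ccm: CCMatrix, cfg: ClusterConfig, sizes: Sequence[int] | None = None
) -> np.ndarray:
    """Distance matrix for Ward linkage from a CCMatrix.

    NaN entries (insufficient overlap) are replaced by the maximum defined
    distance plus a small epsilon so the tree stays connected while such
    pairs merge last.
    """
    if cfg.use_penalty:
        if sizes is None:
            raise ValueError("penalty variant needs per-set reflection counts")
        sizes = np.asarray(sizes, dtype=float)
        w = 2.0 * ccm.n_common / (sizes[:, None] + sizes[None, :])
        d = np.sqrt(1.0 - np.clip(ccm.cc, -1.0, 1.0) * w)
    else:
        d = cc_distance(ccm.cc)
    nan_mask = np.isnan(d)
    if nan_mask.all():
        raise ValueError("no pair has sufficient overlap to define a distance")
    if nan_mask.any():
        dmax = np.nanmax(d)
        d[nan_mask] = dmax + 1e-6 * max(dmax, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


# --------------------------------------------------------------------------
# Ward agglomeration
# --------------------------------------------------------------------------

def ward_linkage(D: np.ndarray, ids: Sequence[str] | None = None) -> LinkageTree:
    """Ward minimum-variance agglomeration of a distance matrix.

    Implements the Lance-Williams recurrence with Ward coefficients on
    squared distances,

        d²(k, i∪j) = [(nᵢ+nₖ)d²(k,i) + (nⱼ+nₖ)d²(k,j) − nₖ d²(i,j)] / (nᵢ+nⱼ+nₖ),

    and reports each merge height as the square root, so heights live on the
    scale of the input distances (the same convention as standard reference
    implementations). At each step the globally closest active pair merges;
    exact ties break to the lexicographically smallest (i, j) node pair.
    Heights are non-decreasing (Ward admits no inversions).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError(
            "distance matrix contains NaN; gate sets on completeness/overlap first"
        )
    if not np.allclose(D, D.T, atol=1e-12, rtol=0):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length must match the matrix")
    if n < 1:
        raise ValueError("need at least one leaf")
    if n == 1:
        return LinkageTree(leaf_ids=ids, merges=[])

    D2 = D.astype(float) ** 2
    active = list(range(n))            # current cluster -> node number
    sizes = {i: 1 for i in range(n)}
    # work matrix indexed by position in `active`
    work = D2.copy()
    np.fill_diagonal(work, np.inf)
    merges: list[tuple[int, int, float, int]] = []
    next_node = n
    for _ in range(n - 1):
        k = len(active)
        # global minimum with lexicographic tie-break on node numbers
        flat = np.argmin(work[:k, :k])
        i, j = divmod(int(flat), k)
        best = work[i, j]
        # resolve ties deterministically by (node_i, node_j)
        ties = np.argwhere(work[:k, :k] <= best + 0.0)
        if len(ties) > 2:
            pairs = sorted(
                (min(active[p], active[q]), max(active[p], active[q]), p, q)
                for p, q in ties if p < q and work[p, q] == best
            )
            _, _, i, j = pairs[0]
        if i > j:
            i, j = j, i
        ni, nj = sizes[active[i]], sizes[active[j]]
        height = math.sqrt(max(best, 0.0))
        left, right = sorted((active[i], active[j]))
        merges.append((left, right, height, ni + nj))
        # Lance-Williams update of distances to the new cluster, stored in row/col i
        others = [p for p in range(k) if p not in (i, j)]
        if others:
            idx = np.array(others)
            nk = np.array([sizes[active[p]] for p in others], dtype=float)
            dki = work[idx, i]
            dkj = work[idx, j]
            new = ((ni + nk) * dki + (nj + nk) * dkj - nk * best) / (ni + nj + nk)
            work[idx, i] = new
            work[i, idx] = new
        sizes[next_node] = ni + nj
        active[i] = next_node
        next_node += 1
        # remove j by swapping in the last active cluster
        last = k - 1
        if j != last:
            work[j, :k] = work[last, :k]
            work[:k, j] = work[:k, last]
            work[j, j] = np.inf
            active[j] = active[last]
        active.pop()
    return LinkageTree(leaf_ids=ids, merges=merges)


def cut_tree(tree: LinkageTree, k: float) -> ClusterAssignment:
    """Cut a linkage tree at height k: clusters are the components left
    after removing every merge with height > k.

    k = 0 yields all singletons (any strictly positive merge is removed);
    k at or above the root height yields one cluster. Partitions at k₁ < k₂
    are nested refinements.
    """
    if k < 0:
        raise ValueError("cut height must be non-negative")
    keep = [m for m in tree.merges if m[2] <= k]
    return _assignment_from_merges(tree, keep, cut_height=k)


def cut_tree_n(tree: LinkageTree, n_clusters: int) -> ClusterAssignment:
    """Cut a linkage tree to a requested number of flat clusters."""
    n = tree.n_leaves
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must lie in [1, {n}]")
    keep = tree.merges[: n - n_clusters]
    height = keep[-1][2] if keep else 0.0
    return _assignment_from_merges(
        tree, keep, cut_height=height, n_clusters_requested=n_clusters
    )


def _assignment_from_merges(
    tree: LinkageTree,
    merges: list[tuple[int, int, float, int]],
    cut_height: float,
    n_clusters_requested: int | None = None,
) -> ClusterAssignment:
    n = tree.n_leaves
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for offset, (l, r, _, _) in enumerate(tree.merges):
        node = n + offset
        if (l, r) in {(m[0], m[1]) for m in merges}:
            parent[find(l)] = node
            parent[find(r)] = node
    labels: dict[str, int] = {}
    root_label: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in root_label:
            root_label[root] = len(root_label)
        labels[tree.leaf_ids[leaf]] = root_label[root]
    return ClusterAssignment(
        labels=labels,
        stage="fine",
        cut_height=cut_height,
        n_clusters_requested=n_clusters_requested,
    )


def cluster_count(tree: LinkageTree) -> int:
    """Number of merge nodes in the dendrogram: n − 1 for n leaves."""
    return len(tree.merges)


# --------------------------------------------------------------------------
# combined two-factor workflow
# --------------------------------------------------------------------------

def two_factor_cluster(
    sets: Sequence[ReflectionSet],
    cfg: ClusterConfig = ClusterConfig(),
    cell_cut: float | None = 2.0,
    amp_cut: float | None = None,
    n_coarse: int | None = None,
    n_fine: Mapping[int, int] | int | None = None,
    angle_weight: float = 0.25,
) -> tuple[ClusterAssignment, dict[int, LinkageTree]]:
    """Coarse cell clustering followed by fine CC clustering.

    Stage 1 partitions the crystals by unit-cell similarity (Ward on the
    weighted cell-parameter distance, cut at ``cell_cut`` Å or into
    ``n_coarse`` clusters). Stage 2, within each coarse cluster, gates sets
    on completeness, computes pairwise CC distances and cuts the Ward tree
    at ``amp_cut`` (default ``cfg.cut_height``) or into ``n_fine`` clusters
    (an int applied to every coarse cluster, or a per-coarse-cluster map).

    Returns the fine :class:`ClusterAssignment` (labels global across
    coarse clusters; gated-out sets labeled -1 with a reason) and the fine
    :class:`LinkageTree` per coarse cluster.
    """
    from .cell_cluster import coarse_partition  # deferred: avoids module cycle

    if len(sets) < 2:
        raise ValueError("need at least 2 data sets")
    coarse = coarse_partition(
        sets, cut_height=None if n_coarse else cell_cut,
        n_clusters=n_coarse, angle_weight=angle_weight,
    )
    by_coarse: dict[int, list[ReflectionSet]] = {}
    for s in sets:
        by_coarse.setdefault(coarse.labels[s.id], []).append(s)

    labels: dict[str, int] = {}
    status: dict[str, str] = {}
    coarse_of: dict[str, int] = {}
    trees: dict[int, LinkageTree] = {}
    next_label = 0
    for clabel in sorted(by_coarse):
        members = by_coarse[clabel]
        for s in members:
            coarse_of[s.id] = clabel
        if len(members) == 1:
            labels[members[0].id] = next_label
            status[members[0].id] = "assigned"
            next_label += 1
            continue
        admitted, excluded = [], []
        for s in members:
            comp = completeness(s)
            if comp >= cfg.min_completeness:
                admitted.append(s)
            else:
                excluded.append((s, comp))
        for s, comp in excluded:
            labels[s.id] = -1
            status[s.id] = f"unassigned:completeness {comp:.2f} < {cfg.min_completeness:.2f}"
        if not admitted:
            continue
        if len(admitted) == 1:
            labels[admitted[0].id] = next_label
            status[admitted[0].id] = "assigned"
            next_label += 1
            continue
        ccm = cc_matrix(admitted, cfg)
        D = distance_matrix_from_cc(
            ccm, cfg, sizes=[len(s) for s in admitted] if cfg.use_penalty else None
        )
        tree = ward_linkage(D, ids=[s.id for s in admitted])
        trees[clabel] = tree
        if n_fine is not None:
            want = n_fine[clabel] if isinstance(n_fine, Mapping) else int(n_fine)
            sub = cut_tree_n(tree, min(want, tree.n_leaves))
        else:
            sub = cut_tree(tree, cfg.cut_height if amp_cut is None else amp_cut)
        relabel: dict[int, int] = {}
        for sid, lab in sub.labels.items():
            if lab not in relabel:
                relabel[lab] = next_label
                next_label += 1
            labels[sid] = relabel[lab]
            status[sid] = "assigned"
    assignment = ClusterAssignment(
        labels=labels, stage="fine", cut_height=amp_cut, status=status, coarse_of=coarse_of
    )
    return assignment, trees
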