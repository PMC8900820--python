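"""Structural diagnostics for cluster-average models.

Once each cluster has been merged and refined into a model, the question is
whether the clusters are physically distinct states or noise. This module
provides the comparison layer: Cα extraction from PDB files, rigid
least-squares superposition, the per-residue maximum Cα displacement
profile (dot plot), minimum-volume enclosing ellipsoids of per-cluster Cα
clouds, and plot-ready exports of the cell scatter and colored dendrogram.

All operations return data structures; rendering (SVG/PNG via matplotlib)
is a thin layer on top so tests target numbers, not pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .amplitude_cluster import ClusterAssignment, LinkageTree
from .reflection_model import ReflectionSet

__all__ = [
    "CoordinateEnsemble",
    "Ellipsoid",
    "PdbParseError",
    "read_pdb_calpha",
    "load_ensemble",
    "superpose",
    "superpose_ensemble",
    "max_calpha_spread",
    "min_volume_ellipsoid",
    "cluster_ellipsoids",
    "cell_scatter_data",
    "dendrogram_export",
]


# --------------------------------------------------------------------------
# coordinate containers and PDB reading
# --------------------------------------------------------------------------

@dataclass
class CoordinateEnsemble:
    """Residue-indexed Cα traces for a set of structures.

    ``structures`` maps structure label -> {residue number -> xyz (Å)};
    ``cluster_of`` maps structure label -> cluster label. Residue numbering
    is assumed consistent across structures where present; gaps (e.g. an
    unresolved loop) are simply missing keys.
    """

    structures: dict[str, dict[int, np.ndarray]]
    cluster_of: dict[str, int | str] = field(default_factory=dict)

    def residues(self) -> list[int]:
        all_res: set[int] = set()
        for coords in self.structures.values():
            all_res.update(coords)
        return sorted(all_res)

    def labels(self) -> list[str]:
        return list(self.structures)

    def coords_at(self, residue: int) -> dict[str, np.ndarray]:
        return {
            label: c[residue]
            for label, c in self.structures.items()
            if residue in c
        }


class PdbParseError(ValueError):
    """Raised for malformed ATOM records; message carries the line number."""


def read_pdb_calpha(path: str | Path, chain: str | None = None) -> dict[int, np.ndarray]:
    """Extract one Cα coordinate per residue from PDB-format ATOM records.

    Fixed-column parsing of ATOM/HETATM lines per the wwPDB format. Where a
    residue has alternate locations, the highest-occupancy altloc wins,
    ties broken by altloc identifier order. Missing residues are simply
    absent from the result. Only the first model is read; ``chain``
    restricts to one chain identifier (default: all chains, later chains
    never overriding earlier ones for a duplicate residue number).
    """
    path = Path(path)
    best: dict[int, tuple[float, str, np.ndarray]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PdbParseError(f"{path}:{lineno}: ATOM record shorter than 54 columns")
            name = line[12:16].strip()
            if name != "CA":
                continue
            altloc = line[16]
            chain_id = line[21]
            if chain is not None and chain_id != chain:
                continue
            try:
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PdbParseError(f"{path}:{lineno}: malformed ATOM record ({exc})") from None
            occ_field = line[54:60].strip()
            try:
                occ = float(occ_field) if occ_field else 1.0
            except ValueError:
                raise PdbParseError(f"{path}:{lineno}: malformed occupancy {occ_field!r}") from None
            xyz = np.array([x, y, z])
            if resseq not in best:
                best[resseq] = (occ, altloc, xyz)
            else:
                old_occ, old_alt, _ = best[resseq]
                if occ > old_occ or (occ == old_occ and altloc < old_alt):
                    best[resseq] = (occ, altloc, xyz)
    return {res: xyz for res, (_, _, xyz) in sorted(best.items())}


def load_ensemble(
    paths: Mapping[str, str | Path],
    cluster_of: Mapping[str, int | str] | None = None,
    chain: str | None = None,
) -> CoordinateEnsemble:
    """Read several PDB files into one :class:`CoordinateEnsemble`."""
    structures = {label: read_pdb_calpha(p, chain=chain) for label, p in paths.items()}
    return CoordinateEnsemble(structures=structures, cluster_of=dict(cluster_of or {}))


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

def superpose(
    ref: Mapping[int, np.ndarray], mov: Mapping[int, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mov`` onto ``ref`` over shared
    residues (Kabsch algorithm).

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``R @ x + t`` maps mover coordinates onto the
    reference frame. Degenerate (e.g. collinear) point sets do not error:
    the SVD still yields one optimal — though not unique — transform.
    """
    shared = sorted(set(ref) & set(mov))
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared residues, got {len(shared)}")
    P = np.array([mov[r] for r in shared], dtype=float)
    Q = np.array([ref[r] for r in shared], dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def superpose_ensemble(ens: CoordinateEnsemble, ref_label: str | None = None) -> CoordinateEnsemble:
    """Superpose every structure onto a reference (default: the first)."""
    labels = ens.labels()
    if not labels:
        raise ValueError("empty ensemble")
    ref_label = ref_label or labels[0]
    ref = ens.structures[ref_label]
    out: dict[str, dict[int, np.ndarray]] = {}
    for label in labels:
        if label == ref_label:
            out[label] = {r: np.array(x) for r, x in ref.items()}
            continue
        R, t, _ = superpose(ref, ens.structures[label])
        out[label] = {r: R @ x + t for r, x in ens.structures[label].items()}
    return CoordinateEnsemble(structures=out, cluster_of=dict(ens.cluster_of))


# --------------------------------------------------------------------------
# per-residue spread
# --------------------------------------------------------------------------

def max_calpha_spread(
    ens: CoordinateEnsemble, superpose_first: bool = False
) -> dict[int, float]:
    """Largest pairwise Cα distance per residue across the ensemble.

    For every residue present in at least two structures, the maximum
    Euclidean distance between any two structures' Cα positions — the
    "largest value per amino acid" dot-plot profile. Structures are assumed
    pre-superposed unless ``superpose_first`` is set.
    """
    if len(ens.structures) < 2:
        raise ValueError("spread needs at least 2 structures")
    if superpose_first:
        ens = superpose_ensemble(ens)
    out: dict[int, float] = {}
    for res in ens.residues():
        pts = list(ens.coords_at(res).values())
        if len(pts) < 2:
            continue
        arr = np.array(pts)
        diff = arr[:, None, :] - arr[None, :, :]
        out[res] = float(np.sqrt((diff**2).sum(axis=-1)).max())
    return out


# --------------------------------------------------------------------------
# minimum-volume enclosing ellipsoid
# --------------------------------------------------------------------------

@dataclass
class Ellipsoid:
    """Ellipsoid {p : (p-center)ᵀ A (p-center) ≤ 1} with A symmetric PSD."""

    center: np.ndarray
    shape: np.ndarray  # the matrix A, units Å⁻²

    @property
    def volume(self) -> float:
        det = np.linalg.det(self.shape)
        if det <= 0:
            return math.inf
        return float(4.0 * math.pi / 3.0 / math.sqrt(det))

    def radii(self) -> np.ndarray:
        """Semi-axis lengths (Å), descending."""
        evals = np.linalg.eigvalsh(self.shape)
        return np.sort(1.0 / np.sqrt(np.clip(evals, 1e-300, None)))[::-1]

    def mean_radius(self) -> float:
        """Geometric mean semi-axis, (abc)^(1/3)."""
        return float(np.exp(np.mean(np.log(self.radii()))))

    def contains(self, p: np.ndarray, tol: float = 1e-6) -> bool:
        v = np.asarray(p, dtype=float) - self.center
        return float(v @ self.shape @ v) <= 1.0 + tol

    def to_dict(self) -> dict:
        return {
            "center": [float(x) for x in self.center],
            "shape": [[float(x) for x in row] for row in self.shape],
            "volume": self.volume,
        }


#: regularisation added to rank-deficient scatter matrices (Å² scale)
MVE_EPSILON = 1e-4


def min_volume_ellipsoid(
    points: Sequence[Sequence[float]] | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 20000,
) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid of a 3D point cloud.

    Khachiyan-style barycentric-coordinate ascent with Wolfe–Atwood away
    steps: weights u on the points are pushed toward the point farthest
    outside the current trial ellipsoid, or pulled away from an over-
    weighted interior support point, until the relative violation falls
    below ``tol``; the away steps make convergence linear rather than
    sublinear. All points end up inside to within membership 1 + O(tol).
    Rank-deficient clouds (a single point, collinear or coplanar sets) are
    regularised by adding ε·I to the scatter matrix so a drawable ellipsoid
    always results.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(P)
    if n == 0:
        raise ValueError("cannot enclose an empty point set")
    mean = P.mean(axis=0)
    centered = P - mean
    # affine rank decides the working dimension; flat directions get the
    # epsilon regularisation only
    U_svd, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    scale = svals[0] if svals.size and svals[0] > 0 else 0.0
    rank = int(np.sum(svals > max(scale, 1.0) * 1e-9))
    if rank == 0:
        return Ellipsoid(center=mean.copy(), shape=np.eye(3) / (3.0 * MVE_EPSILON))
    V = Vt[:rank].T                      # (3, rank) orthonormal basis
    W = centered @ V                     # points in the affine subspace
    u = _khachiyan_weights(W, tol=tol, max_iter=max_iter)
    center_sub = W.T @ u
    scatter_sub = W.T @ (u[:, None] * W) - np.outer(center_sub, center_sub)
    # lift back to 3D and add eps*I so flat directions stay invertible
    scatter = V @ scatter_sub @ V.T + MVE_EPSILON * (np.eye(3) - V @ V.T)
    shape = np.linalg.inv(scatter) / rank
    shape = 0.5 * (shape + shape.T)
    return Ellipsoid(center=mean + V @ center_sub, shape=shape)


def _khachiyan_weights(P: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Optimal barycentric weights u for the MVE of full-rank points P (n,d)."""
    n, d = P.shape
    dp1 = d + 1
    Q = np.column_stack([P, np.ones(n)])
    u = np.full(n, 1.0 / n)

    def _inv(X: np.ndarray) -> np.ndarray:
        try:
            return np.linalg.inv(X)
        except np.linalg.LinAlgError:
            return np.linalg.inv(X + 1e-12 * np.trace(X) / dp1 * np.eye(dp1))

    Xinv = _inv(Q.T @ (u[:, None] * Q))
    for it in range(max_iter):
        M = np.einsum("ni,ij,nj->n", Q, Xinv, Q)
        j_plus = int(np.argmax(M))
        eps_plus = M[j_plus] / dp1 - 1.0
        m_masked = np.where(u > 0, M, np.inf)
        j_minus = int(np.argmin(m_masked))
        eps_minus = 1.0 - M[j_minus] / dp1
        if max(eps_plus, eps_minus) <= tol:
            break
        # away step only when it is the larger violation AND well defined
        if eps_minus > eps_plus and M[j_minus] > 1.0 + 1e-12:
            j, mj = j_minus, M[j_minus]
            lam = (mj - dp1) / (dp1 * (mj - 1.0))  # negative: away step
            if u[j] < 1.0:
                lam = max(lam, -u[j] / (1.0 - u[j]))
        else:
            j, mj = j_plus, M[j_plus]
            if eps_plus <= 0.0:  # ascent cannot proceed further
                break
            lam = (mj - dp1) / (dp1 * (mj - 1.0))
        # u <- (1 - lam) u + lam e_j ; rank-1 Sherman-Morrison update of Xinv
        u *= 1.0 - lam
        u[j] += lam
        u = np.clip(u, 0.0, None)
        if it % 50 == 49:
            Xinv = _inv(Q.T @ (u[:, None] * Q))  # periodic refresh for stability
        else:
            q = Q[j]
            Xq = Xinv @ q
            denom = 1.0 + (lam / (1.0 - lam)) * mj
            Xinv = (Xinv - (lam / ((1.0 - lam) * denom)) * np.outer(Xq, Xq)) / (1.0 - lam)
    return u / u.sum()


def cluster_ellipsoids(
    ens: CoordinateEnsemble, residue: int, tol: float = 1e-6
) -> dict[int | str, Ellipsoid]:
    """Per-cluster minimum-volume ellipsoid of the Cα positions at one
    residue — the color-coded ellipsoid diagnostic.

    Small, well-separated ellipsoids relative to the spacing of their
    centers indicate that the clusters are genuinely distinct states.
    """
    by_cluster: dict[int | str, list[np.ndarray]] = {}
    for label, xyz in ens.coords_at(residue).items():
        cl = ens.cluster_of.get(label, 0)
        by_cluster.setdefault(cl, []).append(xyz)
    if not by_cluster:
        raise ValueError(f"no structure resolves residue {residue}")
    return {
        cl: min_volume_ellipsoid(np.array(pts), tol=tol)
        for cl, pts in sorted(by_cluster.items(), key=lambda kv: str(kv[0]))
    }


# --------------------------------------------------------------------------
# plot-ready exports
# --------------------------------------------------------------------------

def cell_scatter_data(
    sets: Sequence[ReflectionSet], assignment: ClusterAssignment
):
    """Rows (id, a, c, coarse, fine) for the cell-parameter scatter.

    Returns a pandas DataFrame with one row per data set; the plotting
    layer assigns a stable color per fine cluster.
    """
    import pandas as pd

    if not assignment.labels:
        raise ValueError("empty cluster assignment")
    missing = [s.id for s in sets if s.id not in assignment.labels]
    if missing:
        raise ValueError(f"assignment does not cover sets: {missing[:5]}")
    rows = [
        {
            "id": s.id,
            "a": s.cell.a,
            "c": s.cell.c,
            "coarse": assignment.coarse_of.get(s.id, 0),
            "fine": assignment.labels[s.id],
        }
        for s in sets
    ]
    return pd.DataFrame(rows)


def dendrogram_export(tree: LinkageTree, assignment: ClusterAssignment) -> dict:
    """Plot-ready dendrogram: leaf order, junction coordinates, leaf colors.

    Leaves are ordered by tree traversal (scipy convention), each leaf
    carries its fine-cluster label as the color key, and junction heights
    equal the linkage heights. Returns a dict with keys ``leaves``
    (ordered ids), ``leaf_clusters``, ``icoord``/``dcoord`` (segment
    geometry, leaf axis in units of 5 per leaf), and ``heights``.
    """
    from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

    if tree.n_leaves == 1:
        return {
            "leaves": list(tree.leaf_ids),
            "leaf_clusters": [assignment.labels.get(tree.leaf_ids[0], 0)],
            "icoord": [],
            "dcoord": [],
            "heights": [],
        }
    Z = tree.to_scipy()
    info = _scipy_dendrogram(Z, no_plot=True)
    leaves = [tree.leaf_ids[i] for i in info["leaves"]]
    return {
        "leaves": leaves,
        "leaf_clusters": [assignment.labels.get(l, -1) for l in leaves],
        "icoord": info["icoord"],
        "dcoord": info["dcoord"],
        "heights": [m[2] for m in tree.merges],
    }
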