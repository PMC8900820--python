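"""Coarse clustering of crystals by unit-cell similarity.

Unit-cell parameters respond to changes in the outer shape of the molecule
and its packing, and are available from indexing alone — long before
amplitudes are reliable — so they make a natural first, coarse partition of
a multi-crystal data collection. The metric here is a weighted Euclidean
distance on (a, b, c, α, β, γ) with angles converted to Å-equivalents by a
configurable weight; clustering is Ward linkage on that matrix, shared with
the fine stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .amplitude_cluster import (
    ClusterAssignment,
    LinkageTree,
    cut_tree,
    cut_tree_n,
    ward_linkage,
)
from .reflection_model import ReflectionSet, UnitCell

__all__ = [
    "CellDistanceMatrix",
    "cell_distance",
    "cell_distance_matrix",
    "coarse_partition",
    "DEFAULT_ANGLE_WEIGHT",
]

#: Å per degree; 0.25 makes a 4° angle difference count like 1 Å of edge.
DEFAULT_ANGLE_WEIGHT = 0.25


@dataclass
class CellDistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("cell distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("cell distances must be finite with zero diagonal")


def cell_distance(
    c1: UnitCell, c2: UnitCell, angle_weight: float = DEFAULT_ANGLE_WEIGHT
) -> float:
    """Weighted Euclidean distance between two unit cells, in Å.

    The 6-vector (Δa, Δb, Δc, w·Δα, w·Δβ, w·Δγ) is measured with the
    Euclidean norm; ``angle_weight`` w (Å/degree) puts angle differences on
    the length scale. Zero iff the parameters are identical. Cells are
    assumed consistently indexed — no Niggli/lattice-character reduction is
    attempted.
    """
    if angle_weight < 0:
        raise ValueError("angle_weight must be non-negative")
    p1 = np.array(c1.parameters())
    p2 = np.array(c2.parameters())
    delta = p1 - p2
    delta[3:] *= angle_weight
    return float(np.linalg.norm(delta))


def cell_distance_matrix(
    sets: Sequence[ReflectionSet], angle_weight: float = DEFAULT_ANGLE_WEIGHT
) -> CellDistanceMatrix:
    """Pairwise cell distances for a list of data sets."""
    if angle_weight < 0:
        raise ValueError("angle_weight must be non-negative")
    params = np.array([s.cell.parameters() for s in sets], dtype=float)
    params[:, 3:] *= angle_weight
    diff = params[:, None, :] - params[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry despite floating-point noise
    return CellDistanceMatrix(ids=[s.id for s in sets], d=d)


def coarse_partition(
    sets: Sequence[ReflectionSet],
    cut_height: float | None = None,
    n_clusters: int | None = None,
    angle_weight: float = DEFAULT_ANGLE_WEIGHT,
) -> ClusterAssignment:
    """Stage-1 partition of data sets by unit-cell similarity.

    Ward linkage on the weighted cell distance matrix, cut either at
    ``cut_height`` (Å) or into ``n_clusters`` flat clusters (exactly one of
    the two must be given). Cluster labels are stable under input
    reordering up to renaming.
    """
    if len(sets) < 2:
        raise ValueError("coarse clustering needs at least 2 data sets")
    if (cut_height is None) == (n_clusters is None):
        raise ValueError("specify exactly one of cut_height or n_clusters")
    cdm = cell_distance_matrix(sets, angle_weight=angle_weight)
    tree = ward_linkage(cdm.d, ids=cdm.ids)
    if n_clusters is not None:
        assignment = cut_tree_n(tree, n_clusters)
    else:
        assignment = cut_tree(tree, cut_height)
    assignment.stage = "coarse"
    return assignment


def coarse_linkage(
    sets: Sequence[ReflectionSet], angle_weight: float = DEFAULT_ANGLE_WEIGHT
) -> LinkageTree:
    """The full cell-distance Ward tree (for dendrogram export)."""
    cdm = cell_distance_matrix(sets, angle_weight=angle_weight)
    return ward_linkage(cdm.d, ids=cdm.ids)
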