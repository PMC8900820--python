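"""Merging structure factors across the data sets of a cluster.

Each flat cluster from the two-factor workflow is turned into a single
averaged reflection set — the data from which a cluster-average structure
would be refined — together with the usual merging statistics: R_merge,
completeness, multiplicity and mean signal-to-noise.

Scaling: independently measured crystals sit on arbitrary overall scales,
so an optional alternating-least-squares step fits one positive factor per
set (normalised to geometric mean 1) before averaging.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .reflection_model import (
    LaueGroup,
    ReflectionSet,
    UnitCell,
    asu_keys,
    completeness,
    decode_hkl,
)

__all__ = ["MergeReport", "scale_sets", "merge_cluster", "r_merge"]


@dataclass
class MergeReport:
    """Merging statistics for one cluster."""

    cluster_id: str
    n_sets: int
    n_unique: int
    n_observations: int
    completeness: float
    r_merge: float | None       # None for a single set (no redundancy)
    mean_multiplicity: float
    mean_f_over_sigma: float
    scales: list[float] | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def table(self) -> str:
        rows = [
            ("cluster", self.cluster_id),
            ("data sets", str(self.n_sets)),
            ("unique reflections", str(self.n_unique)),
            ("observations", str(self.n_observations)),
            ("completeness", f"{self.completeness:.3f}"),
            ("R_merge", "n/a" if self.r_merge is None else f"{self.r_merge:.4f}"),
            ("multiplicity", f"{self.mean_multiplicity:.2f}"),
            ("<F/sigF>", f"{self.mean_f_over_sigma:.2f}"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def _stacked_observations(
    sets: Sequence[ReflectionSet],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate all sets on shared ASU indexing.

    Returns (unique_hkl, obs_row, set_of_obs, F, sigF) where ``obs_row``
    maps each observation to its row in ``unique_hkl``.
    """
    all_keys = np.concatenate([asu_keys(s.hkl, s.laue) for s in sets])
    keys, inverse = np.unique(all_keys, return_inverse=True)
    uniq = decode_hkl(keys)
    set_of = np.concatenate([np.full(len(s.hkl), i) for i, s in enumerate(sets)])
    f = np.concatenate([s.amplitude for s in sets])
    sig = np.concatenate([s.sigma for s in sets])
    return uniq, inverse, set_of, f, sig


def scale_sets(
    sets: Sequence[ReflectionSet], tol: float = 1e-8, max_iter: int = 20
) -> np.ndarray:
    """Fit one positive multiplicative scale per set by alternating least
    squares.

    Alternates k_j = argmin Σᵢ (F_ij − k_j·⟨F⟩ᵢ)² with re-averaging of the
    scaled amplitudes until the largest relative change in any scale falls
    below ``tol`` (or ``max_iter`` sweeps). Scales are normalised to
    geometric mean 1, so the overall scale of the cluster is untouched.
    """
    if len(sets) < 2:
        raise ValueError("scaling needs at least 2 data sets")
    uniq, rows, set_of, f, _ = _stacked_observations(sets)
    n_sets = len(sets)
    # every set must share at least one index with another set
    counts = np.bincount(rows, minlength=len(uniq))
    for j, s in enumerate(sets):
        shared = counts[rows[set_of == j]] > 1
        if not shared.any():
            raise ValueError(f"set {s.id!r} shares no reflections with the others")
    k = np.ones(n_sets)
    for _ in range(max_iter):
        # mean of scaled amplitudes per unique index
        mean = np.bincount(rows, weights=f / k[set_of], minlength=len(uniq)) / counts
        m_obs = mean[rows]
        num = np.bincount(set_of, weights=f * m_obs, minlength=n_sets)
        den = np.bincount(set_of, weights=m_obs * m_obs, minlength=n_sets)
        new_k = num / den
        new_k /= np.exp(np.mean(np.log(new_k)))
        delta = np.max(np.abs(new_k - k) / np.abs(k))
        k = new_k
        if delta < tol:
            break
    return k


def r_merge(sets: Sequence[ReflectionSet], scales: np.ndarray | None = None) -> float:
    """R_merge = Σ_hkl Σ_j |F_j − ⟨F⟩| / Σ_hkl Σ_j F_j over multiply-observed
    unique indices, with the conventional unweighted mean ⟨F⟩.

    Invariant to a common positive rescaling of all sets; per-set ``scales``
    (as from :func:`scale_sets`) are divided out first when given.
    """
    uniq, rows, set_of, f, _ = _stacked_observations(sets)
    if scales is not None:
        f = f / np.asarray(scales, dtype=float)[set_of]
    counts = np.bincount(rows, minlength=len(uniq))
    multi = counts > 1
    if not multi.any():
        raise ValueError("no redundancy: no index observed more than once")
    mean = np.bincount(rows, weights=f, minlength=len(uniq)) / counts
    sel = multi[rows]
    num = np.sum(np.abs(f[sel] - mean[rows][sel]))
    den = np.sum(f[sel])
    return float(num / den)


def merge_cluster(
    sets: Sequence[ReflectionSet],
    cluster_id: str | None = None,
    apply_scaling: bool = False,
) -> tuple[ReflectionSet, MergeReport]:
    """Average the structure factors of a cluster into one reflection set.

    Per unique ASU index the merged amplitude is the inverse-variance-
    weighted mean of the (optionally scaled) member amplitudes, with sigma
    1/sqrt(Σ 1/σ²). The merged cell is the unweighted mean of the member
    cells; the resolution range spans the members. R_merge in the report
    uses the conventional unweighted mean (see :func:`r_merge`) — a
    deliberate asymmetry with the weighted merged output.
    """
    if len(sets) == 0:
        raise ValueError("cannot merge an empty cluster")
    laue_names = {s.laue.name for s in sets}
    if len(laue_names) > 1:
        raise ValueError(f"incompatible Laue groups in cluster: {sorted(laue_names)}")
    cluster_id = cluster_id or f"merge-of-{len(sets)}"

    scales = None
    if apply_scaling and len(sets) > 1:
        scales = scale_sets(sets)

    uniq, rows, set_of, f, sig = _stacked_observations(sets)
    if scales is not None:
        f = f / scales[set_of]
        sig = sig / scales[set_of]
    w = 1.0 / sig**2
    sw = np.bincount(rows, weights=w, minlength=len(uniq))
    swf = np.bincount(rows, weights=w * f, minlength=len(uniq))
    merged_f = swf / sw
    merged_sigma = 1.0 / np.sqrt(sw)

    cells = np.array([s.cell.parameters() for s in sets])
    mean_cell = UnitCell(*np.mean(cells, axis=0))
    dmin = min(s.dmin for s in sets)
    dmax = max(s.dmax for s in sets)
    merged = ReflectionSet(
        id=cluster_id,
        cell=mean_cell,
        laue=LaueGroup.from_name(next(iter(laue_names))),
        hkl=uniq,
        amplitude=merged_f,
        sigma=merged_sigma,
        dmin=dmin,
        dmax=dmax,
    )
    counts = np.bincount(rows, minlength=len(uniq))
    rm: float | None
    if len(sets) == 1 or not (counts > 1).any():
        rm = None
    else:
        rm = r_merge(sets, scales=scales)
    report = MergeReport(
        cluster_id=cluster_id,
        n_sets=len(sets),
        n_unique=len(uniq),
        n_observations=int(counts.sum()),
        completeness=completeness(merged),
        r_merge=rm,
        mean_multiplicity=float(counts.mean()),
        mean_f_over_sigma=float(np.mean(merged_f / merged_sigma)),
        scales=None if scales is None else [float(x) for x in scales],
    )
    return merged, report
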