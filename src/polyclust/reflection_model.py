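"""Reflection data model: unit cells, Laue symmetry, d-spacings, completeness, HKL I/O.

A :class:`ReflectionSet` holds one crystal's unique structure-factor
amplitudes together with its unit cell, Laue group and resolution range.
Symmetry-equivalent observations are reduced to a single representative per
reciprocal-space asymmetric unit (ASU) before any between-crystal comparison.

Columnar storage (one ``(n, 3)`` integer array of Miller indices plus float
arrays for F and sigma) keeps per-set operations vectorised; the scalar
:class:`Reflection` view exists for convenience and tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "MillerIndex",
    "LaueGroup",
    "Reflection",
    "ReflectionSet",
    "HklParseError",
    "map_to_asu",
    "map_to_asu_array",
    "asu_keys",
    "encode_hkl",
    "decode_hkl",
    "merge_equivalents",
    "d_spacing",
    "d_spacing_array",
    "completeness",
    "enumerate_asu_indices",
    "read_hkl",
    "write_hkl",
    "amplitudes_from_intensities",
]

#: Relative tolerance for resolution-range membership checks.
RESOLUTION_RTOL = 1e-6


# --------------------------------------------------------------------------
# unit cell
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: edge lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180) degrees")
        # reciprocal metric must be positive definite; equivalently the
        # direct metric tensor must be, which fails e.g. for alpha+beta+gamma
        # combinations that cannot close a parallelepiped
        g = self.metric_tensor()
        if np.linalg.det(g) <= 0:
            raise ValueError("unit-cell angles do not define a valid lattice")

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, Å²)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal-space metric tensor G* = G⁻¹ (Å⁻²)."""
        return np.linalg.inv(self.metric_tensor())

    def volume(self) -> float:
        """Cell volume in Å³."""
        return float(math.sqrt(np.linalg.det(self.metric_tensor())))

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


# --------------------------------------------------------------------------
# Miller indices and Laue symmetry
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class MillerIndex:
    h: int
    k: int
    l: int  # noqa: E741 - crystallographic convention

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)

    def is_zero(self) -> bool:
        return self.h == 0 and self.k == 0 and self.l == 0


def _close_group(generators: Sequence[np.ndarray]) -> tuple[np.ndarray, ...]:
    """Close a set of 3x3 integer matrices under multiplication."""
    eye = np.eye(3, dtype=int)
    seen: dict[bytes, np.ndarray] = {eye.tobytes(): eye}
    frontier = [eye] + [np.asarray(g, dtype=int) for g in generators]
    for g in frontier:
        seen.setdefault(g.tobytes(), g)
    changed = True
    while changed:
        changed = False
        mats = list(seen.values())
        for g1 in mats:
            for g2 in mats:
                p = g1 @ g2
                key = p.tobytes()
                if key not in seen:
                    seen[key] = p
                    changed = True
    return tuple(seen.values())


_INV = -np.eye(3, dtype=int)
_TWO_FOLD_B = np.diag([-1, 1, -1])
_TWO_FOLD_A = np.diag([1, -1, -1])
_TWO_FOLD_C = np.diag([-1, -1, 1])
_FOUR_FOLD_C = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])

_LAUE_GENERATORS: dict[str, list[np.ndarray]] = {
    "-1": [_INV],
    "2/m": [_INV, _TWO_FOLD_B],
    "mmm": [_INV, _TWO_FOLD_A, _TWO_FOLD_C],
    "4/mmm": [_INV, _FOUR_FOLD_C, _TWO_FOLD_A],
}

#: accepted spellings, including the long Hermann-Mauguin form
_LAUE_ALIASES = {
    "4/m 2/m 2/m": "4/mmm",
    "4/m2/m2/m": "4/mmm",
    "2/m 2/m 2/m": "mmm",
    "p-1": "-1",
}


@dataclass(frozen=True)
class LaueGroup:
    """A Laue point group as an explicit finite set of integer matrices.

    Only the groups observed for tetragonal/orthorhombic/monoclinic protein
    crystals are built in (-1, 2/m, mmm, 4/mmm); each contains the inversion,
    so Friedel mates are always equivalent.
    """

    name: str
    ops: tuple[np.ndarray, ...] = field(repr=False, compare=False, default=())

    @classmethod
    def from_name(cls, name: str) -> "LaueGroup":
        canonical = _LAUE_ALIASES.get(name.strip().lower(), name.strip())
        if canonical not in _LAUE_GENERATORS:
            raise ValueError(
                f"unsupported Laue group {name!r}; supported: "
                + ", ".join(sorted(_LAUE_GENERATORS))
            )
        ops = _close_group(_LAUE_GENERATORS[canonical])
        return cls(name=canonical, ops=ops)

    @property
    def order(self) -> int:
        return len(self.ops)

    def ops_array(self) -> np.ndarray:
        """All operations stacked as an (n_ops, 3, 3) integer array."""
        return np.stack(self.ops)


def map_to_asu(index: MillerIndex, laue: LaueGroup) -> MillerIndex:
    """Map a Miller index to its asymmetric-unit representative.

    The representative is the lexicographically greatest member of the
    symmetry orbit {R·(h,k,l)} — a deterministic, group-agnostic convention
    (Friedel inversion is part of every Laue group, so ±(h,k,l) share one
    representative). Idempotent; (0,0,0) is a fixed point of every group.
    """
    hkl = np.array(index.as_tuple())
    orbit = laue.ops_array() @ hkl
    best = max(map(tuple, orbit))
    return MillerIndex(*(int(x) for x in best))


#: packed-key field size; supports |h|,|k|,|l| < 2048
_KEY_HALF = 2048
_KEY_BASE = 2 * _KEY_HALF


def encode_hkl(hkl: np.ndarray) -> np.ndarray:
    """Pack (n,3) Miller indices into order-preserving int64 keys.

    Numeric order on the key equals lexicographic order on (h, k, l), which
    makes unique/intersection/representative operations cheap 1-D work.
    """
    hkl = np.asarray(hkl, dtype=np.int64)
    if hkl.size and np.abs(hkl).max() >= _KEY_HALF:
        raise ValueError(f"Miller index magnitude exceeds {_KEY_HALF - 1}")
    return (
        (hkl[..., 0] + _KEY_HALF) * _KEY_BASE + (hkl[..., 1] + _KEY_HALF)
    ) * _KEY_BASE + (hkl[..., 2] + _KEY_HALF)


def decode_hkl(keys: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_hkl`."""
    keys = np.asarray(keys, dtype=np.int64)
    l = keys % _KEY_BASE - _KEY_HALF
    rest = keys // _KEY_BASE
    k = rest % _KEY_BASE - _KEY_HALF
    h = rest // _KEY_BASE - _KEY_HALF
    return np.stack([h, k, l], axis=-1)


_OPS_FLOAT_CACHE: dict[str, np.ndarray] = {}


def _ops_stacked(laue: LaueGroup) -> np.ndarray:
    """All ops transposed and stacked as one (3, 3*n_ops) float matrix.

    Lets the whole orbit of many indices be computed as a single BLAS
    matmul; exact because index magnitudes stay far below 2**53.
    """
    mat = _OPS_FLOAT_CACHE.get(laue.name)
    if mat is None or mat.shape[1] != 3 * laue.order:
        mat = np.concatenate([op.T.astype(float) for op in laue.ops], axis=1)
        _OPS_FLOAT_CACHE[laue.name] = mat
    return mat


def _orbit_key_max(hkl: np.ndarray, laue: LaueGroup) -> tuple[np.ndarray, np.ndarray]:
    """(max packed key per orbit, full orbit array (n, n_ops, 3))."""
    hkl = np.asarray(hkl, dtype=np.int64)
    if hkl.size and np.abs(hkl).max() >= _KEY_HALF:
        raise ValueError(f"Miller index magnitude exceeds {_KEY_HALF - 1}")
    orbit = (hkl.astype(float) @ _ops_stacked(laue)).reshape(len(hkl), laue.order, 3)
    keys = (
        (orbit[..., 0] + _KEY_HALF) * _KEY_BASE + (orbit[..., 1] + _KEY_HALF)
    ) * _KEY_BASE + (orbit[..., 2] + _KEY_HALF)
    return keys.max(axis=1).astype(np.int64), orbit


def map_to_asu_array(hkl: np.ndarray, laue: LaueGroup) -> np.ndarray:
    """Vectorised ASU mapping for an (n, 3) integer index array."""
    hkl = np.asarray(hkl, dtype=np.int64)
    if hkl.size == 0:
        return hkl.reshape(0, 3)
    keys, _ = _orbit_key_max(hkl, laue)
    return decode_hkl(keys)


def asu_keys(hkl: np.ndarray, laue: LaueGroup) -> np.ndarray:
    """Packed keys of the ASU representatives of each index."""
    hkl = np.asarray(hkl, dtype=np.int64)
    if hkl.size == 0:
        return np.empty(0, dtype=np.int64)
    keys, _ = _orbit_key_max(hkl, laue)
    return keys


# --------------------------------------------------------------------------
# reflections
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Reflection:
    """One unique reflection: Miller index, amplitude |F| and its sigma."""

    index: MillerIndex
    amplitude: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not math.isfinite(self.amplitude) or self.amplitude < 0:
            raise ValueError("amplitude must be finite and non-negative")


class ReflectionSet:
    """One crystal's reflection data.

    Parameters
    ----------
    id : str
        Data-set label.
    cell : UnitCell
    laue : LaueGroup
    hkl : (n, 3) int array of Miller indices.
    amplitude, sigma : (n,) float arrays, sigma > 0.
    dmin, dmax : resolution limits in Å (dmin = high-resolution limit).
    """

    def __init__(
        self,
        id: str,
        cell: UnitCell,
        laue: LaueGroup,
        hkl: np.ndarray,
        amplitude: np.ndarray,
        sigma: np.ndarray,
        dmin: float,
        dmax: float,
    ) -> None:
        hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
        amplitude = np.asarray(amplitude, dtype=float).ravel()
        sigma = np.asarray(sigma, dtype=float).ravel()
        if not (len(hkl) == len(amplitude) == len(sigma)):
            raise ValueError("hkl, amplitude and sigma must have equal length")
        if np.any(sigma <= 0):
            raise ValueError("all sigmas must be positive")
        if np.any(~np.isfinite(amplitude)):
            raise ValueError("amplitudes must be finite")
        if np.any(np.all(hkl == 0, axis=1)):
            raise ValueError("(0,0,0) is not an observable reflection")
        if not 0 < dmin < dmax:
            raise ValueError("require 0 < dmin < dmax")
        self.id = id
        self.cell = cell
        self.laue = laue
        self.hkl = hkl
        self.amplitude = amplitude
        self.sigma = sigma
        self.dmin = float(dmin)
        self.dmax = float(dmax)

    def __len__(self) -> int:
        return len(self.hkl)

    def __iter__(self) -> Iterator[Reflection]:
        for (h, k, l), f, s in zip(self.hkl, self.amplitude, self.sigma):
            yield Reflection(MillerIndex(int(h), int(k), int(l)), float(f), float(s))

    def __repr__(self) -> str:
        return (
            f"ReflectionSet(id={self.id!r}, n={len(self)}, laue={self.laue.name!r}, "
            f"cell=({self.cell.a:.2f}, {self.cell.b:.2f}, {self.cell.c:.2f}), "
            f"resolution={self.dmax:.2f}-{self.dmin:.2f} Å)"
        )

    def d_spacings(self) -> np.ndarray:
        return d_spacing_array(self.cell, self.hkl)

    def copy_with(self, **kwargs) -> "ReflectionSet":
        args = dict(
            id=self.id, cell=self.cell, laue=self.laue, hkl=self.hkl,
            amplitude=self.amplitude, sigma=self.sigma, dmin=self.dmin, dmax=self.dmax,
        )
        args.update(kwargs)
        return ReflectionSet(**args)

    def amplitude_map(self) -> dict[tuple[int, int, int], float]:
        return {tuple(map(int, idx)): float(f) for idx, f in zip(self.hkl, self.amplitude)}


# --------------------------------------------------------------------------
# d-spacing
# --------------------------------------------------------------------------

def d_spacing(cell: UnitCell, index: MillerIndex) -> float:
    """Lattice-plane spacing d(hkl) in Å via the reciprocal metric tensor.

    1/d² = hᵀ G* h. For a tetragonal cell this reduces to
    (h²+k²)/a² + l²/c².
    """
    if index.is_zero():
        raise ValueError("undefined d-spacing for (0,0,0)")
    return float(d_spacing_array(cell, np.array([index.as_tuple()]))[0])


def d_spacing_array(cell: UnitCell, hkl: np.ndarray) -> np.ndarray:
    """Vectorised d-spacings for an (n, 3) index array."""
    hkl = np.asarray(hkl, dtype=float).reshape(-1, 3)
    gstar = cell.reciprocal_metric_tensor()
    inv_d2 = np.einsum("ni,ij,nj->n", hkl, gstar, hkl)
    with np.errstate(divide="ignore"):
        return 1.0 / np.sqrt(inv_d2)


# --------------------------------------------------------------------------
# ASU merging and completeness
# --------------------------------------------------------------------------

def _group_rows(hkl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique rows of an (n,3) int array plus the inverse map."""
    keys, inverse = np.unique(encode_hkl(hkl), return_inverse=True)
    return decode_hkl(keys), inverse


def merge_equivalents(rs: ReflectionSet) -> ReflectionSet:
    """Reduce a set to one reflection per ASU orbit.

    Amplitudes are combined by the inverse-variance-weighted mean; the merged
    sigma is the propagated uncertainty of that mean, 1/sqrt(Σ 1/σᵢ²). Total
    Fisher information Σ 1/σ² is conserved within each orbit.
    """
    if len(rs) == 0:
        return rs
    asu = map_to_asu_array(rs.hkl, rs.laue)
    uniq, inverse = _group_rows(asu)
    w = 1.0 / rs.sigma**2
    sw = np.bincount(inverse, weights=w, minlength=len(uniq))
    swf = np.bincount(inverse, weights=w * rs.amplitude, minlength=len(uniq))
    merged_f = swf / sw
    merged_sigma = 1.0 / np.sqrt(sw)
    return rs.copy_with(hkl=uniq, amplitude=merged_f, sigma=merged_sigma)


def enumerate_asu_indices(
    cell: UnitCell, laue: LaueGroup, dmin: float, dmax: float = math.inf
) -> np.ndarray:
    """All theoretically possible unique ASU indices with d in [dmin, dmax].

    Enumerates the full hkl box bounded by |hᵢ| ≤ |aᵢ|/dmin (an exact bound:
    h = aᵢ·s with |s| ≤ 1/dmin), filters on resolution with relative
    tolerance, then maps to ASU representatives. Exact but O(box volume) —
    intended for desk-scale resolution limits.
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    if dmin >= dmax:
        raise ValueError("require dmin < dmax")
    g = cell.metric_tensor()
    lengths = np.sqrt(np.diag(g))  # |a|, |b|, |c|
    hmax = np.floor(lengths / dmin).astype(int) + 1
    axes = [np.arange(-m, m + 1) for m in hmax]
    hh, kk, ll = np.meshgrid(*axes, indexing="ij")
    box = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()])
    box = box[~np.all(box == 0, axis=1)]
    d = d_spacing_array(cell, box)
    lo = dmin * (1.0 - RESOLUTION_RTOL)
    hi = dmax if math.isinf(dmax) else dmax * (1.0 + RESOLUTION_RTOL)
    box = box[(d >= lo) & (d <= hi)]
    return decode_hkl(np.unique(asu_keys(box, laue)))


def completeness(rs: ReflectionSet, dmin: float | None = None, dmax: float | None = None) -> float:
    """Fraction of the theoretically possible unique reflections observed.

    The set must already be ASU-merged. The denominator is the exhaustive
    enumeration of unique ASU indices in the resolution shell; the numerator
    counts observed unique ASU indices whose d lies in the shell.
    """
    dmin = rs.dmin if dmin is None else dmin
    dmax = rs.dmax if dmax is None else dmax
    if dmin >= dmax:
        raise ValueError("require dmin < dmax")
    possible = enumerate_asu_indices(rs.cell, rs.laue, dmin, dmax)
    if len(possible) == 0:
        raise ValueError("no theoretically possible reflections in the requested shell")
    if len(rs) == 0:
        return 0.0
    asu = decode_hkl(np.unique(asu_keys(rs.hkl, rs.laue)))
    d = d_spacing_array(rs.cell, asu)
    lo = dmin * (1.0 - RESOLUTION_RTOL)
    hi = dmax * (1.0 + RESOLUTION_RTOL)
    asu = asu[(d >= lo) & (d <= hi)]
    if len(asu) == 0:
        return 0.0
    n_obs = np.intersect1d(
        encode_hkl(possible), encode_hkl(asu), assume_unique=True
    ).size
    return n_obs / len(possible)


# --------------------------------------------------------------------------
# intensities
# --------------------------------------------------------------------------

def amplitudes_from_intensities(
    intensity: np.ndarray, sigma_i: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convert intensities to amplitudes by F = sqrt(max(I, 0)), σF = σI/(2F).

    A pragmatic truncation, not a Bayesian (French-Wilson) treatment; where
    F would be 0 the sigma is propagated from a small positive floor so it
    stays finite.
    """
    intensity = np.asarray(intensity, dtype=float)
    sigma_i = np.asarray(sigma_i, dtype=float)
    f = np.sqrt(np.clip(intensity, 0.0, None))
    f_safe = np.where(f > 0, f, np.sqrt(np.clip(sigma_i, 1e-12, None)))
    sigma_f = sigma_i / (2.0 * f_safe)
    return f, sigma_f


# --------------------------------------------------------------------------
# HKL text I/O
# --------------------------------------------------------------------------

class HklParseError(ValueError):
    """Raised for malformed HKL text files; message names the line number."""


_REQUIRED_HEADERS = ("ID", "CELL", "LAUE", "RESOLUTION")


def read_hkl(path: str | Path) -> ReflectionSet:
    """Read one reflection set from the plain-text HKL dialect.

    Header lines: ``# ID <label>``, ``# CELL a b c alpha beta gamma``,
    ``# LAUE <name>``, ``# RESOLUTION dmax dmin``; optionally
    ``# COLUMNS h k l I sigI`` to declare intensity rows (converted on read).
    Data rows are ``h k l F sigF``. Other ``#`` lines are comments.
    """
    path = Path(path)
    headers: dict[str, list[str]] = {}
    rows: list[tuple[int, int, int, float, float]] = []
    columns = "F"
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split()
                if fields and fields[0].upper() in _REQUIRED_HEADERS:
                    headers[fields[0].upper()] = fields[1:]
                elif fields and fields[0].upper() == "COLUMNS":
                    spec = " ".join(fields[1:]).lower()
                    if spec in ("h k l f sigf", ""):
                        columns = "F"
                    elif spec == "h k l i sigi":
                        columns = "I"
                    else:
                        raise HklParseError(
                            f"{path}:{lineno}: unsupported COLUMNS declaration {spec!r}"
                        )
                continue
            fields = line.split()
            if len(fields) != 5:
                raise HklParseError(
                    f"{path}:{lineno}: expected 5 fields 'h k l F sigF', got {len(fields)}"
                )
            try:
                h, k, l = (int(x) for x in fields[:3])
            except ValueError:
                raise HklParseError(f"{path}:{lineno}: non-integer Miller index") from None
            try:
                f, s = float(fields[3]), float(fields[4])
            except ValueError:
                raise HklParseError(f"{path}:{lineno}: non-numeric amplitude/sigma") from None
            if s <= 0:
                raise HklParseError(f"{path}:{lineno}: sigma must be positive, got {s}")
            rows.append((h, k, l, f, s))
    for key in _REQUIRED_HEADERS:
        if key not in headers:
            raise HklParseError(f"{path}: missing required header line '# {key} ...'")
    if len(headers["CELL"]) != 6:
        raise HklParseError(f"{path}: '# CELL' must carry 6 numbers")
    if len(headers["RESOLUTION"]) != 2:
        raise HklParseError(f"{path}: '# RESOLUTION' must carry 'dmax dmin'")
    cell = UnitCell(*(float(x) for x in headers["CELL"]))
    laue = LaueGroup.from_name(" ".join(headers["LAUE"]))
    dmax, dmin = (float(x) for x in headers["RESOLUTION"])
    set_id = " ".join(headers["ID"]) or path.stem
    arr = np.array(rows, dtype=float).reshape(-1, 5)
    hkl = arr[:, :3].astype(np.int64)
    fcol, scol = arr[:, 3], arr[:, 4]
    if columns == "I":
        fcol, scol = amplitudes_from_intensities(fcol, scol)
        keep = scol > 0
        hkl, fcol, scol = hkl[keep], fcol[keep], scol[keep]
    return ReflectionSet(
        id=set_id, cell=cell, laue=laue, hkl=hkl,
        amplitude=fcol, sigma=scol, dmin=dmin, dmax=dmax,
    )


def write_hkl(rs: ReflectionSet, path: str | Path) -> None:
    """Write a reflection set in the HKL text dialect (reals at 6 sig. figs)."""
    path = Path(path)
    c = rs.cell
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# ID {rs.id}\n")
        fh.write(
            "# CELL "
            + " ".join(f"{x:.6g}" for x in (c.a, c.b, c.c, c.alpha, c.beta, c.gamma))
            + "\n"
        )
        fh.write(f"# LAUE {rs.laue.name}\n")
        fh.write(f"# RESOLUTION {rs.dmax:.6g} {rs.dmin:.6g}\n")
        for (h, k, l), f, s in zip(rs.hkl, rs.amplitude, rs.sigma):
            fh.write(f"{h} {k} {l} {f:.6g} {s:.6g}\n")
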