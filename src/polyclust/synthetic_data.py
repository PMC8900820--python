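"""Seeded generators of multi-crystal reflection data and coordinate
ensembles with planted polymorph structure.

The reflection generator emulates the regime of a tetragonal multi-crystal
collection that splits into a small number of unit-cell polymorphs (e.g.
a ≈ 111 Å vs a ≈ 114–115 Å, c ≈ 52 Å), each containing amplitude subgroups
— conformational states that barely move the cell but perturb the
structure-factor amplitudes. Master intensities are Wilson-like
(exponential), amplitudes F = sqrt(I); each subgroup redraws a fraction rho
of the master amplitudes; each crystal gets a jittered cell, an arbitrary
overall scale, multiplicative amplitude noise and random incompleteness.

Under this scheme (unit-mean exponential intensities) the expected Pearson
CC between two crystals of the same subgroup at full overlap is

    CC_within = v / (v + sigma_F²),  v = Var(F) = 1 − π/4 ≈ 0.2146,

and between different subgroups of the same cell group approximately
(1 − rho)² · CC_within, since each subgroup independently redraws its rho
fraction. The defaults below target CC_within ≈ 0.95 and between ≈ 0.5.

The coordinate generator plants a rigid shared backbone with one mobile
segment displaced along a cluster-specific direction, mimicking an ensemble
of cluster-average models that differ in a single loop.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ensemble_analysis import CoordinateEnsemble
from .reflection_model import (
    LaueGroup,
    ReflectionSet,
    UnitCell,
    d_spacing_array,
    enumerate_asu_indices,
)

__all__ = [
    "CellGroupSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_reflection_sets",
    "generate_coordinate_ensemble",
    "expected_cc_within",
    "expected_cc_between",
    "write_simulation",
    "AMPLITUDE_VARIANCE_FRACTION",
]

#: Var(F)/E[F²] for F = sqrt(I), I ~ Exp: 1 - pi/4.
AMPLITUDE_VARIANCE_FRACTION = 1.0 - math.pi / 4.0


@dataclass(frozen=True)
class CellGroupSpec:
    """One unit-cell polymorph: tetragonal cell (a = b) and its subgroups."""

    a: float
    c: float
    weight: float
    n_subgroups: int = 1
    subgroup_weights: tuple[float, ...] | None = None

    def resolved_subgroup_weights(self) -> np.ndarray:
        if self.subgroup_weights is not None:
            w = np.asarray(self.subgroup_weights, dtype=float)
            if len(w) != self.n_subgroups or np.any(w <= 0):
                raise ValueError("subgroup_weights must be positive, one per subgroup")
            return w / w.sum()
        return np.full(self.n_subgroups, 1.0 / self.n_subgroups)


def _default_cell_groups() -> tuple[CellGroupSpec, ...]:
    # two tetragonal polymorphs: the larger-cell group carries 2 amplitude
    # subgroups, the smaller-cell group 3, with the smaller group dominant
    return (
        CellGroupSpec(a=111.4, c=52.0, weight=118 / 146, n_subgroups=3),
        CellGroupSpec(a=114.5, c=52.3, weight=28 / 146, n_subgroups=2),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the reflection-set generator.

    sigma_f:
        relative multiplicative amplitude noise; the default 0.1063 targets
        an expected within-subgroup CC of 0.95 (see module docstring).
    rho:
        fraction of master amplitudes redrawn per subgroup; the default
        0.2746 targets a between-subgroup CC of ≈ 0.5.
    completeness_range:
        each crystal keeps a uniform-random fraction of the unique
        reflections drawn from this interval.
    scale_spread:
        log-normal sigma of the arbitrary per-crystal overall scale.
    """

    n_sets: int = 146
    cell_groups: tuple[CellGroupSpec, ...] = field(default_factory=_default_cell_groups)
    rho: float = 0.2746
    sigma_cell: float = 0.1
    sigma_f: float = 0.1063
    completeness_range: tuple[float, float] = (0.8, 1.0)
    dmin: float = 3.0
    laue: str = "4/mmm"
    sigma_floor: float = 0.01
    scale_spread: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(g.weight for g in self.cell_groups)
        if not math.isclose(w, 1.0, rel_tol=1e-6):
            raise ValueError(f"cell-group weights must sum to 1, got {w}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        lo, hi = self.completeness_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("completeness_range must satisfy 0 < lo <= hi <= 1")
        if self.n_sets < 1:
            raise ValueError("n_sets must be positive")
        if self.sigma_f < 0 or self.sigma_cell < 0:
            raise ValueError("noise levels must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        data = json.loads(text)
        groups = data.pop("cell_groups", None)
        if groups is not None:
            data["cell_groups"] = tuple(
                CellGroupSpec(**{
                    **g,
                    "subgroup_weights": tuple(g["subgroup_weights"])
                    if g.get("subgroup_weights") else None,
                })
                for g in groups
            )
        if "completeness_range" in data:
            data["completeness_range"] = tuple(data["completeness_range"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted labels: set id -> (cell group index, global subgroup index)."""

    membership: dict[str, tuple[int, int]]

    def coarse_labels(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.membership[i][0] for i in ids])

    def fine_labels(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.membership[i][1] for i in ids])


def expected_cc_within(sigma_f: float) -> float:
    """Expected full-overlap Pearson CC between same-subgroup crystals."""
    v = AMPLITUDE_VARIANCE_FRACTION
    return v / (v + sigma_f**2)


def expected_cc_between(sigma_f: float, rho: float) -> float:
    """Expected CC between crystals of different subgroups (same cell)."""
    return (1.0 - rho) ** 2 * expected_cc_within(sigma_f)


def _apportion(n: int, weights: np.ndarray) -> np.ndarray:
    """Deterministic largest-remainder apportionment of n into len(weights)."""
    raw = n * np.asarray(weights, dtype=float)
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def generate_reflection_sets(
    cfg: SimulationConfig = SimulationConfig(),
) -> tuple[list[ReflectionSet], GroundTruth]:
    """Generate ``cfg.n_sets`` reflection sets with planted polymorphs.

    Draw order (single stream seeded from ``cfg.seed``): per cell group the
    master intensities, then per subgroup the redraw mask and replacement
    intensities, then per data set the cell jitter, overall scale, kept
    subset, amplitude noise. Fully reproducible from the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    laue = LaueGroup.from_name(cfg.laue)
    group_counts = _apportion(cfg.n_sets, np.array([g.weight for g in cfg.cell_groups]))

    sets: list[ReflectionSet] = []
    membership: dict[str, tuple[int, int]] = {}
    global_subgroup = 0
    set_index = 0
    for gi, (group, n_in_group) in enumerate(zip(cfg.cell_groups, group_counts)):
        base_cell = UnitCell(group.a, group.a, group.c)
        asu = enumerate_asu_indices(base_cell, laue, cfg.dmin)
        n_unique = len(asu)
        if n_unique < 100:
            raise ValueError(
                f"dmin={cfg.dmin} too coarse: only {n_unique} unique indices for "
                f"cell group {gi}"
            )
        master_i = rng.exponential(1.0, size=n_unique)
        sub_amplitudes: list[np.ndarray] = []
        for _ in range(group.n_subgroups):
            f = np.sqrt(master_i)
            if cfg.rho > 0:
                n_redraw = int(round(cfg.rho * n_unique))
                mask = rng.choice(n_unique, size=n_redraw, replace=False)
                f = f.copy()
                f[mask] = np.sqrt(rng.exponential(1.0, size=n_redraw))
            sub_amplitudes.append(f)
        sub_counts = _apportion(n_in_group, group.resolved_subgroup_weights())
        for si, n_in_sub in enumerate(sub_counts):
            f_master = sub_amplitudes[si]
            for _ in range(n_in_sub):
                sid = f"set{set_index:04d}"
                a = group.a + rng.normal(0.0, cfg.sigma_cell)
                c = group.c + rng.normal(0.0, cfg.sigma_cell)
                cell = UnitCell(a, a, c)
                scale = float(np.exp(rng.normal(0.0, cfg.scale_spread)))
                target = rng.uniform(*cfg.completeness_range)
                n_keep = max(2, int(round(target * n_unique)))
                keep = np.sort(rng.choice(n_unique, size=n_keep, replace=False))
                noise = rng.normal(0.0, cfg.sigma_f, size=n_keep)
                f_obs = np.clip(f_master[keep] * (1.0 + noise), 0.0, None) * scale
                sigma = cfg.sigma_f * f_obs + cfg.sigma_floor * scale
                d = d_spacing_array(cell, asu[keep])
                sets.append(
                    ReflectionSet(
                        id=sid,
                        cell=cell,
                        laue=laue,
                        hkl=asu[keep],
                        amplitude=f_obs,
                        sigma=sigma,
                        dmin=cfg.dmin,
                        dmax=float(d.max()) * 1.001,
                    )
                )
                membership[sid] = (gi, global_subgroup + si)
                set_index += 1
        global_subgroup += group.n_subgroups
    return sets, GroundTruth(membership=membership)


# --------------------------------------------------------------------------
# coordinate ensembles
# --------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_coordinate_ensemble(
    n_clusters: int = 5,
    n_structures_per_cluster: int = 4,
    mobile_range: range = range(139, 147),
    displacement: float = 3.0,
    jitter: float = 0.1,
    n_residues: int = 200,
    seed: int = 0,
) -> tuple[CoordinateEnsemble, dict[str, int]]:
    """Synthetic Cα ensemble: rigid shared backbone, one mobile segment.

    All structures share one smooth 200-residue backbone trace. Within
    ``mobile_range`` each cluster displaces the trace along a
    cluster-specific direction (well-separated unit vectors), with
    magnitude ramping linearly from 0 at the start of the range to
    ``displacement`` Å at its last residue. Isotropic Gaussian jitter
    (sigma ``jitter`` Å per coordinate) models refinement noise.

    Returns the ensemble and the planted structure -> cluster map (also
    stored in ``ensemble.cluster_of``).
    """
    if displacement < 0:
        raise ValueError("displacement must be non-negative")
    if len(mobile_range) == 0:
        raise ValueError("mobile range must not be empty")
    if max(mobile_range) > n_residues or min(mobile_range) < 1:
        raise ValueError("mobile range must lie within the chain")
    rng = np.random.default_rng(seed)
    res = np.arange(1, n_residues + 1)
    # loose helical trace: non-degenerate, realistic ~3.8 Å spacing scale
    t = res.astype(float)
    backbone = np.column_stack(
        [9.0 * np.cos(t / 3.0), 9.0 * np.sin(t / 3.0), 1.5 * t]
    )
    directions = _fibonacci_directions(max(n_clusters, 2))[:n_clusters]
    mobile = np.array(list(mobile_range))
    ramp = np.linspace(0.0, 1.0, len(mobile) + 1)[1:]  # ends at 1 at the last residue

    structures: dict[str, dict[int, np.ndarray]] = {}
    cluster_of: dict[str, int] = {}
    for cl in range(n_clusters):
        offset = np.zeros((n_residues, 3))
        offset[mobile - 1] = displacement * ramp[:, None] * directions[cl]
        for rep in range(n_structures_per_cluster):
            label = f"c{cl}s{rep}"
            coords = backbone + offset
            if jitter > 0:
                coords = coords + rng.normal(0.0, jitter, size=coords.shape)
            structures[label] = {int(r): coords[r - 1].copy() for r in res}
            cluster_of[label] = cl
    ens = CoordinateEnsemble(structures=structures, cluster_of=dict(cluster_of))
    return ens, cluster_of


# --------------------------------------------------------------------------
# on-disk output
# --------------------------------------------------------------------------

def write_simulation(
    cfg: SimulationConfig, out_dir: str | Path
) -> tuple[list[ReflectionSet], GroundTruth]:
    """Generate and write .hkl files plus truth.tsv and config.json."""
    from .reflection_model import write_hkl

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sets, truth = generate_reflection_sets(cfg)
    for s in sets:
        write_hkl(s, out / f"{s.id}.hkl")
    with (out / "truth.tsv").open("w", encoding="utf-8") as fh:
        fh.write("id\tcell_group\tsubgroup\n")
        for sid, (g, sg) in truth.membership.items():
            fh.write(f"{sid}\t{g}\t{sg}\n")
    (out / "config.json").write_text(cfg.to_json(), encoding="utf-8")
    return sets, truth
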