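"""Tests for PDB Cα extraction, superposition, spread profiles, minimum-volume
ellipsoids and the plot-ready exports."""

import json
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from polyclust import (
    CoordinateEnsemble,
    cell_scatter_data,
    cluster_ellipsoids,
    cut_tree,
    dendrogram_export,
    max_calpha_spread,
    min_volume_ellipsoid,
    read_pdb_calpha,
    superpose,
    ward_linkage,
)
from polyclust.ensemble_analysis import PdbParseError, superpose_ensemble

from conftest import make_set


def _atom_line(serial, resseq, x, y, z, occ=1.0, altloc=" ", name=" CA "):
    return (
        f"ATOM  {serial:>5d} {name}{altloc}ALA A{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f} 10.00           C"
    )


class TestReadPdbCalpha:
    def test_reads_exactly_the_calphas(self, tmp_path):
        lines = [
            _atom_line(1, 1, 1.0, 2.0, 3.0),
            _atom_line(2, 1, 9.0, 9.0, 9.0, name=" CB "),
            _atom_line(3, 2, 4.0, 5.0, 6.0),
            _atom_line(4, 3, 7.0, 8.0, 9.0),
            "END",
        ]
        p = tmp_path / "m.pdb"
        p.write_text("\n".join(lines) + "\n")
        got = read_pdb_calpha(p)
        assert sorted(got) == [1, 2, 3]
        np.testing.assert_allclose(got[1], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(got[3], [7.0, 8.0, 9.0])

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        lines = [
            _atom_line(1, 1, 1.0, 1.0, 1.0, occ=0.6, altloc="A"),
            _atom_line(2, 1, 2.0, 2.0, 2.0, occ=0.4, altloc="B"),
            _atom_line(3, 2, 5.0, 5.0, 5.0, occ=0.5, altloc="B"),
            _atom_line(4, 2, 6.0, 6.0, 6.0, occ=0.5, altloc="A"),
        ]
        p = tmp_path / "m.pdb"
        p.write_text("\n".join(lines) + "\n")
        got = read_pdb_calpha(p)
        np.testing.assert_allclose(got[1], [1.0, 1.0, 1.0])  # occupancy 0.6 > 0.4
        np.testing.assert_allclose(got[2], [6.0, 6.0, 6.0])  # tie: altloc A < B

    def test_gap_residues_absent_without_error(self, tmp_path):
        lines = [_atom_line(i, r, float(r), 0.0, 0.0)
                 for i, r in enumerate([145, 146, 151, 152], start=1)]
        p = tmp_path / "m.pdb"
        p.write_text("\n".join(lines) + "\n")
        got = read_pdb_calpha(p)
        assert sorted(got) == [145, 146, 151, 152]
        assert 147 not in got and 150 not in got

    def test_malformed_record_names_line(self, tmp_path):
        good = _atom_line(1, 1, 1.0, 2.0, 3.0)
        bad = "ATOM      2  CA  ALA A   x      bad coords"
        p = tmp_path / "m.pdb"
        p.write_text(good + "\n" + bad + "\n")
        with pytest.raises(PdbParseError, match=":2:"):
            read_pdb_calpha(p)


class TestSuperpose:
    def _trace(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return {i + 1: rng.normal(0, 5, 3) for i in range(n)}

    def test_identity_on_identical(self):
        ref = self._trace()
        R, t, rmsd = superpose(ref, ref)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_rotation(self):
        ref = self._trace()
        R_true = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        t_true = np.array([1.0, -2.0, 3.0])
        mov = {r: R_true.T @ (x - t_true) for r, x in ref.items()}
        R, t, rmsd = superpose(ref, mov)
        assert rmsd < 1e-9
        np.testing.assert_allclose(R, R_true, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_requires_three_shared_residues(self):
        ref = {1: np.zeros(3), 2: np.ones(3)}
        with pytest.raises(ValueError, match="3 shared"):
            superpose(ref, ref)

    def test_collinear_fallback_still_optimal(self):
        # degenerate input: points on a line; transform is non-unique but
        # must still achieve zero residual for a compatible mover
        ref = {i: np.array([float(i), 0.0, 0.0]) for i in range(1, 6)}
        mov = {i: np.array([0.0, float(i), 0.0]) for i in range(1, 6)}
        R, t, rmsd = superpose(ref, mov)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_never_worse_than_identity_alignment(self):
        rng = np.random.default_rng(4)
        ref = self._trace(seed=1)
        mov = {r: x + rng.normal(0, 1.0, 3) for r, x in ref.items()}
        _, _, rmsd = superpose(ref, mov)
        identity_rmsd = math.sqrt(
            np.mean([np.sum((mov[r] - ref[r]) ** 2) for r in ref])
        )
        assert rmsd <= identity_rmsd + 1e-12


class TestMaxCalphaSpread:
    def test_zero_for_identical_structures(self):
        coords = {i: np.array([i, 0.0, 0.0]) for i in range(1, 10)}
        ens = CoordinateEnsemble(structures={"a": coords, "b": dict(coords)})
        spread = max_calpha_spread(ens)
        assert all(v == 0.0 for v in spread.values())

    def test_displaced_residue_reported(self):
        coords = {i: np.array([i, 0.0, 0.0]) for i in range(140, 150)}
        moved = {i: np.array(c) for i, c in coords.items()}
        moved[146] = moved[146] + np.array([0.0, 3.0, 0.0])
        ens = CoordinateEnsemble(structures={"a": coords, "b": moved})
        spread = max_calpha_spread(ens)
        assert spread[146] == pytest.approx(3.0)
        assert spread[145] == 0.0

    def test_matches_bruteforce_pairwise_maximum(self):
        rng = np.random.default_rng(5)
        structures = {
            f"s{j}": {r: rng.normal(0, 2, 3) for r in range(1, 30)} for j in range(5)
        }
        ens = CoordinateEnsemble(structures=structures)
        spread = max_calpha_spread(ens)
        for r in range(1, 30):
            pts = [structures[f"s{j}"][r] for j in range(5)]
            best = max(
                np.linalg.norm(p - q) for i, p in enumerate(pts) for q in pts[i + 1:]
            )
            assert spread[r] == pytest.approx(best, rel=1e-12)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(6)
        structures = {
            f"s{j}": {r: rng.normal(0, 2, 3) for r in range(1, 10)} for j in range(4)
        }
        e1 = CoordinateEnsemble(structures=dict(structures))
        e2 = CoordinateEnsemble(structures=dict(reversed(list(structures.items()))))
        assert max_calpha_spread(e1) == max_calpha_spread(e2)


class TestMinVolumeEllipsoid:
    def test_octahedron_gives_unit_ball(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        e = min_volume_ellipsoid(pts)
        assert e.volume == pytest.approx(4 * math.pi / 3, rel=1e-4)
        np.testing.assert_allclose(e.center, 0.0, atol=1e-6)

    def test_single_point_degenerate(self):
        e = min_volume_ellipsoid(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(e.center, [1, 2, 3])
        assert e.contains(np.array([1.0, 2.0, 3.0]))
        assert 0 < e.volume < 1e-3

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            min_volume_ellipsoid(np.empty((0, 3)))

    def test_containment_random_clouds(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            P = rng.normal(size=(int(rng.integers(4, 25)), 3)) * rng.uniform(0.5, 3, 3)
            e = min_volume_ellipsoid(P, tol=1e-6)
            mem = np.einsum("ni,ij,nj->n", P - e.center, e.shape, P - e.center)
            assert mem.max() <= 1.0 + 1e-5

    def test_minimality_witness(self):
        # shrinking by 1% must expel at least one point
        rng = np.random.default_rng(8)
        for _ in range(100):
            P = rng.normal(size=(int(rng.integers(4, 20)), 3))
            e = min_volume_ellipsoid(P, tol=1e-7)
            shrunk = e.shape / 0.99**2
            mem = np.einsum("ni,ij,nj->n", P - e.center, shrunk, P - e.center)
            assert mem.max() > 1.0

    def test_volume_close_to_high_precision_and_box_bound(self):
        rng = np.random.default_rng(9)
        P = rng.normal(size=(50, 3))
        tol = 1e-6
        e = min_volume_ellipsoid(P, tol=tol)
        ref = min_volume_ellipsoid(P, tol=1e-10)
        assert e.volume <= ref.volume * (1 + 6 * tol)
        assert e.volume >= ref.volume * (1 - 6 * tol)
        # analytic bound: ellipsoid circumscribing the bounding box has
        # semi-axes sqrt(3)*half-widths
        half = (P.max(axis=0) - P.min(axis=0)) / 2
        box_ellipsoid_volume = 4 * math.pi / 3 * np.prod(np.sqrt(3.0) * half)
        assert e.volume <= box_ellipsoid_volume * (1 + 1e-9)

    def test_rigid_motion_equivariance(self):
        rng = np.random.default_rng(10)
        P = rng.normal(size=(20, 3))
        R = Rotation.random(random_state=11).as_matrix()
        shift = np.array([5.0, -3.0, 2.0])
        e1 = min_volume_ellipsoid(P)
        e2 = min_volume_ellipsoid(P @ R.T + shift)
        assert e2.volume == pytest.approx(e1.volume, rel=1e-9)
        np.testing.assert_allclose(e2.center, R @ e1.center + shift, atol=1e-6)

    def test_degenerate_clouds_still_contained(self):
        for P in (
            np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]),           # collinear
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]),  # coplanar
        ):
            e = min_volume_ellipsoid(P)
            mem = np.einsum("ni,ij,nj->n", P - e.center, e.shape, P - e.center)
            assert mem.max() <= 1.0 + 1e-5
            assert np.isfinite(e.volume)


class TestClusterEllipsoids:
    def test_separated_clusters_have_separated_ellipsoids(self):
        rng = np.random.default_rng(12)
        structures, cluster_of = {}, {}
        centers = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        for cl in range(2):
            for j in range(5):
                label = f"c{cl}s{j}"
                structures[label] = {1: centers[cl] + rng.normal(0, 0.1, 3)}
                cluster_of[label] = cl
        ens = CoordinateEnsemble(structures=structures, cluster_of=cluster_of)
        ells = cluster_ellipsoids(ens, residue=1)
        gap = np.linalg.norm(ells[0].center - ells[1].center)
        assert gap > 5 * max(ells[0].mean_radius(), ells[1].mean_radius())


class TestPlotReadyExports:
    def test_cell_scatter_rows(self):
        from polyclust.amplitude_cluster import ClusterAssignment
        from polyclust import UnitCell

        sets = [
            make_set([[1, 0, 0]], [1.0], cell=UnitCell(111, 111, 52), id="x"),
            make_set([[1, 0, 0]], [1.0], cell=UnitCell(114.5, 114.5, 52.3), id="y"),
            make_set([[1, 0, 0]], [1.0], cell=UnitCell(111.1, 111.1, 52.0), id="z"),
        ]
        assignment = ClusterAssignment(
            labels={"x": 0, "y": 1, "z": 0}, stage="fine",
            coarse_of={"x": 0, "y": 1, "z": 0},
        )
        df = cell_scatter_data(sets, assignment)
        assert len(df) == 3
        assert df.set_index("id").loc["y", "fine"] == 1
        assert df.set_index("id").loc["z", "a"] == pytest.approx(111.1)

    def test_cell_scatter_empty_assignment_errors(self):
        from polyclust.amplitude_cluster import ClusterAssignment

        with pytest.raises(ValueError):
            cell_scatter_data([], ClusterAssignment(labels={}, stage="fine"))

    def test_dendrogram_export_geometry(self):
        from scipy.spatial.distance import pdist, squareform

        pts = np.array([[0.0], [0.1], [5.0], [5.1], [10.0]])
        tree = ward_linkage(squareform(pdist(pts)), ids=list("abcde"))
        assignment = cut_tree(tree, 1.0)
        export = dendrogram_export(tree, assignment)
        assert sorted(export["leaves"]) == list("abcde")
        assert len(export["icoord"]) == len(tree.merges)
        np.testing.assert_allclose(
            sorted(max(d) for d in export["dcoord"]), sorted(tree.heights()), atol=1e-12
        )
        # leaf colors are contiguous per cluster in dendrogram order
        colors = export["leaf_clusters"]
        seen = []
        for c in colors:
            if not seen or seen[-1] != c:
                seen.append(c)
        assert len(seen) == len(set(colors))

    def test_two_leaf_dendrogram(self):
        tree = ward_linkage(np.array([[0.0, 2.0], [2.0, 0.0]]), ids=["p", "q"])
        assignment = cut_tree(tree, 10.0)
        export = dendrogram_export(tree, assignment)
        assert len(export["icoord"]) == 1
        assert max(export["dcoord"][0]) == pytest.approx(2.0)

    def test_ellipsoid_json_roundtrip(self):
        e = min_volume_ellipsoid(np.random.default_rng(0).normal(size=(10, 3)))
        blob = json.loads(json.dumps(e.to_dict()))
        assert blob["volume"] == pytest.approx(e.volume)
        np.testing.assert_allclose(blob["center"], e.center)
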