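"""Geometry kernel: PDB parsing, Kabsch RMSD, SASA, burial, metal sites."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ptcsig.struct_metrics import (
    AtomRecord,
    StructureError,
    StructureModel,
    buried_interface_area,
    kabsch_rmsd,
    metal_site,
    read_pdb,
    sasa,
    total_sasa,
)

from conftest import pdb_line


def atom(element, x, y, z, chain="A", resnum=1, resname="UNK", name=None):
    return AtomRecord(
        chain=chain, resnum=resnum, resname=resname,
        atom_name=name or element, element=element, x=x, y=y, z=z,
    )


# ---------------------------------------------------------------- PDB I/O


def test_read_tiny_pdb_exact_coordinates(tiny_pdb):
    model = read_pdb(tiny_pdb)
    assert len(model) == 3
    assert [a.atom_name for a in model.atoms] == ["N", "CA", "C"]
    assert model.atoms[1].coords == pytest.approx([2.5, 2.0, 3.0])
    assert model.atoms[0].element == "N"


def test_altloc_keeps_highest_occupancy(tmp_path):
    text = (
        pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.3, element="C", altloc="A")
        + pdb_line(2, "CA", "ALA", "A", 1, 9.0, 0.0, 0.0, occ=0.7, element="C", altloc="B")
        + "END\n"
    )
    path = tmp_path / "alt.pdb"
    path.write_text(text)
    model = read_pdb(path)
    assert len(model) == 1
    assert model.atoms[0].x == pytest.approx(9.0)


def test_empty_pdb_errors(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("")
    with pytest.raises(StructureError):
        read_pdb(path)


def test_malformed_coordinate_reports_line(tmp_path):
    good = pdb_line(1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0)
    bad = good[:30] + "  xx.xxx" + good[38:]
    path = tmp_path / "bad.pdb"
    path.write_text(good + bad)
    with pytest.raises(StructureError, match=":2"):
        read_pdb(path)


def test_selection_by_chain_and_range(tiny_pdb):
    model = read_pdb(tiny_pdb)
    assert len(model.select_expr("A:1-1")) == 3
    assert len(model.select_expr("B")) == 0
    assert len(model.select(atom_names=["CA"])) == 1


# ---------------------------------------------------------------- Kabsch


def random_coords(rng, n):
    return rng.normal(size=(n, 3)) * 5.0


def test_identical_sets_rmsd_zero():
    rng = np.random.default_rng(0)
    pts = random_coords(rng, 10)
    _, _, rmsd = kabsch_rmsd(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-10)


def test_rigid_motion_rmsd_zero():
    rng = np.random.default_rng(1)
    pts = random_coords(rng, 25)
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    moved = pts @ rot.T + np.array([5.0, -3.0, 12.0])
    r, t, rmsd = kabsch_rmsd(pts, moved)
    assert rmsd <= 1e-8
    assert np.linalg.det(r) == pytest.approx(1.0)
    assert np.allclose(pts @ r.T + t, moved, atol=1e-8)


def test_rmsd_symmetric():
    rng = np.random.default_rng(2)
    a, b = random_coords(rng, 12), random_coords(rng, 12)
    assert kabsch_rmsd(a, b)[2] == pytest.approx(kabsch_rmsd(b, a)[2], rel=1e-10)


def rmsd_by_numeric_minimization(a, b):
    """Oracle: minimize RMSD over rotation vectors with restarts."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def objective(rv):
        rot = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((a0 @ rot.T - b0) ** 2).sum() / len(a0))

    best = np.inf
    rng = np.random.default_rng(123)
    for _ in range(24):
        res = minimize(objective, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return best


def test_four_point_rmsd_matches_numeric_oracle():
    rng = np.random.default_rng(3)
    for _ in range(3):
        a = random_coords(rng, 4)
        b = a + rng.normal(scale=0.4, size=a.shape)
        kab = kabsch_rmsd(a, b)[2]
        assert abs(kab - rmsd_by_numeric_minimization(a, b)) <= 1e-6


def test_too_few_or_collinear_points_error():
    with pytest.raises(StructureError):
        kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
    with pytest.raises(StructureError, match="collinear"):
        kabsch_rmsd(line, line)


# ---------------------------------------------------------------- SASA


def test_single_atom_analytic_sphere():
    model = StructureModel(atoms=[atom("C", 0, 0, 0)])
    area = sasa(model)[0]
    assert area == pytest.approx(4 * math.pi * (1.70 + 1.4) ** 2, rel=0.01)


def test_fully_enclosed_atom_zero_area():
    # Central carbon caged by an icosahedral shell at 1.0 A: every
    # surface sample point lies inside a neighbour's expanded sphere.
    phi = (1 + math.sqrt(5)) / 2
    verts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            verts += [(0, a, b), (a, b, 0), (b, 0, a)]
    norm = math.sqrt(1 + phi * phi)
    atoms = [atom("C", 0, 0, 0)] + [
        atom("C", *(np.array(v) / norm)) for v in verts
    ]
    areas = sasa(StructureModel(atoms=atoms))
    assert areas[0] == 0.0


def two_sphere_analytic(r1, r2, d, probe=1.4):
    """Exact SASA of two intersecting spheres via spherical caps."""
    e1, e2 = r1 + probe, r2 + probe
    full1, full2 = 4 * math.pi * e1**2, 4 * math.pi * e2**2
    if d >= e1 + e2:
        return full1 + full2
    h1 = e1 - (d * d + e1 * e1 - e2 * e2) / (2 * d)
    h2 = e2 - (d * d + e2 * e2 - e1 * e1) / (2 * d)
    return (full1 - 2 * math.pi * e1 * h1) + (full2 - 2 * math.pi * e2 * h2)


@pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
def test_two_sphere_sasa_matches_analytic(d):
    model = StructureModel(atoms=[atom("C", 0, 0, 0), atom("N", d, 0, 0)])
    total = total_sasa(model)
    assert total == pytest.approx(two_sphere_analytic(1.70, 1.55, d), rel=0.01)


def test_cluster_sasa_matches_monte_carlo_oracle():
    """Independent seeded Monte Carlo surface sampling on a 5-atom cluster."""
    rng = np.random.default_rng(11)
    coords = rng.normal(size=(5, 3)) * 1.5
    elements = ["C", "N", "O", "S", "C"]
    model = StructureModel(atoms=[atom(e, *c) for e, c in zip(elements, coords)])
    mine = sasa(model)
    radii = np.array([1.70, 1.55, 1.52, 1.80, 1.70]) + 1.4
    n_pts = 40000
    oracle = np.empty(5)
    for i in range(5):
        dirs = rng.normal(size=(n_pts, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = coords[i] + radii[i] * dirs
        free = np.ones(n_pts, dtype=bool)
        for j in range(5):
            if j != i:
                free &= ((pts - coords[j]) ** 2).sum(axis=1) > radii[j] ** 2
        oracle[i] = 4 * math.pi * radii[i] ** 2 * free.mean()
    assert np.sum(mine) == pytest.approx(np.sum(oracle), rel=0.015)


def test_total_sasa_invariant_under_rigid_motion():
    rng = np.random.default_rng(7)
    coords = rng.normal(size=(6, 3)) * 2.0
    model = StructureModel(atoms=[atom("C", *c) for c in coords])
    rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
    moved = StructureModel(atoms=[atom("C", *(rot @ c + 3.0)) for c in coords])
    assert total_sasa(moved) == pytest.approx(total_sasa(model), rel=0.01)


def test_unknown_element_errors():
    model = StructureModel(atoms=[atom("UUO", 0, 0, 0)])
    with pytest.raises(StructureError, match="van der Waals"):
        sasa(model)


# ---------------------------------------------------------------- burial


def test_distant_atoms_bury_nothing():
    a = StructureModel(atoms=[atom("C", 0, 0, 0)])
    b = StructureModel(atoms=[atom("C", 100.0, 0, 0, chain="B")])
    assert buried_interface_area(a, b) == (0.0, 0.0)


def test_mirror_symmetric_dimer_buries_equally():
    half = [("C", 0.0, 0.0, 0.0), ("N", 1.4, 0.0, 0.0), ("O", 0.0, 1.3, 0.0)]
    a = StructureModel(atoms=[atom(e, x - 2.0, y, z) for e, x, y, z in half])
    b = StructureModel(
        atoms=[atom(e, -(x - 2.0), y, z, chain="B") for e, x, y, z in half]
    )
    # The spiral quadrature is not mirror-symmetric, so equality holds
    # to quadrature accuracy; it tightens with the point count.
    buried_a, buried_b = buried_interface_area(a, b)
    assert buried_a > 0
    assert buried_a == pytest.approx(buried_b, rel=0.02)
    fine = buried_interface_area(a, b, n_sphere_points=20000)
    assert fine[0] == pytest.approx(fine[1], rel=0.004)


def test_overlapping_selections_rejected():
    shared = atom("C", 0, 0, 0)
    a = StructureModel(atoms=[shared])
    b = StructureModel(atoms=[shared])
    with pytest.raises(StructureError, match="overlap"):
        buried_interface_area(a, b)


# ---------------------------------------------------------------- metal site


def octahedron_model(bond=2.1, jitter=0.0, rng=None):
    dirs = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
    )
    if jitter and rng is not None:
        dirs = dirs + rng.normal(scale=jitter, size=dirs.shape)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    atoms = [atom("NI", 0, 0, 0, name="NI", resname="NI")]
    for k, d in enumerate(dirs):
        el = "N" if k < 3 else "O"
        atoms.append(atom(el, *(bond * d), resnum=10 + k))
    return StructureModel(atoms=atoms)


def test_ideal_octahedron_recognized():
    report = metal_site(octahedron_model())
    assert report is not None
    assert report.geometry == "octahedral"
    assert len(report.ligands) == 6
    assert all(d == pytest.approx(2.1) for _, d in report.ligands)
    assert max(report.angle_deviations) == pytest.approx(0.0, abs=1e-9)


def test_tetrahedron_is_other():
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    dirs /= math.sqrt(3)
    atoms = [atom("NI", 0, 0, 0)] + [atom("N", *(2.1 * d)) for d in dirs]
    report = metal_site(StructureModel(atoms=atoms))
    assert report.geometry == "other"
    assert len(report.ligands) == 4


def test_planar_hexagon_is_other():
    atoms = [atom("NI", 0, 0, 0)]
    for k in range(6):
        ang = k * math.pi / 3
        atoms.append(atom("O", 2.1 * math.cos(ang), 2.1 * math.sin(ang), 0.0))
    report = metal_site(StructureModel(atoms=atoms))
    assert len(report.ligands) == 6
    assert report.geometry == "other"


def test_absent_metal_returns_none():
    model = StructureModel(atoms=[atom("C", 0, 0, 0)])
    assert metal_site(model, element="NI") is None


def test_distance_cutoff_limits_ligands():
    model = octahedron_model(bond=3.0)
    report = metal_site(model, distance_cutoff=2.6)
    assert report.ligands == []
    assert report.geometry == "other"
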