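"""Structural geometry kernel: PDB parsing, Kabsch superposition,
Shrake-Rupley solvent accessibility, interface burial and metal-site
coordination geometry.

These are the measurements used to characterize the putrescine
transcarbamylase trimer: Calpha superposition RMSDs between subunits
and against ornithine transcarbamylases, the surface area of the
C-terminal helix (residues 320-337) buried against the adjacent
subunit (probe radius 1.4 A), and the octahedral Ni site on the trimer
threefold axis (three histidine N ligands plus three waters).

PDB files are parsed with gemmi; coordinates are then handled as plain
numpy arrays. SASA uses a deterministic golden-spiral quadrature (no
randomness), so repeated runs are byte-identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np
from scipy.spatial import cKDTree

# Van der Waals radii (A) for the elements that occur in protein
# crystal structures handled here.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "NI": 1.63, "ZN": 1.39, "MG": 1.73,
    "FE": 1.63, "CD": 1.58, "MN": 1.61, "CA": 2.31, "NA": 2.27,
    "K": 2.75, "CL": 1.75,
}

DEFAULT_PROBE = 1.4
DEFAULT_SPHERE_POINTS = 960
DEFAULT_METAL_CUTOFF = 2.6
DEFAULT_ANGLE_TOL = 20.0


class StructureError(ValueError):
    """Raised for unparseable files or invalid geometric input."""


@dataclass
class AtomRecord:
    chain: str
    resnum: int
    resname: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    is_water: bool = False
    is_hetero: bool = False

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """Ordered atom list with simple chain/residue selection queries."""

    atoms: list[AtomRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms]) if self.atoms else np.empty((0, 3))

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def select(
        self,
        chain: Optional[str] = None,
        residue_range: Optional[tuple[int, int]] = None,
        atom_names: Optional[Iterable[str]] = None,
        include_waters: bool = True,
    ) -> "StructureModel":
        names = set(atom_names) if atom_names is not None else None
        picked = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if residue_range is not None and not (residue_range[0] <= a.resnum <= residue_range[1]):
                continue
            if names is not None and a.atom_name not in names:
                continue
            if not include_waters and a.is_water:
                continue
            picked.append(a)
        return StructureModel(atoms=picked)

    def select_expr(self, expression: str) -> "StructureModel":
        """Selection like ``A`` (whole chain) or ``A:320-337``."""
        m = re.fullmatch(r"(\w+)(?::(\d+)-(\d+))?", expression.strip())
        if not m:
            raise StructureError(f"bad selection expression {expression!r}")
        chain = m.group(1)
        rng = (int(m.group(2)), int(m.group(3))) if m.group(2) else None
        return self.select(chain=chain, residue_range=rng)

    def ca_coords(self) -> np.ndarray:
        return self.select(atom_names=["CA"]).coords()


def read_pdb(path) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Atoms keep file order; alternate locations are resolved to the
    highest-occupancy conformer; waters and hetero atoms are retained
    and flagged. Raises :class:`StructureError` for empty or malformed
    files (gemmi's message carries the offending line).
    """
    path = Path(path)
    # gemmi is lenient about malformed numeric fields; validate the
    # fixed coordinate columns up front so errors carry line numbers.
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi, name in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                field_text = line[lo:hi].strip()
                try:
                    float(field_text)
                except ValueError:
                    raise StructureError(
                        f"{path}:{lineno}: malformed {name} coordinate {field_text!r}"
                    ) from None
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureError(f"{path}: no models found")
    model = structure[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            # Resolve altlocs: keep the highest-occupancy atom per name.
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in residue:
                key = atom.name
                if key not in best:
                    best[key] = atom
                    order.append(key)
                elif atom.occ > best[key].occ:
                    best[key] = atom
            is_water = residue.is_water()
            is_hetero = residue.het_flag == "H"
            for key in order:
                atom = best[key]
                el = atom.element.name.upper()
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        resname=residue.name,
                        atom_name=atom.name,
                        element=el,
                        x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                        is_water=is_water,
                        is_hetero=is_hetero,
                    )
                )
    if not atoms:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    return StructureModel(atoms=atoms)


def kabsch_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired coordinates (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_a @ rotation.T + translation`` best fits ``coords_b``.
    The rotation is proper (determinant +1, no reflection). Raises
    :class:`StructureError` for fewer than 3 points or degenerate
    (collinear) sets.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise StructureError("coordinate sets must be matched (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise StructureError("need at least 3 paired atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if min(np.linalg.matrix_rank(a0), np.linalg.matrix_rank(b0)) < 2:
        raise StructureError("degenerate (collinear) coordinate set")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = a0 @ rot.T - b0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    trans = cb - rot @ ca
    return rot, trans, rmsd


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii(model: StructureModel) -> np.ndarray:
    radii = np.empty(len(model.atoms))
    for i, atom in enumerate(model.atoms):
        try:
            radii[i] = VDW_RADII[atom.element]
        except KeyError:
            raise StructureError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.atom_name} {atom.chain}/{atom.resnum})"
            ) from None
    return radii


def sasa(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom (A^2).

    Each atom is expanded by the probe radius and sampled with a
    deterministic golden-spiral quadrature; a sample point is
    accessible when outside every neighbouring expanded sphere.
    """
    n = len(model.atoms)
    if n == 0:
        return np.empty(0)
    coords = model.coords()
    radii = _radii(model) + probe_radius
    unit = _sphere_points(n_sphere_points)
    rmax = radii.max()
    tree = cKDTree(coords)
    areas = np.empty(n)
    for i in range(n):
        ri = radii[i]
        pts = coords[i] + ri * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * ri * ri * accessible.sum() / n_sphere_points
    return areas


def total_sasa(model: StructureModel, **kwargs) -> float:
    return float(np.sum(sasa(model, **kwargs)))


def buried_interface_area(
    model_a: StructureModel,
    model_b: StructureModel,
    probe_radius: float = DEFAULT_PROBE,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> tuple[float, float]:
    """Surface buried on each partner upon complexation.

    ``buried_x = SASA(x alone) - SASA(x in the a+b complex)``, summed
    over the partner's atoms. Selections must be disjoint.
    """
    ids_a = {id(a) for a in model_a.atoms}
    if any(id(b) in ids_a for b in model_b.atoms):
        raise StructureError("selections overlap")
    key_a = {(a.chain, a.resnum, a.atom_name) for a in model_a.atoms}
    if any((b.chain, b.resnum, b.atom_name) in key_a for b in model_b.atoms):
        raise StructureError("selections overlap")
    na = len(model_a.atoms)
    complex_model = StructureModel(atoms=model_a.atoms + model_b.atoms)
    area_complex = sasa(complex_model, probe_radius, n_sphere_points)
    area_a = sasa(model_a, probe_radius, n_sphere_points)
    area_b = sasa(model_b, probe_radius, n_sphere_points)
    buried_a = float(area_a.sum() - area_complex[:na].sum())
    buried_b = float(area_b.sum() - area_complex[na:].sum())
    return buried_a, buried_b


@dataclass
class MetalSiteReport:
    metal_element: str
    metal_position: np.ndarray
    ligands: list[tuple[AtomRecord, float]]
    geometry: str  # "octahedral" or "other"
    angle_deviations: list[float]


def metal_site(
    model: StructureModel,
    element: str = "NI",
    distance_cutoff: float = DEFAULT_METAL_CUTOFF,
    angle_tolerance: float = DEFAULT_ANGLE_TOL,
) -> Optional[MetalSiteReport]:
    """Coordination analysis of the first atom of ``element``.

    Ligands are non-metal atoms within the cutoff. The geometry is
    octahedral iff there are exactly 6 ligands whose metal-centred
    inter-ligand angles partition into 12 near-90 and 3 near-180 degree
    pairs within the tolerance. Returns ``None`` when the element is
    absent.
    """
    element = element.upper()
    metal = next((a for a in model.atoms if a.element == element), None)
    if metal is None:
        return None
    mpos = metal.coords
    ligands: list[tuple[AtomRecord, float]] = []
    for a in model.atoms:
        if a is metal or a.element == element:
            continue
        d = float(np.linalg.norm(a.coords - mpos))
        if d <= distance_cutoff:
            ligands.append((a, d))
    ligands.sort(key=lambda t: t[1])
    geometry = "other"
    deviations: list[float] = []
    if len(ligands) == 6:
        vecs = [(a.coords - mpos) / d for a, d in ligands]
        angles = []
        for i in range(6):
            for j in range(i + 1, 6):
                cosang = float(np.clip(np.dot(vecs[i], vecs[j]), -1.0, 1.0))
                angles.append(np.degrees(np.arccos(cosang)))
        angles.sort()
        near_90 = [abs(a - 90.0) for a in angles[:12]]
        near_180 = [abs(a - 180.0) for a in angles[12:]]
        deviations = near_90 + near_180
        if all(dev <= angle_tolerance for dev in deviations):
            geometry = "octahedral"
    return MetalSiteReport(
        metal_element=element,
        metal_position=mpos,
        ligands=ligands,
        geometry=geometry,
        angle_deviations=deviations,
    )
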