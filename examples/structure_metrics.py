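"""Geometry kernel: superposition RMSD, SASA, burial, metal coordination.

Constructs small synthetic atom sets with known answers: a rigidly moved
point cloud (RMSD must be 0), an isolated carbon (SASA must equal the
analytic probe-expanded sphere), a contact dimer (buried area > 0), and
an ideal octahedral Ni site of the kind found on the PTC trimer
threefold axis (three His N + three water O ligands).
"""

import math

import numpy as np
from scipy.spatial.transform import Rotation

from ptcsig import buried_interface_area, kabsch_rmsd, metal_site, sasa
from ptcsig.struct_metrics import AtomRecord, StructureModel


def atom(element, x, y, z, chain="A", resnum=1, resname="UNK"):
    return AtomRecord(chain=chain, resnum=resnum, resname=resname,
                      atom_name=element, element=element, x=x, y=y, z=z)


rng = np.random.default_rng(1)
pts = rng.normal(size=(25, 3)) * 5.0
rot = Rotation.from_rotvec([0.4, -0.9, 0.2]).as_matrix()
moved = pts @ rot.T + np.array([3.0, -1.0, 8.0])
_, _, rmsd = kabsch_rmsd(pts, moved)
print(f"Kabsch RMSD after an exact rigid motion: {rmsd:.2e} A (should be ~0)")

lone = StructureModel(atoms=[atom("C", 0, 0, 0)])
area = sasa(lone)[0]
print(f"single carbon SASA: {area:.2f} A^2 (analytic 4*pi*(1.70+1.40)^2 = "
      f"{4 * math.pi * 3.1**2:.2f})")

a = StructureModel(atoms=[atom("C", 0, 0, 0), atom("N", 1.4, 0, 0)])
b = StructureModel(atoms=[atom("C", 3.5, 0, 0, chain="B"), atom("O", 4.9, 0, 0, chain="B")])
buried_a, buried_b = buried_interface_area(a, b)
print(f"buried interface area: {buried_a:.1f} / {buried_b:.1f} A^2 per partner")

atoms = [atom("NI", 0, 0, 0, resname="NI")]
directions = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
for k, d in enumerate(directions):
    element = "N" if k < 3 else "O"
    resname = "HIS" if k < 3 else "HOH"
    atoms.append(atom(element, *(2.1 * np.array(d)), resnum=10 + k, resname=resname))
report = metal_site(StructureModel(atoms=atoms), element="NI")
ligs = ", ".join(f"{a.resname}/{a.element}@{d:.1f}A" for a, d in report.ligands)
print(f"Ni site geometry: {report.geometry}; ligands: {ligs}")
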