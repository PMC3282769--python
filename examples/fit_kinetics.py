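"""Fit Michaelis-Menten saturation data and report catalytic efficiency.

Builds noise-free saturation curves at the wild-type putrescine
parameters (Vmax = 813 U/mg, Km = 1.41 mM) and at the engineered
(loop-swapped) enzyme's parameters, fits the hyperbola v = Vmax*S/(Km+S)
by nonlinear least squares, and prints Vmax/Km in U mg^-1 mM^-1.
"""

import numpy as np

from ptcsig import SaturationDataset, catalytic_efficiency, fit_hyperbola
from ptcsig.kinetics import michaelis_menten

cases = [
    ("wild type / putrescine", 813.0, 1.41, 3),
    ("engineered / ornithine", 82.0, 32.0, 2),
    ("engineered / putrescine", 1.13, 32.9, 1),
]

for label, vmax, km, sig in cases:
    grid = np.array([0.5, 1, 2, 5, 10, 20, 40]) * (1 if km < 10 else 4)
    data = SaturationDataset(label, grid, michaelis_menten(grid, vmax, km))
    fit = fit_hyperbola(data)
    eff = catalytic_efficiency(fit, sig_figs=sig)
    print(
        f"{label:<26} Vmax = {fit.vmax:8.2f} U/mg   Km = {fit.km:6.2f} mM   "
        f"Vmax/Km = {eff} U mg^-1 mM^-1"
    )

print(
    "\nThe loop swap cuts putrescine efficiency ~20,000-fold while raising\n"
    "ornithine efficiency: the 230-loop controls amine-substrate choice."
)
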