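"""Hertz fitting of AFM force curves and a radial elasticity map.

Simulates force-indentation curves (45 um polystyrene bead, 5 nN force cap)
on a collagen gel whose stiffness decays with distance from a spheroid,
fits Young's modulus per curve and grids the moduli into a 1-D map.
"""

import numpy as np

from contractile_escape import NoiseSpec, elasticity_map, fit_hertz, make_hertz_curve

R_BEAD = 22.5  # um
fits = []
for i, d in enumerate(np.linspace(10, 190, 10)):  # um from the spheroid edge
    E_true = 400.0 * np.exp(-d / 100.0) + 100.0
    curve = make_hertz_curve(
        E_true, nu=0.45, R=R_BEAD, max_force=5.0, noise=NoiseSpec(0.02, i), position=(d, 0.5)
    )
    fit = fit_hertz(curve, R=R_BEAD, nu=0.45, force_cap=5.0)
    fits.append(fit)
    print(f"d = {d:5.1f} um   E_true = {E_true:6.1f} Pa   E_fit = {fit.E:6.1f} Pa")

grid = elasticity_map(fits, x_edges=np.linspace(0, 200, 11), y_edges=[0, 1])
print("elasticity map (Pa):", np.round(grid[0]))
# The gel is stiffest next to the spheroid and softens with distance — the
# strain-stiffening signature of the cells pulling on the collagen network.
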