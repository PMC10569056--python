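"""Find the minimum-energy path of the model potential with CI-NEB.

Runs a climbing-image nudged-elastic-band optimization between the two
relaxed minima and reports where the climbing image lands.  The exact
transition point is (0, ±1) with barrier V = 1 above minima at −1/12;
the barrier top is quartic along the path (a degenerate saddle), so a
tight force tolerance is used to refine it.
"""

import numpy as np

import transtube as tt
from transtube.mep import fit_mep_spline

calc = tt.Toy2D()
a = tt.relax(calc, tt.Geometry(["X"], [[-1.1, 0.05, 0.0]]), f_tol=1e-9)
b = tt.relax(calc, tt.Geometry(["X"], [[1.1, 0.05, 0.0]]), f_tol=1e-9)

band = tt.neb_optimize(calc, a, b, n_images=15, f_tol=1e-4, max_steps=100000)
hi = band.highest_image()
ci = band.frames[hi].coords[0]
print(f"climbing image at ({ci[0]:+.6f}, {ci[1]:+.6f}), E = {band.energies[hi]:.6f}")
print(f"barrier height: {band.energies[hi] - band.energies[0]:.6f} "
      f"(exact: {1 + 1/12:.6f})")

mep = fit_mep_spline(band)
print(f"\ncontinuous path: arc length L = {mep.arc_length:.4f} Å")
print("energy profile along xi:")
for xi in np.linspace(0.0, 1.0, 11):
    e, _ = calc.evaluate(mep.coords(xi))
    print(f"  xi = {xi:.1f}  E = {e:+.4f}")
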