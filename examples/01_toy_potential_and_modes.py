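"""Relax the 2D model potential and inspect its normal modes.

Builds the double-minimum model surface, relaxes one minimum, computes
the numerical Hessian and prints the harmonic frequencies.  The surface
has two minima at (±√5/2, 0) with V = −1/12 and degenerate barrier tops
at (0, ±1) with V = 1.
"""

import numpy as np

import transtube as tt

calc = tt.Toy2D()
guess = tt.Geometry(["X"], [[1.0, 0.3, 0.0]])
minimum = tt.relax(calc, guess, f_tol=1e-8)
print(f"relaxed minimum at ({minimum.coords[0,0]:+.6f}, {minimum.coords[0,1]:+.6f})")
print(f"energy {minimum.energy:.6f}  (exact: {-1/12:.6f})")

hessian = tt.numerical_hessian(calc, minimum)
modes = tt.normal_mode_analysis(hessian, minimum.masses, minimum)
print(f"\n{modes.n_internal} internal modes, "
      f"{len(modes.zero_mode_indices)} flat direction(s) (z):")
for w in modes.frequencies:
    print(f"  omega = {w:.5f} fs^-1")
print("\nThe two frequencies are sqrt(13/3) and sqrt(40/3) times the unit")
print("conversion: the curvatures of the two in-plane principal directions.")
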