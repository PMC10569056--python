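"""Internal unit system and physical constants.

All quantities in the package are carried in a single fixed unit system:
energies in eV, lengths in Å, masses in amu, times in fs and temperatures
in K.  Mass-weighted coordinates therefore have units of Å·√amu and
frequencies obtained from a mass-weighted Hessian (eV Å⁻² amu⁻¹) are
converted to fs⁻¹ through :data:`EV_TO_AMU_A2_FS2`.

The 2019 SI exact values are used throughout.
"""

from __future__ import annotations

import math

#: elementary charge, J per eV (exact)
E_CHARGE = 1.602176634e-19
#: atomic mass constant, kg (CODATA 2018)
AMU_KG = 1.66053906660e-27
#: Boltzmann constant, eV / K (exact)
KB = 1.380649e-23 / E_CHARGE
#: reduced Planck constant, eV·fs (exact)
HBAR = 6.62607015e-34 / (2.0 * math.pi) / E_CHARGE * 1e15

#: 1 eV expressed in amu·Å²/fs² (the internal mass·length²/time² energy unit)
EV_TO_AMU_A2_FS2 = E_CHARGE / AMU_KG * 1e-10
#: inverse conversion
AMU_A2_FS2_TO_EV = 1.0 / EV_TO_AMU_A2_FS2

#: mapping used by the CLI ``version`` output and the RunConfig echo
CONSTANTS = {
    "k_B [eV/K]": KB,
    "hbar [eV fs]": HBAR,
    "1 eV [amu Angstrom^2 fs^-2]": EV_TO_AMU_A2_FS2,
    "1 amu Angstrom^2 fs^-2 [eV]": AMU_A2_FS2_TO_EV,
}


def constants_table() -> str:
    """Human-readable table of the internal constants."""
    width = max(len(k) for k in CONSTANTS)
    lines = [f"{k:<{width}}  {v:.12e}" for k, v in CONSTANTS.items()]
    return "\n".join(lines)


def beta_from_temperature(temperature: float) -> float:
    """Inverse temperature β = 1/(k_B T) in eV⁻¹ (``inf`` at T = 0)."""
    if temperature < 0:
        raise ValueError(f"temperature must be non-negative, got {temperature}")
    if temperature == 0:
        return math.inf
    return 1.0 / (KB * temperature)
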