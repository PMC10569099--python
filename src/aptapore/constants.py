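"""Physical constants and shared defaults (SI units throughout)."""

from scipy import constants as _sc

FARADAY = _sc.physical_constants["Faraday constant"][0]  # C/mol
GAS_CONSTANT = _sc.R  # J/(mol K)
BOLTZMANN = _sc.k  # J/K
ELEMENTARY_CHARGE = _sc.e  # C
AVOGADRO = _sc.N_A  # 1/mol
VACUUM_PERMITTIVITY = _sc.epsilon_0  # F/m

#: Relative permittivity of water at 25 C.
WATER_REL_PERMITTIVITY = 78.4

#: Default temperature (K).
TEMPERATURE = 298.15

#: Default bias at which figures-of-merit are extracted from I-V sweeps (V).
V_EVAL_DEFAULT = 0.5

#: Tracer diffusivities at 25 C (m^2/s), standard tabulated values.
D_NA = 1.33e-9
D_CL = 2.03e-9
D_K = 1.96e-9


def thermal_voltage(temperature: float = TEMPERATURE) -> float:
    """RT/F in volts (~25.7 mV at 298 K)."""
    return GAS_CONSTANT * temperature / FARADAY
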