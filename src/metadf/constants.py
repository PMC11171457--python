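"""Physical constants and unit conventions.

Internal units: length Å, energy kJ/mol, time ps, angle rad, mass u
(for the angular coordinate an effective moment of inertia in u·Å²).
With these units 1 kJ/mol = 100 u·Å²/ps², hence the conversion factor
applied when turning forces into accelerations.
"""

#: Boltzmann constant, kJ/(mol·K)
KB = 0.0083144621

#: Gas constant R = kB·N_A expressed per mole, kJ/(mol·K) — numerically
#: identical to KB in molar energy units; kept as a separate name for the
#: thermodynamic relations (ΔG = −R·T·ln K).
R_GAS = KB

#: kJ/mol expressed in u·Å²/ps² (1 kJ/mol = 1 u·nm²/ps² = 100 u·Å²/ps²)
ENERGY_TO_MASS_UNITS = 100.0

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0
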