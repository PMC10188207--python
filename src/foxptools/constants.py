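"""Physical constants and default experimental conditions.

Energies are in kcal/mol throughout the package; concentrations in nM at the
API surface (converted to M internally where mass-action expressions need
molar units); times in ns for photon physics and s for macrotimes unless a
field name says otherwise.
"""

# Gas constant in kcal/(mol*K)
R_KCAL = 1.987e-3

# Boltzmann constant in the same molar units (identical to R here)
KB_KCAL = R_KCAL

# Binding/titration experiments are incubated at 37 C
T_BINDING_K = 310.15

# Chemical unfolding defaults to room temperature
T_UNFOLDING_K = 298.15

# Landscape analysis temperature (replica closest to ambient)
T_LANDSCAPE_K = 300.0

NM_TO_M = 1e-9


def kt_kcal(temperature_k: float) -> float:
    """Thermal energy k_B*T in kcal/mol (0.596 at 300 K)."""
    return KB_KCAL * temperature_k
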