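"""Physical constants (CODATA 2018).

Operator algebra throughout the package works in natural units with
ħ = 1: all interaction strengths are angular frequencies in rad s⁻¹.
The physical constants below enter only where an energy or field scale
is genuinely needed (thermal density operators, dipolar couplings).
"""

HBAR = 1.054571817e-34  # J s
K_B = 1.380649e-23  # J K⁻¹
MU0_OVER_4PI = 1.0e-7  # T² m³ J⁻¹ (μ₀/4π)
ANGSTROM = 1.0e-10  # m
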