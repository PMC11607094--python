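"""Fixed model constants (not varied in the sensitivity analysis).

Units: lengths in mm, times in days, stresses in kPa, densities in cells/mm^3.
"""

#: breast tissue carrying capacity (cells/mm^3)
THETA = 2.02e6

#: stress-diffusivity coupling constant (1/kPa)
GAMMA_N = 2.5

#: Winkler boundary constant (kPa/mm)
K_W = 0.20

#: tumor-induced solid stress (kPa)
G_N = 5.0

#: Poisson's ratio of breast tissue (homogeneous average)
NU = 0.45

#: Young's modulus of breast tissue (kPa, homogeneous average)
E_YOUNG = 3.0

#: reference (no-treatment) simulation parameters
D0_REFERENCE = 2.0e-4  # mm^2/day
RHO0_REFERENCE = 2.5e-2  # 1/day
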