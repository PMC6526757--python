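"""Unit conversion constants.

External interfaces use clinical units (mmHg, mL/s, mm); all fluid-mechanic
formulas are evaluated in SI and converted at the boundary.
"""

PA_PER_MMHG = 133.322
"""Pascals per millimetre of mercury."""

M3_PER_ML = 1e-6
"""Cubic metres per millilitre."""

M_PER_MM = 1e-3
"""Metres per millimetre."""

DYN_CM2_PER_PA = 10.0
"""dyn/cm^2 per pascal (CGS shear-stress unit used in clinical reports)."""

# Hydraulic resistance: Pa*s/m^3  ->  mmHg*s/mL
CLINICAL_R_PER_SI_R = M3_PER_ML / PA_PER_MMHG
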