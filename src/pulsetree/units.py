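"""Unit conversion constants.

The topology file format and all user-facing I/O use clinical units
(mmHg, cm, mm, mL, kPa^-1 x 10^-3); the solver works in SI internally.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

CM_TO_M = 1e-2
MM_TO_M = 1e-3

ML_TO_M3 = 1e-6
M3_TO_ML = 1e6

#: distensibility: kPa^-1 x 10^-3  ->  Pa^-1
DIST_UNIT_TO_PA = 1e-6

#: Windkessel resistance: mmHg.s/mL -> Pa.s/m^3
R_UNIT_TO_SI = MMHG_TO_PA / ML_TO_M3
#: Windkessel compliance: mL/mmHg -> m^3/Pa
C_UNIT_TO_SI = ML_TO_M3 / MMHG_TO_PA
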