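"""Unit conventions and conversion constants.

The package works in clinical units throughout: pressure in mmHg, volume in
ml, flow in ml/s, time in s, resistance in mmHg*s/ml, compliance in ml/mmHg,
elastance in mmHg/ml, material stiffness in kPa.  All conversions go through
the constants below so there is a single conversion site.
"""

MMHG_TO_KPA = 0.133322
"""1 mmHg expressed in kPa."""

KPA_TO_MMHG = 1.0 / MMHG_TO_KPA

MMHG_ML_TO_J = 1.33322e-4
"""1 mmHg*ml of pressure-volume work expressed in joules."""

LMIN_TO_MLS = 1000.0 / 60.0
"""1 L/min expressed in ml/s."""

BLOOD_DENSITY_G_MM3 = 0.00106
"""Blood density in g/mm^3 (= 1060 kg/m^3)."""

BLOOD_VISCOSITY_G_MMS = 0.004
"""Blood dynamic viscosity in g/(mm*s) (= 4 mPa*s)."""

WOOD_UNIT = 1.0
"""PVRi is reported in Wood units * m^2 = mmHg/(L/min/m^2); kept dimensionless here."""
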