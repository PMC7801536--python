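"""Package-wide physical constants and unit conventions.

Units used throughout: energy MeV (spectra also in keV where noted),
time hours, activity Bq, absorbed dose Gy, lineal energy keV/um,
density g/cm^3, length mm for image spacing and um for microdosimetry.
"""

import numpy as np

#: 1 MeV in joules (CODATA exact).
MEV_TO_J = 1.602176634e-13

#: 1 keV in joules.
KEV_TO_J = 1.602176634e-16

#: Dose in Gy delivered by 1 keV/um^3 in unit-density water:
#: 1 keV / (1 um^3 * 1 g/cm^3) = 1.602e-16 J / 1e-15 kg.
KEV_PER_UM3_TO_GY = 0.1602176634

#: Electron rest energy, MeV.
ELECTRON_REST_MEV = 0.51099895

LN2 = float(np.log(2.0))

SECONDS_PER_HOUR = 3600.0
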