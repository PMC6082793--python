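"""Internal unit system: eV / angstrom / amu / rad.

The derived time unit is t* = sqrt(amu * A**2 / eV); all frequencies, momenta
and time steps in the package are expressed in these units unless stated
otherwise.
"""

import math

#: 1 amu in kg
_AMU_KG = 1.66053906660e-27
#: 1 eV in J
_EV_J = 1.602176634e-19
#: hbar in eV s
_HBAR_EV_S = 6.582119569e-16

#: internal time unit t* = sqrt(amu A^2 / eV), in seconds (~1.018e-14 s)
T_STAR_SECONDS = math.sqrt(_AMU_KG * 1e-20 / _EV_J)

#: hbar expressed in eV * t* (~0.0647)
HBAR_EFF_DEFAULT = _HBAR_EV_S / T_STAR_SECONDS
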