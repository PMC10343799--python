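"""Unit system and physical constants.

The whole package works in a single internal unit system:

========  ==========
length    angstrom (A)
mass      atomic mass unit (a.m.u.)
time      picosecond (ps)
force     piconewton (pN)
energy    pN*A  (1 pN*A = 1e-22 J)
charge    elementary charge (e)
dipole    e*A
========  ==========

Mechanical (a.m.u., A, ps) and force (pN) quantities are related through
``FORCE_TO_ACC``: an acceleration in A/ps^2 equals ``FORCE_TO_ACC * F/m``
with F in pN and m in a.m.u.  Kinetic energy computed as ``0.5*m*v**2`` in
a.m.u.*A^2/ps^2 is converted to pN*A by ``KE_TO_PNA`` (the reciprocal).
"""

# Boltzmann constant, pN*A per kelvin (1.380649e-23 J/K / 1e-22 J).
KB = 0.1380649

# 1 pN acting on 1 a.m.u., expressed in A/ps^2.
FORCE_TO_ACC = 6.02214076

# a.m.u.*A^2/ps^2 -> pN*A
KE_TO_PNA = 1.0 / FORCE_TO_ACC

# 1 e*A in debye.
EA_TO_DEBYE = 4.8032

# Average atomic masses, a.m.u.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
}
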