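"""Physical constants in the package's internal unit system.

Units throughout: energy kJ/mol, length nm, time ps, temperature K,
charge in elementary charges, mass in g/mol (amu).  This system is
self-consistent: 1 kJ/mol == 1 amu nm^2 ps^-2, so masses in g/mol can be
used directly in the equations of motion.
"""

#: Boltzmann constant, kJ mol^-1 K^-1 (CODATA).
KB = 0.008314462618

#: Coulomb prefactor f = 1/(4 pi eps0), kJ mol^-1 nm e^-2.
F_COULOMB = 138.935458

#: Molecular volume of a water molecule in pure water at ambient
#: conditions, nm^3 — the default standard-state volume for absolute
#: binding free energies of water.
V_STANDARD_WATER = 0.02992
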