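"""Unit conventions and physical constants.

Internal units follow the GROMACS convention throughout: length in nm, time
in ps, energy in kJ/mol, mass in Da, temperature in K, charge in elementary
charges.  With these choices accelerations come out in nm/ps^2 with no
conversion factors.  Structure export converts nm -> Angstrom at the PDB
boundary only.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083145

#: Coulomb prefactor e^2/(4 pi eps_0), kJ mol^-1 nm e^-2 (vacuum)
COULOMB = 138.935458

#: thermal energy at 300 K, kJ/mol
KBT_300 = KB * 300.0

#: nm -> Angstrom
NM_TO_ANGSTROM = 10.0
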