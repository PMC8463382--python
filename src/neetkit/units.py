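"""Physical constants and unit conversions used across the toolkit.

Internal conventions: lengths in Bohr for volumetric data, Angstrom for
structure coordinates (PDB convention), nanometre for every reported
geometry table; energies in Hartree internally, kJ/mol in reports;
charges in units of the elementary charge e.
"""

# CODATA 2018
BOHR_ANGSTROM = 0.529177210903
ANGSTROM_BOHR = 1.0 / BOHR_ANGSTROM
BOHR_NM = BOHR_ANGSTROM / 10.0
HARTREE_KJMOL = 2625.4996394799

#: 1 Hartree/Bohr^2 expressed in kJ/mol/nm^2 (force-constant conversion)
HARTREE_PER_BOHR2_TO_KJMOL_NM2 = HARTREE_KJMOL / BOHR_NM**2
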