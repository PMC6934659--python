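"""Physical constants and package-wide defaults.

Energies are kcal/mol throughout; distances are nm at every measured
interface (coordinate containers keep the PDB-native angstrom).
"""

#: Molar gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Coulomb constant k_e, kcal A mol^-1 e^-2 (energy of two unit charges 1 A apart).
COULOMB_K = 332.0636

#: Default temperature for chemical denaturation, K (30 degC incubation).
DEFAULT_TEMPERATURE = 303.15

#: Default effective dielectric constant screening intra-protein electrostatics.
DEFAULT_EPSILON_EFF = 4.0

#: Default donor-to-centroid distance cutoff for XH...pi detection, nm.
DEFAULT_D_MAX_NM = 0.6

#: Default minimum heavy-H-centroid angle for XH...pi detection, degrees.
DEFAULT_OMEGA_MIN_DEG = 120.0

#: Ideal bond lengths used when constructing hydrogens / synthetic groups, nm.
BOND_CC_AROMATIC_NM = 0.139
BOND_CH_NM = 0.109
BOND_NH_NM = 0.101

ANGSTROM_PER_NM = 10.0
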