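"""Physical constants and the shipped water parameter set.

Unit system (AKMA-style): length Å, mass amu, energy kcal/mol, charge e.
The consistent internal time unit is then AKMA_TIME_FS femtoseconds;
all user-facing times are in fs.
"""

# Boltzmann constant, kcal mol^-1 K^-1
KB = 0.0019872041

# 1 internal (AKMA) time unit in femtoseconds: sqrt(amu * Å^2 / (kcal/mol))
AKMA_TIME_FS = 48.88821

# Coulomb constant, kcal Å mol^-1 e^-2
COULOMB = 332.0637157

# Atomic masses, amu
MASS_O = 15.9994
MASS_H = 1.008

# Flexible three-site (TIP3P-like) water: standard published charges and
# Lennard-Jones parameters, harmonic bond/angle terms in place of rigid
# constraints.  All editable through WaterForceField.
TIP3P = {
    "q_O": -0.834,          # e
    "q_H": 0.417,           # e
    "eps_O": 0.1521,        # kcal/mol
    "rmin_half_O": 1.7682,  # Å  (LJ Rmin/2)
    "eps_H": 0.0460,        # kcal/mol
    "rmin_half_H": 0.2245,  # Å
    "k_bond": 450.0,        # kcal/mol/Å^2
    "r0": 0.9572,           # Å   O-H equilibrium bond length
    "k_angle": 55.0,        # kcal/mol/rad^2
    "theta0_deg": 104.52,   # H-O-H equilibrium angle
}
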