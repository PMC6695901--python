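"""Physical constants and nuclear data used across the package.

Neutron coherent scattering lengths are the standard Sears tabulation
(bound coherent values, in fm); only the elements that occur in the
materials handled here (water, silica, lipids, sugars/proteins, common
salts) are included.  Atomic masses in g/mol.
"""

from __future__ import annotations

#: Avogadro constant scaled so that density [g/cm^3] / mass [g/mol] gives
#: number density in A^-3  (6.02214076e23 / 1e24).
N_A_PER_A3 = 0.602214076

#: fm -> Angstrom
FM_TO_A = 1.0e-5

#: Bound coherent neutron scattering lengths, fm.  'D' is deuterium.
COHERENT_B_FM: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "F": 5.654,
    "Na": 3.63,
    "Si": 4.1491,
    "P": 5.13,
    "S": 2.847,
    "Cl": 9.5770,
    "K": 3.67,
    "Ca": 4.70,
}

#: Atomic masses, g/mol.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00794,
    "D": 2.01410,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
}

# AT-cut quartz, standard values used with 5 MHz QCM-D sensors.
QUARTZ_DENSITY = 2648.0  # kg/m^3
QUARTZ_SHEAR_MODULUS = 2.947e10  # Pa

# Reference solvent densities, g/cm^3 (room temperature).
H2O_DENSITY = 1.000
D2O_DENSITY = 1.105

# Semi-infinite media SLDs, A^-2 (computed from the table above; silicon
# at 2.33 g/cm^3, amorphous SiO2 at 2.2 g/cm^3).
SILICON_SLD = 2.073e-6
SILICA_SLD = 3.474e-6
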