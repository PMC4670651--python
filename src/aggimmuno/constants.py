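"""Physical constants and unit conversions shared across modules.

Concentrations are carried in pM (1 pM = 1e-12 mol/L), time in days and
rates per day throughout the package, matching the per-site binding rate
scale of 8.64e-3 pM^-1 day^-1 used for antibody--antigen association.
"""

#: Avogadro constant, mol^-1 (2019 SI exact value).
N_AVOGADRO = 6.02214076e23

#: Molecules per liter represented by 1 pM.
MOLECULES_PER_L_PER_PM = 1e-12 * N_AVOGADRO


def pM_to_molecules_per_L(conc_pM: float) -> float:
    """Convert a concentration in pM to absolute molecules per liter."""
    return conc_pM * MOLECULES_PER_L_PER_PM


def molecules_per_L_to_pM(count_per_L: float) -> float:
    """Convert absolute molecules per liter to a concentration in pM."""
    return count_per_L / MOLECULES_PER_L_PER_PM
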