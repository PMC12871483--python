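"""Physical constants and default material parameters.

All values are SI.  The lipid table holds per-species defaults used by the
CLI and config layer; entries are plain dicts so users can extend or
override them at run time.
"""

# CODATA 2018 exact values
BOLTZMANN = 1.380649e-23        # J/K
AVOGADRO = 6.02214076e23        # 1/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)

#: viscosity of D2O at 25 degC, Pa s
ETA_D2O_25C = 1.1e-3

#: Per-lipid defaults: molecular volume (m^3), molar mass (kg/mol), bilayer
#: thickness (m) and hydrophobic tail thickness (m).  Editable; the POPC row
#: doubles as the package-wide fallback.
LIPIDS = {
    "POPC": {
        "molecular_volume": 1256e-30,
        "molar_mass": 0.7601,
        "thickness": 4.0e-9,
        "tail_thickness": 2.9e-9,
    },
    "POPS": {
        "molecular_volume": 1205e-30,
        "molar_mass": 0.7839,
        "thickness": 4.0e-9,
        "tail_thickness": 2.9e-9,
    },
    "DOPC": {
        "molecular_volume": 1303e-30,
        "molar_mass": 0.7861,
        "thickness": 3.9e-9,
        "tail_thickness": 2.7e-9,
    },
    "DPPC": {
        "molecular_volume": 1148e-30,
        "molar_mass": 0.7341,
        "thickness": 4.2e-9,
        "tail_thickness": 3.4e-9,
    },
}

#: lipids for which the polymer-brush closure of the leaflet-coupling
#: relation is known to be unreliable (polyunsaturated tails, sterols,
#: peptide-laden membranes)
POLYMER_BRUSH_CAVEATS = ("DHA", "cholesterol", "chol", "peptide")


def thermal_energy(temperature: float) -> float:
    """k_B * T in joules."""
    return BOLTZMANN * temperature
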