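"""Package-wide physical constants.

All thermodynamics is calorie-based (cal, cal/mol, cal/(K·mol)) to match the
units conventional in protein-unfolding calorimetry; hydrodynamics is CGS
(g, cm, s, poise) with sedimentation coefficients expressed in svedbergs at
the interface.
"""

#: Gas constant, cal/(K·mol).
R_CAL = 1.987

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.022e23

#: 0 °C in kelvin.
KELVIN_OFFSET = 273.15

#: One svedberg, seconds.
SVEDBERG = 1e-13

#: Default solvent (PBS at 20 °C): density g/mL and viscosity poise.
PBS_DENSITY = 1.005
PBS_VISCOSITY = 0.01002

#: Default partial specific volumes, mL/g.
VBAR_PROTEIN = 0.730
VBAR_SSDNA = 0.550

#: Mean residue mass of single-stranded DNA, Da per nucleotide.
SSDNA_DA_PER_BASE = 330.0


def celsius_to_kelvin(t_c):
    return t_c + KELVIN_OFFSET


def kelvin_to_celsius(t_k):
    return t_k - KELVIN_OFFSET
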