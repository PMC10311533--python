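"""Published benchmark values for [DyL1] used as reference inputs.

Pseudocontact shifts (ppm) of the three chemically distinct pyridyl protons
H1–H3 of [DyL1] in three deuterated solvents: the experimental values, the
time-averaged values from the solution-MD + multireference study of the same
complex, and the values computed from its superposition-averaged structure.
Also the summary of the O–Ln–C̃3 angle distributions from those trajectories.
These serve as regression fixtures and as inputs to the statistics module
(RMSD, ranges, orderings); they are reference data, not outputs of this
package's surrogate engine.
"""

SOLVENTS = ("D2O", "MeOD", "d6-DMSO")
PYRIDYL_PROTONS = ("H1", "H2", "H3")

#: Experimental pseudocontact shifts (ppm)
EXPERIMENTAL_SHIFTS_PPM = {
    "D2O": {"H1": 2.9, "H2": 2.4, "H3": 1.7},
    "MeOD": {"H1": 16.2, "H2": 13.6, "H3": 16.6},
    "d6-DMSO": {"H1": 21.6, "H2": 18.0, "H3": 22.3},
}

#: Time-averaged calculated shifts over the solution trajectories (ppm)
TIME_AVERAGED_CALC_SHIFTS_PPM = {
    "D2O": {"H1": -1.4, "H2": -1.9, "H3": -3.2},
    "MeOD": {"H1": 16.0, "H2": 13.5, "H3": 17.5},
    "d6-DMSO": {"H1": 4.1, "H2": 3.6, "H3": 4.9},
}

#: Shifts calculated from the superposition-averaged structure (ppm)
AVG_STRUCTURE_CALC_SHIFTS_PPM = {
    "D2O": {"H1": 44.1, "H2": 30.4, "H3": 119.5},
    "MeOD": {"H1": 37.1, "H2": 19.4, "H3": 26.9},
    "d6-DMSO": {"H1": 59.6, "H2": -25.3, "H3": -94.5},
}

#: Printed H1–H3 ranges (ppm) of the experimental and time-averaged columns
PRINTED_RANGES_PPM = {
    ("D2O", "experimental"): 1.2,
    ("D2O", "time_averaged"): 1.8,
    ("MeOD", "experimental"): 3.0,
    ("MeOD", "time_averaged"): 4.0,
    ("d6-DMSO", "experimental"): 4.3,
    ("d6-DMSO", "time_averaged"): 1.3,
}

#: Per-frame extremes (min, max) of the calculated shifts (ppm)
FLUCTUATION_EXTREMES_PPM = {
    "D2O": (-91.7, 62.1),
    "MeOD": (-79.2, 98.2),
    "d6-DMSO": (-150.0, 103.2),
}

#: O–Ln–C̃3 angle summary over the solution trajectories (degrees)
ANGLE_SUMMARY_DEG = {
    "D2O": {"min": 40.1, "max": 64.1, "mean": 51.8},
    "MeOD": {"min": 40.0, "max": 69.6, "mean": 53.6},
    "d6-DMSO": {"min": 34.5, "max": 69.8, "mean": 52.5},
}

#: Reported isotropic susceptibility (cgs molar) at 298 K
REPORTED_CHI_ISO_CGS = 0.05


def shifts_as_list(table: dict, solvent: str) -> list[float]:
    """H1, H2, H3 values of one solvent column as an ordered list."""
    return [table[solvent][h] for h in PYRIDYL_PROTONS]
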