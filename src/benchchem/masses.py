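"""Bundled element mass data, Z = 1..92.

Conventional atomic weights (g/mol) and most-abundant-isotope masses (Da),
frozen as data so that mass arithmetic is reproducible offline. Values follow
the IUPAC conventional weights as distributed with mainstream cheminformatics
toolkits; radioelements without a standard weight carry the mass number of
their longest-lived isotope.
"""

from __future__ import annotations

ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.941, "Be": 9.012, "B": 10.812,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.18,
    "Na": 22.99, "Mg": 24.305, "Al": 26.982, "Si": 28.086, "P": 30.974,
    "S": 32.067, "Cl": 35.453, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.944, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.39,
    "Ga": 69.723, "Ge": 72.61, "As": 74.922, "Se": 78.96, "Br": 79.904,
    "Kr": 83.8, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.94, "Tc": 98.0, "Ru": 101.07, "Rh": 102.906,
    "Pd": 106.42, "Ag": 107.868, "Cd": 112.412, "In": 114.818, "Sn": 118.711,
    "Sb": 121.76, "Te": 127.6, "I": 126.904, "Xe": 131.29, "Cs": 132.905,
    "Ba": 137.328, "La": 138.906, "Ce": 140.116, "Pr": 140.908, "Nd": 144.24,
    "Pm": 145.0, "Sm": 150.36, "Eu": 151.964, "Gd": 157.25, "Tb": 158.925,
    "Dy": 162.5, "Ho": 164.93, "Er": 167.26, "Tm": 168.934, "Yb": 173.04,
    "Lu": 174.967, "Hf": 178.49, "Ta": 180.948, "W": 183.84, "Re": 186.207,
    "Os": 190.23, "Ir": 192.217, "Pt": 195.078, "Au": 196.967, "Hg": 200.59,
    "Tl": 204.383, "Pb": 207.2, "Bi": 208.98, "Po": 209.0, "At": 210.0,
    "Rn": 222.0, "Fr": 223.0, "Ra": 226.0, "Ac": 227.0, "Th": 232.038,
    "Pa": 231.036, "U": 238.029,
}

MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.007825032, "He": 4.002603254, "Li": 7.01600455, "Be": 9.0121822,
    "B": 11.0093054, "C": 12.0, "N": 14.003074, "O": 15.99491462,
    "F": 18.99840322, "Ne": 19.99244018, "Na": 22.98976928, "Mg": 23.9850417,
    "Al": 26.98153863, "Si": 27.97692653, "P": 30.97376163, "S": 31.972071,
    "Cl": 34.96885268, "Ar": 39.96238312, "K": 38.96370668, "Ca": 39.96259098,
    "Sc": 44.9559119, "Ti": 47.9479463, "V": 50.9439595, "Cr": 51.9405075,
    "Mn": 54.9380451, "Fe": 55.9349375, "Co": 58.933195, "Ni": 57.9353429,
    "Cu": 62.9295975, "Zn": 63.9291422, "Ga": 68.9255736, "Ge": 73.9211778,
    "As": 74.9215965, "Se": 79.9165213, "Br": 78.9183371, "Kr": 83.911507,
    "Rb": 84.91178974, "Sr": 87.9056121, "Y": 88.9058483, "Zr": 89.9047044,
    "Nb": 92.9063781, "Mo": 97.9054082, "Tc": 96.906365, "Ru": 101.9043493,
    "Rh": 102.905504, "Pd": 105.903486, "Ag": 106.905097, "Cd": 113.9033585,
    "In": 114.903878, "Sn": 119.9021947, "Sb": 120.9038157, "Te": 129.9062244,
    "I": 126.904473, "Xe": 131.9041535, "Cs": 132.9054519, "Ba": 137.9052472,
    "La": 138.9063533, "Ce": 139.9054387, "Pr": 140.9076528, "Nd": 141.9077233,
    "Pm": 144.912749, "Sm": 151.9197324, "Eu": 152.9212303, "Gd": 157.9241039,
    "Tb": 158.9253468, "Dy": 163.9291748, "Ho": 164.9303221, "Er": 165.9302931,
    "Tm": 168.9342133, "Yb": 173.9388621, "Lu": 174.9407718, "Hf": 179.94655,
    "Ta": 180.9479958, "W": 183.9509312, "Re": 186.9557531, "Os": 191.9614807,
    "Ir": 192.9629264, "Pt": 194.9647911, "Au": 196.9665687, "Hg": 201.970643,
    "Tl": 204.9744275, "Pb": 207.9766521, "Bi": 208.9803987, "Po": 208.9824304,
    "At": 209.987148, "Rn": 222.0175706, "Fr": 223.0197359, "Ra": 226.0254026,
    "Ac": 227.0277521, "Th": 232.0380553, "Pa": 231.035884, "U": 238.0507882,
}

KNOWN_ELEMENTS: frozenset[str] = frozenset(ATOMIC_WEIGHTS)
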