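"""Residue mass tables for the 20 standard amino acids.

Values are residue (i.e. dehydrated) masses in daltons; a peptide's
chemical mass is the sum of its residue masses plus one water. Both
average and monoisotopic tables are embedded as constants so that mass
validation is reproducible offline and version-pinned.

Source: IUPAC 2021 atomic weights as tabulated by ExPASy/Unimod
(average) and the CODATA monoisotopic masses used throughout
mass-spectrometry software.
"""

from __future__ import annotations

MASS_TABLE_VERSION = "expasy-2021"

WATER_AVERAGE = 18.01528
WATER_MONOISOTOPIC = 18.0105646863

AVERAGE: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

MONOISOTOPIC: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

STANDARD_RESIDUES = frozenset(AVERAGE)

# Ambiguity / non-standard one-letter codes: never matchable, rejected in
# strict library loading (B/Z = Asx/Glx, J = Leu/Ile, X = any, U = Sec,
# O = Pyl).
AMBIGUITY_CODES = frozenset("BJZXUO")
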