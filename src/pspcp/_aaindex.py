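"""Embedded amino-acid physicochemical property scales.

The nine scales below are transcribed from the AAindex1 database
(https://www.genome.jp/aaindex/), keyed by AAindex accession.  Values are
stored per one-letter residue code so that no assumption about row order in
the source database leaks into the package; callers remap to the canonical
residue order on load.

Provenance, per accession (AAindex1 release; entry title in parentheses):
  BULH740101  Bull & Breese 1974   (Transfer free energy to surface, kcal/mol)
  EISD840101  Eisenberg 1984       (Consensus normalized hydrophobicity)
  HOPT810101  Hopp & Woods 1981    (Hydrophilicity value)
  RADA880108  Radzicka & Wolfenden 1988 (Mean polarity)
  ZIMJ680104  Zimmerman et al. 1968 (Isoelectric point)
  MCMT640101  McMeekin et al. 1964 (Refractivity)
  BHAR880101  Bhaskaran & Ponnuswamy 1988 (Average flexibility indices)
  CHOC750101  Chothia 1975         (Average volume of buried residue, A^3)
  COSI940101  Cosic 1994           (Electron-ion interaction potential)
"""

from __future__ import annotations

# Accessions in the order the method enumerates its R = 9 default properties.
DEFAULT_ACCESSIONS: tuple[str, ...] = (
    "BULH740101",
    "EISD840101",
    "HOPT810101",
    "RADA880108",
    "ZIMJ680104",
    "MCMT640101",
    "BHAR880101",
    "CHOC750101",
    "COSI940101",
)

AAINDEX_SCALES: dict[str, dict[str, object]] = {
    "BULH740101": {
        "description": "Transfer free energy to surface",
        "values": {
            "A": 0.610, "R": 0.690, "N": 0.890, "D": 0.610, "C": 0.360,
            "Q": 0.970, "E": 0.510, "G": 0.810, "H": 0.690, "I": -1.450,
            "L": -1.650, "K": 0.460, "M": -0.660, "F": -1.520, "P": -0.170,
            "S": 0.420, "T": 0.290, "W": -1.200, "Y": -1.430, "V": -0.750,
        },
    },
    "EISD840101": {
        "description": "Consensus normalized hydrophobicity",
        "values": {
            "A": 0.620, "R": -2.530, "N": -0.780, "D": -0.900, "C": 0.290,
            "Q": -0.850, "E": -0.740, "G": 0.480, "H": -0.400, "I": 1.380,
            "L": 1.060, "K": -1.500, "M": 0.640, "F": 1.190, "P": 0.120,
            "S": -0.180, "T": -0.050, "W": 0.810, "Y": 0.260, "V": 1.080,
        },
    },
    "HOPT810101": {
        "description": "Hydrophilicity value",
        "values": {
            "A": -0.500, "R": 3.000, "N": 0.200, "D": 3.000, "C": -1.000,
            "Q": 0.200, "E": 3.000, "G": 0.000, "H": -0.500, "I": -1.800,
            "L": -1.800, "K": 3.000, "M": -1.300, "F": -2.500, "P": 0.000,
            "S": 0.300, "T": -0.400, "W": -3.400, "Y": -2.300, "V": -1.500,
        },
    },
    "RADA880108": {
        "description": "Mean polarity",
        "values": {
            "A": -0.060, "R": -0.840, "N": -0.480, "D": -0.800, "C": 1.360,
            "Q": -0.730, "E": -0.770, "G": -0.410, "H": 0.490, "I": 1.310,
            "L": 1.210, "K": -1.180, "M": 1.270, "F": 1.270, "P": 0.000,
            "S": -0.500, "T": -0.270, "W": 0.880, "Y": 0.330, "V": 1.090,
        },
    },
    "ZIMJ680104": {
        "description": "Isoelectric point",
        "values": {
            "A": 6.000, "R": 10.760, "N": 5.410, "D": 2.770, "C": 5.050,
            "Q": 5.650, "E": 3.220, "G": 5.970, "H": 7.590, "I": 6.020,
            "L": 5.980, "K": 9.740, "M": 5.740, "F": 5.480, "P": 6.300,
            "S": 5.680, "T": 5.660, "W": 5.890, "Y": 5.660, "V": 5.960,
        },
    },
    "MCMT640101": {
        "description": "Refractivity",
        "values": {
            "A": 4.340, "R": 26.660, "N": 13.280, "D": 12.000, "C": 35.770,
            "Q": 17.560, "E": 17.260, "G": 0.000, "H": 21.810, "I": 19.060,
            "L": 18.780, "K": 21.290, "M": 21.640, "F": 29.400, "P": 10.930,
            "S": 6.350, "T": 11.010, "W": 42.530, "Y": 31.530, "V": 13.920,
        },
    },
    "BHAR880101": {
        "description": "Average flexibility indices",
        "values": {
            "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346,
            "Q": 0.493, "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462,
            "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314, "P": 0.509,
            "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.420, "V": 0.386,
        },
    },
    "CHOC750101": {
        "description": "Average volume of buried residue",
        "values": {
            "A": 91.500, "R": 202.100, "N": 135.200, "D": 124.500, "C": 117.700,
            "Q": 161.100, "E": 155.100, "G": 66.400, "H": 167.300, "I": 168.800,
            "L": 167.900, "K": 171.300, "M": 170.800, "F": 203.400, "P": 129.300,
            "S": 99.100, "T": 122.100, "W": 237.600, "Y": 203.600, "V": 141.700,
        },
    },
    "COSI940101": {
        "description": "Electron-ion interaction potential values",
        "values": {
            "A": 0.0373, "R": 0.0959, "N": 0.0036, "D": 0.1263, "C": 0.0829,
            "Q": 0.0761, "E": 0.0058, "G": 0.0050, "H": 0.0242, "I": 0.0000,
            "L": 0.0000, "K": 0.0371, "M": 0.0823, "F": 0.0946, "P": 0.0198,
            "S": 0.0829, "T": 0.0941, "W": 0.0548, "Y": 0.0516, "V": 0.0057,
        },
    },
}
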