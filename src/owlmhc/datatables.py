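"""Physicochemical data tables for the 20 proteinogenic amino acids.

Two tables are shipped:

* ``GRANTHAM_PROPERTIES`` — Grantham's (1974) side-chain composition,
  polarity and molecular volume, the inputs of the Grantham distance
  D(a, b) = rho * [alpha*(c_a-c_b)^2 + beta*(p_a-p_b)^2 + gamma*(v_a-v_b)^2]^(1/2)
  with alpha=1.833, beta=0.1018, gamma=0.000399 and rho normalising the
  mean over the 190 unordered residue pairs to 100.

* ``Z_SCALES`` — the five z-scale descriptors (z1 hydrophilicity,
  z2 steric bulk/polarisability, z3 polarity, z4/z5 electronic properties)
  of Sandberg et al. (1998), the "five physicochemical metrics" used to
  describe peptide-binding residues when clustering MHC alleles into
  supertypes.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# residue -> (composition c, polarity p, molecular volume v)
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "A": (0.0, 8.1, 31.0),
    "R": (0.65, 10.5, 124.0),
    "N": (1.33, 11.6, 56.0),
    "D": (1.38, 13.0, 54.0),
    "C": (2.75, 5.5, 55.0),
    "Q": (0.89, 10.5, 85.0),
    "E": (0.92, 12.3, 83.0),
    "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0),
    "I": (0.0, 5.2, 111.0),
    "L": (0.0, 4.9, 111.0),
    "K": (0.33, 11.3, 119.0),
    "M": (0.0, 5.7, 105.0),
    "F": (0.0, 5.2, 132.0),
    "P": (0.39, 8.0, 32.5),
    "S": (1.42, 9.2, 32.0),
    "T": (0.71, 8.6, 61.0),
    "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0),
    "V": (0.0, 5.9, 84.0),
}

GRANTHAM_ALPHA = 1.833
GRANTHAM_BETA = 0.1018
GRANTHAM_GAMMA = 0.000399

# residue -> (z1, z2, z3, z4, z5); Sandberg et al. 1998, J Med Chem 41:2481
Z_SCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}
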