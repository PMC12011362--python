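"""Physicochemical property tables for composition descriptors.

``CTD_GROUPS`` is the classic 13-attribute, 3-group residue partition used
by composition/transition/distribution descriptors: for each attribute the
20 standard residues are split into three disjoint classes (e.g. low /
medium / high hydrophobicity).  ``PAAC_*`` are the canonical property
scales (hydrophobicity, hydrophilicity, side-chain mass) used by
pseudo-amino-acid composition.
"""

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# attribute -> (group1, group2, group3); each a string of residue letters.
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

# classic pseudo-amino-acid-composition property triple
PAAC_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

PAAC_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

PAAC_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

# UniProt-like background residue frequencies (approximate Swiss-Prot
# composition), an alternative to the uniform default of the generator.
UNIPROT_FREQUENCIES = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0707, "H": 0.0228, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}
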