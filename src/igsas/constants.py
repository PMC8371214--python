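"""Physical and compositional constants.

Masses are monoisotopic residue masses in Da (the residue is the monomer
minus water, i.e. as incorporated in the chain).  Solvent reference values
are standard water at 20 degC.
"""

from __future__ import annotations

# --- amino acids, one-letter codes -> monoisotopic residue mass (Da) ---
AMINO_ACID_MASS: dict[str, float] = {
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

# --- glycan residue classes -> monoisotopic residue mass (Da) ---
# Hex = C6H10O5, HexNAc = C8H13NO5, NeuNAc = C11H17NO8, dHex = C6H10O4
GLYCAN_RESIDUE_MASS: dict[str, float] = {
    "Hex": 162.05282,
    "HexNAc": 203.07937,
    "NeuNAc": 291.09542,
    "dHex": 146.05791,
}

#: common monosaccharide names mapped onto their residue class
GLYCAN_SYNONYMS: dict[str, str] = {
    "Gal": "Hex",
    "Man": "Hex",
    "Glc": "Hex",
    "GlcNAc": "HexNAc",
    "GalNAc": "HexNAc",
    "Fuc": "dHex",
    "Sia": "NeuNAc",
}

# --- approximate residue volumes (nm^3), used for bookkeeping only ---
MEAN_AA_VOLUME_NM3 = 0.134
MEAN_GLYCAN_VOLUME_NM3 = 0.200

# --- solvent reference: water at 20 degC ---
RHO_20W = 0.99823      # g/ml
ETA_20W = 0.010019     # poise
AVOGADRO = 6.02214076e23

#: default partial specific volume for a glycosylated IgG (ml/g)
VBAR_IGG = 0.776

#: Calpha-Calpha virtual bond length of the one-bead-per-residue chain (nm)
VIRTUAL_BOND_NM = 0.365

#: default non-bonded excluded-volume cutoff between bead centers (nm)
CLASH_CUTOFF_NM = 0.35

#: IgG3 upper-hinge pattern with repeat notation (expands to 70 residues)
IGG3_HINGE_PATTERN = "ELKTPLGDTTHTCPRCP(EPKSCDTPPPCPRCP)3APELLGGP"

#: IgG1-like short hinge used by the compact control geometry
IGG1_HINGE_PATTERN = "EPKSCDKTHTCPPCP"

#: offset between continuous numbering and EU numbering in the hinge/Fc
#: (Asn344 continuous = Asn297 EU)
EU_OFFSET = -47
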