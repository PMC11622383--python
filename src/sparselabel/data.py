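"""Bundled physical constants and example sequences.

Isotope masses and abundances are the IUPAC 2013 recommended values
(Meija et al., Pure Appl. Chem. 88, 2016), truncated to seven decimal
places so that test expectations are bit-stable.  The two pseudo-elements
``C13label`` and ``N15label`` represent enforced sparse labels: a single
isotope at 100% abundance, so convolving them into a pattern is a pure
mass shift.
"""

from __future__ import annotations

# proton mass used for all m/z conversions (Da)
PROTON_MASS = 1.00727646

# monoisotopic mass of water (H2 O16), from the table below
WATER_MASS = 2 * 1.0078250 + 15.9949146

# mass added per enforced label (Da)
C13_SHIFT = 13.0033548 - 12.0  # = 1.0033548
N15_SHIFT = 15.0001089 - 14.0030740  # = 0.9970349

#: element -> ordered list of (isotope mass Da, abundance fraction)
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250, 0.999885), (2.0141018, 0.000115)],
    "C": [(12.0000000, 0.9893), (13.0033548, 0.0107)],
    "N": [(14.0030740, 0.99636), (15.0001089, 0.00364)],
    "O": [(15.9949146, 0.99757), (16.9991317, 0.00038), (17.9991610, 0.00205)],
    "S": [
        (31.9720710, 0.9499),
        (32.9714588, 0.0075),
        (33.9678669, 0.0425),
        (35.9670808, 0.0001),
    ],
    # enforced-label pseudo-elements: one isotope, unit abundance
    "C13label": [(13.0033548, 1.0)],
    "N15label": [(15.0001089, 1.0)],
}

#: residue (= amino acid minus water) elemental formulas, one-letter codes
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

#: GFP-CD16a fusion construct used as the bundled example protein
GFP_CD16A = (
    "MHHHHHHHHMSGLNDIFEAQKIEWHEMSKGEELFTGVVPILVELDGDVNGHKFSVRGEGEGDATNGK"
    "LTLKFICTTGKLPVPWPTLVTTLTYGVQCFSRYPDHMKRHDFFKSAMPEGYVQERTISFKDDGTYKT"
    "RAEVKFEGDTLVNRIELKGIDFKEDGNILGHKLEYNFNSHNVYITADKQKNGIKANFKIRHNVEDGS"
    "VQLADHYQQNTPIGDGPVLLPDNHYLSTQSVLSKDPNEKRDHMVLLEFVTAAGITHGEFSSENLYFQ"
    "GRTEDLPKAVVFLEPQWYRVLEKDSVTLKCQGAYSPEDNSTQWFHNESLISSQASSYFIDAATVDDS"
    "GEYRCQTNLSTLSDPVQLEVHIGWLLLQAPRWVFKEEDPIHLRCHSWKNTALHKVTYLQNGKGRKYF"
    "HHNSDFYIPKATLKDSGSYFCRGLVGSKNVSSETVNITITQG"
)

#: Val/Ile/Leu labeling rules: [15N,13C5]-Val, 15N-Ile, 15N-Leu
VIL_SCHEME = {
    "V": {"n15N": 1, "n13C": 5, "units": [1, 5]},
    "I": {"n15N": 1, "n13C": 0, "units": [1]},
    "L": {"n15N": 1, "n13C": 0, "units": [1]},
}

#: Lys/Gly/Ser labeling rules: 15N-Lys (one retained 15N; the second
#: amino nitrogen exchanges quantitatively), [15N,13C2]-Gly, 15N-Ser
KGS_SCHEME = {
    "K": {"n15N": 1, "n13C": 0, "units": [1]},
    "G": {"n15N": 1, "n13C": 2, "units": [1, 2]},
    "S": {"n15N": 1, "n13C": 0, "units": [1]},
}
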