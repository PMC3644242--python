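"""Shared domain-model constants for the AP2/ERF superfamily pipeline.

The AP2 DNA-binding domain is described on a fixed 58-position coordinate
system anchored to the AtERF1 three-dimensional structure: structural
positions 145-202, with an optional insertion slot ("167i") between
positions 167 and 168 that is occupied only in ERF group IX (giving that
group a 59-residue domain).  Internally the position-specific model uses
1-based model positions 1..58; ``PAPER_OFFSET`` converts between the two
(structural = model + 144).
"""

from __future__ import annotations

PAPER_OFFSET = 144          # structural position = model position + 144
MODEL_LENGTH = 58
FIRST_POSITION = 145
LAST_POSITION = 202
INSERTION_AFTER = 167       # the "167i" slot sits between 167 and 168
INSERTION_KEY = "167i"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# 58-residue consensus scaffold for the single-AP2 (ERF-type) domain.
# Index 0 is structural position 145.  It carries the YRG element
# (146-148), the WLG motif (172-174), the RAYD element (183-186) and the
# ten residues invariant across all ERF groups (see UNIVERSAL_RESIDUES).
# Positions 158/163 default to the A/D (ERF-subfamily) state; DREB-type
# groups override them to V/E.
AP2_SCAFFOLD = "AYRGVRQRTWGKWAAEIRDPHNGSRTFWLGAFTAEEAARAYDVAAREYDSGLNFADST"
assert len(AP2_SCAFFOLD) == MODEL_LENGTH

def scaffold_residue(position: int) -> str:
    """Scaffold residue at a structural position (145..202)."""
    return AP2_SCAFFOLD[position - FIRST_POSITION]

# Residues totally conserved in every ERF group (structural numbering).
UNIVERSAL_RESIDUES = {
    148: "G", 150: "R", 152: "R", 155: "G", 160: "E",
    161: "I", 172: "W", 173: "L", 174: "G", 182: "A",
}

# DREB/ERF subfamily diagnostics at positions 158 and 163.
DREB_DIAGNOSTIC = {158: "V", 163: "E"}   # Nakano groups I-IV (Sakuma A)
ERF_DIAGNOSTIC = {158: "A", 163: "D"}    # Nakano groups V-X (Sakuma B)

ERF_GROUPS = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "VI-L"]
DREB_GROUPS = {"I", "II", "III", "IV"}

# Group-diagnostic residues: structural deviations from the scaffold that
# are conserved within one group (or one family) and absent from the
# background.  Group IX is marked by occupancy of the 167i insertion slot
# instead of a substitution.
GROUP_MARKERS: dict[str, list[tuple[int | str, str]]] = {
    "AP2": [(150, "T"), (150, "A")],   # split ~92/8 within the AP2 family
    "I": [(168, "R")],
    "II": [(175, "S"), (176, "Y")],
    "III": [(181, "M")],
    "IV": [(168, "G")],
    "V": [(168, "K")],
    "VI": [(153, "P")],
    "VI-L": [(189, "K"), (196, "M")],
    "VII": [(149, "I"), (168, "G"), (169, "V")],
    "VIII": [(153, "P"), (168, "K")],
    "IX": [(INSERTION_KEY, "X")],      # +X167: one extra residue after 167
    "X": [(168, "A")],
    "RAV": [(150, "V")],
}

# Positions that carry any group/family marker substitution.
MARKER_POSITIONS = {149, 150, 153, 168, 169, 175, 176, 181, 189, 196}
SUBFAMILY_POSITIONS = {158, 163}

# KREYD (group VI-L hallmark) is K189 followed by the scaffold's own
# R190-E191-Y192-D193; VI-L domains never vary over 189-196.
VI_L_FROZEN = {189, 190, 191, 192, 193, 196}

# Positions free to drift in the synthetic cohort: everything that is not
# a universal residue, a subfamily diagnostic or a marker position.
VARIABLE_POSITIONS = sorted(
    p for p in range(FIRST_POSITION, LAST_POSITION + 1)
    if p not in UNIVERSAL_RESIDUES
    and p not in SUBFAMILY_POSITIONS
    and p not in MARKER_POSITIONS
)

# AP2-family signature: positions where double-domain (AP2 family) repeats
# drift away from the ERF scaffold in ~85% of members.  Kept below the 90%
# marker-discovery threshold so that T150/A150 remains the family's only
# reported marker, while giving the homology override several informative
# columns instead of one.
AP2_SIGNATURE = {156: "E", 162: "K", 170: "S", 178: "V", 194: "A", 199: "S"}
AP2_SIGNATURE_RATE = 0.85

_MARKER_RESIDUES_BY_POS: dict[int | str, set[str]] = {}
for _entries in GROUP_MARKERS.values():
    for _pos, _res in _entries:
        _MARKER_RESIDUES_BY_POS.setdefault(_pos, set()).add(_res)


def alternative_residue(position: int) -> str:
    """Deterministic minor-allele residue for a structural position.

    Chosen to collide with neither the scaffold residue nor any marker or
    signature residue defined at that position.
    """
    excluded = {scaffold_residue(position)}
    excluded |= _MARKER_RESIDUES_BY_POS.get(position, set())
    if position in AP2_SIGNATURE:
        excluded.add(AP2_SIGNATURE[position])
    excluded.update(DREB_DIAGNOSTIC.get(position, ""), ERF_DIAGNOSTIC.get(position, ""))
    for aa in "NQHKESTVLFADGIMPRWYC":
        if aa not in excluded:
            return aa
    raise RuntimeError("no alternative residue available")  # pragma: no cover


# Soloist domains miss six consecutive residues, including R152.
SOLOIST_DELETION = list(range(149, 155))

# Synthetic B3 domain consensus (invented scaffold; the RAV family is
# defined by one AP2 plus one B3 domain).
B3_SCAFFOLD = "GMKSWEDVTAYFNRPLSEGDRIVMQGHKLPNFAESTVKWRDCLIGEYSAT"

# Nakano group -> Sakuma subfamily/subgroup band (Table 6 layout).
SAKUMA_BANDS = {
    **{g: ("DREB", "A-1 to A-6") for g in ["I", "II", "III", "IV"]},
    **{g: ("ERF", "B-1 to B-6") for g in ["V", "VI", "VII", "VIII", "IX", "X"]},
    "VI-L": ("ERF", "B-6"),
    "Xb-L": ("ERF", "B-6"),
}

# Nakano subgroup letters carried by the reference panel (labels only,
# never inferred from sequence).
GROUP_SUBGROUPS = {
    "I": ["a", "b"], "II": ["a", "b"], "III": ["b", "c", "d", "e"],
    "IV": ["a"], "V": ["a", "b"], "VI": [""], "VII": ["a"],
    "VIII": ["a", "b"], "IX": ["a", "b", "c"], "X": ["a"], "VI-L": [""],
}

# Default tissue libraries and read-share weights (five 454 libraries).
DEFAULT_TISSUE_WEIGHTS = {
    "root": 0.298,
    "bark": 0.222,
    "latex": 0.212,
    "embryogenic": 0.164,
    "leaf": 0.104,
}

MOTIFS = ("YRG", "WLG", "RAYD", "KREYD")
EAR_PATTERN = r"[LF]DLN[LF].P"   # ERF-associated amphiphilic repression motif
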