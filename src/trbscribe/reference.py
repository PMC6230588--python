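"""Reference profiles: V-domain template with IMGT-style numbering, gene
structure constants shared by the annotator and the synthetic generator.

The V-domain template is a synthetic but structurally canonical TRBV
V-REGION: 96 residues spanning IMGT positions 1-104 with the four conserved
anchors (1st-CYS 23, CONSERVED-TRP 41, hydrophobic 89, 2nd-CYS 104), an
8-residue CDR1-IMGT (positions 27-30 / 35-38) and a 6-residue CDR2-IMGT
(positions 56-58 / 63-65).  Gaps inside the CDR intervals follow the IMGT
middle-out convention: a CDR of length L fills the first ceil(L/2) and the
last floor(L/2) positions of its interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# V-domain template

TEMPLATE_FR1 = "DAGVTQTPRHLIKTRGQQVTLRCSPI"        # IMGT 1-26, C at 23
TEMPLATE_CDR1 = "SGHRSNFS"                          # 8 aa -> 27-30, 35-38
TEMPLATE_FR2 = "YQWYRQILGQGPEFLTY"                  # IMGT 39-55, W at 41
TEMPLATE_CDR2 = "FQNEAQ"                            # 6 aa -> 56-58, 63-65
TEMPLATE_FR3 = "LEKSRLLSDRFSAERPKGSFSTLVEIQRTEQGDSAMYLC"  # IMGT 66-104

TEMPLATE_V_AA = TEMPLATE_FR1 + TEMPLATE_CDR1 + TEMPLATE_FR2 + TEMPLATE_CDR2 + TEMPLATE_FR3

CDR1_INTERVAL = (27, 38)
CDR2_INTERVAL = (56, 65)
CDR3_INTERVAL = (105, 117)

ANCHOR_POSITIONS = {"cys23": 23, "trp41": 41, "hydrophobic89": 89, "cys104": 104}
HYDROPHOBIC = set("VILFMAWY")


def imgt_region_positions(lo: int, hi: int, length: int) -> List[int]:
    """IMGT positions occupied by a CDR of *length* residues in [lo, hi].

    Middle-out gapping: the first ceil(L/2) positions from the start and the
    last floor(L/2) from the end of the interval are used.
    """
    width = hi - lo + 1
    if length > width:
        raise ValueError(f"CDR length {length} exceeds interval {lo}-{hi}")
    front = math.ceil(length / 2)
    back = length - front
    return list(range(lo, lo + front)) + list(range(hi - back + 1, hi + 1))


def template_imgt_positions(cdr1_len: int = 8, cdr2_len: int = 6) -> List[int]:
    """IMGT position of each residue of a V region with the given CDR lengths."""
    pos = list(range(1, 27))
    pos += imgt_region_positions(*CDR1_INTERVAL, cdr1_len)
    pos += list(range(39, 56))
    pos += imgt_region_positions(*CDR2_INTERVAL, cdr2_len)
    pos += list(range(66, 105))
    return pos


TEMPLATE_IMGT_POSITIONS = template_imgt_positions()
assert len(TEMPLATE_IMGT_POSITIONS) == len(TEMPLATE_V_AA) == 96

# ---------------------------------------------------------------------------
# Gene structure constants (shared grammar of generator and annotator)

L_PART1_LEN = 48          # leader exon, starts ATG, full codons
L_PART2_LEN = 12          # leader tail on the V exon
V_INTRON_LEN = 90
V_REGION_NT = 3 * len(TEMPLATE_V_AA)          # 288
V_TAIL_NT = "GCCAGCAGC"   # germline-encoded CDR3 start (A-S-S, IMGT 105-107)
V_EXON_LEN = L_PART2_LEN + V_REGION_NT + len(V_TAIL_NT)   # 309

DONOR_MOTIF = "GTAAGT"
ACCEPTOR_MOTIF = "TTTCAG"   # pyrimidine tract + AG

LEADER_AA = "MGSRLLCWVLLCLLGA"   # 16 codons = 48 nt

# Default synthetic TRBD sequences.  Lengths follow the pig genes (14, 17,
# 16 nt, G-rich, glycine-encoding in every frame); the three sequences use
# disjoint 4-mer vocabularies so that a >=5-nt junction match identifies its
# source D unambiguously (the identifiability margin of the generator, the
# same philosophy as generating subgroup founders below 70% identity).
DEFAULT_D_SEQS = ("GGGAGGGAGGGAGG", "GGCGGCGGCGGCGGCGG", "GGTGGTGGTGGTGGTG")

J_FGXG_TAIL_LEN = 33      # FGXG (12 nt) + 7 codons of J tail
J_HEAD_CHOICES = (12, 15, 18)   # CDR3-side head lengths -> J coding 45/48/51 nt

C_EXON_LENS = (387, 45, 84, 15)   # 531 nt coding, 177 aa
C_INTRON_LEN = 90

STANDARD_CODONS: Dict[str, Tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"), "E": ("GAA", "GAG"), "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",), "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"), "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",), "Y": ("TAT", "TAC"),
}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def back_translate(aa: str, rng: np.random.Generator) -> str:
    """Random codon choice per residue."""
    return "".join(STANDARD_CODONS[a][rng.integers(len(STANDARD_CODONS[a]))] for a in aa)


def _reference_c_sequence() -> Tuple[str, ...]:
    """Deterministic reference TRBC exon sequences (synthetic)."""
    rng = np.random.default_rng(20181105)
    aa_len = sum(C_EXON_LENS) // 3
    aa = "".join(AA_ALPHABET[rng.integers(20)] for _ in range(aa_len))
    nt = back_translate(aa, rng)
    exons, off = [], 0
    for ln in C_EXON_LENS:
        exons.append(nt[off : off + ln])
        off += ln
    return tuple(exons)


REFERENCE_C_EXONS = _reference_c_sequence()


@dataclass
class ReferenceProfile:
    """Expected exon lengths, motifs and the numbered V template used by the
    annotator to parse gene structure and by ``number_v_domain`` to anchor
    IMGT positions."""

    template_aa: str = TEMPLATE_V_AA
    template_positions: Sequence[int] = field(
        default_factory=lambda: list(TEMPLATE_IMGT_POSITIONS)
    )
    l_part1_len: int = L_PART1_LEN
    l_part2_len: int = L_PART2_LEN
    v_intron_len: int = V_INTRON_LEN
    v_exon_len: int = V_EXON_LEN
    v_tail_nt: str = V_TAIL_NT
    donor_motif: str = DONOR_MOTIF
    acceptor_motif: str = ACCEPTOR_MOTIF
    c_exons: Tuple[str, ...] = REFERENCE_C_EXONS
    c_intron_len: int = C_INTRON_LEN
    d_len_range: Tuple[int, int] = (10, 25)
    j_len_range: Tuple[int, int] = (40, 60)
    # fractional tolerance on the V-exon length before rule (d) fires
    v_len_tolerance: float = 0.10


DEFAULT_PROFILE = ReferenceProfile()
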