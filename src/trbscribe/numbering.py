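"""IMGT-style unique numbering of translated V domains.

A query V-REGION peptide is aligned globally to the packaged numbered
template and every residue inherits the IMGT position of its template
column.  The four V-domain anchors (1st-CYS 23, CONSERVED-TRP 41,
hydrophobic 89, 2nd-CYS 104) are then read off the mapping, and the
CDR1/CDR2 intervals are derived from it.  A missing 2nd-CYS makes the
domain unanchorable (CDR3 cannot be located) and raises; any other absent
anchor is reported as a defect, mirroring in-frame pseudogenes that have
lost 1st-CYS only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align

from .reference import (
    ANCHOR_POSITIONS,
    CDR1_INTERVAL,
    CDR2_INTERVAL,
    HYDROPHOBIC,
    ReferenceProfile,
    DEFAULT_PROFILE,
)


@dataclass
class NumberedVDomain:
    """Per-residue IMGT numbering of a translated V region."""

    peptide: str
    positions: List[Optional[int]]      # IMGT position per residue (None = unplaced)
    anchors: Dict[str, Optional[int]]   # anchor name -> residue index (0-based)
    anchor_defects: List[str] = field(default_factory=list)

    def index_of_position(self, imgt_pos: int) -> Optional[int]:
        try:
            return self.positions.index(imgt_pos)
        except ValueError:
            return None

    def cdr_interval(self, which: int) -> Tuple[int, int]:
        """0-based half-open residue interval of CDR1 or CDR2."""
        lo, hi = {1: CDR1_INTERVAL, 2: CDR2_INTERVAL}[which]
        idx = [i for i, p in enumerate(self.positions) if p is not None and lo <= p <= hi]
        if not idx:
            return (0, 0)
        return (min(idx), max(idx) + 1)

    def cdr_length(self, which: int) -> int:
        a, b = self.cdr_interval(which)
        return b - a


def _aa_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -1.0
    return aligner


def number_v_domain(
    v_aa: str,
    profile: ReferenceProfile = DEFAULT_PROFILE,
    partial: bool = False,
) -> NumberedVDomain:
    """Number a translated V region against the reference template.

    Raises ``ValueError("unanchored domain")`` when the 2nd-CYS (position
    104) cannot be located; clones hitting this are flagged and excluded
    from CDR3 statistics downstream.
    """
    v_aa = v_aa.upper()
    if not v_aa:
        raise ValueError("empty peptide")
    if len(v_aa) < 90 and not partial:
        raise ValueError(
            f"peptide of {len(v_aa)} aa is shorter than a complete V domain; "
            "pass partial=True to number a fragment"
        )
    geometric = _geometric_numbering(v_aa, profile)
    if geometric is not None:
        return geometric
    aln = _aa_aligner().align(v_aa, profile.template_aa)[0]
    gq, gt = str(aln[0]), str(aln[1])
    positions: List[Optional[int]] = []
    ti = 0
    qi = 0
    tmpl_pos = list(profile.template_positions)
    for cq, ct in zip(gq, gt):
        if cq != "-" and ct != "-":
            positions.append(tmpl_pos[ti])
            qi += 1
            ti += 1
        elif cq != "-":
            positions.append(None)   # insertion relative to template (CDR expansion)
            qi += 1
        else:
            ti += 1
    # CDR insertions: fill unplaced runs flanked by CDR positions middle-out
    _fill_cdr_insertions(positions)

    anchors: Dict[str, Optional[int]] = {}
    defects: List[str] = []
    checks = {
        "cys23": ("C",),
        "trp41": ("W",),
        "hydrophobic89": tuple(HYDROPHOBIC),
        "cys104": ("C",),
    }
    for key, allowed in checks.items():
        pos = ANCHOR_POSITIONS[key]
        idx = None
        for i, p in enumerate(positions):
            if p == pos:
                idx = i
                break
        if idx is None or v_aa[idx] not in allowed:
            anchors[key] = idx
            defects.append(key)
        else:
            anchors[key] = idx
    if "cys104" in defects:
        raise ValueError("unanchored domain: 2nd-CYS (position 104) not found")
    dom = NumberedVDomain(v_aa, positions, anchors, defects)
    # anchors must be strictly increasing where present
    placed = [anchors[k] for k in ("cys23", "trp41", "hydrophobic89", "cys104")
              if anchors[k] is not None]
    if placed != sorted(placed):
        raise ValueError("anchor order violated")
    return dom


def _geometric_numbering(v_aa: str, profile: ReferenceProfile) -> Optional[NumberedVDomain]:
    """Number a full-length domain from the profile's fixed FR geometry.

    With FR1/FR2/FR3 lengths fixed by the profile (26/17/39 residues), only
    the CDR1/CDR2 lengths vary; every candidate split is scored by anchor
    correctness plus FR2 similarity to the template, and the numbering is
    accepted only when all four anchors check out.  Domains with indels in
    the frameworks fall through to the alignment path.
    """
    from .reference import imgt_region_positions

    fr1, fr2, fr3 = 26, 17, 39
    total_cdr = len(v_aa) - fr1 - fr2 - fr3
    if not (2 <= total_cdr <= 22):
        return None
    if v_aa[22] != "C" or v_aa[-1] != "C":
        return None
    if v_aa[len(v_aa) - fr3 + 23] not in HYDROPHOBIC:
        return None
    tmpl_fr2 = profile.template_aa[34:51] if len(profile.template_aa) == 96 else None
    best = None
    for L1 in range(max(1, total_cdr - 10), min(12, total_cdr - 1) + 1):
        L2 = total_cdr - L1
        if not (1 <= L2 <= 10):
            continue
        w_idx = fr1 + L1 + 2
        if v_aa[w_idx] != "W":
            continue
        fr2_seg = v_aa[fr1 + L1 : fr1 + L1 + fr2]
        sim = sum(a == b for a, b in zip(fr2_seg, tmpl_fr2)) if tmpl_fr2 else 0
        if best is None or sim > best[0]:
            best = (sim, L1, L2)
    if best is None:
        return None
    _, L1, L2 = best
    positions: List[Optional[int]] = list(range(1, 27))
    positions += imgt_region_positions(*CDR1_INTERVAL, min(L1, 12))
    positions += list(range(39, 56))
    positions += imgt_region_positions(*CDR2_INTERVAL, min(L2, 10))
    positions += list(range(66, 105))
    anchors = {
        "cys23": 22,
        "trp41": 26 + L1 + 2,
        "hydrophobic89": len(v_aa) - fr3 + 23,
        "cys104": len(v_aa) - 1,
    }
    return NumberedVDomain(v_aa, positions, anchors, [])


def _fill_cdr_insertions(positions: List[Optional[int]]) -> None:
    """Leave insertions unplaced but bounded: residues between two numbered
    CDR-interval positions stay None (extra loop residues beyond the
    template's CDR length have no integer IMGT position of their own)."""
    # nothing to renumber: the surrounding interval already delimits the CDR
    return
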