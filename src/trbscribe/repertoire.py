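"""Expressed-clone analysis: V/J assignment, CDR3 extraction, TRBD calling
and D-J-C rearrangement topology, plus usage matrices and CDR3 statistics.

The CDR3 is the peptide strictly between the conserved 2nd-CYS (IMGT
position 104) of the V gene and the phenylalanine of the J gene's FGXG
motif, both anchors excluded.  A junction stretch is attributed to a TRBD
gene when at least ``min_d_len`` (default 5) consecutive nucleotides match
the germline D; the longest match wins, equal-length matches to several D
genes form an unresolved ambiguity set, and two disjoint matches to
different D genes flag a double-D junction.

Rearrangement topology is read off the locus map's 5'-to-3' cluster order
(pig: 1, 3, 2): same cluster = intra, D strictly upstream of J = inter
(direct 5'-to-3' joining across clusters), D downstream of J = trans
(inversion or trans-rearrangement).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .germline import LocusMap
from .identity import AlleleAssignment, assign_allele, pairwise_identity
from .numbering import NumberedVDomain, number_v_domain   # re-exported surface
from .reference import DEFAULT_PROFILE, ReferenceProfile

__all__ = [
    "NumberedVDomain", "number_v_domain", "DCall", "RepertoireClone",
    "UsageMatrix", "VAssignment", "JAssignment", "call_d",
    "classify_rearrangement", "extract_cdr3", "assign_v", "assign_j",
    "analyze_clone", "analyze_repertoire", "usage_matrix", "cdr3_stats",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# TRBD calling

@dataclass(frozen=True)
class DCall:
    """Outcome of TRBD identification in a junction.

    ``status``: 'unique' | 'ambiguous' | 'two-D' | 'none'.
    ``genes`` holds the D names involved (the ambiguity set for
    'ambiguous', both genes for 'two-D'); ``primary`` is the gene with the
    longest match where one exists.
    """

    status: str
    genes: Tuple[str, ...]
    primary: Optional[str]
    match_len: int
    matched: str = ""
    offset: int = -1

    @property
    def is_unambiguous(self) -> bool:
        return self.status == "unique"


def _longest_common_substring(a: str, b: str) -> Tuple[int, int, int]:
    """(length, offset_in_a, offset_in_b) of the longest common substring,
    earliest occurrence on ties."""
    best = (0, -1, -1)
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best[0]:
                    best = (cur[j], i - cur[j], j - cur[j])
        prev = cur
    return best


def call_d(
    junction_nt: str,
    d_genes: Sequence[Tuple[str, str, int]],
    min_len: int = 5,
) -> DCall:
    """Identify the TRBD gene(s) contributing to a junction.

    *d_genes* is a sequence of (name, germline sequence, genomic cluster
    index).  The longest exact common substring of at least *min_len* nt
    decides; ties across genes give an unresolved set; two disjoint
    above-threshold matches to different genes report a double-D junction.
    """
    if not d_genes:
        raise ValueError("empty D gene set")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    junction_nt = junction_nt.upper()
    results = []
    for name, seq, _cluster in d_genes:
        ln, off_j, off_d = _longest_common_substring(junction_nt, seq.upper())
        results.append((name, ln, off_j, off_d))
    best_len = max(r[1] for r in results)
    if best_len < min_len:
        return DCall("none", (), None, best_len)
    winners = [r for r in results if r[1] == best_len]
    order = {name: k for k, (name, _, _) in enumerate(d_genes)}
    winners.sort(key=lambda r: order[r[0]])
    name, ln, off_j, _ = winners[0]
    matched = junction_nt[off_j : off_j + ln]
    if len(winners) > 1:
        return DCall("ambiguous", tuple(r[0] for r in winners), name, ln, matched, off_j)
    # double-D: a disjoint >=min_len match to a different gene
    win_iv = (off_j, off_j + ln)
    for other, oln, ooff, _ in sorted(results, key=lambda r: -r[1]):
        if other == name or oln < min_len:
            continue
        left = junction_nt[: win_iv[0]]
        right = junction_nt[win_iv[1] :]
        for part, base in ((left, 0), (right, win_iv[1])):
            if len(part) >= min_len:
                pln, poff, _ = _longest_common_substring(part, dict(
                    (n, s) for n, s, _ in d_genes)[other].upper())
                if pln >= min_len:
                    return DCall("two-D", (name, other), name, ln, matched, off_j)
    return DCall("unique", (name,), name, ln, matched, off_j)


# ---------------------------------------------------------------------------
# Rearrangement topology

def classify_rearrangement(
    d_call: DCall,
    j_call: Optional[str],
    locus_map: LocusMap,
) -> str:
    """intra / inter / trans / undetermined for one clone.

    An ambiguous D call still classifies when every member of its set
    yields the same class.
    """
    if j_call is None or j_call in ("", "nd"):
        raise ValueError("J cluster unknown")
    order = list(locus_map.cluster_order_5to3)
    j_cluster = locus_map.cluster_of(j_call)
    gj = order.index(j_cluster)
    if d_call.status in ("none",):
        return "undetermined"
    genes = d_call.genes if d_call.status != "two-D" else d_call.genes
    classes = set()
    for d in genes:
        gd = order.index(locus_map.cluster_of(d))
        if gd == gj:
            classes.add("intra")
        elif gd < gj:
            classes.add("inter")
        else:
            classes.add("trans")
    return classes.pop() if len(classes) == 1 else "undetermined"


# ---------------------------------------------------------------------------
# V / J assignment on clones

@dataclass
class VAssignment:
    assignment: AlleleAssignment
    window: Tuple[int, int]        # clone span matching the germline V-REGION
    cdr3_start: int                # nt offset just after the codon at IMGT 104
    domain: Optional[NumberedVDomain] = None

    @property
    def gene(self) -> Optional[str]:
        return self.assignment.gene

    @property
    def identity(self) -> float:
        return self.assignment.percent_identity


@dataclass
class JAssignment:
    gene: Optional[str]            # None -> 'nd'
    f_start: int                   # nt offset of the FGXG phenylalanine codon
    distance: int = 0

    @property
    def call(self) -> str:
        return self.gene if self.gene else "nd"


def assign_v(
    clone_nt: str,
    germline_v: Sequence[Tuple[str, str]],
    gene_threshold: float = 97.0,
    positions: Optional[Dict[str, int]] = None,
    profile: ReferenceProfile = DEFAULT_PROFILE,
) -> VAssignment:
    """Locate and identify the V gene of a clone.

    Each germline V-REGION is searched in the clone (edlib infix
    alignment); near-best candidates are rescored with the exact
    global-alignment identity used for allele assignment; the 2nd-CYS is then
    anchored by IMGT numbering of the translated window.
    """
    clone_nt = clone_nt.upper()
    scored = []
    for name, seq in germline_v:
        res = edlib.align(seq.upper(), clone_nt, mode="HW", task="locations")
        scored.append((res["editDistance"], name, seq, res["locations"][0]))
    scored.sort(key=lambda t: t[0])
    best_d = scored[0][0]
    finalists = [s for s in scored if s[0] <= best_d + 3]
    results = []
    for dist, name, seq, loc in finalists:
        window = clone_nt[loc[0] : loc[1] + 1]
        pid = pairwise_identity(window, seq, "clone", name).percent_identity
        results.append((pid, name, loc))
    pos = positions or {n: i for i, (n, _) in enumerate(germline_v)}
    results.sort(key=lambda t: (-t[0], pos[t[1]]))
    best_pid, best_name, loc = results[0]
    ties = tuple(n for p, n, _ in results[1:] if p == best_pid)
    if best_pid == 100.0:
        status = "exact"
    elif best_pid > gene_threshold:
        status = "allele"
    else:
        status = "unassigned"
    assignment = AlleleAssignment(status, best_name, best_pid, ties)

    window_start, window_end = loc[0], loc[1] + 1
    aa_len = (window_end - window_start) // 3
    v_aa = str(Seq(clone_nt[window_start : window_start + 3 * aa_len]).translate())
    domain = None
    try:
        domain = number_v_domain(v_aa, profile, partial=True)
    except ValueError:
        domain = None
    # anchor the 2nd-CYS on the germline 3' end rather than the window
    # boundary: the V-REGION is never trimmed, so the last nucleotides of
    # the assigned germline end exactly at the 104 codon
    germ = dict(germline_v)[best_name].upper()
    tail30 = germ[-30:]
    lo = max(0, window_end - len(tail30) - 15)
    sub = clone_nt[lo : window_end + 15]
    res = edlib.align(tail30, sub, mode="HW", task="locations")
    cdr3_start = lo + res["locations"][0][1] + 1
    return VAssignment(assignment, (window_start, window_end), cdr3_start, domain)


def assign_j(
    clone_nt: str,
    germline_j: Sequence[Tuple[str, str, int]],
    search_from: int = 0,
    max_distance_frac: float = 0.25,
) -> JAssignment:
    """Identify the J gene from the clone's 3' region.

    *germline_j* entries are (name, coding sequence, head length); the head
    (CDR3-side) may be trimmed away in the clone, so the constant block
    downstream of the head anchors the FGXG position.
    """
    clone_nt = clone_nt.upper()
    region = clone_nt[search_from:]
    scored = []
    for name, coding, head_len in germline_j:
        res = edlib.align(coding.upper(), region, mode="HW", task="distance")
        scored.append((res["editDistance"], name, coding, head_len))
    scored.sort(key=lambda t: (t[0], t[1]))
    dist, name, coding, head_len = scored[0]
    if dist > max_distance_frac * len(coding):
        return JAssignment(None, -1, dist)
    block = coding[head_len:].upper()
    res = edlib.align(block, region, mode="HW", task="locations")
    f_start = search_from + res["locations"][0][0]
    return JAssignment(name, f_start, dist)


# ---------------------------------------------------------------------------
# CDR3 extraction

def extract_cdr3(
    clone_nt: str,
    v_assignment: VAssignment,
    j_assignment: JAssignment,
    inclusive: bool = False,
) -> Tuple[str, str, int]:
    """(junction_nt, cdr3_aa, cdr3_len) between the 104 and FGXG anchors.

    Both anchor residues are excluded by default; ``inclusive=True`` widens
    to the 104..F-118 junction convention for interoperability.
    """
    clone_nt = clone_nt.upper()
    start = v_assignment.cdr3_start
    f_start = j_assignment.f_start

    def fgxg_at(p: int) -> bool:
        aa = str(Seq(clone_nt[p : p + 12]).translate())
        return len(aa) == 4 and aa[0] == "F" and aa[1] == "G" and aa[3] == "G"

    # joint re-anchoring: edlib locations can slip a base or two at either
    # anchor when a substitution sits on an edge; accept the (CYS, FGXG)
    # candidate pair closest to the located anchors that is in frame
    cys_candidates = [
        p for p in range(max(3, start - 6), start + 7)
        if clone_nt[p - 3 : p] in ("TGT", "TGC")
    ] or [start]
    if f_start < 0:
        f_candidates = []
    else:
        f_candidates = [
            q for q in range(max(0, f_start - 4), f_start + 5) if fgxg_at(q)
        ]
    best = None
    for p in cys_candidates:
        for q in f_candidates:
            if q > p and (q - p) % 3 == 0:
                cost = abs(p - start) + abs(q - f_start)
                if best is None or cost < best[0]:
                    best = (cost, p, q)
    if best is None:
        # fall back: first in-frame FGXG downstream of the 2nd-CYS
        for p in cys_candidates:
            q = _find_fgxg(clone_nt, p)
            if q >= 0:
                best = (0, p, q)
                break
        if best is None:
            raise ValueError("motif not found: no FGXG downstream of the V region")
    _, start, f_start = best
    if inclusive:
        junction = clone_nt[start - 3 : f_start + 3]
    else:
        junction = clone_nt[start:f_start]
    cdr3_aa = str(Seq(junction).translate())
    if "*" in cdr3_aa:
        raise ValueError("stop codon inside CDR3")
    return junction, cdr3_aa, len(cdr3_aa)


def _find_fgxg(clone_nt: str, start: int) -> int:
    for p in range(start, len(clone_nt) - 11, 3):
        aa = str(Seq(clone_nt[p : p + 12]).translate())
        if len(aa) == 4 and aa[0] == "F" and aa[1] == "G" and aa[3] == "G":
            return p
    return -1


# ---------------------------------------------------------------------------
# Clone records and the end-to-end analyzer

@dataclass
class RepertoireClone:
    clone_id: str
    tissue: str
    v_call: Optional[str] = None
    v_identity: Optional[float] = None
    v_status: str = "unassigned"
    j_call: str = "nd"
    junction_nt: str = ""
    cdr3_aa: str = ""
    cdr3_len: Optional[int] = None
    d_call: Optional[DCall] = None
    rearrangement_class: str = "undetermined"
    errors: List[str] = field(default_factory=list)

    @property
    def d_call_label(self) -> str:
        d = self.d_call
        if d is None or d.status == "none":
            return "none"
        if d.status == "unique":
            return d.genes[0]
        if d.status == "ambiguous":
            return "unresolved{" + ",".join(d.genes) + "}"
        return "two-D{" + ",".join(d.genes) + "}"


def analyze_clone(
    clone_id: str,
    tissue: str,
    clone_nt: str,
    germline_v: Sequence[Tuple[str, str]],
    germline_j: Sequence[Tuple[str, str, int]],
    d_genes: Sequence[Tuple[str, str, int]],
    locus_map: LocusMap,
    min_d_len: int = 5,
    gene_threshold: float = 97.0,
) -> RepertoireClone:
    clone = RepertoireClone(clone_id, tissue)
    va = assign_v(clone_nt, germline_v, gene_threshold)
    clone.v_call = va.gene
    clone.v_identity = va.identity
    clone.v_status = va.assignment.status
    ja = assign_j(clone_nt, germline_j, search_from=max(0, va.window[1] - 6))
    clone.j_call = ja.call
    try:
        junction, cdr3_aa, cdr3_len = extract_cdr3(clone_nt, va, ja)
        clone.junction_nt = junction
        clone.cdr3_aa = cdr3_aa
        clone.cdr3_len = cdr3_len
    except ValueError as exc:
        clone.errors.append(str(exc))
        return clone
    clone.d_call = call_d(junction, d_genes, min_d_len)
    if ja.gene is not None:
        try:
            clone.rearrangement_class = classify_rearrangement(
                clone.d_call, ja.gene, locus_map
            )
        except (KeyError, ValueError) as exc:
            clone.errors.append(str(exc))
    return clone


def analyze_repertoire(
    records: Sequence[Tuple[str, str, str]],      # (clone_id, tissue, sequence)
    locus_map: LocusMap,
    v_regions: Optional[Sequence[Tuple[str, str]]] = None,
    j_codings: Optional[Sequence[Tuple[str, str, int]]] = None,
    min_d_len: int = 5,
    gene_threshold: float = 97.0,
) -> List[RepertoireClone]:
    """Run the full per-clone analysis against an annotated locus."""
    if v_regions is None:
        v_regions = [(g.name, g.v_region_nt) for g in locus_map.v_genes if g.v_region_nt]
    if j_codings is None:
        # head length unknown for annotated J genes: anchor FGXG by search
        j_codings = [
            (g.name, g.coding_nt, _head_len_of(g.coding_nt))
            for g in locus_map.j_genes if g.coding_nt
        ]
    d_genes = [
        (g.name, g.coding_nt, locus_map.cluster_order_5to3.index(g.cluster))
        for g in locus_map.d_genes
    ]
    return [
        analyze_clone(cid, tissue, seq, v_regions, j_codings, d_genes,
                      locus_map, min_d_len, gene_threshold)
        for cid, tissue, seq in records
    ]


def _head_len_of(j_coding: str) -> int:
    """Offset of the FGXG phenylalanine within a germline J coding region."""
    aa = str(Seq(j_coding[: 3 * (len(j_coding) // 3)]).translate())
    for i in range(len(aa) - 3):
        if aa[i] == "F" and aa[i + 1] == "G" and aa[i + 3] == "G":
            return 3 * i
    return max(0, len(j_coding) - 24)


# ---------------------------------------------------------------------------
# Usage matrices and CDR3 statistics

@dataclass
class UsageMatrix:
    """V-gene x J-gene count table with margins and per-row frequencies."""

    tissue: str
    counts: pd.DataFrame            # rows: V genes; columns: J genes + 'nd'

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    @property
    def relative_frequencies(self) -> pd.Series:
        total = self.grand_total
        if total == 0:
            return self.row_totals.astype(float)
        return self.row_totals.apply(lambda r: round_half_up(100.0 * r / total, 1))

    def with_margins(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["total"] = self.row_totals
        df.loc["Total"] = df.sum(axis=0)
        return df


def usage_matrix(
    clones: Sequence[RepertoireClone],
    tissue: Optional[str] = None,
    row_order: Optional[Sequence[str]] = None,
    col_order: Optional[Sequence[str]] = None,
) -> UsageMatrix:
    """Count V x J usage for one tissue; unrecognized J goes to 'nd'."""
    selected = [c for c in clones if tissue is None or c.tissue == tissue]
    rows = row_order or _first_seen([c.v_call or "unassigned" for c in selected])
    cols = col_order or (
        sorted({c.j_call for c in selected if c.j_call != "nd"}) + ["nd"]
    )
    if "nd" not in cols:
        cols = list(cols) + ["nd"]
    df = pd.DataFrame(0, index=list(rows), columns=list(cols), dtype=int)
    for c in selected:
        v = c.v_call or "unassigned"
        j = c.j_call if c.j_call in df.columns else "nd"
        if v not in df.index:
            df.loc[v] = 0
        df.loc[v, j] += 1
    return UsageMatrix(tissue or "all", df)


def _first_seen(items: Sequence[str]) -> List[str]:
    seen: Dict[str, None] = {}
    for x in items:
        seen.setdefault(x, None)
    return list(seen)


def cdr3_stats(
    clones: Sequence[RepertoireClone],
    tissue: Optional[str] = None,
) -> Dict[str, object]:
    """Mean (half-up, 1 decimal), range and histogram of CDR3 lengths.

    Clones whose CDR3 could not be extracted are excluded and counted."""
    selected = [c for c in clones if tissue is None or c.tissue == tissue]
    lengths = [c.cdr3_len for c in selected if c.cdr3_len is not None]
    failed = len(selected) - len(lengths)
    if not lengths:
        raise ValueError("no clone with an extractable CDR3")
    return {
        "mean": round_half_up(float(np.mean(lengths)), 1),
        "min": int(min(lengths)),
        "max": int(max(lengths)),
        "histogram": dict(sorted(Counter(lengths).items())),
        "n": len(lengths),
        "n_failed": failed,
    }
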