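"""Synthetic TRB locus and repertoire generation with known truth.

The generator emulates the pig-like TRB architecture: a library of V genes
(leader exon, GT..AG intron, V-REGION ending in the conserved 2nd-CYS,
23-spacer recombination signal) in subgroup families derived from founders,
upstream of tandem D-J-C clusters (D with 12/23 signals, J with 12-signal,
FGXG-encoding cores and donor splice sites, C with four exons), optionally
followed by a single inverted V gene.  Designated pseudogenes carry planted
lesions drawn from the functionality rules: missing leader (a), broken
splice (c), wrong coding length (d), stop codon or frameshift (e).

Identifiability margins (documented design choices, not biology):

* subgroup founders are regenerated until every cross-subgroup identity is
  below 70%, so the >75% subgroup criterion is unambiguous on truth;
* the default D genes use disjoint 4-mer vocabularies so a >=5-nt junction
  match names its source D uniquely;
* random segments are screened against chance recombination-signal hits at
  the annotator's discovery thresholds.

Rearranged repertoires are produced clone by clone: pick V, D and J
(respecting 5'-to-3' cluster feasibility, with a configurable
trans-rearrangement probability), trim ends geometrically, insert N
nucleotides, splice to C, apply point substitutions.  The truth table
records every choice, including the surviving D segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .germline import (
    AnnotationConfig,
    GermlineGene,
    LocusMap,
    _flip_gene,
    build_locus_map,
    classify_functionality,
    name_v_genes,
)
from .identity import SubgroupPartition
from .reference import (
    AA_ALPHABET,
    DEFAULT_D_SEQS,
    DEFAULT_PROFILE,
    J_FGXG_TAIL_LEN,
    J_HEAD_CHOICES,
    LEADER_AA,
    STANDARD_CODONS,
    TEMPLATE_CDR1,
    TEMPLATE_CDR2,
    TEMPLATE_FR1,
    TEMPLATE_FR2,
    TEMPLATE_FR3,
    ReferenceProfile,
    back_translate,
)
from .rss import HEPTAMER, NONAMER, RecombinationSignal, hamming_matches, revcomp, scan_rss

NT = "ACGT"


# ---------------------------------------------------------------------------
# Specs

@dataclass
class LocusSpec:
    """Parameters of a synthetic germline locus (pig-like defaults)."""

    n_v_genes: int = 38
    n_subgroups: int = 24
    intra_subgroup_identity: Tuple[float, float] = (0.92, 0.98)
    pseudogene_fraction: float = 12 / 38
    cluster_layout: Sequence[Tuple[int, int]] = ((7, 14), (7, 17), (6, 16))
    inverted_v: bool = True
    seed: int = 0
    subgroup_sizes: Optional[Sequence[int]] = None
    d_seqs: Optional[Sequence[str]] = None
    j_rss_defects: Sequence[Tuple[int, int]] = ((0, 3),)   # (cluster idx, J idx): TRBJ1-4-like
    cluster_label_order: Optional[Sequence[int]] = None
    founder_max_identity: float = 70.0
    substitution_rate: float = 0.0      # extra noise on the finished contig

    def validate(self) -> None:
        if self.n_subgroups > self.n_v_genes:
            raise ValueError("n_subgroups cannot exceed n_v_genes")
        if self.n_v_genes < 1 or not self.cluster_layout:
            raise ValueError("need at least one V gene and one cluster")
        for _, dlen in self.cluster_layout:
            if not (10 <= dlen <= 25):
                raise ValueError(f"D length {dlen} outside 10-25 nt")
        if not (0 <= self.pseudogene_fraction <= 1):
            raise ValueError("pseudogene_fraction outside [0, 1]")


@dataclass
class RepertoireSpec:
    """Parameters of a synthetic rearranged repertoire."""

    n_clones: int = 197
    tissues: Sequence[Tuple[str, float]] = (("PBL", 163 / 197), ("thymus", 34 / 197))
    trim_mean: float = 2.0          # geometric mean, per trimmed end
    n_addition_mean: float = 3.0    # geometric mean, per N region
    substitution_rate: float = 0.005
    trans_probability: float = 0.03
    v_bias: Optional[Dict[str, float]] = None
    j_bias: Optional[Dict[str, float]] = None
    include_pseudogene_v: bool = False
    productive_only: bool = True
    c_prefix_len: int = 60
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        for r in (self.substitution_rate, self.trans_probability):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if abs(sum(p for _, p in self.tissues) - 1.0) > 1e-9:
            raise ValueError("tissue proportions must sum to 1")


# ---------------------------------------------------------------------------
# Locus simulation

@dataclass
class SimulatedLocus:
    contig: str
    truth: LocusMap
    spec: LocusSpec
    partition: SubgroupPartition
    v_payload: Dict[str, dict] = field(default_factory=dict)   # name -> parts
    j_payload: Dict[str, dict] = field(default_factory=dict)
    d_payload: Dict[str, str] = field(default_factory=dict)
    c_payload: Dict[str, str] = field(default_factory=dict)

    def fasta(self, contig_id: str = "synthetic_locus") -> str:
        return f">{contig_id}\n" + "\n".join(
            self.contig[i : i + 70] for i in range(0, len(self.contig), 70)
        ) + "\n"


def _geom_lengths(rng: np.random.Generator, mean: float, n: int = 1) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=int)
    return rng.geometric(1.0 / (1.0 + mean), size=n) - 1


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, size=n))


def _screened_rand_nt(rng: np.random.Generator, n: int, config: AnnotationConfig) -> str:
    for _ in range(200):
        seg = _rand_nt(rng, n)
        if _rss_clean(seg, config):
            return seg
    raise RuntimeError("could not generate signal-free segment")


def _rss_clean(seg: str, config: AnnotationConfig) -> bool:
    """No chance recombination-signal hits at discovery thresholds."""
    for spacer in (12, 23):
        for orient in ("forward", "reverse"):
            if scan_rss(seg, spacer, config.discovery_min_heptamer,
                        config.discovery_min_nonamer, orient):
                return False
    return True


def _default_subgroup_sizes(n_v: int, n_sub: int) -> List[int]:
    if (n_v, n_sub) == (38, 24):
        return [5, 5, 3, 3, 2, 2] + [1] * 18   # pig-like expansion profile
    sizes = [1] * n_sub
    i = 0
    for _ in range(n_v - n_sub):
        sizes[i % n_sub] += 1
        i += 1
    return sizes


def _founder_aa(rng: np.random.Generator) -> Tuple[str, Dict[int, str]]:
    """Random V-region protein with the template layout and fixed anchors.

    Returns the protein and a map {residue index: required amino acid(s)}
    for the four conserved anchors, used to preserve them in members.
    """
    def mutate_fr(fr: str, keep: Dict[int, str]) -> str:
        out = []
        for i, a in enumerate(fr):
            if i in keep:
                out.append(keep[i])
            elif rng.random() < 0.25:
                out.append(AA_ALPHABET[rng.integers(20)])
            else:
                out.append(a)
        return "".join(out)

    fr1 = mutate_fr(TEMPLATE_FR1, {22: "C"})
    fr2 = mutate_fr(TEMPLATE_FR2, {2: "W"})
    fr3 = mutate_fr(TEMPLATE_FR3, {23: "V", 38: "C"})
    cdr1 = "".join(AA_ALPHABET[rng.integers(20)] for _ in range(rng.integers(6, 11)))
    cdr2 = "".join(AA_ALPHABET[rng.integers(20)] for _ in range(rng.integers(4, 8)))
    aa = fr1 + cdr1 + fr2 + cdr2 + fr3
    anchors = {
        22: "C",
        26 + len(cdr1) + 2: "W",
        len(aa) - 39 + 23: "VILFMAWY",
        len(aa) - 1: "C",
    }
    return aa, anchors


def _mutate_nt(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    seq = list(seq)
    pos = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    for p in pos:
        alternatives = [c for c in NT if c != seq[p]]
        seq[p] = alternatives[rng.integers(3)]
    return "".join(seq)


def _member_nt(founder_nt: str, anchors: Dict[int, str], target_identity: float,
               rng: np.random.Generator, functional: bool,
               config: AnnotationConfig) -> str:
    n_subs = int(round((1 - target_identity) * len(founder_nt)))
    for _ in range(100):
        cand = _mutate_nt(founder_nt, n_subs, rng)
        aa = str(Seq(cand[: 3 * (len(cand) // 3)]).translate())
        if functional:
            if "*" in aa:
                continue
            if any(aa[i] not in allowed for i, allowed in anchors.items()):
                continue
        if not _rss_clean(cand, config):
            continue
        return cand
    raise RuntimeError("could not generate subgroup member")


def simulate_locus(spec: LocusSpec,
                   profile: ReferenceProfile = DEFAULT_PROFILE,
                   config: AnnotationConfig = AnnotationConfig()) -> SimulatedLocus:
    """Generate a contig and its truth annotation."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = list(spec.subgroup_sizes or _default_subgroup_sizes(spec.n_v_genes, spec.n_subgroups))
    if sum(sizes) != spec.n_v_genes or len(sizes) != spec.n_subgroups:
        raise ValueError("subgroup_sizes inconsistent with n_v_genes/n_subgroups")

    # --- founders below the identity margin (edlib screen)
    founders: List[str] = []
    founder_anchors: List[Dict[int, str]] = []
    for _ in range(spec.n_subgroups):
        for _attempt in range(100):
            aa, anchors = _founder_aa(rng)
            nt = back_translate(aa, rng)
            if not _rss_clean(nt, config):
                continue
            ok = True
            for other in founders:
                dist = edlib.align(nt, other, task="distance")["editDistance"]
                ident = 100.0 * (1 - dist / max(len(nt), len(other)))
                if ident >= spec.founder_max_identity:
                    ok = False
                    break
            if ok:
                founders.append(nt)
                founder_anchors.append(anchors)
                break
        else:
            raise RuntimeError("founder generation failed")

    # --- V gene family sequences
    lo, hi = spec.intra_subgroup_identity
    families: List[List[str]] = []
    for f_idx, size in enumerate(sizes):
        fam: List[str] = []
        for _m in range(size):
            if size == 1:
                fam.append(founders[f_idx])
                continue
            for _ in range(50):
                cand = _member_nt(founders[f_idx], founder_anchors[f_idx],
                                  rng.uniform(lo, hi), rng, True, config)
                if cand not in fam:
                    fam.append(cand)
                    break
            else:
                raise RuntimeError("could not generate distinct member")
        families.append(fam)

    # --- pseudogene selection (never the inverted 3' V)
    n_pseudo = int(np.floor(spec.pseudogene_fraction * spec.n_v_genes + 0.5))
    flat: List[Tuple[int, int]] = [
        (i, j) for i, fam in enumerate(families) for j in range(len(fam))
    ]
    selectable = flat[:-1] if spec.inverted_v else flat
    n_pseudo = min(n_pseudo, len(selectable))
    pseudo_idx = set(
        tuple(selectable[k]) for k in rng.choice(len(selectable), size=n_pseudo, replace=False)
    )
    lesions = ("stop", "leader", "length", "splice", "frameshift")

    # --- assemble the contig
    parts: List[str] = []
    cursor = 0
    genes: List[GermlineGene] = []
    v_payload: Dict[str, dict] = {}
    truth_members: List[List[str]] = [[] for _ in families]
    lesion_cycle = 0

    def emit(seg: str) -> int:
        nonlocal cursor
        parts.append(seg)
        start = cursor
        cursor += len(seg)
        return start

    emit(_screened_rand_nt(rng, 220, config))

    d_seqs = list(spec.d_seqs) if spec.d_seqs else _derive_d_seqs(spec.cluster_layout)

    v_order: List[Tuple[int, int]] = flat[:-1] if spec.inverted_v else flat
    for i, j in v_order:
        lesion = None
        if (i, j) in pseudo_idx:
            lesion = lesions[lesion_cycle % len(lesions)]
            lesion_cycle += 1
            if lesion == "length" and len(families[i]) > 1:
                # a large deletion would drop the member below the 75%
                # subgroup criterion and make the planted partition
                # ambiguous; use a stop codon in multi-member families
                lesion = "stop"
        gene, seg, payload = _build_v_gene(families[i][j], lesion, rng, profile, config)
        start = emit(seg)
        gene.contig_span = (gene.contig_span[0] + start, gene.contig_span[1] + start)
        gene.exons = [(a + start, b + start) for a, b in gene.exons]
        gene.rss = tuple(
            RecombinationSignal(s.heptamer_start + start, s.spacer_len,
                                s.heptamer_matches, s.nonamer_matches, s.orientation)
            for s in gene.rss
        )
        gene.name = f"@{gene.start}"
        genes.append(gene)
        truth_members[i].append(gene.name)
        v_payload[gene.name] = payload
        emit(_screened_rand_nt(rng, int(rng.integers(150, 300)), config))

    # --- D-J-C clusters
    j_payload: Dict[str, dict] = {}
    d_payload: Dict[str, str] = {}
    c_payload: Dict[str, str] = {}
    cluster_gene_keys: List[dict] = []
    for c_idx, (n_j, d_len) in enumerate(spec.cluster_layout):
        d_seq = d_seqs[c_idx][:d_len]
        d_gene, d_seg = _build_d_gene(d_seq, rng, config)
        start = emit(d_seg)
        _shift(d_gene, start)
        genes.append(d_gene)
        keys = {"d": d_gene, "js": [], "c": None}
        emit(_screened_rand_nt(rng, 120, config))
        for j_idx in range(n_j):
            defective = (c_idx, j_idx) in set(map(tuple, spec.j_rss_defects))
            j_gene, j_seg, payload = _build_j_gene(rng, profile, config, d_seqs, defective)
            start = emit(j_seg)
            _shift(j_gene, start)
            genes.append(j_gene)
            keys["js"].append(j_gene)
            j_payload[id(j_gene)] = payload
            emit(_screened_rand_nt(rng, 60, config))
        c_gene, c_seg, c_coding = _build_c_gene(rng, profile, config)
        start = emit(c_seg)
        _shift(c_gene, start)
        genes.append(c_gene)
        keys["c"] = c_gene
        c_payload[id(c_gene)] = c_coding
        cluster_gene_keys.append(keys)
        d_payload[id(d_gene)] = d_seq
        emit(_screened_rand_nt(rng, 400, config))

    # --- inverted 3' V gene
    if spec.inverted_v:
        i, j = flat[-1]
        gene, seg, payload = _build_v_gene(families[i][j], None, rng, profile, config)
        emit(_screened_rand_nt(rng, 500, config))
        start = emit(revcomp(seg))
        inverted = (gene, len(seg), start, payload, i)
    else:
        inverted = None

    emit(_screened_rand_nt(rng, 200, config))
    contig = "".join(parts)

    if inverted is not None:
        gene, seg_len, start, payload, fam_i = inverted
        offset = len(contig) - start - seg_len   # position of segment on revcomp(contig)
        _shift(gene, offset)
        gene = _flip_gene(gene, len(contig))
        gene.name = f"@{gene.start}"
        genes.append(gene)
        truth_members[fam_i].append(gene.name)
        v_payload[gene.name] = payload

    if spec.substitution_rate > 0:
        n = rng.binomial(len(contig), spec.substitution_rate)
        contig = _mutate_nt(contig, n, rng)

    # --- truth naming
    vs = sorted([g for g in genes if g.gene_type == "V"], key=lambda g: g.start)
    subgroups = {}
    ordered = sorted(
        [m for m in truth_members if m],
        key=lambda m: min(int(x[1:]) for x in m),
    )
    for label, members in enumerate(ordered, start=1):
        subgroups[label] = sorted(members, key=lambda x: int(x[1:]))
    partition = SubgroupPartition(75.0, subgroups)
    gene_by_old = {g.name: g for g in vs}
    name_v_genes(vs, partition)
    v_payload = {gene_by_old[old].name: p for old, p in v_payload.items()}

    truth = build_locus_map(genes, "synthetic_locus", spec.cluster_label_order)
    j_named = {k: g.name for g in truth.genes if g.gene_type == "J"
               for k in (id(g),)}
    d_named = {id(g): g.name for g in truth.genes if g.gene_type == "D"}
    c_named = {id(g): g.name for g in truth.genes if g.gene_type == "C"}

    return SimulatedLocus(
        contig=contig,
        truth=truth,
        spec=spec,
        partition=SubgroupPartition(
            75.0,
            {lab: [gene_by_old[m].name for m in mem] for lab, mem in subgroups.items()},
        ),
        v_payload=v_payload,
        j_payload={j_named[k]: v for k, v in j_payload.items()},
        d_payload={d_named[k]: v for k, v in d_payload.items()},
        c_payload={c_named[k]: v for k, v in c_payload.items()},
    )


def _shift(gene: GermlineGene, start: int) -> None:
    gene.contig_span = (gene.contig_span[0] + start, gene.contig_span[1] + start)
    gene.exons = [(a + start, b + start) for a, b in gene.exons]
    gene.rss = tuple(
        RecombinationSignal(s.heptamer_start + start, s.spacer_len,
                            s.heptamer_matches, s.nonamer_matches, s.orientation)
        for s in gene.rss
    )


def _derive_d_seqs(layout: Sequence[Tuple[int, int]]) -> List[str]:
    patterns = ["GGGA", "GGCG", "GGTG", "GGAT", "GGCT"]
    out = []
    for k, (_, dlen) in enumerate(layout):
        if k < len(DEFAULT_D_SEQS) and len(DEFAULT_D_SEQS[k]) == dlen:
            out.append(DEFAULT_D_SEQS[k])
        else:
            pat = patterns[k % len(patterns)]
            out.append((pat * (dlen // len(pat) + 1))[:dlen])
    return out


def _build_v_gene(v_region: str, lesion: Optional[str], rng: np.random.Generator,
                  profile: ReferenceProfile, config: AnnotationConfig):
    """Assemble one V gene segment and its truth record (segment coords)."""
    leader = back_translate(LEADER_AA, rng)
    l_part2 = back_translate("LHAS", rng)
    tail = profile.v_tail_nt
    intron_mid = _rand_nt(rng, profile.v_intron_len - 12)
    while profile.acceptor_motif in intron_mid:
        intron_mid = _rand_nt(rng, profile.v_intron_len - 12)
    intron = profile.donor_motif + intron_mid + profile.acceptor_motif
    heptamer, nonamer = HEPTAMER, NONAMER
    spacer = _rand_nt(rng, 23)

    leader_ok = splice_ok = frame_ok = no_stops = True
    anchors_known = True
    if lesion == "leader":
        leader = "ACG" + leader[3:]
        leader_ok = False
    elif lesion == "splice":
        intron = "GC" + intron[2:]
        splice_ok = False
    elif lesion == "length":
        # codon-aligned 45-nt deletion early in FR3, away from every anchor
        sa = len(v_region) // 3 - 39 + 2
        v_region = v_region[: 3 * sa] + v_region[3 * sa + 45 :]
        length_lesion = True
    elif lesion == "stop":
        p = 3 * int(rng.integers(10, len(v_region) // 3 - 10))
        v_region = v_region[:p] + "TAA" + v_region[p + 3 :]
        no_stops = False
        anchors_known = False
    elif lesion == "frameshift":
        p = int(rng.integers(30, len(v_region) - 30))
        v_region = v_region[:p] + v_region[p + 1 :]
        frame_ok = False
        no_stops = False
        anchors_known = False

    v_exon = l_part2 + v_region + tail
    seg = leader + intron + v_exon + heptamer + spacer + nonamer

    l1_start = 0
    intron_start = len(leader)
    v_exon_start = intron_start + len(intron)
    hept = v_exon_start + len(v_exon)
    sig = RecombinationSignal(hept, 23, 7, 9, "forward")

    aa = ""
    if frame_ok:
        aa = str(Seq(v_region[: 3 * (len(v_region) // 3)]).translate())
    gene = GermlineGene(
        name="", gene_type="V",
        contig_span=(l1_start, hept + 7 + 23 + 9),
        exons=[(l1_start, intron_start), (v_exon_start, hept)],
        rss=(sig,),
        leader_ok=leader_ok, splice_ok=splice_ok,
        length_ok=abs(len(v_exon) - profile.v_exon_len)
        <= profile.v_len_tolerance * profile.v_exon_len,
        frame_ok=frame_ok,
        no_stops=no_stops and ("*" not in aa),
        anchors_ok=True if anchors_known and no_stops and frame_ok else None,
        coding_nt=v_exon,
        v_region_nt=v_exon[profile.l_part2_len : len(v_exon) - len(tail)],
        translated=aa,
    )
    verdict, defects = classify_functionality(gene, config=config)
    gene.functionality, gene.defect_reasons = verdict, defects
    payload = {
        "leader": leader, "l_part2": l_part2, "v_region": v_region,
        "tail": tail, "functional": verdict == "F",
    }
    return gene, seg, payload


def _build_d_gene(d_seq: str, rng: np.random.Generator, config: AnnotationConfig):
    sp12, sp23 = _rand_nt(rng, 12), _rand_nt(rng, 23)
    seg = revcomp(NONAMER) + sp12 + revcomp(HEPTAMER) + d_seq + HEPTAMER + sp23 + NONAMER
    five = RecombinationSignal(9 + 12, 12, 7, 9, "reverse")
    three = RecombinationSignal(9 + 12 + 7 + len(d_seq), 23, 7, 9, "forward")
    gene = GermlineGene(
        name="", gene_type="D",
        contig_span=(0, len(seg)),
        exons=[(five.heptamer_end, three.heptamer_start)],
        rss=(five, three),
        length_ok=True,
        coding_nt=d_seq,
    )
    gene.functionality, gene.defect_reasons = classify_functionality(gene, config=config)
    return gene, seg


def _build_j_gene(rng: np.random.Generator, profile: ReferenceProfile,
                  config: AnnotationConfig, d_seqs: Sequence[str], defective: bool):
    d_5mers = {d[k : k + 5] for d in d_seqs for k in range(len(d) - 4)}
    head_len = int(rng.choice(J_HEAD_CHOICES))
    for _ in range(500):
        head_aa = "".join(AA_ALPHABET[rng.integers(20)] for _ in range(head_len // 3))
        head = back_translate(head_aa, rng)
        f_codon = ("TTT", "TTC")[rng.integers(2)]
        g1 = STANDARD_CODONS["G"][rng.integers(4)]
        x = back_translate(AA_ALPHABET[rng.integers(20)], rng)
        g2 = STANDARD_CODONS["G"][rng.integers(4)]
        tail = back_translate(
            "".join(AA_ALPHABET[rng.integers(20)] for _ in range(7)), rng
        )
        coding = head + f_codon + g1 + x + g2 + tail
        if profile.donor_motif in coding:
            continue
        # the head is junction material: it must not fake a D match
        if any(head[k : k + 5] in d_5mers for k in range(len(head) - 4)):
            continue
        if "*" in head_aa:
            continue
        break
    else:
        raise RuntimeError("could not generate J coding region")

    heptamer = HEPTAMER
    if defective:
        heptamer = heptamer[:4] + "C" + heptamer[5:]   # 5th-position G -> C
    sp12 = _rand_nt(rng, 12)
    seg = revcomp(NONAMER) + sp12 + revcomp(heptamer) + coding + profile.donor_motif
    hm = hamming_matches(heptamer, HEPTAMER)
    sig = RecombinationSignal(9 + 12, 12, hm, 9, "reverse")
    j_start = sig.heptamer_end
    aa = str(Seq(coding).translate())
    gene = GermlineGene(
        name="", gene_type="J",
        contig_span=(0, j_start + len(coding)),
        exons=[(j_start, j_start + len(coding))],
        rss=(sig,),
        splice_ok=True,
        length_ok=profile.j_len_range[0] <= len(coding) <= profile.j_len_range[1],
        frame_ok=True, no_stops="*" not in aa,
        fgxg_ok=True,
        coding_nt=coding, translated=aa,
    )
    gene.functionality, gene.defect_reasons = classify_functionality(gene, config=config)
    payload = {"head_len": head_len, "coding": coding,
               "constant_block": coding[head_len:]}
    return gene, seg, payload


def _build_c_gene(rng: np.random.Generator, profile: ReferenceProfile,
                  config: AnnotationConfig):
    exon_sets = []
    for base in profile.c_exons:
        exon_sets.append(base)
    # a few substitutions per gene, away from the first/last 6 nt of each exon
    exons = []
    for e in exon_sets:
        e = list(e)
        for _ in range(rng.integers(0, 3)):
            if len(e) > 14:
                p = int(rng.integers(6, len(e) - 6))
                e[p] = [c for c in NT if c != e[p]][rng.integers(3)]
        exons.append("".join(e))
    segs = []
    spans = []
    off = 0
    for k, e in enumerate(exons):
        segs.append(e)
        spans.append((off, off + len(e)))
        off += len(e)
        if k < len(exons) - 1:
            intron_mid = _rand_nt(rng, profile.c_intron_len - 12)
            segs.append(profile.donor_motif + intron_mid + profile.acceptor_motif)
            off += profile.c_intron_len
    seg = "".join(segs)
    gene = GermlineGene(
        name="", gene_type="C",
        contig_span=(0, spans[-1][1]),
        exons=spans,
        splice_ok=True,
        coding_nt="".join(exons),
    )
    gene.functionality, gene.defect_reasons = classify_functionality(gene, config=config)
    return gene, seg, "".join(exons)


# ---------------------------------------------------------------------------
# Repertoire simulation

@dataclass
class SimulatedRepertoire:
    fasta: str
    truth: pd.DataFrame
    spec: RepertoireSpec


def simulate_repertoire(locus: SimulatedLocus, spec: RepertoireSpec) -> SimulatedRepertoire:
    """Rearranged cDNA clones with a full truth table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = locus.truth

    # the inverted 3' V recombines by inversion and is expressed like any other
    v_pool = [g for g in truth.v_genes
              if g.functionality == "F" or spec.include_pseudogene_v]
    if not v_pool:
        raise ValueError("no usable V gene in locus")
    order_labels = truth.cluster_order_5to3
    clusters = []
    for gidx, label in enumerate(order_labels):
        dname, jnames, cname = truth.clusters[label]
        js = [truth.get(j) for j in jnames]
        js = [j for j in js if j.functionality == "F"]
        if dname is None or not js:
            continue
        clusters.append({"genomic": gidx, "label": label, "d": truth.get(dname),
                         "js": js, "c": truth.get(cname)})
    if not clusters:
        raise ValueError("no usable D-J-C cluster in locus")

    cis_pairs = [(a, b) for a in range(len(clusters)) for b in range(len(clusters)) if a <= b]
    trans_pairs = [(a, b) for a in range(len(clusters)) for b in range(len(clusters)) if a > b]

    def weights(pool, bias):
        if not bias:
            return np.ones(len(pool)) / len(pool)
        w = np.array([bias.get(g.name, 1.0) for g in pool], dtype=float)
        return w / w.sum()

    vw = weights(v_pool, spec.v_bias)
    tissue_names = [t for t, _ in spec.tissues]
    tissue_p = np.array([p for _, p in spec.tissues])

    rows = []
    fasta_parts = []
    for k in range(spec.n_clones):
        tissue = tissue_names[rng.choice(len(tissue_names), p=tissue_p)]
        v = v_pool[rng.choice(len(v_pool), p=vw)]
        if spec.trans_probability > 0 and trans_pairs and rng.random() < spec.trans_probability:
            a, b = trans_pairs[rng.integers(len(trans_pairs))]
        else:
            a, b = cis_pairs[rng.integers(len(cis_pairs))]
        dcl, jcl = clusters[a], clusters[b]
        d_gene = dcl["d"]
        jw = weights(jcl["js"], spec.j_bias)
        j_gene = jcl["js"][rng.choice(len(jcl["js"]), p=jw)]
        jp = locus.j_payload[j_gene.name]

        vp = locus.v_payload[v.name]
        tail = vp["tail"]
        d_seq = locus.d_payload[d_gene.name]
        head = jp["coding"][: jp["head_len"]]

        for _attempt in range(200):
            tv = min(int(_geom_lengths(rng, spec.trim_mean)[0]), len(tail))
            d5 = int(_geom_lengths(rng, spec.trim_mean)[0])
            d3 = int(_geom_lengths(rng, spec.trim_mean)[0])
            if d5 + d3 >= len(d_seq):
                d_kept = ""
                d5, d3 = len(d_seq), 0
            else:
                d_kept = d_seq[d5 : len(d_seq) - d3]
            tj = min(int(_geom_lengths(rng, spec.trim_mean)[0]), len(head))
            n1 = int(_geom_lengths(rng, spec.n_addition_mean)[0])
            n2 = int(_geom_lengths(rng, spec.n_addition_mean)[0])
            if spec.productive_only:
                total = (len(tail) - tv) + n1 + len(d_kept) + n2 + (len(head) - tj)
                n2 += (-total) % 3
            junction = (
                tail[: len(tail) - tv] + _rand_nt(rng, n1) + d_kept
                + _rand_nt(rng, n2) + head[tj:]
            )
            if spec.productive_only:
                if len(junction) % 3 != 0:
                    continue
                if "*" in str(Seq(junction).translate()):
                    continue
            break

        # J contribution past the junction: constant block (FGXG + tail)
        cdna = (
            vp["leader"] + vp["l_part2"] + vp["v_region"] + junction
            + jp["constant_block"]
            + locus.c_payload[jcl["c"].name][: spec.c_prefix_len]
        )

        # point substitutions, preserving productivity and the FGXG frame
        if spec.substitution_rate > 0:
            v_start = len(vp["leader"]) + len(vp["l_part2"])
            junc_start = v_start + len(vp["v_region"])
            f_start = junc_start + len(junction)
            for _attempt in range(100):
                n_subs = rng.binomial(len(cdna), spec.substitution_rate)
                cand = _mutate_nt(cdna, n_subs, rng) if n_subs else cdna
                vr_aa = str(Seq(cand[v_start : v_start + len(vp["v_region"])]).translate())
                if "*" in vr_aa or vr_aa[-1] != "C":
                    continue
                if spec.productive_only and "*" in str(
                    Seq(cand[junc_start:f_start]).translate()
                ):
                    continue
                fg = str(Seq(cand[f_start : f_start + 12]).translate())
                if not (fg[0] == "F" and fg[1] == "G" and fg[3] == "G"):
                    continue
                cdna = cand
                break
        v_start = len(vp["leader"]) + len(vp["l_part2"])
        junc_start = v_start + len(vp["v_region"])
        f_start = junc_start + len(junction)
        junction_final = cdna[junc_start:f_start]
        cdr3_aa = (
            str(Seq(junction_final).translate()) if len(junction_final) % 3 == 0 else ""
        )

        if a == b:
            klass = "intra"
        elif a < b:
            klass = "inter"
        else:
            klass = "trans"
        clone_id = f"clone{k:04d}"
        fasta_parts.append(f">{clone_id}|tissue={tissue}\n{cdna}\n")
        rows.append({
            "clone_id": clone_id, "tissue": tissue,
            "v_true": v.name, "d_true": d_gene.name, "j_true": j_gene.name,
            "trim_v": tv, "trim_d5": d5, "trim_d3": d3, "trim_j": tj,
            "n1": n1, "n2": n2,
            "d_retained_len": len(d_kept), "d_retained_seq": d_kept,
            "junction_nt": junction_final,
            "cdr3_aa": cdr3_aa, "cdr3_len": len(cdr3_aa),
            "rearrangement_true": klass,
        })

    return SimulatedRepertoire("".join(fasta_parts), pd.DataFrame(rows), spec)
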