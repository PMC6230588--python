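"""Germline TRB gene detection, functionality classification and locus maps.

Discovery is recombination-signal anchored: candidate 23-spacer signals
(3' of V, 3' of D) and 12-spacer signals (5' of J, 5' of D) are scanned at
permissive thresholds, paired into D genes where a 12- and a 23-signal
flank a 10-25 nt core, and otherwise parsed as V or J genes by the locus
grammar (leader exon, GT..AG intron motifs, donor splice, expected exon
lengths from the reference profile).  C genes carry no signal and are
located by seeded homology to the reference C exon 1.

Functionality follows the IMGT-style rules: (a) leader present, (b) proper
recombination signals, (c) conserved splice sites, (d) expected coding
length, (e) no frameshifts or stop codons; J genes additionally need the
canonical FGXG motif and a 3' donor site, V genes the four conserved
anchors.  Frame-intact genes with only signal/anchor defects are ORF;
anything with a broken frame, stop, missing leader, bad splice or wrong
length is a pseudogene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
from Bio.Seq import Seq

from .identity import SubgroupPartition, cluster_subgroups
from .numbering import number_v_domain
from .reference import DEFAULT_PROFILE, ReferenceProfile
from .rss import RecombinationSignal, revcomp, scan_rss

PSEUDO_CODES = {"a", "c", "d", "e", "FGXG"}
ORF_CODES = {"RSS", "RSS-missing", "anchor"}


@dataclass
class AnnotationConfig:
    """Thresholds applied during discovery and functionality calls."""

    discovery_min_heptamer: int = 5
    discovery_min_nonamer: int = 6
    functional_min_heptamer: int = 7   # paper's one defective J differs at one heptamer base
    functional_min_nonamer: int = 7
    spacer_tolerance: int = 0          # +/- nt around 12 / 23
    rss_search_window: int = 600
    strong_rss_score: int = 15         # heptamer+nonamer floor to accept motif-less parses


@dataclass
class GermlineGene:
    """One annotated V, D, J or C gene on a contig (0-based half-open)."""

    name: str
    gene_type: str                       # V | D | J | C
    contig_span: Tuple[int, int]
    strand: str = "+"
    exons: List[Tuple[int, int]] = field(default_factory=list)
    rss: Tuple[RecombinationSignal, ...] = ()
    functionality: str = "F"
    defect_reasons: List[str] = field(default_factory=list)
    # observations feeding classify_functionality
    leader_ok: Optional[bool] = None
    splice_ok: Optional[bool] = None
    length_ok: Optional[bool] = None
    frame_ok: Optional[bool] = None
    no_stops: Optional[bool] = None
    anchors_ok: Optional[bool] = None
    fgxg_ok: Optional[bool] = None
    # sequence payloads
    coding_nt: str = ""
    v_region_nt: str = ""
    translated: str = ""
    # assignments filled later
    subgroup: Optional[int] = None
    cluster: Optional[int] = None

    @property
    def start(self) -> int:
        return self.contig_span[0]

    @property
    def end(self) -> int:
        return self.contig_span[1]


def classify_functionality(
    gene: GermlineGene,
    translated_v_region: Optional[str] = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> Tuple[str, List[str]]:
    """Apply the functionality rules in order and return (verdict, defects).

    Rule codes: 'a' missing leader, 'c' splice defect, 'd' unexpected
    coding length, 'e' frameshift/stop, 'FGXG' missing J motif, 'RSS' /
    'RSS-missing' signal defects, 'anchor' missing conserved V anchor.
    F requires every check to pass; signal/anchor-only defects give ORF;
    the rest are pseudogenes.
    """
    defects: List[str] = []
    if gene.gene_type == "V" and gene.leader_ok is False:
        defects.append("a")
    expected_rss = {"V": 1, "D": 2, "J": 1, "C": 0}[gene.gene_type]
    if len(gene.rss) < expected_rss:
        defects.append("RSS-missing")
    for sig in gene.rss:
        if (
            sig.heptamer_matches < config.functional_min_heptamer
            or sig.nonamer_matches < config.functional_min_nonamer
        ):
            if "RSS" not in defects:
                defects.append("RSS")
    if gene.splice_ok is False:
        defects.append("c")
    if gene.length_ok is False:
        defects.append("d")
    aa = translated_v_region if translated_v_region is not None else gene.translated
    if gene.frame_ok is False or gene.no_stops is False or (aa and "*" in aa):
        defects.append("e")
    if gene.gene_type == "J" and gene.fgxg_ok is False:
        defects.append("FGXG")
    if gene.gene_type == "V" and gene.anchors_ok is False:
        defects.append("anchor")

    if set(defects) & PSEUDO_CODES:
        verdict = "P"
    elif defects:
        verdict = "ORF"
    else:
        verdict = "F"
    return verdict, defects


def _finalize(gene: GermlineGene, config: AnnotationConfig) -> GermlineGene:
    verdict, defects = classify_functionality(gene, config=config)
    gene.functionality = verdict
    gene.defect_reasons = defects
    return gene


# ---------------------------------------------------------------------------
# V genes

def annotate_v_gene(
    contig: str,
    candidate_region: Tuple[int, int],
    reference_profile: ReferenceProfile = DEFAULT_PROFILE,
    config: AnnotationConfig = AnnotationConfig(),
    rss_hit: Optional[RecombinationSignal] = None,
) -> GermlineGene:
    """Annotate one V gene inside *candidate_region*.

    Locates the 23-spacer signal (unless already supplied), then parses the
    structure upstream of the heptamer: V exon, GT..AG intron, leader exon.
    A gene is always emitted; missing elements become defect codes.
    """
    contig = contig.upper()
    p = reference_profile
    if rss_hit is None:
        lo, hi = candidate_region
        window = contig[lo : min(len(contig), hi + config.rss_search_window)]
        hits = scan_rss(window, 23, config.discovery_min_heptamer,
                        config.discovery_min_nonamer, "forward")
        if hits:
            best = max(hits, key=lambda h: (h.heptamer_matches + h.nonamer_matches, -h.heptamer_start))
            rss_hit = replace(best, heptamer_start=best.heptamer_start + lo)

    hept = rss_hit.heptamer_start if rss_hit else candidate_region[1]
    expected_intron_start = hept - p.v_exon_len - p.v_intron_len
    s = _find_intron(contig, expected_intron_start, p, slack=60)
    splice_ok = True
    if s is None:
        # donor corrupted: look for the acceptor motif alone
        s = _find_acceptor_only(contig, expected_intron_start, p, slack=60)
        splice_ok = False
        if s is None:
            s = expected_intron_start
    v_exon_start = s + p.v_intron_len
    l1_start = s - p.l_part1_len
    leader_ok = contig[l1_start : l1_start + 3] == "ATG"

    v_exon = contig[v_exon_start:hept]
    length_ok = abs(len(v_exon) - p.v_exon_len) <= p.v_len_tolerance * p.v_exon_len
    frame_ok = (len(v_exon) - p.v_exon_len) % 3 == 0
    v_region = v_exon[p.l_part2_len : len(v_exon) - len(p.v_tail_nt)]
    coding_aa = ""
    anchors_ok: Optional[bool] = None
    no_stops = True
    if frame_ok:
        trimmed = v_region[: 3 * (len(v_region) // 3)]
        coding_aa = str(Seq(trimmed).translate())
        no_stops = "*" not in coding_aa
        if no_stops:
            try:
                dom = number_v_domain(coding_aa, p, partial=True)
                anchors_ok = not dom.anchor_defects
            except ValueError:
                anchors_ok = False
    else:
        no_stops = False

    exons = [(l1_start, s), (v_exon_start, hept)]
    span_end = rss_hit.span[1] if rss_hit else hept
    gene = GermlineGene(
        name="", gene_type="V",
        contig_span=(l1_start, span_end),
        exons=exons,
        rss=(rss_hit,) if rss_hit else (),
        leader_ok=leader_ok, splice_ok=splice_ok, length_ok=length_ok,
        frame_ok=frame_ok, no_stops=no_stops, anchors_ok=anchors_ok,
        coding_nt=v_exon, v_region_nt=v_region, translated=coding_aa,
    )
    return _finalize(gene, config)


def _find_intron(contig: str, expected: int, p: ReferenceProfile, slack: int) -> Optional[int]:
    best = None
    ln = p.v_intron_len
    for s in range(max(0, expected - slack), expected + slack + 1):
        if (
            contig[s : s + len(p.donor_motif)] == p.donor_motif
            and contig[s + ln - len(p.acceptor_motif) : s + ln] == p.acceptor_motif
        ):
            if best is None or abs(s - expected) < abs(best - expected):
                best = s
    return best


def _find_acceptor_only(contig: str, expected: int, p: ReferenceProfile, slack: int) -> Optional[int]:
    best = None
    ln = p.v_intron_len
    for s in range(max(0, expected - slack), expected + slack + 1):
        if contig[s + ln - len(p.acceptor_motif) : s + ln] == p.acceptor_motif:
            if best is None or abs(s - expected) < abs(best - expected):
                best = s
    return best


# ---------------------------------------------------------------------------
# J, D, C genes

def _annotate_j(contig: str, sig: RecombinationSignal, p: ReferenceProfile,
                config: AnnotationConfig) -> Optional[GermlineGene]:
    j_start = sig.heptamer_end
    lo, hi = p.j_len_range
    dpos = -1
    for cand in range(j_start + lo, min(len(contig) - len(p.donor_motif), j_start + hi) + 1):
        if contig[cand : cand + len(p.donor_motif)] == p.donor_motif:
            dpos = cand
            break
    splice_ok = dpos >= 0
    strong = sig.heptamer_matches + sig.nonamer_matches >= config.strong_rss_score
    if not splice_ok:
        if not strong:
            return None   # not credible without a donor site
        dpos = j_start + 48
    coding = contig[j_start:dpos]
    length_ok = lo <= len(coding) <= hi
    frame_ok = len(coding) % 3 == 0
    aa = str(Seq(coding[: 3 * (len(coding) // 3)]).translate()) if coding else ""
    fgxg_ok = re.search(r"FG.G", aa) is not None
    if not (strong or fgxg_ok):
        return None   # weak signal and no J motif: chance hit
    gene = GermlineGene(
        name="", gene_type="J",
        contig_span=(sig.span[0], dpos),
        exons=[(j_start, dpos)],
        rss=(sig,),
        splice_ok=splice_ok, length_ok=length_ok, frame_ok=frame_ok,
        no_stops="*" not in aa, fgxg_ok=fgxg_ok,
        coding_nt=coding, translated=aa,
    )
    return _finalize(gene, config)


def _annotate_d(contig: str, five: RecombinationSignal, three: RecombinationSignal,
                p: ReferenceProfile, config: AnnotationConfig) -> GermlineGene:
    core = contig[five.heptamer_end : three.heptamer_start]
    gene = GermlineGene(
        name="", gene_type="D",
        contig_span=(five.span[0], three.span[1]),
        exons=[(five.heptamer_end, three.heptamer_start)],
        rss=(five, three),
        length_ok=p.d_len_range[0] <= len(core) <= p.d_len_range[1],
        coding_nt=core,
    )
    return _finalize(gene, config)


def _annotate_c_genes(contig: str, p: ReferenceProfile,
                      config: AnnotationConfig) -> List[GermlineGene]:
    ex1 = p.c_exons[0]
    seed_len = 55
    votes: Dict[int, int] = {}
    for off in range(0, len(ex1) - seed_len + 1, seed_len):
        seed = ex1[off : off + seed_len]
        start = contig.find(seed)
        while start != -1:
            votes[start - off] = votes.get(start - off, 0) + 1
            start = contig.find(seed, start + 1)
    candidates = sorted(votes)
    merged: List[int] = []
    for t in candidates:
        if merged and t - merged[-1] < 50:
            continue
        merged.append(t)
    genes = []
    for t in merged:
        window = contig[t : t + len(ex1)]
        if len(window) < len(ex1):
            continue
        res = edlib.align(ex1, window, task="distance")
        if res["editDistance"] > 0.2 * len(ex1):
            continue
        exons = []
        off = t
        splice_ok = True
        for k, ln in enumerate(len(e) for e in p.c_exons):
            exons.append((off, off + ln))
            if k < len(p.c_exons) - 1:
                intron = contig[off + ln : off + ln + p.c_intron_len]
                if not (intron.startswith(p.donor_motif[:2]) and intron.endswith("AG")):
                    splice_ok = False
                off = off + ln + p.c_intron_len
        gene = GermlineGene(
            name="", gene_type="C",
            contig_span=(t, exons[-1][1]),
            exons=exons, splice_ok=splice_ok,
            coding_nt="".join(contig[a:b] for a, b in exons),
        )
        genes.append(_finalize(gene, config))
    return genes


# ---------------------------------------------------------------------------
# Locus map

@dataclass
class LocusMap:
    contig_id: str
    genes: List[GermlineGene]
    clusters: Dict[int, Tuple[Optional[str], List[str], str]]   # label -> (D, [J..], C)
    cluster_order_5to3: Tuple[int, ...]

    def get(self, name: str) -> GermlineGene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def cluster_of(self, name: str) -> int:
        for label, (d, js, c) in self.clusters.items():
            if name == d or name == c or name in js:
                return label
        raise KeyError(f"{name} not in any D-J-C cluster")

    @property
    def v_genes(self) -> List[GermlineGene]:
        return [g for g in self.genes if g.gene_type == "V"]

    @property
    def d_genes(self) -> List[GermlineGene]:
        return [g for g in self.genes if g.gene_type == "D"]

    @property
    def j_genes(self) -> List[GermlineGene]:
        return [g for g in self.genes if g.gene_type == "J"]


def build_locus_map(
    genes: Sequence[GermlineGene],
    contig_id: str = "contig",
    cluster_label_order: Optional[Sequence[int]] = None,
) -> LocusMap:
    """Group J genes with the nearest downstream C, attach each D to its
    immediately following J set, and label clusters.

    The default labelling convention for a three-cluster (pig-like) layout
    is (1, 3, 2) in genomic order, keeping the last cluster orthologous to
    cluster 2 of two-cluster species; any other cluster count is labelled
    1..n in genomic order.  J genes are numbered by genomic position within
    their cluster.
    """
    genes = sorted(genes, key=lambda g: (g.start, g.end))
    cs = [g for g in genes if g.gene_type == "C"]
    if not cs:
        raise ValueError("no C gene annotated")
    js = [g for g in genes if g.gene_type == "J"]
    ds = [g for g in genes if g.gene_type == "D"]

    n_clusters = len(cs)
    if cluster_label_order is None:
        cluster_label_order = (1, 3, 2) if n_clusters == 3 else tuple(range(1, n_clusters + 1))
    if len(cluster_label_order) != n_clusters:
        raise ValueError("cluster_label_order length does not match C gene count")

    cluster_js: Dict[int, List[GermlineGene]] = {i: [] for i in range(n_clusters)}
    for j in js:
        downstream = [i for i, c in enumerate(cs) if c.start >= j.end]
        if not downstream:
            raise ValueError(f"orphan J at {j.contig_span}: no downstream C gene")
        cluster_js[min(downstream, key=lambda i: cs[i].start - j.end)].append(j)

    cluster_ds: Dict[int, Optional[GermlineGene]] = {i: None for i in range(n_clusters)}
    for d in ds:
        following = [i for i in range(n_clusters) if cluster_js[i]
                     and cluster_js[i][0].start >= d.end]
        if not following:
            continue
        tgt = min(following, key=lambda i: cluster_js[i][0].start - d.end)
        if cluster_ds[tgt] is None or d.start > cluster_ds[tgt].start:
            cluster_ds[tgt] = d

    clusters: Dict[int, Tuple[Optional[str], List[str], str]] = {}
    for i in range(n_clusters):
        label = cluster_label_order[i]
        c = cs[i]
        c.name = f"TRBC{label}"
        c.cluster = label
        jnames = []
        for k, j in enumerate(sorted(cluster_js[i], key=lambda g: g.start), start=1):
            j.name = f"TRBJ{label}-{k}"
            j.cluster = label
            jnames.append(j.name)
        d = cluster_ds[i]
        dname = None
        if d is not None:
            d.name = f"TRBD{label}"
            d.cluster = label
            dname = d.name
        clusters[label] = (dname, jnames, c.name)

    return LocusMap(contig_id, list(genes), clusters, tuple(cluster_label_order))


def name_v_genes(v_genes: Sequence[GermlineGene], partition: SubgroupPartition) -> None:
    """Assign IMGT-style names from the subgroup partition: single-member
    subgroups are TRBV<k>, multi-member TRBV<k>-<i> with members numbered
    by genomic position."""
    by_key = {g.name or f"@{g.start}": g for g in v_genes}
    for label, members in partition.subgroups.items():
        if len(members) == 1:
            by_key[members[0]].name = f"TRBV{label}"
            by_key[members[0]].subgroup = label
        else:
            for i, m in enumerate(members, start=1):
                by_key[m].name = f"TRBV{label}-{i}"
                by_key[m].subgroup = label


# ---------------------------------------------------------------------------
# Whole-contig annotation

def annotate_contig(
    contig: str,
    contig_id: str = "contig",
    profile: ReferenceProfile = DEFAULT_PROFILE,
    config: AnnotationConfig = AnnotationConfig(),
    subgroup_threshold: float = 75.0,
    cluster_label_order: Optional[Sequence[int]] = None,
) -> LocusMap:
    """Detect and annotate every TRB gene element on a germline contig."""
    contig = contig.upper()
    genes: List[GermlineGene] = []

    fwd23 = _dedup_hits(scan_rss(contig, 23, config.discovery_min_heptamer,
                                 config.discovery_min_nonamer, "forward"))
    rev12 = _dedup_hits(scan_rss(contig, 12, config.discovery_min_heptamer,
                                 config.discovery_min_nonamer, "reverse"))
    # --- D genes: reverse-12 and forward-23 flanking a short core
    used23, used12 = set(), set()
    dmin, dmax = profile.d_len_range
    for i12, five in enumerate(rev12):
        for i23, three in enumerate(fwd23):
            gap = three.heptamer_start - five.heptamer_end
            if dmin <= gap <= dmax:
                # both flanks must be convincing: a chance low-threshold hit
                # near a real signal must not turn a V or J into a D
                if (five.heptamer_matches + five.nonamer_matches
                        < config.strong_rss_score
                        or three.heptamer_matches + three.nonamer_matches
                        < config.strong_rss_score):
                    continue
                genes.append(_annotate_d(contig, five, three, profile, config))
                used12.add(i12)
                used23.add(i23)

    # --- J genes from remaining reverse-12 signals
    for i12, sig in enumerate(rev12):
        if i12 in used12:
            continue
        j = _annotate_j(contig, sig, profile, config)
        if j is not None:
            genes.append(j)

    # --- V genes from remaining forward-23 signals (both strands)
    for strand, seq in (("+", contig), ("-", revcomp(contig))):
        hits = (
            [h for i, h in enumerate(fwd23) if i not in used23]
            if strand == "+"
            else _dedup_hits(scan_rss(seq, 23, config.discovery_min_heptamer,
                                      config.discovery_min_nonamer, "forward"))
        )
        for hit in hits:
            v = _try_v(seq, hit, profile, config)
            if v is None:
                continue
            if strand == "-":
                v = _flip_gene(v, len(contig))
            genes.append(v)

    # --- collapse V parses sharing an exon (echo signals downstream of a
    # real one re-parse the same gene body)
    genes = [g for g in genes if g.gene_type != "V"] + _dedup_v(
        [g for g in genes if g.gene_type == "V"]
    )

    # --- C genes by homology
    genes.extend(_annotate_c_genes(contig, profile, config))

    # --- subgroups and names
    vs = sorted([g for g in genes if g.gene_type == "V"], key=lambda g: g.start)
    if vs:
        named = [(f"@{g.start}", g.v_region_nt) for g in vs]
        positions = {f"@{g.start}": g.start for g in vs}
        partition = cluster_subgroups(named, subgroup_threshold, positions=positions)
        for g in vs:
            g.name = f"@{g.start}"
        name_v_genes(vs, partition)

    return build_locus_map(genes, contig_id, cluster_label_order)


def _dedup_v(vs: List[GermlineGene]) -> List[GermlineGene]:
    """Keep one V gene per overlapping span group: fewest defects, then the
    strongest recombination signal."""
    def score(g: GermlineGene):
        rss_score = sum(s.heptamer_matches + s.nonamer_matches for s in g.rss)
        return (len(g.defect_reasons), -rss_score)

    out: List[GermlineGene] = []
    for g in sorted(vs, key=lambda g: (g.strand, g.start)):
        if out and g.strand == out[-1].strand and g.start < out[-1].end:
            if score(g) < score(out[-1]):
                out[-1] = g
        else:
            out.append(g)
    return out


def _dedup_hits(hits: List[RecombinationSignal],
                min_sep: int = 12) -> List[RecombinationSignal]:
    """Collapse clusters of overlapping signal hits (low-threshold scans
    produce shifted echoes of a strong signal), keeping the best-scoring
    hit of each cluster."""
    out: List[RecombinationSignal] = []
    for h in hits:
        if out and h.heptamer_start - out[-1].heptamer_start < min_sep:
            if (h.heptamer_matches + h.nonamer_matches
                    > out[-1].heptamer_matches + out[-1].nonamer_matches):
                out[-1] = h
        else:
            out.append(h)
    return out


def _try_v(seq: str, hit: RecombinationSignal, profile: ReferenceProfile,
           config: AnnotationConfig) -> Optional[GermlineGene]:
    """Parse a V gene upstream of a 23-signal; None if the grammar fails."""
    hept = hit.heptamer_start
    min_upstream = profile.l_part1_len + profile.v_intron_len + profile.v_exon_len
    if hept < min_upstream - 80:
        return None
    expected = hept - profile.v_exon_len - profile.v_intron_len
    s = _find_intron(seq, expected, profile, slack=60)
    gene = None
    if s is None:
        # no intron evidence: a strong signal alone is not enough, because
        # the exact nonamer of a real 12-signal on the other strand plus a
        # chance heptamer mimics a 23-signal; demand an otherwise intact
        # gene body (leader and open frame) around a splice-defective V
        score = hit.heptamer_matches + hit.nonamer_matches
        if score < config.strong_rss_score:
            return None
        gene = annotate_v_gene(seq, (max(0, hept - 2000), hept), profile, config, rss_hit=hit)
        if "a" in gene.defect_reasons or "e" in gene.defect_reasons:
            return None
        return gene
    gene = annotate_v_gene(seq, (max(0, hept - 2000), hept), profile, config, rss_hit=hit)
    # weak signal plus a broken gene body is noise, not a pseudogene: every
    # credible V candidate has either a convincing signal or an intact body
    if "RSS" in gene.defect_reasons and {"a", "e"} & set(gene.defect_reasons):
        return None
    return gene


def _flip_gene(gene: GermlineGene, contig_len: int) -> GermlineGene:
    """Convert a gene annotated on the reverse complement to forward
    coordinates with strand '-'."""
    def flip(span: Tuple[int, int]) -> Tuple[int, int]:
        return (contig_len - span[1], contig_len - span[0])

    flipped_rss = tuple(
        replace(s, heptamer_start=contig_len - s.heptamer_end) for s in gene.rss
    )
    gene.contig_span = flip(gene.contig_span)
    gene.exons = [flip(e) for e in reversed(gene.exons)]
    gene.rss = flipped_rss
    gene.strand = "-"
    return gene
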