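"""Identity-threshold classification of V genes.

Two rules drive the classification:

* genes whose V-REGIONs share **more than 75%** nucleotide identity belong
  to the same subgroup (single-linkage over the pairwise criterion);
* an expressed sequence sharing **more than 97%** identity with a germline
  gene is an allele of that gene; 100% is an exact match; at or below 97%
  it is unassigned and becomes a candidate new gene for the phylogenetic
  step.

Identity is computed over a global pairwise alignment (affine gaps).  The
denominator excludes columns where either sequence has a terminal gap;
internal gap columns count as mismatches.  Both choices are config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align

DNA_AMBIG = set("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class IdentityResult:
    query_id: str
    subject_id: str
    percent_identity: float
    aligned_length: int


@dataclass
class SubgroupPartition:
    """Partition of gene names into subgroups (connected components of the
    identity-above-threshold graph)."""

    threshold: float
    subgroups: Dict[int, List[str]]   # label -> member names, label order = genomic

    def label_of(self, name: str) -> int:
        for lab, members in self.subgroups.items():
            if name in members:
                return lab
        raise KeyError(name)

    @property
    def n_subgroups(self) -> int:
        return len(self.subgroups)

    def as_blocks(self) -> List[frozenset]:
        return [frozenset(m) for m in self.subgroups.values()]


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    query_id: str = "query",
    subject_id: str = "subject",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> IdentityResult:
    """Percent nucleotide identity between two sequences.

    Global affine-gap alignment; identity = matches / alignment columns in
    which neither sequence has a terminal gap, x 100.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    for s in (a, b):
        bad = set(s) - DNA_AMBIG
        if bad:
            raise ValueError(f"invalid nucleotide(s) {sorted(bad)}")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    # terminal-gap bounds: first/last column where both sequences have residues
    lo = max(len(ga) - len(ga.lstrip("-")), len(gb) - len(gb.lstrip("-")))
    hi = len(ga) - max(len(ga) - len(ga.rstrip("-")), len(gb) - len(gb.rstrip("-")))
    cols = hi - lo
    if cols <= 0:
        raise ValueError("no overlapping alignment columns")
    matches = sum(1 for x, y in zip(ga[lo:hi], gb[lo:hi]) if x == y and x != "-")
    return IdentityResult(query_id, subject_id, 100.0 * matches / cols, cols)


def identity_matrix(named_seqs: Sequence[Tuple[str, str]], **kwargs) -> Dict[Tuple[str, str], float]:
    """All-vs-all percent identities (upper triangle, symmetric closure)."""
    out: Dict[Tuple[str, str], float] = {}
    for i in range(len(named_seqs)):
        for j in range(i + 1, len(named_seqs)):
            ni, si = named_seqs[i]
            nj, sj = named_seqs[j]
            pid = pairwise_identity(si, sj, ni, nj, **kwargs).percent_identity
            out[(ni, nj)] = pid
            out[(nj, ni)] = pid
    return out


def screened_identity_matrix(
    named_seqs: Sequence[Tuple[str, str]],
    threshold: float,
    margin: float = 8.0,
    **kwargs,
) -> Dict[Tuple[str, str], float]:
    """All-vs-all identities for thresholding, with an edit-distance screen.

    Pairs whose alignment-free identity estimate (edlib global edit
    distance over the longer sequence) is far from the threshold keep the
    estimate; pairs within *margin* points are rescored with the exact
    global alignment.  Decisions at the threshold are therefore always
    taken on the exact score.
    """
    import edlib

    out: Dict[Tuple[str, str], float] = {}
    for i in range(len(named_seqs)):
        for j in range(i + 1, len(named_seqs)):
            ni, si = named_seqs[i]
            nj, sj = named_seqs[j]
            dist = edlib.align(si.upper(), sj.upper(), task="distance")["editDistance"]
            approx = 100.0 * (1 - dist / max(len(si), len(sj)))
            if abs(approx - threshold) <= margin:
                pid = pairwise_identity(si, sj, ni, nj, **kwargs).percent_identity
            else:
                pid = approx
            out[(ni, nj)] = pid
            out[(nj, ni)] = pid
    return out


def cluster_subgroups(
    genes: Sequence[Tuple[str, str]],
    threshold: float = 75.0,
    linkage: str = "single",
    positions: Optional[Dict[str, int]] = None,
    precomputed: Optional[Dict[Tuple[str, str], float]] = None,
) -> SubgroupPartition:
    """Partition genes into subgroups at identity strictly above *threshold*.

    ``linkage="single"`` takes connected components of the graph with edges
    where identity > threshold; ``"complete"`` requires every intra-block
    pair above threshold (greedy agglomeration, deterministic order).
    Subgroup labels are 1-based, ordered by the genomic position (or input
    order) of each block's first member.
    """
    if not genes:
        raise ValueError("no genes to cluster")
    names = [n for n, _ in genes]
    pid = precomputed if precomputed is not None else screened_identity_matrix(genes, threshold)
    pos = positions or {n: i for i, n in enumerate(names)}

    if linkage == "single":
        parent = {n: n for n in names}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (a, b), p in pid.items():
            if p > threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        blocks: Dict[str, List[str]] = {}
        for n in names:
            blocks.setdefault(find(n), []).append(n)
        groups = list(blocks.values())
    elif linkage == "complete":
        groups = []
        for n in names:
            placed = False
            for g in groups:
                if all(pid[(n, m)] > threshold for m in g):
                    g.append(n)
                    placed = True
                    break
            if not placed:
                groups.append([n])
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    for g in groups:
        g.sort(key=lambda n: pos[n])
    groups.sort(key=lambda g: pos[g[0]])
    return SubgroupPartition(threshold, {i + 1: g for i, g in enumerate(groups)})


@dataclass(frozen=True)
class AlleleAssignment:
    status: str              # "exact" | "allele" | "unassigned"
    gene: Optional[str]      # best germline gene (None only for empty input)
    percent_identity: float
    tied_with: Tuple[str, ...] = ()


def assign_allele(
    cdna_v_region: str,
    germline_genes: Sequence[Tuple[str, str]],
    gene_threshold: float = 97.0,
    positions: Optional[Dict[str, int]] = None,
) -> AlleleAssignment:
    """Assign an expressed V region to a germline gene.

    100% identity -> exact match; identity in (threshold, 100) -> allele of
    the best gene; at or below the threshold (strict ``>``) -> unassigned
    (candidate new gene).  Ties on best identity are broken by earliest
    genomic position and recorded in ``tied_with``.
    """
    if not germline_genes:
        raise ValueError("germline gene set is empty")
    pos = positions or {n: i for i, (n, _) in enumerate(germline_genes)}
    scored = []
    for name, seq in germline_genes:
        pid = pairwise_identity(cdna_v_region, seq, "cdna", name).percent_identity
        scored.append((name, pid))
    best_pid = max(p for _, p in scored)
    ties = sorted([n for n, p in scored if p == best_pid], key=lambda n: pos[n])
    best = ties[0]
    if best_pid == 100.0:
        status = "exact"
    elif best_pid > gene_threshold:
        status = "allele"
    else:
        status = "unassigned"
    return AlleleAssignment(status, best, best_pid, tuple(ties[1:]))
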