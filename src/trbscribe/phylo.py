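"""Distance-based phylogenetics for TRBV subgroup classification.

Trees are reconstructed with canonical Saitou-Nei neighbor joining on
p-distances (proportion of differing sites after complete deletion of
gap/ambiguity columns), with per-split bootstrap support from column
resampling.  ``group_by_reference`` resolves expressed (query) sequences
into germline-anchored groups or provisional new genes, formalizing the
visual group reading of subgroup trees: on the midpoint-rooted tree each
query walks up to its nearest ancestor clade containing a reference leaf;
exactly one reference there means the query inherits that gene's name, two
or more mean the query sits in a reference-free clade and receives a
provisional S-numbered name.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

GAP_CHARS = set("-.")
UNAMBIG = set("ACGT")


# ---------------------------------------------------------------------------
# Distance matrix

@dataclass
class DistanceMatrix:
    """Symmetric matrix of p-distances (substitutions per site)."""

    taxa: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("nonzero diagonal")

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.matrix[i, j])


def p_distance_matrix(
    aligned: Sequence[Tuple[str, str]], deletion: str = "complete"
) -> DistanceMatrix:
    """p-distances between equal-length aligned sequences.

    ``deletion="complete"``: columns containing a gap or ambiguity code in
    any sequence are removed globally before counting differences.
    """
    if len(aligned) < 3:
        raise ValueError("need at least 3 taxa")
    names = [n for n, _ in aligned]
    seqs = [s.upper() for _, s in aligned]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(s) for s in seqs])
    if deletion == "complete":
        ok = np.ones(L, dtype=bool)
        for row in arr:
            ok &= np.isin(row, list(UNAMBIG))
        arr = arr[:, ok]
    elif deletion != "none":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    if arr.shape[1] == 0:
        raise ValueError("no comparable positions after gap/ambiguity removal")
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(arr[i] != arr[j])
    return DistanceMatrix(names, d)


# ---------------------------------------------------------------------------
# Trees

@dataclass
class Clade:
    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: List["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["Clade"]:
        if self.is_leaf:
            return [self]
        out: List[Clade] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> List[str]:
        return [l.name for l in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def newick(self) -> str:
        if self.is_leaf:
            lab = self.name or ""
        else:
            lab = (
                "(" + ",".join(c.newick() for c in self.children) + ")"
                + (f"{self.support:g}" if self.support is not None else "")
            )
        return f"{lab}:{self.length:g}"


@dataclass
class PhyloTree:
    """Unrooted tree stored as a basal multifurcation."""

    root: Clade
    clamped_deficit: float = 0.0   # total negative branch length clamped to 0

    def leaf_names(self) -> List[str]:
        return self.root.leaf_names()

    def total_branch_length(self) -> float:
        return sum(c.length for c in self.root.walk() if c is not self.root)

    def newick(self) -> str:
        return "(" + ",".join(c.newick() for c in self.root.children) + ");"

    def splits(self, nontrivial: bool = True) -> Set[FrozenSet[str]]:
        """Canonical splits: the side not containing the lexicographically
        smallest taxon."""
        all_taxa = set(self.leaf_names())
        anchor = min(all_taxa)
        out: Set[FrozenSet[str]] = set()
        for node in self.root.walk():
            if node is self.root:
                continue
            side = set(node.leaf_names())
            if anchor in side:
                side = all_taxa - side
            if nontrivial and not (2 <= len(side) <= len(all_taxa) - 2):
                continue
            out.add(frozenset(side))
        return out


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Q-matrix pair selection with deterministic tie-break on the smallest
    (i, j) index pair; standard branch-length formulas; negative branch
    lengths clamped to zero with the total deficit recorded on the tree.
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: List[Clade] = [Clade(name=t) for t in d.taxa]
    mat = d.matrix.astype(float).copy()
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = mat[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        u = Clade(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        # distances from u to remaining nodes
        new_row = np.zeros(mat.shape[0] + 1)
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            new_row[k] = 0.5 * (sub[a, c] + sub[b, c] - dij)
        mat = np.pad(mat, ((0, 1), (0, 1)))
        mat[-1, : len(new_row) - 1] = new_row[:-1]
        mat[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(u)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    dij, dik, djk = mat[i, j], mat[i, k], mat[j, k]
    root = Clade(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length = clamp(0.5 * (dij + dik - djk))
    nodes[j].length = clamp(0.5 * (dij + djk - dik))
    nodes[k].length = clamp(0.5 * (dik + djk - dij))
    return PhyloTree(root, clamped_deficit=deficit)


def bootstrap_support(
    aligned: Sequence[Tuple[str, str]],
    n_replicates: int = 1000,
    seed: int = 0,
    deletion: str = "complete",
) -> PhyloTree:
    """NJ tree with per-split bootstrap supports.

    Columns are resampled with replacement; the support of each internal
    split of the reference tree is the percentage of replicate trees
    containing that split.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ref = neighbor_joining(p_distance_matrix(aligned, deletion))
    names = [n for n, _ in aligned]
    L = len(aligned[0][1])
    cols = np.array([list(s.upper()) for _, s in aligned])
    rng = np.random.default_rng(seed)
    counts: Dict[FrozenSet[str], int] = {s: 0 for s in ref.splits()}
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        rep = [(n, "".join(cols[i, idx])) for i, n in enumerate(names)]
        try:
            rt = neighbor_joining(p_distance_matrix(rep, deletion))
        except ValueError:   # replicate with no comparable positions
            continue
        for s in rt.splits():
            if s in counts:
                counts[s] += 1
    all_taxa = set(ref.leaf_names())
    anchor = min(all_taxa)
    for node in ref.root.walk():
        if node is ref.root or node.is_leaf:
            continue
        side = set(node.leaf_names())
        canon = frozenset(all_taxa - side if anchor in side else side)
        if canon in counts:
            node.support = 100.0 * counts[canon] / n_replicates
    return ref


# ---------------------------------------------------------------------------
# Rooting and reference-anchored grouping

def midpoint_root(tree: PhyloTree) -> Clade:
    """Rooted copy of the tree at the midpoint of the longest leaf-leaf path."""
    import copy

    tree = PhyloTree(copy.deepcopy(tree.root), tree.clamped_deficit)
    parent: Dict[int, Optional[Clade]] = {id(tree.root): None}
    for node in tree.root.walk():
        for c in node.children:
            parent[id(c)] = node

    leaves = tree.root.leaves()

    def path_to_root(n: Clade) -> List[Clade]:
        path = [n]
        while parent[id(path[-1])] is not None:
            path.append(parent[id(path[-1])])
        return path

    best = None
    for a, b in itertools.combinations(leaves, 2):
        pa, pb = path_to_root(a), path_to_root(b)
        sa = {id(x) for x in pa}
        lca = next(x for x in pb if id(x) in sa)
        dist = sum(x.length for x in pa[: pa.index(lca)]) + sum(
            x.length for x in pb[: pb.index(lca)]
        )
        if best is None or dist > best[0]:
            best = (dist, a, b, lca, pa, pb)
    total, a, b, lca, pa, pb = best
    # walk from a toward b accumulating branch lengths until half the path
    half = total / 2.0
    chain = pa[: pa.index(lca)] + list(reversed(pb[: pb.index(lca)]))
    # chain entries are nodes whose .length is the edge toward the lca side
    acc = 0.0
    on_a_side = True
    for idx, node in enumerate(chain):
        edge = node.length
        if acc + edge >= half or idx == len(chain) - 1:
            return _reroot_on_edge(tree, node, half - acc)
        acc += edge
    return _reroot_on_edge(tree, chain[-1], chain[-1].length / 2)  # pragma: no cover


def _reroot_on_edge(tree: PhyloTree, child: Clade, dist_from_child: float) -> Clade:
    """Root on the edge above *child*, ``dist_from_child`` along it."""
    parent: Dict[int, Optional[Clade]] = {id(tree.root): None}
    for node in tree.root.walk():
        for c in node.children:
            parent[id(c)] = node
    dist_from_child = min(max(dist_from_child, 0.0), child.length)
    old_len = child.length
    child.length = dist_from_child
    new_root = Clade(children=[child])
    # reverse parent pointers along the path from child's parent to the old root
    below = child                  # node we arrived from (already re-attached)
    node = parent[id(child)]
    edge_above = old_len - dist_from_child   # length of edge from `node` up to its new parent
    attach_to = new_root
    while node is not None:
        nxt = parent[id(node)]
        node.children = [c for c in node.children if id(c) != id(below)]
        next_edge = node.length
        node.length = edge_above
        attach_to.children.append(node)
        attach_to, below, node, edge_above = node, node, nxt, next_edge
    # the old root ends up as an internal node; dissolve unary nodes
    _suppress_unary(new_root)
    return new_root


def _suppress_unary(node: Clade) -> None:
    for c in list(node.children):
        _suppress_unary(c)
    node.children = [
        c.children[0] if (len(c.children) == 1 and _absorb(c)) else c
        for c in node.children
    ]


def _absorb(c: Clade) -> bool:
    # merge a unary internal node into its single child
    child = c.children[0]
    child.length += c.length
    if child.support is None:
        child.support = c.support
    return True


PROVISIONAL_RE = re.compile(r"^(?P<prefix>.*?)-?(?P<num>\d+)$")


def group_by_reference(
    tree: PhyloTree,
    reference_labels: Sequence[str],
    query_labels: Sequence[str],
) -> Dict[str, str]:
    """Map each query leaf to a germline gene name or a provisional new gene.

    On the midpoint-rooted tree, each query's nearest ancestor clade that
    contains at least one reference leaf decides: exactly one reference
    there -> the query inherits its name; otherwise the query belongs to a
    reference-free clade and the whole clade receives a provisional name
    ``<subgroup>S<k>``, numbered after the last germline member of the
    subgroup, in tree traversal order.
    """
    refs = set(reference_labels)
    queries = set(query_labels)
    present = set(tree.leaf_names())
    missing = (refs | queries) - present
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")

    if not refs:
        # no reference anywhere: the whole tree is one provisional group
        return {q: "S1" for q in queries}

    rooted = midpoint_root(tree)
    parent: Dict[int, Optional[Clade]] = {id(rooted): None}
    for node in rooted.walk():
        for c in node.children:
            parent[id(c)] = node
    leaf_by_name = {l.name: l for l in rooted.leaves()}

    assignment: Dict[str, str] = {}
    provisional_clades: List[Tuple[Clade, List[str]]] = []
    claimed: Dict[int, List[str]] = {}

    for q in rooted.leaf_names():
        if q not in queries:
            continue
        node = leaf_by_name[q]
        prev = node
        while node is not None:
            names = set(node.leaf_names())
            n_refs = len(names & refs)
            if n_refs >= 1:
                break
            prev = node
            node = parent[id(node)]
        if node is not None and len(set(node.leaf_names()) & refs) == 1:
            (ref,) = set(node.leaf_names()) & refs
            assignment[q] = ref
        else:
            # prev is the maximal reference-free clade containing q
            claimed.setdefault(id(prev), []).append(q)
            if len(claimed[id(prev)]) == 1:
                provisional_clades.append((prev, claimed[id(prev)]))

    if provisional_clades:
        prefix, k0 = _provisional_base(reference_labels)
        # order clades by traversal order of the rooted tree
        order = {id(n): i for i, n in enumerate(rooted.walk())}
        provisional_clades.sort(key=lambda t: order[id(t[0])])
        for offset, (_, members) in enumerate(provisional_clades):
            name = f"{prefix}S{k0 + 1 + offset}"
            for q in members:
                assignment[q] = name
    return assignment


def _provisional_base(reference_labels: Sequence[str]) -> Tuple[str, int]:
    """Subgroup prefix and the last germline member number among references."""
    prefixes, nums = set(), []
    for r in reference_labels:
        m = PROVISIONAL_RE.match(r)
        if m:
            prefixes.add(m.group("prefix"))
            nums.append(int(m.group("num")))
        else:
            prefixes.add(r)
            nums.append(1)
    prefix = prefixes.pop() if len(prefixes) == 1 else ""
    return prefix, (max(nums) if nums else 0)


# ---------------------------------------------------------------------------
# Internal progressive aligner (guide tree + profile-profile alignment)

def _kmer_distance(a: str, b: str, k: int = 4) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_align(pa: List[List[str]], pb: List[List[str]],
                   gap: float = -2.0) -> Tuple[List[List[str]], List[List[str]]]:
    """Needleman-Wunsch on column profiles, linear gap penalty."""
    def colscore(ca: List[str], cb: List[str]) -> float:
        s = 0.0
        for x in ca:
            for y in cb:
                if x == "-" or y == "-":
                    s += -0.5
                else:
                    s += 1.0 if x == y else -1.0
        return s / (len(ca) * len(cb))

    la, lb = len(pa), len(pb)
    F = np.zeros((la + 1, lb + 1))
    F[:, 0] = gap * np.arange(la + 1)
    F[0, :] = gap * np.arange(lb + 1)
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            opts = (
                (F[i - 1, j - 1] + colscore(pa[i - 1], pb[j - 1]), 0),
                (F[i - 1, j] + gap, 1),
                (F[i, j - 1] + gap, 2),
            )
            F[i, j], ptr[i, j] = max(opts, key=lambda t: t[0])
    na, nb = len(pa[0]), len(pb[0])
    out_a: List[List[str]] = []
    out_b: List[List[str]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and ptr[i, j] == 0:
            out_a.append(pa[i - 1]); out_b.append(pb[j - 1]); i -= 1; j -= 1
        elif i > 0 and (j == 0 or ptr[i, j] == 1):
            out_a.append(pa[i - 1]); out_b.append(["-"] * nb); i -= 1
        else:
            out_a.append(["-"] * na); out_b.append(pb[j - 1]); j -= 1
    out_a.reverse(); out_b.reverse()
    return out_a, out_b


def progressive_align(named_seqs: Sequence[Tuple[str, str]]) -> List[Tuple[str, str]]:
    """Multiple alignment by guide-tree progressive profile alignment.

    A light internal aligner: k-mer guide distances, NJ guide tree,
    post-order profile merging with linear gap penalties.  An externally
    produced alignment can be supplied anywhere one is accepted.
    """
    if not named_seqs:
        raise ValueError("no sequences")
    if len(named_seqs) == 1:
        return list(named_seqs)
    names = [n for n, _ in named_seqs]
    seqs = {n: s.upper() for n, s in named_seqs}

    def merge_order() -> List[Tuple]:
        if len(names) == 2:
            return [(names[0], names[1])]
        n = len(names)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _kmer_distance(seqs[names[i]], seqs[names[j]])
        tree = neighbor_joining(DistanceMatrix(list(names), d))
        pairs: List[Tuple] = []

        def collapse(node: Clade):
            if node.is_leaf:
                return node.name
            parts = [collapse(c) for c in node.children]
            left = parts[0]
            for right in parts[1:]:
                pairs.append((left, right))
                left = (left, right)
            return left

        collapse(tree.root)
        return pairs

    profiles: Dict = {n: ([ [c] for c in seqs[n]], [n]) for n in names}

    def get(key):
        if isinstance(key, str):
            return profiles[key]
        return profiles[key]

    for left, right in merge_order():
        pa, ma = profiles.pop(left)
        pb, mb = profiles.pop(right)
        oa, ob = _profile_align(pa, pb)
        merged = [ca + cb for ca, cb in zip(oa, ob)]
        profiles[(left, right)] = (merged, ma + mb)

    (cols, members), = profiles.values()
    aligned_rows = ["".join(col[i] for col in cols) for i in range(len(members))]
    by_name = dict(zip(members, aligned_rows))
    return [(n, by_name[n]) for n in names]
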