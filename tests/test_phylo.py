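"""p-distances, neighbor joining, bootstrap and reference-anchored grouping."""

import itertools

import numpy as np
import pytest

from trbscribe.phylo import (
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    group_by_reference,
    midpoint_root,
    neighbor_joining,
    p_distance_matrix,
    progressive_align,
)


# ---------------------------------------------------------------------------
# independent oracles

def naive_p_distance(a, b):
    keep = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    return sum(x != y for x, y in keep) / len(keep)


def random_additive_tree(n, rng):
    """Random rooted binary tree with positive branch lengths; returns
    (split set, patristic distance matrix, names)."""
    names = [f"t{i}" for i in range(n)]

    def build(leaves):
        if len(leaves) == 1:
            return {"leaves": leaves, "children": []}
        k = int(rng.integers(1, len(leaves)))
        return {"leaves": leaves,
                "children": [build(leaves[:k]), build(leaves[k:])]}

    order = list(names)
    rng.shuffle(order)
    root = build(order)
    anchor = min(names)
    paths = {}

    def walk2(node, depth):
        if not node["children"]:
            paths[node["leaves"][0]] = depth
            return []
        out = []
        for c in node["children"]:
            ln = lengths[id(c)]
            out.extend(walk2(c, depth + ln))
        return out

    # assign lengths deterministically in one pass
    lengths = {}

    def assign(node):
        for c in node["children"]:
            lengths[id(c)] = float(rng.uniform(0.05, 0.4))
            assign(c)

    assign(root)
    walk2(root, 0.0)

    def lca_depth(node, a, b, depth):
        for c in node["children"]:
            if a in c["leaves"] and b in c["leaves"]:
                return lca_depth(c, a, b, depth + lengths[id(c)])
        return depth

    M = np.zeros((n, n))
    idx = {nm: i for i, nm in enumerate(names)}
    for a, b in itertools.combinations(names, 2):
        d = paths[a] + paths[b] - 2 * lca_depth(root, a, b, 0.0)
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = d

    splits = set()

    def collect(node):
        for c in node["children"]:
            side = set(c["leaves"])
            canon = frozenset(set(names) - side if anchor in side else side)
            if 2 <= len(canon) <= n - 2:
                splits.add(canon)
            collect(c)

    collect(root)
    return splits, M, names


def patristic(tree: PhyloTree):
    """Leaf-to-leaf path lengths of a PhyloTree."""
    parent = {id(tree.root): None}
    for nd in tree.root.walk():
        for c in nd.children:
            parent[id(c)] = nd
    leaves = tree.root.leaves()

    def path(n):
        out = [n]
        while parent[id(out[-1])] is not None:
            out.append(parent[id(out[-1])])
        return out

    D = {}
    for a, b in itertools.combinations(leaves, 2):
        pa, pb = path(a), path(b)
        sa = {id(x) for x in pa}
        lca = next(x for x in pb if id(x) in sa)
        d = sum(x.length for x in pa[: pa.index(lca)]) + \
            sum(x.length for x in pb[: pb.index(lca)])
        D[frozenset((a.name, b.name))] = d
    return D


# ---------------------------------------------------------------------------
# p-distance

def test_identical_sequences_zero_matrix():
    aln = [("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGTACGT")]
    assert np.all(p_distance_matrix(aln).matrix == 0)


def test_single_difference_in_ten_retained_sites():
    aln = [("a", "ACGTACGTAC"), ("b", "ACGTACGTAA"), ("c", "ACGTACGTAC")]
    d = p_distance_matrix(aln)
    assert d[("a", "b")] == pytest.approx(0.1)


def test_complete_deletion_removes_gap_columns():
    aln = [("a", "A-GTACGTAC"), ("b", "ACGTACGTAA"), ("c", "ACGTACNTAC")]
    # columns 1 (gap) and 6 (N) removed globally: 8 retained
    d = p_distance_matrix(aln)
    assert d[("a", "b")] == pytest.approx(1 / 8)


def test_random_alignment_matches_naive_recount(rng):
    seqs = []
    for i in range(5):
        s = "".join(np.array(list("ACGT-"))[rng.integers(0, 5, 50)])
        seqs.append((f"s{i}", s))
    arr = [s for _, s in seqs]
    keep = [j for j in range(50) if all(s[j] in "ACGT" for s in arr)]
    if len(keep) == 0:
        pytest.skip("degenerate draw")
    d = p_distance_matrix(seqs)
    for i in range(5):
        for j in range(i + 1, 5):
            expected = sum(arr[i][k] != arr[j][k] for k in keep) / len(keep)
            assert d.matrix[i, j] == pytest.approx(expected)


def test_no_comparable_positions_errors():
    with pytest.raises(ValueError, match="no comparable"):
        p_distance_matrix([("a", "--"), ("b", "AC"), ("c", "AC")])


# ---------------------------------------------------------------------------
# neighbor joining

def test_three_taxa_closed_form():
    d = DistanceMatrix(["A", "B", "C"],
                       np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]]))
    tree = neighbor_joining(d)
    br = {c.name: c.length for c in tree.root.children}
    assert br["A"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
    assert br["B"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
    assert br["C"] == pytest.approx((0.4 + 0.5 - 0.3) / 2)


def test_five_taxon_additive_recovery(rng):
    splits, M, names = random_additive_tree(5, rng)
    tree = neighbor_joining(DistanceMatrix(names, M))
    assert tree.splits() == splits
    D = patristic(tree)
    for a, b in itertools.combinations(range(5), 2):
        assert D[frozenset((names[a], names[b]))] == pytest.approx(M[a, b])


def test_random_matrix_matches_dendropy_nj(rng):
    """Independent cross-check: dendropy's NJ on the same random (noisy,
    non-additive) matrix yields the same unrooted topology."""
    import dendropy

    n = 6
    names = [f"t{i}" for i in range(n)]
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = rng.uniform(0.1, 1.0)
    mine = neighbor_joining(DistanceMatrix(names, M))

    csv = "," + ",".join(names) + "\n"
    for i, nm in enumerate(names):
        csv += nm + "," + ",".join(str(M[i, j]) for j in range(n)) + "\n"
    import io as _io
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        _io.StringIO(csv), taxon_namespace=dendropy.TaxonNamespace(names))
    dtree = pdm.nj_tree()
    allt = set(names)
    anchor = min(allt)
    dsplits = set()
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = {l.taxon.label for l in nd.leaf_iter()}
        if anchor in side:
            side = allt - side
        if 2 <= len(side) <= n - 2:
            dsplits.add(frozenset(side))
    assert mine.splits() == dsplits


def test_total_branch_length_invariant_under_permutation(rng):
    splits, M, names = random_additive_tree(7, rng)
    t1 = neighbor_joining(DistanceMatrix(names, M))
    perm = list(rng.permutation(7))
    names2 = [names[i] for i in perm]
    M2 = M[np.ix_(perm, perm)]
    t2 = neighbor_joining(DistanceMatrix(names2, M2))
    assert t1.total_branch_length() == pytest.approx(t2.total_branch_length())
    assert t1.splits() == t2.splits()


def test_nonsymmetric_matrix_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b", "c"],
                       np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))


def test_negative_branch_clamped_and_logged():
    # a strongly non-additive matrix forces a negative NJ branch estimate
    M = np.array([
        [0.0, 0.1, 0.6, 0.6],
        [0.1, 0.0, 0.6, 0.6],
        [0.6, 0.6, 0.0, 0.01],
        [0.6, 0.6, 0.01, 0.0],
    ])
    tree = neighbor_joining(DistanceMatrix(list("abcd"), M))
    assert all(c.length >= 0 for c in tree.root.walk() if c is not tree.root)


# ---------------------------------------------------------------------------
# bootstrap

def _two_clade_alignment(rng, diagnostic=50, noise=10):
    left = "".join("ACGT"[i] for i in rng.integers(0, 4, diagnostic))
    right = "".join("ACGT"[(i + 2) % 4] for i in
                    (ord(c) % 4 for c in left))
    def jitter(s, k):
        s = list(s)
        for p in rng.choice(len(s), size=k, replace=False):
            s[p] = "ACGT"[rng.integers(4)]
        return "".join(s)
    return [("a1", jitter(left, 2)), ("a2", jitter(left, 2)), ("a3", jitter(left, 2)),
            ("b1", jitter(right, 2)), ("b2", jitter(right, 2)), ("b3", jitter(right, 2))]


def test_clear_split_gets_high_support(rng):
    aln = _two_clade_alignment(rng)
    tree = bootstrap_support(aln, 100, seed=4)
    supports = {frozenset(set(n.leaf_names())): n.support
                for n in tree.root.walk()
                if n is not tree.root and not n.is_leaf and n.support is not None}
    central = [s for side, s in supports.items()
               if {x[0] for x in side} in ({"a"}, {"b"}) and len(side) == 3]
    assert central and min(central) >= 95


def test_single_replicate_supports_are_binary(rng):
    aln = _two_clade_alignment(rng)
    tree = bootstrap_support(aln, 1, seed=0)
    vals = {n.support for n in tree.root.walk()
            if n.support is not None and not n.is_leaf}
    assert vals <= {0.0, 100.0}


def test_bootstrap_deterministic_for_seed(rng):
    aln = _two_clade_alignment(rng)
    assert bootstrap_support(aln, 30, seed=9).newick() == \
        bootstrap_support(aln, 30, seed=9).newick()


# ---------------------------------------------------------------------------
# grouping and alignment

def _family(base, n, subs, rng):
    out = []
    for _ in range(n):
        s = list(base)
        for p in rng.choice(len(base), size=subs, replace=False):
            s[p] = "ACGT"[rng.integers(4)]
        out.append("".join(s))
    return out


def _diverge(base, k, rng):
    s = list(base)
    for p in rng.choice(len(base), size=k, replace=False):
        s[p] = "ACGT"[rng.integers(4)]
    return "".join(s)


def test_queries_inherit_adjacent_reference(rng):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    fam = _family(base, 3, 5, rng)
    other = _diverge(base, 80, rng)
    aln = [("TRBV4-5", fam[0]), ("q1", fam[1]), ("q2", fam[2]), ("TRBV4-1", other)]
    tree = neighbor_joining(p_distance_matrix(aln))
    res = group_by_reference(tree, ["TRBV4-5", "TRBV4-1"], ["q1", "q2"])
    assert res == {"q1": "TRBV4-5", "q2": "TRBV4-5"}


def test_query_only_clades_get_provisional_names(rng):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    famA = _family(base, 4, 5, rng)
    baseB = _diverge(base, 60, rng)
    famB = _family(baseB, 3, 5, rng)
    baseC = _diverge(base, 110, rng)
    famC = _family(baseC, 3, 5, rng)
    aln = ([("TRBV7-1", famA[0])] + [(f"qa{i}", s) for i, s in enumerate(famA[1:])]
           + [("TRBV7-2", famB[0])] + [(f"qb{i}", s) for i, s in enumerate(famB[1:])]
           + [(f"qc{i}", s) for i, s in enumerate(famC)])
    queries = [n for n, _ in aln if n.startswith("q")]
    tree = neighbor_joining(p_distance_matrix(aln))
    res = group_by_reference(tree, ["TRBV7-1", "TRBV7-2"], queries)
    assert all(res[f"qa{i}"] == "TRBV7-1" for i in range(3))
    assert all(res[f"qb{i}"] == "TRBV7-2" for i in range(2))
    provisional = {res[f"qc{i}"] for i in range(3)}
    assert provisional == {"TRBV7S3"}


def test_single_query_single_reference(rng):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
    q = _diverge(base, 5, rng)
    out = _diverge(base, 50, rng)
    tree = neighbor_joining(p_distance_matrix(
        [("TRBV9", base), ("q", q), ("ctx", out)]))
    assert group_by_reference(tree, ["TRBV9"], ["q"])["q"] == "TRBV9"


def test_reference_free_tree_all_provisional(rng):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
    aln = [(f"q{i}", _diverge(base, 5 + i, rng)) for i in range(3)]
    tree = neighbor_joining(p_distance_matrix(aln))
    res = group_by_reference(tree, [], [n for n, _ in aln])
    assert all(v.startswith("S") for v in res.values())


def test_progressive_align_handles_length_variation():
    aligned = progressive_align([("x", "ACGTACGT"), ("y", "ACGGACGT"),
                                 ("z", "ACGTACG")])
    ln = {len(s) for _, s in aligned}
    assert len(ln) == 1
    assert dict(aligned)["x"].replace("-", "") == "ACGTACGT"
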