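"""Germline annotation: discovery, functionality rules and locus maps."""

import random
from dataclasses import replace

import pytest

from trbscribe.germline import (
    AnnotationConfig,
    GermlineGene,
    annotate_contig,
    annotate_v_gene,
    build_locus_map,
    classify_functionality,
)
from trbscribe.numbering import number_v_domain
from trbscribe.rss import RecombinationSignal
from trbscribe.simulate import LocusSpec, simulate_locus
from Bio.Seq import Seq


def gene_key(g):
    return (g.name, g.gene_type, g.contig_span, g.strand, tuple(g.exons),
            g.functionality, tuple(sorted(g.defect_reasons)))


# ---------------------------------------------------------------------------
# round trips

def test_annotation_round_trips_simulator_truth(locus, annotated):
    """At zero mutation rate every simulated gene is recovered with its
    exact coordinates, exon structure, name and functionality verdict."""
    assert sorted(map(gene_key, annotated.genes)) == \
        sorted(map(gene_key, locus.truth.genes))


def test_cluster_layout_recovered(annotated):
    assert annotated.cluster_order_5to3 == (1, 3, 2)
    j_counts = {label: len(js) for label, (_, js, _) in annotated.clusters.items()}
    assert j_counts == {1: 7, 3: 7, 2: 6}
    assert {annotated.clusters[k][0] for k in (1, 2, 3)} == \
        {"TRBD1", "TRBD2", "TRBD3"}


def test_inverted_v_gene_on_minus_strand(annotated):
    minus = [g for g in annotated.v_genes if g.strand == "-"]
    assert len(minus) == 1
    assert minus[0].start > max(g.end for g in annotated.genes
                                if g.gene_type == "C")


def test_planted_defects_recovered(locus, annotated):
    truth_defects = {g.name: tuple(sorted(g.defect_reasons))
                     for g in locus.truth.v_genes}
    ann_defects = {g.name: tuple(sorted(g.defect_reasons))
                   for g in annotated.v_genes}
    assert ann_defects == truth_defects
    codes = {c for v in ann_defects.values() for c in v}
    # the generator plants every pseudogene rule at the pig default size
    assert {"a", "c", "e"} <= codes


def test_defective_j_is_the_only_nonfunctional(annotated):
    """Exactly one J carries the 5th-position heptamer mutation and is the
    only non-functional J gene in the default locus."""
    bad = [g for g in annotated.j_genes if g.functionality != "F"]
    assert len(bad) == 1
    assert bad[0].name == "TRBJ1-4"
    assert bad[0].defect_reasons == ["RSS"]
    assert bad[0].rss[0].heptamer_matches == 6


# ---------------------------------------------------------------------------
# annotate_v_gene on planted constructs

def _v_segment(lesion, seed=3):
    spec = LocusSpec(n_v_genes=2, n_subgroups=2, pseudogene_fraction=0.0,
                     cluster_layout=((2, 14),), inverted_v=False, seed=seed)
    loc = simulate_locus(spec)
    return loc


def test_planted_stop_codon_yields_rule_e(locus):
    stops = [g for g in locus.truth.v_genes if g.defect_reasons == ["e"]]
    assert stops, "default locus plants stop/frameshift lesions"
    ann = annotate_v_gene(locus.contig, (stops[0].start - 10, stops[0].rss[0].heptamer_start + 5))
    assert ann.functionality == "P"
    assert "e" in ann.defect_reasons


def test_deleted_leader_yields_rule_a(locus):
    lead = [g for g in locus.truth.v_genes if g.defect_reasons == ["a"]]
    assert lead
    ann = annotate_v_gene(locus.contig, (lead[0].start - 10, lead[0].rss[0].heptamer_start + 5))
    assert ann.functionality == "P"
    assert "a" in ann.defect_reasons


def test_missing_rss_reported(locus):
    g = [x for x in locus.truth.v_genes if x.functionality == "F"][0]
    # cut the segment just before the signal so none can be found
    segment = locus.contig[g.start - 20 : g.rss[0].heptamer_start]
    ann = annotate_v_gene(segment, (0, len(segment)))
    assert "RSS-missing" in ann.defect_reasons
    assert ann.functionality != "F"


# ---------------------------------------------------------------------------
# classify_functionality

def _f_gene():
    return GermlineGene(
        name="V", gene_type="V", contig_span=(0, 100),
        rss=(RecombinationSignal(0, 23, 7, 9, "forward"),),
        leader_ok=True, splice_ok=True, length_ok=True, frame_ok=True,
        no_stops=True, anchors_ok=True,
    )


def test_intact_gene_is_functional():
    verdict, defects = classify_functionality(_f_gene())
    assert (verdict, defects) == ("F", [])


@pytest.mark.parametrize("field,value,expected", [
    ("leader_ok", False, "P"),
    ("splice_ok", False, "P"),
    ("length_ok", False, "P"),
    ("frame_ok", False, "P"),
    ("no_stops", False, "P"),
    ("anchors_ok", False, "ORF"),
])
def test_single_defect_never_functional(field, value, expected):
    g = _f_gene()
    setattr(g, field, value)
    verdict, defects = classify_functionality(g)
    assert verdict == expected and defects


def test_rss_defect_gives_orf():
    g = _f_gene()
    g.rss = (RecombinationSignal(0, 23, 6, 9, "forward"),)
    verdict, defects = classify_functionality(g)
    assert verdict == "ORF" and defects == ["RSS"]


def test_classification_monotone_under_added_defects():
    """Adding any defect to any gene never moves the verdict toward F."""
    rank = {"F": 0, "ORF": 1, "P": 2}
    fields = ["leader_ok", "splice_ok", "length_ok", "frame_ok",
              "no_stops", "anchors_ok"]
    rnd = random.Random(0)
    for _ in range(50):
        g = _f_gene()
        broken = rnd.sample(fields, rnd.randint(0, 3))
        for f in broken:
            setattr(g, f, False)
        before, _ = classify_functionality(g)
        extra = rnd.choice(fields)
        setattr(g, extra, False)
        after, _ = classify_functionality(g)
        assert rank[after] >= rank[before]


def test_functional_v_translations_carry_anchors(annotated):
    """Every F-classified V gene has C at IMGT 23 and 104 and W at 41."""
    for g in annotated.v_genes:
        if g.functionality != "F":
            continue
        dom = number_v_domain(g.translated, partial=True)
        aa = g.translated
        assert aa[dom.anchors["cys23"]] == "C"
        assert aa[dom.anchors["cys104"]] == "C"
        assert aa[dom.anchors["trp41"]] == "W"


def test_j_fgxg_required_for_functionality(annotated):
    for g in annotated.j_genes:
        if g.functionality == "F":
            aa = str(Seq(g.coding_nt).translate())
            assert any(aa[i] == "F" and aa[i + 1] == "G" and aa[i + 3] == "G"
                       for i in range(len(aa) - 3))


# ---------------------------------------------------------------------------
# locus map construction

def test_single_cluster_toy_locus():
    loc = simulate_locus(LocusSpec(n_v_genes=2, n_subgroups=2,
                                   pseudogene_fraction=0.0,
                                   cluster_layout=((3, 14),),
                                   inverted_v=False, seed=4))
    assert loc.truth.cluster_order_5to3 == (1,)
    assert len(loc.truth.clusters[1][1]) == 3
    ann = annotate_contig(loc.contig)
    assert sorted(map(gene_key, ann.genes)) == sorted(map(gene_key, loc.truth.genes))


def test_shuffled_gene_list_gives_identical_map(locus):
    genes = list(locus.truth.genes)
    rnd = random.Random(1)
    shuffled = genes[:]
    rnd.shuffle(shuffled)
    import copy
    m1 = build_locus_map(copy.deepcopy(genes), "c")
    m2 = build_locus_map(copy.deepcopy(shuffled), "c")
    assert [g.name for g in m1.genes] == [g.name for g in m2.genes]
    assert m1.clusters == m2.clusters


def test_orphan_j_rejected(locus):
    genes = [g for g in locus.truth.genes if g.gene_type == "J"][:2]
    import copy
    with pytest.raises(ValueError, match="no C gene"):
        build_locus_map(copy.deepcopy(genes))
    c = [g for g in locus.truth.genes if g.gene_type == "C"][0]
    j_after_c = [g for g in locus.truth.genes
                 if g.gene_type == "J" and g.start > max(
                     x.end for x in locus.truth.genes if x.gene_type == "C")]
    # construct an orphan: one J downstream of the only C
    j = copy.deepcopy(genes[0])
    j.contig_span = (c.end + 100, c.end + 160)
    j.exons = [(c.end + 110, c.end + 155)]
    with pytest.raises(ValueError, match="orphan J"):
        build_locus_map([copy.deepcopy(c), j])
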