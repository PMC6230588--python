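"""Shared fixtures: one simulated pig-like locus and repertoires derived
from it, reused across the suite to keep the run fast."""

import numpy as np
import pytest

from trbscribe.germline import annotate_contig
from trbscribe.repertoire import analyze_repertoire
from trbscribe.simulate import (
    LocusSpec,
    RepertoireSpec,
    simulate_locus,
    simulate_repertoire,
)

LOCUS_SEED = 5


@pytest.fixture(scope="session")
def locus():
    return simulate_locus(LocusSpec(seed=LOCUS_SEED))


@pytest.fixture(scope="session")
def annotated(locus):
    return annotate_contig(locus.contig, "synthetic_locus")


@pytest.fixture(scope="session")
def analysis_inputs(locus):
    tm = locus.truth
    return {
        "v_regions": [(g.name, g.v_region_nt) for g in tm.v_genes],
        "j_codings": [(n, p["coding"], p["head_len"])
                      for n, p in locus.j_payload.items()],
        "d_genes": [(g.name, g.coding_nt,
                     tm.cluster_order_5to3.index(g.cluster))
                    for g in tm.d_genes],
    }


def _records(rep):
    return [
        (r["clone_id"], r["tissue"], s.split("\n")[1])
        for r, s in zip(rep.truth.to_dict("records"),
                        rep.fasta.strip().split(">")[1:])
    ]


@pytest.fixture(scope="session")
def clean_repertoire(locus):
    """Zero trimming, zero substitutions: the lossless case."""
    rep = simulate_repertoire(
        locus, RepertoireSpec(n_clones=100, trim_mean=0.0,
                              substitution_rate=0.0, seed=7)
    )
    return rep, _records(rep)


@pytest.fixture(scope="session")
def clean_analysis(locus, analysis_inputs, clean_repertoire):
    rep, records = clean_repertoire
    clones = analyze_repertoire(
        records, locus.truth,
        v_regions=analysis_inputs["v_regions"],
        j_codings=analysis_inputs["j_codings"],
    )
    return rep, clones


@pytest.fixture(scope="session")
def noisy_repertoire(locus):
    """Default study-like conditions: trimming mean 2/end, substitutions."""
    rep = simulate_repertoire(
        locus, RepertoireSpec(n_clones=500, trim_mean=2.0, seed=11)
    )
    return rep, _records(rep)


@pytest.fixture(scope="session")
def noisy_analysis(locus, analysis_inputs, noisy_repertoire):
    rep, records = noisy_repertoire
    clones = analyze_repertoire(
        records, locus.truth,
        v_regions=analysis_inputs["v_regions"],
        j_codings=analysis_inputs["j_codings"],
    )
    return rep, clones


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
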