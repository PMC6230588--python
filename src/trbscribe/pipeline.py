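"""End-to-end pipeline: simulate (or load) a locus, annotate it, analyze a
repertoire against it, and write every artifact with a manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .germline import AnnotationConfig, annotate_contig
from .io import (
    PipelineConfig,
    parse_clone_fasta,
    write_airr_tsv,
    write_clone_tsv,
    write_fasta,
    write_gff3,
    write_usage_tsv,
)
from .repertoire import analyze_repertoire, cdr3_stats, usage_matrix
from .simulate import LocusSpec, RepertoireSpec, simulate_locus, simulate_repertoire

log = logging.getLogger("trbscribe")


def run_pipeline(
    config: PipelineConfig,
    locus_fasta: Optional[str] = None,
    cdna_fasta: Optional[str] = None,
) -> Dict:
    """Run every stage and return the result bundle.

    Without input paths, the synthetic generator supplies both the locus
    and the repertoire (with the config's seeds), so a full run needs no
    external data.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann_cfg = AnnotationConfig(
        discovery_min_heptamer=config.discovery_min_heptamer,
        discovery_min_nonamer=config.discovery_min_nonamer,
        functional_min_heptamer=config.functional_min_heptamer,
        functional_min_nonamer=config.functional_min_nonamer,
    )
    log.info("thresholds: subgroup>%s gene>%s min_d_len=%s",
             config.subgroup_threshold, config.gene_threshold, config.min_d_len)

    manifest: Dict[str, str] = {}
    sim = None
    if locus_fasta is None:
        sim = simulate_locus(LocusSpec(seed=config.locus_seed), config=ann_cfg)
        contig = sim.contig
        contig_id = "synthetic_locus"
        (out / "locus.fa").write_text(sim.fasta())
        manifest["locus_fasta"] = "locus.fa"
        log.info("simulated locus: %d bp", len(contig))
    else:
        from .io import read_fasta

        (name, contig), *_ = read_fasta(locus_fasta)
        contig_id = name.split()[0]

    locus_map = annotate_contig(
        contig, contig_id, config=ann_cfg,
        subgroup_threshold=config.subgroup_threshold,
    )
    write_gff3(locus_map, out / "locus.gff3")
    manifest["locus_gff3"] = "locus.gff3"
    log.info("annotated %d genes in %d clusters",
             len(locus_map.genes), len(locus_map.clusters))

    if cdna_fasta is None:
        if sim is None:
            raise ValueError("cannot simulate a repertoire for an external locus")
        rep_spec = RepertoireSpec(
            n_clones=config.n_clones, trim_mean=config.trim_mean,
            n_addition_mean=config.n_addition_mean,
            substitution_rate=config.substitution_rate,
            trans_probability=config.trans_probability,
            seed=config.repertoire_seed,
        )
        rep = simulate_repertoire(sim, rep_spec)
        (out / "clones.fa").write_text(rep.fasta)
        rep.truth.to_csv(out / "clones_truth.tsv", sep="\t", index=False)
        manifest["clones_fasta"] = "clones.fa"
        manifest["clones_truth"] = "clones_truth.tsv"
        records = [
            (r["clone_id"], r["tissue"], s.split("\n")[1])
            for r, s in zip(rep.truth.to_dict("records"),
                            rep.fasta.strip().split(">")[1:])
        ]
    else:
        records = parse_clone_fasta(cdna_fasta)

    if sim is not None:
        v_regions = [(g.name, g.v_region_nt) for g in sim.truth.v_genes]
        j_codings = [(n, p["coding"], p["head_len"]) for n, p in sim.j_payload.items()]
        clones = analyze_repertoire(records, sim.truth, v_regions=v_regions,
                                    j_codings=j_codings,
                                    min_d_len=config.min_d_len,
                                    gene_threshold=config.gene_threshold)
    else:
        clones = analyze_repertoire(records, locus_map,
                                    min_d_len=config.min_d_len,
                                    gene_threshold=config.gene_threshold)

    write_clone_tsv(clones, out / "clones.tsv")
    write_airr_tsv(clones, out / "clones_airr.tsv")
    manifest["clone_table"] = "clones.tsv"
    manifest["airr_table"] = "clones_airr.tsv"

    summary: Dict = {"n_clones": len(clones), "tissues": {}}
    for tissue in sorted({c.tissue for c in clones}):
        um = usage_matrix(clones, tissue)
        write_usage_tsv(um, out / f"usage_{tissue}.tsv")
        manifest[f"usage_{tissue}"] = f"usage_{tissue}.tsv"
        entry: Dict = {"grand_total": um.grand_total}
        try:
            entry["cdr3"] = cdr3_stats(clones, tissue)
        except ValueError:
            entry["cdr3"] = None
        summary["tissues"][tissue] = entry
    summary["rearrangement_classes"] = {
        k: sum(1 for c in clones if c.rearrangement_class == k)
        for k in ("intra", "inter", "trans", "undetermined")
    }
    summary["d_calls"] = {
        k: sum(1 for c in clones if c.d_call is not None and c.d_call.status == k)
        for k in ("unique", "ambiguous", "two-D", "none")
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["summary"] = "summary.json"

    return {
        "locus_map": locus_map,
        "clones": clones,
        "summary": summary,
        "manifest": manifest,
        "simulated": sim,
    }
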