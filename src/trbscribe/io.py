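"""Readers, writers, packaged fixture tables and pipeline configuration.

Fixtures transcribe the published pig TRB usage and germline/cDNA
correspondence tables; their printed margins are re-verified against
recomputed sums at load time.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .germline import GermlineGene, LocusMap
from .phylo import PhyloTree
from .repertoire import RepertoireClone, UsageMatrix


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> List[Tuple[str, str]]:
    """(record id, sequence) pairs; raises on malformed records."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.seq:
            raise ValueError(f"empty sequence for record {rec.id!r}")
        out.append((rec.description, str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(s), id=name.split()[0], description=name) for name, s in records]
    SeqIO.write(recs, str(path), "fasta")


def parse_clone_fasta(path) -> List[Tuple[str, str, str]]:
    """Clone FASTA with headers ``clone_id|tissue=<tissue>``."""
    out = []
    for header, seq in read_fasta(path):
        clone_id = header.split("|")[0].strip()
        tissue = "unknown"
        for tokenpart in header.split("|")[1:]:
            if tokenpart.startswith("tissue="):
                tissue = tokenpart.split("=", 1)[1].strip()
        out.append((clone_id, tissue, seq))
    return out


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(locus_map: LocusMap, path) -> None:
    """One gene-level feature per gene plus one exon feature per exon.

    Coordinates are 1-based inclusive, per GFF3; internal coordinates are
    0-based half-open.
    """
    lines = ["##gff-version 3"]
    contig = locus_map.contig_id
    for k, g in enumerate(locus_map.genes):
        gid = f"gene{k:03d}"
        attrs = (
            f"ID={gid};Name={g.name};gene_type={g.gene_type};"
            f"functionality={g.functionality}"
        )
        if g.defect_reasons:
            attrs += ";defect_reasons=" + ",".join(g.defect_reasons)
        if g.cluster is not None:
            attrs += f";cluster={g.cluster}"
        lines.append(
            "\t".join([contig, "trbscribe", "gene", str(g.start + 1), str(g.end),
                       ".", g.strand, ".", attrs])
        )
        for e_idx, (a, b) in enumerate(g.exons):
            lines.append(
                "\t".join([contig, "trbscribe", "exon", str(a + 1), str(b),
                           ".", g.strand, ".",
                           f"ID={gid}.e{e_idx};Parent={gid}"])
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_genes(path) -> List[dict]:
    """Minimal reader for the gene-level features written above."""
    genes = []
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 at line {n}")
        if fields[2] != "gene":
            continue
        attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
        genes.append({
            "name": attrs.get("Name", ""),
            "gene_type": attrs.get("gene_type", ""),
            "start": int(fields[3]) - 1,
            "end": int(fields[4]),
            "strand": fields[6],
            "functionality": attrs.get("functionality", ""),
            "defect_reasons": attrs.get("defect_reasons", "").split(",")
            if attrs.get("defect_reasons") else [],
        })
    return genes


# ---------------------------------------------------------------------------
# Newick / TSV

def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def write_usage_tsv(matrix: UsageMatrix, path) -> None:
    matrix.with_margins().to_csv(path, sep="\t", index_label="v_gene")


def write_clone_tsv(clones: Sequence[RepertoireClone], path) -> None:
    rows = [{
        "clone_id": c.clone_id, "tissue": c.tissue,
        "v_call": c.v_call or "", "v_identity": c.v_identity,
        "v_status": c.v_status, "j_call": c.j_call,
        "d_call": c.d_call_label,
        "junction_nt": c.junction_nt, "cdr3_aa": c.cdr3_aa,
        "cdr3_len": c.cdr3_len if c.cdr3_len is not None else "",
        "rearrangement_class": c.rearrangement_class,
        "errors": ";".join(c.errors),
    } for c in clones]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_airr_tsv(clones: Sequence[RepertoireClone], path) -> None:
    """AIRR-style rearrangement dialect (standard column names)."""
    rows = [{
        "sequence_id": c.clone_id,
        "v_call": c.v_call or "",
        "d_call": c.d_call_label if c.d_call else "",
        "j_call": "" if c.j_call == "nd" else c.j_call,
        "junction": c.junction_nt,
        "junction_aa": c.cdr3_aa,
        "productive": "T" if c.cdr3_len is not None else "F",
        "tissue": c.tissue,
    } for c in clones]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixture tables

def _data_path(name: str):
    return importlib.resources.files("trbscribe.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Germline gene vs best-matching expressed cDNA (gene, functionality,
    accession, % identity)."""
    df = pd.read_csv(_data_path("table1_germline_cdna.tsv"), sep="\t",
                     dtype={"identity_pct": float})
    return df


def _load_usage(name: str) -> pd.DataFrame:
    df = pd.read_csv(_data_path(name), sep="\t", index_col=0)
    body = df.drop(index="Total")
    counts = body.drop(columns="total")
    # internal consistency of the transcription
    if not (counts.sum(axis=1) == body["total"]).all():
        raise ValueError(f"{name}: row totals disagree with cells")
    totals = df.loc["Total"]
    if not (counts.sum(axis=0) == totals.drop("total")).all():
        raise ValueError(f"{name}: column totals disagree with cells")
    if counts.values.sum() != totals["total"]:
        raise ValueError(f"{name}: grand total disagrees with cells")
    return counts


def load_table2() -> pd.DataFrame:
    """Peripheral-blood V x J usage counts (includes the verbatim 'TRBV5S4'
    row that the source table carries without introducing it elsewhere)."""
    return _load_usage("table2_pbl_usage.tsv")


def load_table3() -> pd.DataFrame:
    """Thymus V x J usage counts."""
    return _load_usage("table3_thymus_usage.tsv")


def usage_table_to_clones(counts: pd.DataFrame, tissue: str) -> List[RepertoireClone]:
    """Expand a printed usage table into per-clone records."""
    clones = []
    k = 0
    for v_gene, row in counts.iterrows():
        for j_gene, n in row.items():
            for _ in range(int(n)):
                clones.append(RepertoireClone(
                    clone_id=f"{tissue}{k:04d}", tissue=tissue,
                    v_call=str(v_gene), v_status="fixture",
                    j_call=str(j_gene),
                ))
                k += 1
    return clones


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class PipelineConfig:
    """Thresholds, scoring and I/O settings of the full pipeline."""

    subgroup_threshold: float = 75.0
    gene_threshold: float = 97.0
    min_d_len: int = 5
    discovery_min_heptamer: int = 5
    discovery_min_nonamer: int = 6
    functional_min_heptamer: int = 7
    functional_min_nonamer: int = 7
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    bootstrap_replicates: int = 100
    seed: int = 0
    locus_seed: int = 0
    repertoire_seed: int = 0
    n_clones: int = 197
    trim_mean: float = 2.0
    n_addition_mean: float = 3.0
    substitution_rate: float = 0.005
    trans_probability: float = 0.03
    out_dir: str = "trbscribe_out"

    def validate(self) -> None:
        if not (0 < self.subgroup_threshold < 100):
            raise ValueError("subgroup_threshold outside (0, 100)")
        if not (0 < self.gene_threshold < 100):
            raise ValueError("gene_threshold outside (0, 100)")
        if self.min_d_len < 1:
            raise ValueError("min_d_len must be >= 1")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
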