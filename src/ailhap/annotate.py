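"""Map significant regions to overlapping genes from a GTF.

Intervals are 1-based inclusive on both sides (GTF convention); a gene is
reported for a region whenever they share at least one base, strand
ignored.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["read_gtf_genes", "overlap_genes"]


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Gene features from a GTF: gene_id, name, chrom, start, end, strand."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for g in db.features_of_type("gene"):
        name = g.attributes.get("gene_name", g.attributes.get("gene_id", ["?"]))[0]
        rows.append(
            dict(
                gene_id=g.attributes.get("gene_id", [g.id])[0],
                name=name,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand,
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "name", "chrom", "start", "end", "strand"])


def overlap_genes(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping each region by ≥1 bp (closed intervals).

    ``regions`` needs columns chrom, start_bp, end_bp.  Raises when no
    region chromosome matches any gene chromosome, which almost always
    means the two inputs use different naming schemes.
    """
    gene_chroms = set(genes["chrom"])
    reg_chroms = set(regions["chrom"])
    if reg_chroms and not (reg_chroms & gene_chroms):
        raise ValueError(
            f"no region chromosome matches the annotation "
            f"(regions use {sorted(reg_chroms)[:3]}, genes use {sorted(gene_chroms)[:3]}); "
            "consider renaming chromosomes"
        )
    trees: dict[str, IntervalTree] = {}
    for _, g in genes.iterrows():
        # +1: IntervalTree is half-open, GTF is closed
        trees.setdefault(g["chrom"], IntervalTree()).addi(g["start"], g["end"] + 1, g["name"])
    rows = []
    for _, r in regions.iterrows():
        tree = trees.get(r["chrom"])
        hits = sorted({iv.data for iv in tree.overlap(r["start_bp"], r["end_bp"] + 1)}) if tree else []
        rows.append(
            dict(
                chrom=r["chrom"],
                start_bp=int(r["start_bp"]),
                end_bp=int(r["end_bp"]),
                n_genes=len(hits),
                genes=",".join(hits),
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_genes", "genes"])
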