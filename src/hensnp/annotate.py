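"""SNP-to-gene mapping within a +/-5 kb window, and trait-set overlaps.

A SNP is assigned to every protein-coding gene whose body, expanded by the
window on both sides, contains the SNP position (coordinates 1-based,
boundaries inclusive).  The location label is ``intragenic`` when the SNP
lies inside the gene body, otherwise ``upstream``/``downstream`` relative
to the gene's strand (the 5' side is upstream).  No nearest-gene
collapsing: a SNP equidistant to two genes yields two hits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["GeneModel", "read_gff3", "map_snps_to_genes", "venn_counts"]

GENE_COLUMNS = ["gene_id", "name", "biotype", "chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    name: str
    biotype: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    strand: str


def read_gff3(path, biotype: str | None = "protein_coding") -> pd.DataFrame:
    """Read gene records from a GFF3 file into a gene table.

    Only ``gene``-type records of the requested biotype are retained
    (``biotype=None`` keeps all).  Raises on malformed lines (wrong column
    count, end < start) with the offending line number.
    """
    import gffutils

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"malformed GFF3 line {lineno} in {path}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
        )
    except Exception as exc:  # pragma: no cover - gffutils wraps many causes
        raise ValueError(f"malformed GFF3 file {path}: {exc}") from exc

    rows = []
    for feat in db.features_of_type("gene"):
        bt = feat.attributes.get("biotype", feat.attributes.get("gene_biotype", [None]))[0]
        if biotype is not None and bt != biotype:
            continue
        if feat.end < feat.start:
            raise ValueError(
                f"gene {feat.id} has end < start ({feat.end} < {feat.start}) in {path}"
            )
        gid = feat.id.split(":", 1)[-1]
        rows.append(
            dict(
                gene_id=gid,
                name=feat.attributes.get("Name", [gid])[0],
                biotype=bt,
                chrom=str(feat.seqid),
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand,
            )
        )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def map_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 5_000
) -> pd.DataFrame:
    """Map SNPs to genes within ``window_bp`` of the gene body.

    Parameters
    ----------
    snps : DataFrame with at least ``snp_id, chrom, pos``
    genes : DataFrame with ``gene_id, name, chrom, start, end, strand``
    window_bp : flank added to both gene ends; boundaries inclusive

    Returns
    -------
    DataFrame ``snp_id, gene_id, name, location, distance`` with one row
    per (SNP, gene) pair; ``distance`` is 0 for intragenic SNPs, else base
    pairs to the nearest gene boundary.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(genes.itertuples()):
        # IntervalTree is half-open; +1 makes [start-w, end+w] inclusive
        trees.setdefault(str(r.chrom), IntervalTree()).addi(
            r.start - window_bp, r.end + window_bp + 1, i
        )

    rows = []
    for s in snps.itertuples():
        tree = trees.get(str(s.chrom))
        if tree is None:
            continue
        for iv in sorted(tree.at(int(s.pos)), key=lambda iv: iv.data):
            g = genes.iloc[iv.data]
            pos = int(s.pos)
            if g.start <= pos <= g.end:
                location, distance = "intragenic", 0
            else:
                distance = g.start - pos if pos < g.start else pos - g.end
                before = pos < g.start  # on the lower-coordinate side
                if g.strand == "-":
                    location = "downstream" if before else "upstream"
                else:
                    location = "upstream" if before else "downstream"
            rows.append(
                dict(
                    snp_id=s.snp_id,
                    gene_id=g.gene_id,
                    name=g["name"],
                    location=location,
                    distance=int(distance),
                )
            )
    out = pd.DataFrame(rows, columns=["snp_id", "gene_id", "name", "location", "distance"])
    return out.drop_duplicates(subset=["snp_id", "gene_id"]).reset_index(drop=True)


def venn_counts(gene_sets: dict[str, set]) -> dict[tuple, int]:
    """Counts of all 2^k - 1 disjoint membership regions of k gene sets.

    Keys are sorted tuples of the set names an element belongs to; values
    sum to the size of the union.  Regions with zero members are included.
    """
    if not gene_sets:
        raise ValueError("gene_sets must not be empty")
    names = sorted(gene_sets)
    counts: dict[tuple, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(gene_sets[n]) for n in combo))
            outside = set.union(set(), *(set(gene_sets[n]) for n in names if n not in combo))
            counts[combo] = len(inside - outside)
    return counts
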