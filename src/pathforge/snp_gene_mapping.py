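"""Windowed SNP-to-gene mapping and mapping-density diagnostics.

A SNP is assigned to every gene whose interval intersects the closed window
``[pos - W, pos + W]`` on the same chromosome, so the mapping is many-to-many
and grows monotonically with W.  The mean number of mappings per mapped SNP
is the standard diagnostic for choosing W: small windows leave gene-desert
SNPs unmapped, large windows let one significant SNP feed many genes and can
inflate whole gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats_io import GeneAnnotation, SumStats


@dataclass
class MappingTable:
    """Many-to-many SNP<->gene assignment at window ``window_bp``.

    ``df`` columns: ``snp, gene, distance`` where distance is base pairs from
    the SNP to the nearest gene edge (0 when the SNP lies inside the gene).
    """

    df: pd.DataFrame
    window_bp: int

    def __post_init__(self) -> None:
        for c in ("snp", "gene", "distance"):
            if c not in self.df.columns:
                raise ValueError(f"MappingTable missing column {c!r}")
        self.df = self.df.loc[:, ["snp", "gene", "distance"]].reset_index(drop=True)
        if len(self.df) and self.df.duplicated(["snp", "gene"]).any():
            raise ValueError("duplicate (snp, gene) pair in mapping")
        if len(self.df) and int(self.df["distance"].max()) > self.window_bp:
            raise ValueError("mapping distance exceeds window")

    def __len__(self) -> int:
        return len(self.df)

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.df["snp"], self.df["gene"]))


@dataclass
class MappingSummary:
    n_snps_input: int
    n_snps_mapped: int
    n_mappings: int
    n_snps_unmapped: int
    mean_mappings_per_snp: float | None

    @property
    def mean_display(self) -> float | None:
        """Mean rounded to one decimal, the conventional reporting precision."""
        if self.mean_mappings_per_snp is None:
            return None
        return round(self.mean_mappings_per_snp, 1)


def map_snps(snps: SumStats, genes: GeneAnnotation, window_bp: int) -> MappingTable:
    """Map each SNP to all genes within ``window_bp`` of its position.

    Window endpoints are closed on both sides: a gene touching
    ``pos - window_bp`` or ``pos + window_bp`` exactly counts as mapped.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    trees: dict[str, IntervalTree] = {}
    gdf = genes.df
    for chrom, sub in gdf.groupby("chrom", sort=False):
        # +1: intervaltree is half-open, internal coordinates are closed
        trees[chrom] = IntervalTree.from_tuples(
            (s, e + 1, g) for s, e, g in zip(sub["start"], sub["end"], sub["gene"])
        )
    rows = []
    for row in snps.df.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.pos - window_bp, row.pos + window_bp + 1):
            start, end = iv.begin, iv.end - 1
            if row.pos < start:
                dist = start - row.pos
            elif row.pos > end:
                dist = row.pos - end
            else:
                dist = 0
            rows.append((row.snp, iv.data, dist))
    df = pd.DataFrame(rows, columns=["snp", "gene", "distance"])
    return MappingTable(df, window_bp=window_bp)


def mapping_summary(table: MappingTable, n_snps_input: int) -> MappingSummary:
    """Mapping-density counts; mean mappings per *mapped* SNP."""
    n_mappings = len(table)
    n_mapped = int(table.df["snp"].nunique())
    return summarize_counts(n_snps_input, n_mapped, n_mappings)


def summarize_counts(n_snps_input: int, n_snps_mapped: int, n_mappings: int) -> MappingSummary:
    """Build a :class:`MappingSummary` from raw counts.

    Exposed separately so published (mapped SNPs, total mappings) count pairs
    can be summarised without the underlying mapping table.
    """
    if n_snps_mapped > n_snps_input:
        raise ValueError("more mapped SNPs than input SNPs")
    if n_snps_mapped == 0:
        mean = None
    else:
        mean = n_mappings / n_snps_mapped
    return MappingSummary(
        n_snps_input=n_snps_input,
        n_snps_mapped=n_snps_mapped,
        n_mappings=n_mappings,
        n_snps_unmapped=n_snps_input - n_snps_mapped,
        mean_mappings_per_snp=mean,
    )


def unmapped_snps(snps: SumStats, table: MappingTable) -> list[str]:
    """SNPs with no gene within the window (gene-desert ledger)."""
    mapped = set(table.df["snp"])
    return [s for s in snps.df["snp"] if s not in mapped]
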