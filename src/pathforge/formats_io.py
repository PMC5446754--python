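"""Readers and writers for the standard files the pipeline touches.

Coordinate convention
---------------------
All coordinates inside the package are **1-based, fully closed** intervals,
the convention of dbSNP positions and GWAS summary-statistics tables.  BED
input (0-based, half-open) is converted once, at the boundary: a BED line
``chr1  999  2000  GENE1`` becomes the internal interval ``[1000, 2000]``.
Chromosome labels are normalised by stripping a leading ``chr``.

Validation is strict and loud: readers drop individually invalid rows (and
count them), but structural problems — duplicate identifiers, inverted
intervals, empty gene sets — raise with the offending line identified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ("snp", "chrom", "pos", "p")

#: default column-name mapping for summary-statistics tables; keys are the
#: internal names, values the column headers expected in the file.
DEFAULT_DIALECT = {"snp": "snp", "chrom": "chr", "pos": "pos", "p": "p"}


def _parse_float(series: pd.Series) -> pd.Series:
    """Correctly rounded string->float conversion (invalid entries -> NaN).

    ``pd.to_numeric`` uses a fast but lossy parser; round-tripping summary
    statistics bit-identically requires the exact one.
    """

    def conv(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    return series.map(conv)


def normalize_chrom(labels) -> pd.Series:
    """Strip a leading ``chr`` prefix and return string labels."""
    s = pd.Series(labels, dtype="string").str.replace(r"^chr", "", regex=True)
    return s.astype(str)


@dataclass
class SumStats:
    """Per-variant association results for one cohort.

    ``df`` holds columns ``snp, chrom, pos, p`` sorted by (chrom, pos);
    p-values lie in (0, 1], positions are 1-based, variant ids unique.
    """

    df: pd.DataFrame
    cohort_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"SumStats missing columns: {missing}")
        df = self.df.loc[:, list(SUMSTATS_COLUMNS)].copy()
        df["snp"] = df["snp"].astype(str)
        df["chrom"] = normalize_chrom(df["chrom"])
        df["pos"] = df["pos"].astype(np.int64)
        df["p"] = df["p"].astype(float)
        if (df["pos"] < 1).any():
            bad = df.loc[df["pos"] < 1, "snp"].iloc[0]
            raise ValueError(f"non-positive position for variant {bad!r}")
        bad_p = (df["p"] <= 0) | (df["p"] > 1)
        if bad_p.any():
            bad = df.loc[bad_p, "snp"].iloc[0]
            raise ValueError(f"p-value outside (0,1] for variant {bad!r}")
        dup = df["snp"].duplicated()
        if dup.any():
            raise ValueError(f"duplicate variant id {df.loc[dup, 'snp'].iloc[0]!r}")
        self.df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> pd.Series:
        return self.df["snp"]


@dataclass
class GeneAnnotation:
    """Gene intervals, internally 1-based closed, with unique names.

    ``df`` columns: ``gene, chrom, start, end`` with start <= end,
    sorted by (chrom, start).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("gene", "chrom", "start", "end"):
            if c not in self.df.columns:
                raise ValueError(f"GeneAnnotation missing column {c!r}")
        df = self.df.loc[:, ["gene", "chrom", "start", "end"]].copy()
        df["gene"] = df["gene"].astype(str)
        df["chrom"] = normalize_chrom(df["chrom"])
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] > df["end"]).any():
            bad = df.loc[df["start"] > df["end"], "gene"].iloc[0]
            raise ValueError(f"inverted interval for gene {bad!r}")
        if (df["start"] < 1).any():
            raise ValueError("gene interval with non-positive start")
        dup = df["gene"].duplicated()
        if dup.any():
            raise ValueError(f"duplicate gene name {df.loc[dup, 'gene'].iloc[0]!r}")
        self.df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_names(self) -> list[str]:
        return self.df["gene"].tolist()


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValueError(f"key {name!r} != set name {gs.name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValueError(f"duplicate gene set name {gs.name!r}")
        self.sets[gs.name] = gs


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path, dialect: dict | None = None, cohort_label: str = "") -> SumStats:
    """Read a tab-delimited summary-statistics table.

    ``dialect`` maps internal names (snp, chrom, pos, p) to the file's column
    headers.  Rows with a missing field or p outside (0, 1] are dropped and
    counted in the log (p = 0 usually indicates underflowed meta-analysis
    output and would break downstream counting).  Duplicate variant ids are
    an error.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in dialect.values() if v not in raw.columns]
    if missing:
        raise IOError(f"{path}: missing columns {missing}")
    df = pd.DataFrame(
        {
            "snp": raw[dialect["snp"]],
            "chrom": raw[dialect["chrom"]],
            "pos": _parse_float(raw[dialect["pos"]]),
            "p": _parse_float(raw[dialect["p"]]),
        }
    )
    n_raw = len(df)
    valid = (
        df["snp"].notna()
        & df["chrom"].notna()
        & df["pos"].notna()
        & (df["pos"] >= 1)
        & df["p"].notna()
        & (df["p"] > 0)
        & (df["p"] <= 1)
    )
    n_dropped = int((~valid).sum())
    df = df.loc[valid]
    if df.empty:
        raise IOError(f"{path}: no valid summary-statistics rows")
    dup = df["snp"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate variant id {df.loc[dup, 'snp'].iloc[0]!r}")
    logger.info("read_sumstats(%s): %d rows, %d dropped", path, n_raw, n_dropped)
    ss = SumStats(df, cohort_label=cohort_label)
    ss.n_dropped = n_dropped  # type: ignore[attr-defined]
    return ss


def write_sumstats(sumstats: SumStats, path) -> None:
    df = sumstats.df.rename(columns={"chrom": "chr"})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# gene annotation (BED)
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> GeneAnnotation:
    """Read BED3+ with the gene name in column 4.

    BED is 0-based half-open; intervals are converted to the internal 1-based
    closed convention: [start, end) -> [start+1, end].
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: BED start >= end for {name!r}")
            rows.append((name, chrom, start + 1, end))
    if not rows:
        logger.warning("read_gene_bed(%s): empty annotation", path)
        return GeneAnnotation(pd.DataFrame(columns=["gene", "chrom", "start", "end"]))
    logger.info("read_gene_bed(%s): %d genes", path, len(rows))
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))


def write_gene_bed(genes: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for row in genes.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: gene set with no members")
            name, desc = parts[0], parts[1]
            members = [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} with no members")
            if len(set(members)) < len(members):
                logger.warning("%s:%d: duplicate members in %s deduplicated", path, lineno, name)
            coll.add(GeneSet(name, desc, frozenset(members)))
    logger.info("read_gmt(%s): %d sets", path, len(coll))
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------

def read_panel(path, format: str = "tsv"):
    """Read a genotype reference panel as a dosage matrix.

    ``tsv``: columns snp, chr, pos, then one column per individual with
    dosages in {0, 1, 2}.  ``vcf``: diploid GT fields converted to alt-allele
    dosage (0/1 -> 1); requires cyvcf2.  Returns a
    :class:`pathforge.ld_ops.GenotypePanel`; monomorphic variants are flagged.
    """
    from .ld_ops import GenotypePanel

    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["snp", "chr", "pos"]
        if [c for c in meta_cols if c not in df.columns]:
            raise ValueError(f"{path}: panel TSV needs columns {meta_cols}")
        sample_cols = [c for c in df.columns if c not in meta_cols]
        if not sample_cols:
            raise ValueError(f"{path}: panel TSV has no sample columns")
        dosages = df[sample_cols].to_numpy(dtype=float).T  # individuals x variants
        panel = GenotypePanel(
            dosages=dosages,
            snp_ids=df["snp"].astype(str).to_numpy(),
            chrom=normalize_chrom(df["chr"]).to_numpy(),
            pos=df["pos"].to_numpy(dtype=np.int64),
        )
    elif format == "vcf":
        from cyvcf2 import VCF

        ids, chroms, poss, rows = [], [], [], []
        for var in VCF(str(path)):
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            chroms.append(var.CHROM)
            poss.append(var.POS)
            gt = np.asarray(var.genotypes)[:, :2]
            dose = np.where(gt < 0, np.nan, gt).sum(axis=1)
            rows.append(dose)
        if not rows:
            raise ValueError(f"{path}: empty VCF")
        panel = GenotypePanel(
            dosages=np.asarray(rows, dtype=float).T,
            snp_ids=np.asarray(ids),
            chrom=normalize_chrom(pd.Series(chroms)).to_numpy(),
            pos=np.asarray(poss, dtype=np.int64),
        )
    else:
        raise ValueError(f"unknown panel format {format!r}")
    logger.info(
        "read_panel(%s): %d individuals x %d variants, %d monomorphic",
        path, panel.n_individuals, panel.n_variants, int(panel.monomorphic.sum()),
    )
    return panel


def write_panel_tsv(panel, path) -> None:
    df = pd.DataFrame(
        {"snp": panel.snp_ids, "chr": panel.chrom, "pos": panel.pos}
    )
    dos = pd.DataFrame(
        panel.dosages.T,
        columns=[f"ind{i}" for i in range(panel.n_individuals)],
    ).astype(int)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False)
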