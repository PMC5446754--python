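"""Synthetic GWAS scenarios with block LD and overlapping gene sets.

The generator exists so every downstream stage — pruning, mapping,
enrichment, replication — can be exercised end to end without any cohort
download, and so the classic false-positive mechanism can be reproduced on
demand: a dense, high-LD ("MHC-like") region whose genes are shared across
several gene sets, carrying one inflated association signal that lights up
all of those sets at once until LD redundancy is removed.

Two coupled models:

* **Genotype panel** — haplotypes are built by a copying/mosaic scheme: in
  each LD block, haplotype h copies a block founder allele with probability
  sqrt(r) and otherwise draws independently at the block allele frequency,
  giving expected allelic correlation r between any two SNPs of the block
  (and hence expected r² = r²).  Blocks are mutually independent.
* **Summary statistics** — z-scores are drawn directly per block from
  MVN(R @ lam, R), where R is the compound-symmetric block correlation
  matrix (off-diagonal r) and lam the vector of per-SNP non-centralities;
  p = 2 * Phi(-|z|).  With lam = 0 each p is exactly Uniform(0, 1).

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import (
    GeneAnnotation,
    GeneSet,
    GeneSetCollection,
    SumStats,
    read_gene_bed,
    read_gmt,
    read_panel,
    read_sumstats,
    write_gene_bed,
    write_gmt,
    write_panel_tsv,
    write_sumstats,
)
from .ld_ops import GenotypePanel


def derive_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31 from a global seed and label."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class BlockSpec:
    """Geometry and LD of a run of equally sized blocks on one chromosome.

    ``within_block_r`` is the target *allelic correlation* r between any two
    SNPs of a block (so pairwise r² targets r**2); blocks are independent of
    each other.  Positions start at ``start_pos`` and are strictly
    increasing: SNPs within a block sit ``snp_spacing_bp`` apart and
    consecutive blocks are separated by an extra ``block_spacing_bp``.
    """

    n_blocks: int
    snps_per_block: int
    within_block_r: float
    block_spacing_bp: int = 50_000
    snp_spacing_bp: int = 2_000
    start_pos: int = 1
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_blocks < 0 or self.snps_per_block < 1:
            raise ValueError("block counts must be positive")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError("within_block_r must be in [0, 1)")
        if self.snp_spacing_bp < 1 or self.block_spacing_bp < 0 or self.start_pos < 1:
            raise ValueError("spacings and start_pos must be positive")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block

    def variant_grid(self) -> pd.DataFrame:
        """Deterministic (snp, chrom, pos, block) table for this spec."""
        rows = []
        pos = self.start_pos
        for b in range(self.n_blocks):
            for _ in range(self.snps_per_block):
                rows.append((f"{self.chrom}:{pos}", self.chrom, pos, b))
                pos += self.snp_spacing_bp
            pos += self.block_spacing_bp
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "block"])

    @property
    def span_end(self) -> int:
        """1 bp past the last SNP position."""
        per_block = self.snps_per_block * self.snp_spacing_bp
        return self.start_pos + self.n_blocks * (per_block + self.block_spacing_bp)


@dataclass(frozen=True)
class EffectSpec:
    """Planted association effects: non-centrality ``lam`` per causal SNP.

    ``lam`` is the expected z-score contribution of each causal SNP; block
    neighbours inherit r * lam through the LD correlation.  ``n_samples`` is
    cohort-size metadata only — effects are specified on the z scale.
    """

    causal_snps: tuple[str, ...] = ()
    lam: float = 0.0
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0 or not np.isfinite(self.lam):
            raise ValueError("lam must be finite and >= 0")


NULL_EFFECTS = EffectSpec()


def simulate_ld_panel(spec: BlockSpec, n_haplotypes: int, seed: int) -> GenotypePanel:
    """Diploid dosage panel with block-exchangeable LD at level r.

    Per haplotype and block a founder allele is drawn at the block allele
    frequency; each SNP copies it with probability sqrt(r) and otherwise
    draws independently at the same frequency, so allelic (and genotype)
    correlation within the block is r in expectation.  Haplotypes are paired
    into n_haplotypes/2 individuals with dosages in {0, 1, 2}.
    """
    if n_haplotypes < 20 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even and >= 20")
    if spec.n_snps < 1:
        raise ValueError("spec contains no SNPs")
    rng = np.random.default_rng(seed)
    grid = spec.variant_grid()
    c = np.sqrt(spec.within_block_r)
    hap = np.empty((n_haplotypes, spec.n_snps), dtype=np.int8)
    col = 0
    for _ in range(spec.n_blocks):
        m = spec.snps_per_block
        f = rng.uniform(0.2, 0.8)
        founder = rng.random(n_haplotypes) < f
        copies = rng.random((n_haplotypes, m)) < c
        indep = rng.random((n_haplotypes, m)) < f
        hap[:, col : col + m] = np.where(copies, founder[:, None], indep)
        col += m
    dosages = hap[0::2].astype(float) + hap[1::2].astype(float)
    return GenotypePanel(
        dosages=dosages,
        snp_ids=grid["snp"].to_numpy(),
        chrom=grid["chrom"].to_numpy(),
        pos=grid["pos"].to_numpy(),
    )


def simulate_sumstats(
    spec: BlockSpec,
    effects: EffectSpec = NULL_EFFECTS,
    seed: int = 0,
    cohort_label: str = "",
) -> SumStats:
    """Per-SNP two-sided p-values from block-correlated z-scores.

    Per block: z ~ MVN(R @ lam, R) with R compound-symmetric (off-diagonal
    ``within_block_r``); p = 2 * Phi(-|z|).  Under lam = 0 every p is
    marginally Uniform(0, 1).
    """
    grid = spec.variant_grid()
    known = set(grid["snp"])
    unknown = [s for s in effects.causal_snps if s not in known]
    if unknown:
        raise ValueError(f"causal SNP {unknown[0]!r} not in the simulated grid")
    lam_all = np.zeros(len(grid))
    if effects.causal_snps:
        idx = grid.set_index("snp").index.get_indexer(list(effects.causal_snps))
        lam_all[idx] = effects.lam
    rng = np.random.default_rng(seed)
    r = spec.within_block_r
    m = spec.snps_per_block
    R = np.full((m, m), r)
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R)
    z = np.empty(len(grid))
    for b in range(spec.n_blocks):
        sl = slice(b * m, (b + 1) * m)
        mean = R @ lam_all[sl]
        z[sl] = mean + L @ rng.standard_normal(m)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)  # keep p in (0, 1]
    df = grid[["snp", "chrom", "pos"]].copy()
    df["p"] = p
    return SumStats(df, cohort_label=cohort_label)


def simulate_gene_annotation(
    chrom_length: int,
    n_genes: int,
    length_range: tuple[int, int],
    seed: int,
    chrom: str = "1",
    start: int = 1,
    name_prefix: str = "GENE",
) -> GeneAnnotation:
    """Non-overlapping (hence non-nested), uniquely named gene intervals.

    Genes are packed left to right into [start, start + chrom_length - 1]
    with random lengths from ``length_range`` and random inter-gene gaps;
    raises if the requested genes cannot fit.
    """
    lo, hi = length_range
    if n_genes < 1 or lo < 1 or hi < lo:
        raise ValueError("invalid n_genes or length_range")
    if n_genes * hi > chrom_length:
        raise ValueError("cannot pack genes: n_genes * max_length exceeds chrom_length")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    slack = chrom_length - int(lengths.sum())
    # split the slack into n_genes + 1 random gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
    gaps = np.diff(np.concatenate([[0], cuts]))
    rows = []
    pos = start
    width = len(str(n_genes))
    for i in range(n_genes):
        pos += int(gaps[i])
        s = pos
        e = s + int(lengths[i]) - 1
        rows.append((f"{name_prefix}{i + 1:0{width}d}", chrom, s, e))
        pos = e + 1
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))


def simulate_geneset_collection(
    genes: GeneAnnotation,
    n_sets: int,
    size_range: tuple[int, int],
    shared_core=(),
    n_core_sets: int = 0,
    planted=(),
    seed: int = 0,
) -> GeneSetCollection:
    """Named gene sets over the annotation, optionally sharing a gene core.

    The first ``n_core_sets`` sets each contain every ``shared_core`` gene
    (the MHC-overlap pattern) plus random fill; all other membership is
    drawn without replacement per set.  Sets named in ``planted`` are
    ordinary random sets whose names mark them for signal planting by
    :func:`make_scenario`.
    """
    names = list(genes.gene_names)
    core = list(shared_core)
    unknown = [g for g in core if g not in set(names)]
    if unknown:
        raise ValueError(f"shared_core gene {unknown[0]!r} not in annotation")
    if n_core_sets > n_sets:
        raise ValueError("n_core_sets exceeds n_sets")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size_range")
    if core and lo < len(core):
        raise ValueError("size_range smaller than the shared core")
    if hi > len(names):
        raise ValueError("set size exceeds number of genes")
    planted = list(planted)
    rng = np.random.default_rng(seed)
    non_core = [g for g in names if g not in set(core)]
    coll = GeneSetCollection()
    width = len(str(n_sets))
    n_named = 0
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < n_core_sets:
            fill = rng.choice(non_core, size=max(0, size - len(core)), replace=False)
            members = frozenset(core) | frozenset(fill.tolist())
            name = f"CORE_SET_{i + 1:0{width}d}"
            desc = "shares the dense-region gene core"
        else:
            members = frozenset(rng.choice(names, size=size, replace=False).tolist())
            if n_named < len(planted):
                name = planted[n_named]
                desc = "signal-planting target"
                n_named += 1
            else:
                name = f"SET_{i + 1:0{width}d}"
                desc = "random gene set"
        coll.add(GeneSet(name, desc, members))
    if n_named < len(planted):
        raise ValueError("more planted names than non-core sets")
    return coll


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a two-cohort synthetic scenario.

    Defaults describe a small genome with 120 moderate-LD blocks plus one
    dense high-LD region: SNPs 5x denser, allelic correlation 0.95, an
    inflated signal inside it, and 15 genes tiled across the region that
    form the shared core of ``n_core_sets`` gene sets.  A polygenic
    background (``n_background_causal`` genuinely associated loci spread
    over the regular blocks) keeps the genome-wide significant-SNP rate
    realistic, as in any real GWAS.  Planted (truly enriched) pathways
    receive a causal SNP in ``planted_gene_fraction`` of their member
    genes.  All causal SNPs share non-centrality ``signal_lam``.
    """

    chrom: str = "1"
    # regular genome
    n_blocks: int = 120
    snps_per_block: int = 8
    within_block_r: float = 0.4
    snp_spacing_bp: int = 2_000
    block_spacing_bp: int = 250_000
    # dense high-LD region (0 dense_blocks disables it)
    dense_blocks: int = 1
    dense_snps_per_block: int = 150
    dense_within_r: float = 0.95
    dense_snp_spacing_bp: int = 400
    dense_gap_bp: int = 300_000
    # panel
    n_haplotypes: int = 400
    # genes
    n_regular_genes: int = 150
    n_core_genes: int = 15
    gene_length_range: tuple[int, int] = (4_000, 12_000)
    # gene sets
    n_sets: int = 20
    set_size_range: tuple[int, int] = (15, 25)
    n_core_sets: int = 4
    # association signal
    signal_lam: float = 6.0
    n_background_causal: int = 15
    # planted truly-enriched pathways
    planted_sets: tuple[str, ...] = ()
    planted_gene_fraction: float = 0.3
    n_samples: int = 20_000

    def regular_spec(self) -> BlockSpec:
        return BlockSpec(
            n_blocks=self.n_blocks,
            snps_per_block=self.snps_per_block,
            within_block_r=self.within_block_r,
            block_spacing_bp=self.block_spacing_bp,
            snp_spacing_bp=self.snp_spacing_bp,
            start_pos=1,
            chrom=self.chrom,
        )

    def dense_spec(self) -> BlockSpec | None:
        if self.dense_blocks == 0:
            return None
        return BlockSpec(
            n_blocks=self.dense_blocks,
            snps_per_block=self.dense_snps_per_block,
            within_block_r=self.dense_within_r,
            block_spacing_bp=2_000,
            snp_spacing_bp=self.dense_snp_spacing_bp,
            start_pos=self.regular_spec().span_end + self.dense_gap_bp,
            chrom=self.chrom,
        )


#: no dense region, no background loci, nothing planted: every p-value null
GLOBAL_NULL = ScenarioConfig(dense_blocks=0, n_background_causal=0, planted_sets=())

#: one truly enriched pathway on an otherwise quiet genome
PLANTED_ONLY = ScenarioConfig(
    dense_blocks=0, n_background_causal=0, planted_sets=("PLANTED_1",)
)


@dataclass
class Scenario:
    """One fully materialised study: panel, two cohorts, genes, sets, truth."""

    config: ScenarioConfig
    seed: int
    panel: GenotypePanel
    sumstats_discovery: SumStats
    sumstats_replication: SumStats
    genes: GeneAnnotation
    collection: GeneSetCollection
    truth: list[str]
    core_genes: list[str] = field(default_factory=list)
    core_sets: list[str] = field(default_factory=list)
    effects: EffectSpec = NULL_EFFECTS


def _concat_panels(panels: list[GenotypePanel]) -> GenotypePanel:
    return GenotypePanel(
        dosages=np.hstack([p.dosages for p in panels]),
        snp_ids=np.concatenate([p.snp_ids for p in panels]),
        chrom=np.concatenate([p.chrom for p in panels]),
        pos=np.concatenate([p.pos for p in panels]),
    )


def _concat_sumstats(parts: list[SumStats], label: str) -> SumStats:
    return SumStats(pd.concat([s.df for s in parts], ignore_index=True), label)


def make_scenario(config: ScenarioConfig = ScenarioConfig(), seed: int = 0) -> Scenario:
    """Generate a deterministic two-cohort scenario from one seed.

    Both cohorts share the variant grid and the planted truth; only the
    z-score noise differs.  The dense region's genes become the shared core
    of the first ``n_core_sets`` gene sets; one causal SNP per dense block
    carries the inflated signal.  Planted pathways get a causal SNP at the
    midpoint-nearest position of 30% (by default) of their member genes.
    """
    reg = config.regular_spec()
    dense = config.dense_spec()
    specs = [reg] + ([dense] if dense else [])

    # --- panel ------------------------------------------------------------
    panels = [
        simulate_ld_panel(s, config.n_haplotypes, derive_seed(seed, f"panel{i}"))
        for i, s in enumerate(specs)
    ]
    panel = _concat_panels(panels)

    # --- genes ------------------------------------------------------------
    regular_genes = simulate_gene_annotation(
        chrom_length=reg.span_end,
        n_genes=config.n_regular_genes,
        length_range=config.gene_length_range,
        seed=derive_seed(seed, "genes"),
        chrom=config.chrom,
        name_prefix="GENE",
    )
    gene_frames = [regular_genes.df]
    core_names: list[str] = []
    if dense is not None and config.n_core_genes > 0:
        span = dense.span_end - dense.start_pos
        core_genes = simulate_gene_annotation(
            chrom_length=span,
            n_genes=config.n_core_genes,
            length_range=(
                min(config.gene_length_range[0], span // (2 * config.n_core_genes) + 1),
                min(config.gene_length_range[1], span // config.n_core_genes),
            ),
            seed=derive_seed(seed, "core_genes"),
            chrom=config.chrom,
            start=dense.start_pos,
            name_prefix="COREG",
        )
        core_names = core_genes.gene_names
        gene_frames.append(core_genes.df)
    genes = GeneAnnotation(pd.concat(gene_frames, ignore_index=True))

    # --- gene sets --------------------------------------------------------
    collection = simulate_geneset_collection(
        genes,
        n_sets=config.n_sets,
        size_range=config.set_size_range,
        shared_core=core_names,
        n_core_sets=config.n_core_sets if core_names else 0,
        planted=config.planted_sets,
        seed=derive_seed(seed, "sets"),
    )
    core_sets = [n for n in collection.names() if n.startswith("CORE_SET_")]

    # --- effects ----------------------------------------------------------
    causal: list[str] = []
    if dense is not None:
        grid = dense.variant_grid()
        causal += grid.groupby("block")["snp"].first().tolist()
    if config.n_background_causal > 0:
        reg_grid = reg.variant_grid()
        picks = np.unique(
            np.linspace(0, config.n_blocks - 1, config.n_background_causal).round()
        ).astype(int)
        leads = reg_grid.groupby("block")["snp"].first()
        causal += leads.iloc[picks].tolist()
    if config.planted_sets:
        rng = np.random.default_rng(derive_seed(seed, "planting"))
        gdf = genes.df.set_index("gene")
        all_pos = panel.pos
        all_ids = panel.snp_ids
        taken = set(causal)
        for name in config.planted_sets:
            members = sorted(collection[name].members - set(core_names))
            n_causal = max(1, int(round(config.planted_gene_fraction * len(members))))
            # prefer genes with a SNP nearby, so the planted signal actually
            # maps back to the gene under the default window
            mids = {g: (gdf.at[g, "start"] + gdf.at[g, "end"]) // 2 for g in members}
            near = {g: int(np.min(np.abs(all_pos - mids[g]))) for g in members}
            eligible = [g for g in members if near[g] <= 50_000]
            pool = eligible if len(eligible) >= n_causal else members
            chosen = rng.choice(pool, size=min(n_causal, len(pool)), replace=False)
            for g in chosen:
                j = int(np.argmin(np.abs(all_pos - mids[g])))
                sid = str(all_ids[j])
                if sid not in taken:
                    causal.append(sid)
                    taken.add(sid)
    lam = config.signal_lam if causal else 0.0
    effects = EffectSpec(causal_snps=tuple(causal), lam=lam, n_samples=config.n_samples)

    # --- summary statistics (two cohorts, shared truth) -------------------
    def cohort(label: str) -> SumStats:
        parts = []
        for i, s in enumerate(specs):
            ids = set(s.variant_grid()["snp"])
            eff = EffectSpec(
                causal_snps=tuple(c for c in causal if c in ids),
                lam=lam,
                n_samples=config.n_samples,
            )
            parts.append(
                simulate_sumstats(s, eff, derive_seed(seed, f"{label}{i}"), label)
            )
        return _concat_sumstats(parts, label)

    return Scenario(
        config=config,
        seed=seed,
        panel=panel,
        sumstats_discovery=cohort("discovery"),
        sumstats_replication=cohort("replication"),
        genes=genes,
        collection=collection,
        truth=list(config.planted_sets),
        core_genes=core_names,
        core_sets=core_sets,
        effects=effects,
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_scenario(scenario: Scenario, outdir) -> None:
    """Write a scenario as TSV/BED/GMT/JSON files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_sumstats(scenario.sumstats_discovery, out / "sumstats_discovery.tsv")
    write_sumstats(scenario.sumstats_replication, out / "sumstats_replication.tsv")
    write_panel_tsv(scenario.panel, out / "panel.tsv")
    write_gene_bed(scenario.genes, out / "genes.bed")
    write_gmt(scenario.collection, out / "sets.gmt")
    meta = {
        "seed": scenario.seed,
        "truth": scenario.truth,
        "core_genes": scenario.core_genes,
        "core_sets": scenario.core_sets,
        "config": asdict(scenario.config),
        "effects": {
            "causal_snps": list(scenario.effects.causal_snps),
            "lam": scenario.effects.lam,
            "n_samples": scenario.effects.n_samples,
        },
    }
    (out / "scenario.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_scenario(indir) -> Scenario:
    """Reload a scenario written by :func:`write_scenario`."""
    d = Path(indir)
    meta = json.loads((d / "scenario.json").read_text())
    cfg_dict = dict(meta["config"])
    for key in ("gene_length_range", "set_size_range", "planted_sets"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = ScenarioConfig(**cfg_dict)
    return Scenario(
        config=config,
        seed=meta["seed"],
        panel=read_panel(d / "panel.tsv", format="tsv"),
        sumstats_discovery=read_sumstats(d / "sumstats_discovery.tsv", cohort_label="discovery"),
        sumstats_replication=read_sumstats(d / "sumstats_replication.tsv", cohort_label="replication"),
        genes=read_gene_bed(d / "genes.bed"),
        collection=read_gmt(d / "sets.gmt"),
        truth=list(meta["truth"]),
        core_genes=list(meta["core_genes"]),
        core_sets=list(meta["core_sets"]),
        effects=EffectSpec(
            causal_snps=tuple(meta["effects"]["causal_snps"]),
            lam=meta["effects"]["lam"],
            n_samples=meta["effects"]["n_samples"],
        ),
    )
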