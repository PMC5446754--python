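"""Two-level counting enrichment with exact tests, FDR and permutation nulls.

Level 1 (gene): for each gene, count its mapped SNPs with p below
``alpha_snp`` against the background rate over all mapped SNPs.
Level 2 (pathway): for each gene set, count member genes with gene-level p
below ``alpha_gene`` against the rate over all tested genes.

Both levels use the same exact counting test: by default the hypergeometric
upper tail (sampling the gene's SNPs / the set's genes without replacement
from the background), optionally an upper-tail binomial with success
probability K/N or a fixed rate.  No normal approximation is involved.

The pathway permutation null redraws gene sets of the same tested size from
the tested-gene universe without replacement and recomputes the significant-
member count; the empirical p-value uses the (1 + exceedances)/(B + 1)
convention, so it is never zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import GeneSetCollection, SumStats
from .snp_gene_mapping import MappingTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentConfig:
    alpha_snp: float = 0.05
    alpha_gene: float = 0.05
    method: str = "hypergeometric"  # "hypergeometric" | "binomial"
    n_permutations: int = 100_000
    fdr_q: float = 0.05
    rng_seed: int = 0
    #: for method="binomial": fixed success probability instead of K/N
    binomial_prob: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha_snp", "alpha_gene", "fdr_q"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.method not in ("hypergeometric", "binomial"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def count_test(
    k,
    n: int,
    K: int,
    N: int,
    method: str = "hypergeometric",
    binomial_prob: float | None = None,
):
    """Upper-tail p-value for observing >= k successes in n trials.

    hypergeometric: P(X >= k), X ~ Hypergeom(N, K, n) — n draws without
    replacement from a background of N with K successes.
    binomial: P(X >= k), X ~ Binomial(n, q) with q = K/N (or a fixed
    ``binomial_prob`` when given).  Both are exact tail sums.  ``k`` may be
    an array, in which case an array of p-values is returned.
    """
    ka = np.asarray(k)
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if (ka < 0).any() or (ka > n).any():
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if method == "hypergeometric":
        if (ka > K).any():
            raise ValueError(f"hypergeometric needs k <= K, got k={k}, K={K}")
        p = stats.hypergeom.sf(ka - 1, N, K, n)
    elif method == "binomial":
        q = binomial_prob if binomial_prob is not None else K / N
        if not (0.0 <= q <= 1.0):
            raise ValueError("binomial success probability outside [0, 1]")
        p = stats.binom.sf(ka - 1, n, q)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(p) if np.isscalar(k) else np.asarray(p)


def gene_enrichment(
    sumstats: SumStats,
    mapping: MappingTable,
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> pd.DataFrame:
    """Per-gene SNP-counting test.

    Background (K, N) is taken over all mapped SNPs, each counted **once**
    regardless of how many genes it maps to — counting per mapping would let
    a single SNP inflate the background and the very gene-set
    overrepresentation artifact this pipeline exists to avoid.

    Returns a DataFrame with columns gene, n_snps, k_sig, p_gene; genes with
    no mapped SNP are omitted.
    """
    if len(mapping) == 0:
        logger.warning("gene_enrichment: empty mapping table")
        return pd.DataFrame(columns=["gene", "n_snps", "k_sig", "p_gene"])
    pmap = sumstats.df.set_index("snp")["p"]
    unknown = set(mapping.df["snp"]) - set(pmap.index)
    if unknown:
        raise ValueError(f"mapping refers to SNPs absent from sumstats, e.g. {next(iter(unknown))!r}")
    m = mapping.df.copy()
    m["sig"] = pmap.reindex(m["snp"]).to_numpy() < cfg.alpha_snp
    uniq = m.drop_duplicates("snp")
    N = len(uniq)
    K = int(uniq["sig"].sum())
    per_gene = m.groupby("gene", sort=True).agg(n_snps=("snp", "size"), k_sig=("sig", "sum"))
    if cfg.method == "hypergeometric":
        # a gene's SNPs are a subset of the background, so k <= K holds
        p = stats.hypergeom.sf(per_gene["k_sig"] - 1, N, K, per_gene["n_snps"])
    else:
        q = cfg.binomial_prob if cfg.binomial_prob is not None else K / N
        p = stats.binom.sf(per_gene["k_sig"] - 1, per_gene["n_snps"], q)
    out = per_gene.reset_index()
    out["k_sig"] = out["k_sig"].astype(int)
    out["p_gene"] = p
    return out


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (q_values, significant flags).

    q_values are the monotone-adjusted p * m / rank with a cumulative minimum
    from the largest p downwards; flags mark all hypotheses up to the largest
    rank i with p(i) <= i*q/m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def pathway_enrichment(
    gene_results: pd.DataFrame,
    collection: GeneSetCollection,
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> pd.DataFrame:
    """Per-pathway gene-counting test with BH-FDR over all testable sets.

    The universe is the set of genes carrying a gene-level result; set
    members outside it are dropped from numerator and denominator alike.
    Sets with no tested member are flagged untestable (p and q absent) and
    excluded from the FDR.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    universe = gene_results.set_index("gene")["p_gene"]
    sig = universe < cfg.alpha_gene
    N = len(universe)
    K = int(sig.sum())
    rows = []
    for gs in collection:
        tested = [g for g in gs.members if g in universe.index]
        n = len(tested)
        k = int(sig.loc[tested].sum()) if n else 0
        if n == 0:
            rows.append((gs.name, 0, 0, np.nan, False))
            continue
        p = count_test(k, n, K, N, method=cfg.method, binomial_prob=cfg.binomial_prob)
        rows.append((gs.name, n, k, p, True))
    out = pd.DataFrame(
        rows, columns=["set_name", "n_genes_tested", "k_sig_genes", "p_pathway", "testable"]
    )
    out["q_value"] = np.nan
    out["significant"] = False
    testable = out["testable"].to_numpy()
    if testable.any():
        qvals, flags = bh_fdr(out.loc[testable, "p_pathway"].to_numpy(), q=cfg.fdr_q)
        out.loc[testable, "q_value"] = qvals
        out.loc[testable, "significant"] = flags
    return out


def _sig_indicator(gene_results: pd.DataFrame, alpha_gene: float) -> pd.Series:
    return (gene_results.set_index("gene")["p_gene"] < alpha_gene)


def permutation_pvalue(
    gene_results: pd.DataFrame,
    members,
    B: int = 100_000,
    seed: int = 0,
    alpha_gene: float = 0.05,
    method: str = "resample",
) -> float:
    """Empirical pathway p-value from size-matched gene-set resampling.

    The observed statistic T is the number of tested members with gene-level
    p below ``alpha_gene``.  The null redraws B gene subsets of the same
    tested size from the universe without replacement and recomputes T;
    p = (1 + #{T_b >= T_obs}) / (B + 1).  ``method="exhaustive"`` enumerates
    all C(N, n) subsets instead and returns the exact tail proportion
    (feasible only for small universes).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sig = _sig_indicator(gene_results, alpha_gene)
    ind = sig.to_numpy(dtype=np.int64)
    N = ind.size
    tested = [g for g in members if g in sig.index]
    n = len(tested)
    if n == 0:
        raise ValueError("no tested members in the universe")
    if n > N:
        raise ValueError("set larger than the universe")
    t_obs = int(sig.loc[tested].sum())
    if method == "exhaustive":
        total = math.comb(N, n)
        if total > 5_000_000:
            raise ValueError("universe too large for exhaustive enumeration")
        hits = sum(
            1 for combo in itertools.combinations(range(N), n)
            if int(ind[list(combo)].sum()) >= t_obs
        )
        return hits / total
    if method != "resample":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(B, 50_000_000 // max(N, 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        keys = rng.random((b, N))
        picks = np.argpartition(keys, n - 1, axis=1)[:, :n]
        t_null = ind[picks].sum(axis=1)
        exceed += int((t_null >= t_obs).sum())
        done += b
    return (1 + exceed) / (B + 1)


def add_permutation_pvalues(
    pathway_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    collection: GeneSetCollection,
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> pd.DataFrame:
    """Attach a ``p_perm`` column to testable pathway results."""
    out = pathway_results.copy()
    out["p_perm"] = np.nan
    for i, row in out.iterrows():
        if not row["testable"]:
            continue
        out.at[i, "p_perm"] = permutation_pvalue(
            gene_results,
            collection[row["set_name"]].members,
            B=cfg.n_permutations,
            seed=cfg.rng_seed + i,
            alpha_gene=cfg.alpha_gene,
        )
    return out
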