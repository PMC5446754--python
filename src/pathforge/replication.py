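"""Discovery–replication protocol and the shared-significant-SNP audit.

A pathway finding is only trusted when it recurs in an independent cohort.
Three diagnostics are provided:

* tiered pathway replication — how many gene sets fall below each p-value
  tier (0.05 / 0.01 / 0.001 by default) in both cohorts;
* gene convergence — the fraction of genes whose gene-level p lands on the
  same side of alpha in both cohorts, tested against a binomial null;
* the shared-SNP audit — for a group of suspiciously co-significant gene
  sets, how many significant SNPs they have in common.  A large common core
  (the MHC pattern) means one LD block is driving all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import GeneSetCollection, SumStats
from .snp_gene_mapping import MappingTable

DEFAULT_TIERS = (0.05, 0.01, 0.001)


@dataclass
class ReplicationReport:
    tiers: tuple[float, ...]
    n_discovery: dict[float, int]
    n_replicated: dict[float, int]
    #: sets below the tier in both cohorts, per tier
    jointly_significant: dict[float, list[str]]
    #: sets below the loosest tier in discovery and below each tier in
    #: replication (discovery threshold held fixed)
    n_joint_at_discovery: dict[float, int]
    #: discovery sets absent from the replication results (non-replicated by
    #: definition)
    missing_in_replication: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tier": list(self.tiers),
                "n_discovery": [self.n_discovery[t] for t in self.tiers],
                "n_replicated": [self.n_replicated[t] for t in self.tiers],
            }
        )


@dataclass
class ConvergenceResult:
    n_total: int
    n_convergent: int
    p_binomial: float
    p0: float
    alpha: float

    @property
    def rate(self) -> float:
        return self.n_convergent / self.n_total


def replicate_pathways(
    disc: pd.DataFrame,
    repl: pd.DataFrame,
    thresholds=DEFAULT_TIERS,
) -> ReplicationReport:
    """Tiered pathway overlap between a discovery and a replication cohort.

    At each tier t, a set replicates when its pathway p is below t in *both*
    cohorts; a set absent from the replication table is non-replicated by
    definition and listed separately.
    """
    tiers = tuple(sorted(thresholds, reverse=True))
    d = disc.loc[disc["p_pathway"].notna(), ["set_name", "p_pathway"]]
    r = repl.loc[repl["p_pathway"].notna(), ["set_name", "p_pathway"]]
    merged = d.merge(r, on="set_name", how="left", suffixes=("_disc", "_repl"))
    if r.empty or merged["p_pathway_repl"].isna().all():
        import logging

        logging.getLogger(__name__).warning("replicate_pathways: no shared set names")
    loosest = tiers[0]
    n_disc, n_repl, joint, joint_at_disc = {}, {}, {}, {}
    for t in tiers:
        in_disc = merged["p_pathway_disc"] < t
        in_both = in_disc & (merged["p_pathway_repl"] < t)
        n_disc[t] = int(in_disc.sum())
        n_repl[t] = int(in_both.sum())
        joint[t] = merged.loc[in_both, "set_name"].tolist()
        joint_at_disc[t] = int(
            ((merged["p_pathway_disc"] < loosest) & (merged["p_pathway_repl"] < t)).sum()
        )
    missing = merged.loc[
        (merged["p_pathway_disc"] < loosest) & merged["p_pathway_repl"].isna(), "set_name"
    ].tolist()
    return ReplicationReport(
        tiers=tiers,
        n_discovery=n_disc,
        n_replicated=n_repl,
        jointly_significant=joint,
        n_joint_at_discovery=joint_at_disc,
        missing_in_replication=missing,
    )


def binomial_tail(k: int, n: int, prob: float, side: str = "upper") -> float:
    """Exact binomial tail probability.

    ``two_sided`` sums the mass of every outcome no more likely than k
    (minimum-likelihood convention).
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < prob < 1.0):
        raise ValueError("prob must be in (0, 1)")
    if side == "upper":
        return float(stats.binom.sf(k - 1, n, prob))
    if side == "lower":
        return float(stats.binom.cdf(k, n, prob))
    if side == "two_sided":
        return float(stats.binomtest(k, n, prob, alternative="two-sided").pvalue)
    raise ValueError(f"unknown side {side!r}")


def gene_convergence(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    subset,
    alpha: float = 0.05,
    p0: float = 0.5,
) -> ConvergenceResult:
    """Cross-cohort gene convergence with an exact binomial test.

    A gene is convergent when its gene-level p falls on the same side of
    ``alpha`` in both cohorts (p exactly equal to alpha counts as
    non-significant on both sides).  ``p0`` is the null convergence
    probability for the two-sided binomial test; it has no canonical value
    and is always reported back.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("empty gene subset")
    pa = res_a.set_index("gene")["p_gene"]
    pb = res_b.set_index("gene")["p_gene"]
    missing = [g for g in subset if g not in pa.index or g not in pb.index]
    if missing:
        raise ValueError(f"genes not tested in both cohorts, e.g. {missing[0]!r}")
    a_sig = pa.loc[subset].to_numpy() < alpha
    b_sig = pb.loc[subset].to_numpy() < alpha
    conv = int((a_sig == b_sig).sum())
    p = binomial_tail(conv, len(subset), p0, side="two_sided")
    return ConvergenceResult(
        n_total=len(subset), n_convergent=conv, p_binomial=p, p0=p0, alpha=alpha
    )


@dataclass
class SharedSnpAudit:
    set_names: list[str]
    #: per set, the significant SNPs mapped to any member gene
    per_set_snps: dict[str, set[str]]
    #: pairwise |intersection| matrix, indexed by set name
    pairwise: pd.DataFrame
    #: SNPs common to every audited set
    common_core: set[str]

    @property
    def per_set_totals(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.per_set_snps.items()}


def pathway_shared_snps(
    set_names,
    collection: GeneSetCollection,
    mapping: MappingTable,
    sumstats: SumStats,
    alpha: float = 0.05,
) -> SharedSnpAudit:
    """Audit how many significant SNPs a group of gene sets share.

    For each named set: the SNPs with p < alpha mapped to any member gene.
    Reports pairwise intersection counts and the core common to all sets.
    """
    set_names = list(set_names)
    for name in set_names:
        if name not in collection:
            raise KeyError(f"unknown gene set {name!r}")
    pmap = sumstats.df.set_index("snp")["p"]
    m = mapping.df
    sig_snps = m.loc[pmap.reindex(m["snp"]).to_numpy() < alpha]
    per_set: dict[str, set[str]] = {}
    for name in set_names:
        members = collection[name].members
        per_set[name] = set(sig_snps.loc[sig_snps["gene"].isin(members), "snp"])
    mat = pd.DataFrame(
        [[len(per_set[a] & per_set[b]) for b in set_names] for a in set_names],
        index=set_names,
        columns=set_names,
    )
    core = set.intersection(*per_set.values()) if per_set else set()
    return SharedSnpAudit(
        set_names=set_names, per_set_snps=per_set, pairwise=mat, common_core=core
    )
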