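import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pathforge import (
    EnrichmentConfig,
    GeneAnnotation,
    GeneSet,
    GeneSetCollection,
    SumStats,
    bh_fdr,
    count_test,
    gene_enrichment,
    pathway_enrichment,
    permutation_pvalue,
    map_snps,
)


def hypergeom_tail_oracle(k, n, K, N):
    """Exact integer enumeration of P(X >= k), X ~ Hypergeom(N, K, n)."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
        if n - j <= N - K
    )
    return hits / total


class TestCountTest:
    def test_zero_successes_gives_one(self):
        assert count_test(0, 5, 10, 100) == pytest.approx(1.0)
        assert count_test(0, 5, 10, 100, method="binomial") == pytest.approx(1.0)

    def test_hypergeometric_worked_example(self):
        # C(10,2)C(90,2) + C(10,3)C(90,1) + C(10,4) over C(100,4)
        assert count_test(2, 4, 10, 100) == pytest.approx(191_235 / 3_921_225)
        assert round(count_test(2, 4, 10, 100), 4) == 0.0488

    def test_binomial_worked_example(self):
        # 1 - 0.95^4 - 4*0.05*0.95^3
        expected = 1 - 0.95**4 - 4 * 0.05 * 0.95**3
        got = count_test(2, 4, 0, 100, method="binomial", binomial_prob=0.05)
        assert got == pytest.approx(expected)
        assert round(got, 4) == 0.0140

    @pytest.mark.parametrize(
        "k,n,K,N", [(3, 2, 5, 10), (1, 5, 0, 10), (2, 4, 10, 8), (-1, 4, 5, 10)]
    )
    def test_bound_violations_rejected(self, k, n, K, N):
        with pytest.raises(ValueError):
            count_test(k, n, K, N)

    def test_monotone_in_k(self):
        ps = [count_test(k, 10, 20, 100) for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(2, 200))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(n, K) + 1))
        assert count_test(k, n, K, N) == pytest.approx(
            hypergeom_tail_oracle(k, n, K, N), rel=1e-10
        )


class TestGeneEnrichment:
    def make_inputs(self, pvals, gene_span):
        n = len(pvals)
        snps = SumStats(
            pd.DataFrame(
                {
                    "snp": [f"rs{i}" for i in range(n)],
                    "chrom": ["1"] * n,
                    "pos": np.arange(1, n + 1) * 100,
                    "p": pvals,
                }
            )
        )
        genes = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene": list(gene_span),
                    "chrom": ["1"] * len(gene_span),
                    "start": [s for s, _ in gene_span.values()],
                    "end": [e for _, e in gene_span.values()],
                }
            )
        )
        return snps, genes

    def test_two_gene_toy_exact_p(self):
        # gene A: 4 SNPs, 3 significant; gene B: 6 SNPs, 0 significant
        pvals = [0.01, 0.01, 0.01, 0.5] + [0.5] * 6
        snps, genes = self.make_inputs(
            pvals, {"A": (50, 450), "B": (451, 1050)}
        )
        mapping = map_snps(snps, genes, window_bp=0)
        res = gene_enrichment(snps, mapping, EnrichmentConfig())
        pa = res.set_index("gene").loc["A", "p_gene"]
        # P(X>=3), X ~ Hypergeom(10, 3, 4) = C(3,3)C(7,1)/C(10,4)
        assert pa == pytest.approx(7 / 210)
        assert round(pa, 4) == 0.0333

    def test_fully_significant_gene_hits_lower_boundary(self):
        pvals = [0.01, 0.01, 0.5, 0.5, 0.5, 0.5]
        snps, genes = self.make_inputs(pvals, {"A": (50, 250), "B": (251, 650)})
        mapping = map_snps(snps, genes, window_bp=0)
        res = gene_enrichment(snps, mapping, EnrichmentConfig()).set_index("gene")
        assert res.loc["A", "p_gene"] == pytest.approx(count_test(2, 2, 2, 6))

    def test_shared_snp_counted_once_in_background(self):
        # two overlapping genes map the same significant SNP; N counts it once
        snps = SumStats(
            pd.DataFrame(
                {
                    "snp": ["rs0", "rs1"],
                    "chrom": ["1", "1"],
                    "pos": [100, 200],
                    "p": [0.01, 0.5],
                }
            )
        )
        genes = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene": ["A", "B"],
                    "chrom": ["1", "1"],
                    "start": [50, 90],
                    "end": [150, 250],
                }
            )
        )
        mapping = map_snps(snps, genes, window_bp=0)
        res = gene_enrichment(snps, mapping, EnrichmentConfig()).set_index("gene")
        # background N=2, K=1 (rs0 once), gene A: n=1, k=1 -> p = 1/2
        assert res.loc["A", "p_gene"] == pytest.approx(0.5)

    def test_empty_mapping_warns_and_returns_empty(self):
        from pathforge.snp_gene_mapping import MappingTable

        snps = SumStats(
            pd.DataFrame({"snp": ["rs0"], "chrom": ["1"], "pos": [1], "p": [0.5]})
        )
        table = MappingTable(pd.DataFrame(columns=["snp", "gene", "distance"]), window_bp=0)
        assert gene_enrichment(snps, table, EnrichmentConfig()).empty


class TestPathwayEnrichment:
    @staticmethod
    def gene_frame(pvals):
        return pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(len(pvals))],
                "n_snps": 1,
                "k_sig": 0,
                "p_gene": pvals,
            }
        )

    def test_set_equal_to_universe_has_p_one(self):
        gr = self.gene_frame([0.01, 0.2, 0.8])
        coll = GeneSetCollection()
        coll.add(GeneSet("ALL", "", frozenset(gr["gene"])))
        res = pathway_enrichment(gr, coll, EnrichmentConfig())
        assert res.loc[0, "p_pathway"] == pytest.approx(1.0)

    def test_worked_hypergeometric_example(self):
        # universe 100 genes, 10 significant; set of 5 with 2 significant
        pvals = [0.01] * 10 + [0.5] * 90
        gr = self.gene_frame(pvals)
        members = frozenset(["G0", "G1", "G20", "G21", "G22"])
        coll = GeneSetCollection()
        coll.add(GeneSet("S", "", members))
        res = pathway_enrichment(gr, coll, EnrichmentConfig())
        assert res.loc[0, "k_sig_genes"] == 2
        assert res.loc[0, "p_pathway"] == pytest.approx(
            hypergeom_tail_oracle(2, 5, 10, 100)
        )
        assert round(res.loc[0, "p_pathway"], 4) == 0.0769

    def test_untested_set_flagged_and_excluded_from_fdr(self):
        gr = self.gene_frame([0.01, 0.5])
        coll = GeneSetCollection()
        coll.add(GeneSet("IN", "", frozenset(["G0"])))
        coll.add(GeneSet("OUT", "", frozenset(["NOT_A_GENE"])))
        res = pathway_enrichment(gr, coll, EnrichmentConfig()).set_index("set_name")
        assert not res.loc["OUT", "testable"]
        assert np.isnan(res.loc["OUT", "q_value"])
        assert res.loc["IN", "testable"]

    def test_members_outside_universe_dropped_from_denominator(self):
        gr = self.gene_frame([0.01, 0.5, 0.5])
        coll = GeneSetCollection()
        coll.add(GeneSet("S", "", frozenset(["G0", "GHOST1", "GHOST2"])))
        res = pathway_enrichment(gr, coll, EnrichmentConfig())
        assert res.loc[0, "n_genes_tested"] == 1


class TestBhFdr:
    def test_step_up_worked_example(self):
        qvals, flags = bh_fdr([0.001, 0.01, 0.04, 0.9], q=0.05)
        assert flags.tolist() == [True, True, False, False]

    def test_all_ones_flags_nothing(self):
        _, flags = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not flags.any()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, size=50)
        q1, f1 = bh_fdr(p, q=0.1)
        perm = rng.permutation(50)
        q2, f2 = bh_fdr(p[perm], q=0.1)
        np.testing.assert_allclose(q1[perm], q2)
        np.testing.assert_array_equal(f1[perm], f2)

    def test_qvalues_monotone_in_sorted_p(self):
        p = np.sort(np.random.default_rng(1).uniform(0.0001, 1, size=30))
        qvals, _ = bh_fdr(p)
        assert (np.diff(qvals) >= -1e-12).all()

    def test_empty_input(self):
        qvals, flags = bh_fdr([])
        assert qvals.size == 0 and flags.size == 0


class TestPermutationPvalue:
    @staticmethod
    def gene_frame(pvals):
        return pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(len(pvals))],
                "n_snps": 1,
                "k_sig": 0,
                "p_gene": pvals,
            }
        )

    def test_floor_is_one_over_b_plus_one(self):
        # the 3 significant genes of a 40-gene universe form the set; a null
        # redraw matches T_obs = 3 with probability 1/C(40,3), so B = 99
        # permutations almost surely find none and p hits the 1/(B+1) floor
        gr = self.gene_frame([0.001] * 3 + [0.9] * 37)
        p = permutation_pvalue(gr, ["G0", "G1", "G2"], B=99, seed=0)
        assert p == pytest.approx(1 / 100)
        gr_all_sig = self.gene_frame([0.001] * 4)
        assert permutation_pvalue(gr_all_sig, ["G0", "G1"], B=99, seed=0) == pytest.approx(1.0)

    def test_exhaustive_enumeration_small_universe(self):
        # universe of 4, one significant; set of 2 containing it:
        # P(T >= 1) over C(4,2)=6 subsets = 3/6
        gr = self.gene_frame([0.01, 0.2, 0.3, 0.4])
        p = permutation_pvalue(gr, ["G0", "G1"], method="exhaustive")
        assert p == pytest.approx(0.5)

    def test_resampling_converges_to_exhaustive(self):
        gr = self.gene_frame([0.01, 0.2, 0.3, 0.4])
        p = permutation_pvalue(gr, ["G0", "G1"], B=20_000, seed=1)
        assert p == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 20_000) + 1e-4)

    def test_deterministic_given_seed(self):
        gr = self.gene_frame(np.random.default_rng(3).uniform(0.001, 1, 20))
        members = ["G1", "G5", "G7"]
        assert permutation_pvalue(gr, members, B=500, seed=42) == permutation_pvalue(
            gr, members, B=500, seed=42
        )

    def test_null_rank_uniformity(self):
        # sets drawn at random from a null universe: empirical p roughly
        # uniform on its discrete support
        rng = np.random.default_rng(7)
        pvals = rng.uniform(0.001, 1, size=30)
        gr = self.gene_frame(pvals)
        ps = []
        for rep in range(200):
            members = rng.choice(gr["gene"], size=5, replace=False).tolist()
            ps.append(permutation_pvalue(gr, members, B=200, seed=rep))
        # mean of a uniform-ish discrete p distribution should be near 0.5+
        assert 0.4 < np.mean(ps) < 0.85
        assert min(ps) < 0.2

    def test_invalid_b_rejected(self):
        gr = self.gene_frame([0.5, 0.5])
        with pytest.raises(ValueError):
            permutation_pvalue(gr, ["G0"], B=0)
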