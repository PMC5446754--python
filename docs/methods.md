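# Methods

## Statistical model

### Counting enrichment, two levels

Both enrichment levels are competitive counting tests. At the gene level the
unit is the SNP: gene g with n mapped SNPs, k of them with association
p < α_snp, is tested against the background of all mapped SNPs (N total, K
significant). At the pathway level the unit is the gene: a set with n tested
members, k of them with gene-level p < α_gene, is tested against the
tested-gene universe. The default test is the exact hypergeometric upper
tail P(X ≥ k), X ~ Hypergeom(N, K, n): the gene's SNPs (the set's genes)
are treated as draws without replacement from the background, which is
literally true here because they are subsets of it. A binomial mode
(P(X ≥ k), X ~ Bin(n, K/N), or a fixed success rate) is provided because
"fraction of significant members vs. expected rate" is an equally defensible
reading of the counting idea; for n ≪ N the two agree closely. Both are
exact tail sums — no normal approximation anywhere.

Two counting rules matter more than the choice of distribution:

* **Each SNP enters the background once**, however many genes it maps to.
  Counting per mapping would let one multiply-mapped SNP inflate K — the
  very artifact (one significant SNP feeding a whole gene set) the pipeline
  exists to remove.
* **Genes with no mapped SNP, and set members outside the tested universe,
  are excluded from numerator and denominator alike.** This keeps the
  two-level counting self-consistent; treating untested members as
  non-significant would penalise sets for annotation coverage rather than
  for biology.

### FDR and permutation null

Pathway p-values are adjusted by Benjamini–Hochberg step-up at q = 0.05
(statsmodels' `fdr_bh`; the hand-worked step-up examples in the test suite
pin the convention). Untestable sets (no tested member) are excluded from
the FDR family.

The permutation null redraws B gene sets of the same tested size from the
universe, without replacement, holding the observed gene-level p landscape
fixed, and recomputes the significant-member count T. The empirical p-value
is (1 + #{T_b ≥ T_obs})/(B + 1), so it is never zero; B defaults to
100,000. This is the only null constructible from summary statistics (there
are no phenotypes to permute). Because it samples member sets without
replacement from the same universe the hypergeometric test describes, the
two must agree up to Monte-Carlo error — a dual-route check enforced in the
tests, with the resampling done by explicit subset draws (vectorised
random-key selection), not by sampling the hypergeometric distribution
directly. An exhaustive mode enumerates all C(N, n) subsets on small
universes.

### LD operations

r² is the squared Pearson correlation of genotype dosages (the PLINK
convention for unphased data), computed from a reference panel with
per-variant mean imputation of missing dosages. Pruning scans each
chromosome in coordinate order and keeps a variant unless its r² with an
already-kept variant within the window reaches the threshold — p-values are
deliberately not consulted, making the filter phenotype-independent.
Clumping visits variants in ascending p order (ties: chrom, pos, id); each
unconsumed variant becomes a lead and consumes unconsumed neighbours with
r² ≥ the threshold, so the most significant variant of every LD block
survives. Defaults: r² threshold 0.3, window 1 Mb. The threshold is the
standard redundancy-elimination value for this pipeline; the window is a
package choice — long-range LD beyond ~1 Mb exists (MHC) but is exceptional,
and the window is configurable. Pruning guarantees no kept pair within the
window at or above the threshold and is idempotent; clumping never removes
the globally most significant variant. Variants absent from the panel (or
monomorphic, where r² is undefined) pass through untouched and are logged.

### SNP-to-gene mapping

SNP s maps to every gene intersecting [pos(s) − W, pos(s) + W], closed on
both ends, on the same chromosome (a gene touching the boundary exactly is
mapped; the choice is stated rather than inferable from any reference, and
boundary-exact cases are immaterial in practice). Internal coordinates are
1-based closed; BED input is converted once at the boundary
([start, end) → [start+1, end]). The mapping is many-to-many and monotone in
W, which is the point of the mappings-per-SNP diagnostic: the mean over
mapped SNPs grows quickly with W (the published window sweep runs
2.6 → 9 → 14.6 over 100 kb → 500 kb → 1 Mb), and large windows let one
significant SNP feed many genes. W defaults to 100 kb. Unmapped SNPs
(gene deserts) are reported but excluded from enrichment backgrounds.

### Replication and convergence

Tiered replication counts sets with pathway p below t in *both* cohorts, at
each tier t ∈ {0.05, 0.01, 0.001}; a set absent from the replication table
is non-replicated by definition. (Holding the discovery cohort at the
loosest tier while tiering only the replication side is also reported, as
`n_joint_at_discovery`, but the symmetric definition is primary: it is the
one under which n_replicated(t) ≤ n_discovery(t) and self-replication is an
identity.) Gene convergence calls a gene convergent when its gene-level p
falls on the same side of α in both cohorts; p exactly equal to α counts as
non-significant on both sides — a measure-zero convention fixed here because
the strict-inequality phrasing of the definition leaves it open. The
convergence count is tested against Bin(n, p0) two-sided
(minimum-likelihood convention); p0 has no canonical value — under
independent null cohorts the convergence probability is
α² + (1−α)² ≈ 0.905, not 0.5 — so p0 is a required, logged parameter
defaulting to 0.5.

The shared-SNP audit reports, for a group of suspect sets, the significant
SNPs mapped to any member gene, their pairwise intersections and the common
core. Four sets whose evidence is one LD block show near-identical per-set
totals and a large common core; after pruning the core shrinks to the
block's lead.

## Synthetic data generator

### What it emulates

* **Block LD**: haplotypes are built per block by a copying scheme — with
  probability √r a SNP copies the haplotype's block founder allele,
  otherwise it draws independently at the block allele frequency — giving
  expected allelic correlation r between any two SNPs of a block (expected
  pairwise r² = r²). Blocks are independent; inter-block LD is zero by
  design, since the pipeline's logic only needs within-block redundancy,
  and the long-range-LD pathology is emulated by one long dense block
  rather than by cross-block correlation.
* **Summary statistics** are drawn directly at the z level, per block, from
  MVN(Rλ, R) with R compound-symmetric (off-diagonal r) and λ the vector of
  per-SNP non-centralities; p = 2Φ(−|z|). Under λ = 0 every p is exactly
  Uniform(0,1). Simulating z directly rather than regressing phenotypes on
  the panel keeps the generator closed-form checkable (neighbours of a
  causal SNP have E|z| ≈ rλ) and mirrors the real division of inputs:
  summary statistics and the LD panel arrive separately, and pruning r² is
  always computed from the panel.
* **The false-positive configuration** (default `ScenarioConfig`): 120
  moderate-LD blocks (8 SNPs, r = 0.4, 2 kb spacing, 250 kb apart) plus one
  dense region — 150 SNPs at 5× density, r = 0.95 — separated by a 300 kb
  gap; 15 genes tiled across the dense region form the shared core of 4 of
  the 20 gene sets; the first dense SNP carries λ = 6; 15 background causal
  loci (λ = 6) are spread over the regular blocks. Cohort size is metadata
  (n = 20,000 nominal); effects are specified on the z scale.
* **Two cohorts** share the variant grid, the truth and the effect vector;
  only the z noise differs (per-stage seeds derived from one scenario seed
  by label hashing).

Why these values: r = 0.95 in the dense region makes every dense SNP echo
the inflated signal (E|z| ≈ 5.7), so all core genes are saturated with
significant SNPs before pruning, while pairwise r² ≈ 0.9 guarantees the
region collapses to a single survivor under r² = 0.3 pruning. The polygenic
background keeps the post-pruning significant-SNP rate K/N comfortably above
α = 0.05, so a core gene left with one significant survivor (p_gene = K/N)
is correctly non-significant — without background signal the contrast
degenerates into a coin flip on sampling noise. The 250 kb block spacing
creates gene deserts, limiting how many bystander genes a causal SNP's
100 kb window can reach; with the original 50 kb spacing, window leakage
made bystander genes the majority of significant genes and planted-pathway
recovery unreliable. These sizes were fixed by a pilot study before the
validation suite was frozen and are not tuned per test.

Planted pathways receive one causal SNP (λ = 6) near the midpoint of 30% of
their member genes, preferring genes with a SNP within 50 kb so the signal
maps back to the gene it is planted in.

### What it does not emulate

Realistic human haplotype structure, allele-frequency spectra, imputation
error, ancestry mismatch between panel and cohort, gene-length biases, and
any correlation between gene-set membership and genomic position (sets are
sampled uniformly). Passing tests therefore demonstrate the *logic* of the
pipeline — the counting tests, the LD guarantees, the false-positive
mechanism and its removal — not calibration on real cohorts.

## Numerical choices and degenerate inputs

* p-values are never 0: permutation uses the +1 correction; exact tests are
  bounded by their smallest atom; simulated p is clipped to the smallest
  positive double; input rows with p = 0 (underflowed meta-analysis output)
  are dropped and counted, not clamped.
* Summary-statistics parsing converts numeric strings with the correctly
  rounded parser (pandas' fast path is lossy in the last bits), so a
  written scenario reloads and re-serialises byte-identically.
* Clumping ties on p are broken by (chrom, pos, id) for reproducibility.
* Monomorphic panel variants have undefined r²; `r2()` raises, and the LD
  filters treat them as unfilterable pass-throughs.
* Chromosome labels are normalised by stripping a leading `chr`; internal
  coordinates are 1-based closed everywhere, converted once at the BED
  boundary.
* Every generator and every pipeline run is a pure function of
  (parameters, seed); stage seeds are SHA-256-derived from the global seed
  and a stage label, and kept below 2³¹.

## Validation problem sizes

The validation suite runs the false-positive contrast, planted recovery and
null-FDR checks on 50 replicate scenarios each (~1,100 SNPs, 165 genes, 20
sets, 200 panel individuals per scenario), the exact-test enumeration on the
full grid N ≤ 60, permutation agreement at B = 10,000 over 50 random
instances, and the convergence calibration on 5,000 genes. These sizes give
the order statistics and rate estimates enough resolution for the stated
bounds (e.g. ±3 standard errors) while keeping a full run in tens of
seconds.

## Known limitations

* The counting tests condition on the observed significance threshold
  exceedances only; score-based enrichment (running-sum statistics) and
  gene-length or LD-score corrections are out of scope.
* The gene-level hypergeometric treats a gene's SNPs as exchangeable draws
  from the background even though they are correlated within LD blocks;
  this is precisely why LD filtering must precede enrichment, and the
  false-positive scenario quantifies the consequence of skipping it.
* Distance-based mapping is the only mode; functional (eQTL/chromatin)
  mapping is not implemented.
* The discovery–replication module compares result tables; it does not
  meta-analyse cohorts.
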