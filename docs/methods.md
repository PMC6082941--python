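# Methods

`indelpanel` analyzes panels of diallelic insertion/deletion (InDel)
markers of the kind used in forensic genetics (e.g., the 30-locus Qiagen
DIPplex panel). Genotypes are stored as insertion-allele dosage (2/1/0,
−1 missing); every statistic is computed per locus from the genotype
counts (n_II, n_ID, n_DD) over non-missing calls (complete-case per
locus), and panel-level quantities combine loci under an independence
assumption that the HWE and LD screens are there to justify.

## Forensic efficiency statistics

For a locus with n typed individuals, insertion frequency
p = (2·n_II + n_ID)/2n and q = 1 − p:

- **Match probability** MP = Σ_g (count_g/n)², summed over the three
  *observed* genotype classes. This is the convention of forensic summary
  spreadsheets (PowerStats-style), not the Hardy–Weinberg-expected
  p⁴ + (2pq)² + q⁴; the two differ measurably (e.g., 0.3481 vs 0.3768 at
  p ≈ 0.459 with the counts used in the test suite), and the observed-count
  form is what published panel tables reproduce. DP = 1 − MP.
- **Expected heterozygosity** uses Nei's unbiased small-sample form
  He = (2n/(2n−1))·2pq. Published tables round p to four decimals but
  compute He from the exact counts, so code paths that need to reproduce
  table cells should go through `reconstruct_counts` (below) rather than
  the rounded frequency.
- **PIC** = 1 − (p² + q²) − 2p²q².
- **Power of exclusion** uses the single-parent (Brenner) form
  PE = Ho²(1 − 2·Ho·(1−Ho)²) with Ho = n_ID/n the observed heterozygosity.
- **TPI** = 1/(2(1 − Ho)); infinite at Ho = 1, which is raised as a
  domain error rather than returned.
- **Panel combination**: CMP = Π MP_l and CPE = 1 − Π(1 − PE_l),
  accumulated in log space (`log` / `log1p`) so 30-locus products at the
  10⁻¹² scale lose no precision; both log₁₀ forms are exposed.

`reconstruct_counts(p, TPI, n)` inverts a published summary row to
integer genotype counts (heterozygotes from TPI, insertion copies from p,
homozygotes by closure) and refuses inconsistent rows. It is the bridge
between printed per-locus tables and count-based statistics.

## Hardy–Weinberg testing

The default test is the Levene–Haldane exact conditional test: holding
the observed allele counts fixed, every compatible heterozygote count h
(same parity as the insertion-copy count) has conditional probability
proportional to 2^h / (n_II! h! n_DD!), normalized over the enumeration;
the two-sided p-value sums configurations no more probable than the
observed one, with a 1e−12 relative slack on the tie comparison.
Monomorphic loci report p = 1. A 1-df chi-square test against (p², 2pq,
q²) expectations is exposed as a cross-check. The two agree in rank and
in significance calls at typical panel sizes, but the exact p runs
noticeably higher than the chi-square p in the non-significant range —
a consequence of the two-sided summation convention, not an error.
Multiple testing across a panel uses the Bonferroni threshold α/L
(0.05/30 ≈ 0.00167 for a 30-locus panel).

## Linkage disequilibrium

Two-locus haplotype frequencies are estimated from unphased genotype
pair counts by EM. Only the double heterozygote is phase-ambiguous; its
expected split between coupling (I-I/D-D) and repulsion (I-D/D-I) phases
is refreshed each iteration from the current haplotype frequencies
(standard E-step), starting from linkage equilibrium of the observed
margins. Convergence: max frequency change < 1e−10 or 1,000 iterations.
Because the allele-count margins are directly observed, the likelihood
has a single free parameter and this EM needs no restarts. From the
haplotype frequencies: D = f_II − p₁p₂, D′ = |D|/D_max with the
sign-dependent D_max, r² = D²/(p₁q₁p₂q₂). Pairs with a monomorphic
margin are reported as undefined and never counted against the r²
threshold (default 0.8). A panel of L loci yields L(L−1)/2 pair results
(435 for L = 30).

## Interpopulation differentiation and distances

Locus-by-locus differentiation between two populations defaults to the
two-sided Fisher exact test on the 2×2 allele-count table (the natural
exact test for diallelic loci); a permutation test on the locus-wise
Weir–Cockerham θ (individuals shuffled between populations,
p = (1 + #{θ* ≥ θ})/(n_perm + 1), seed mandatory) is provided as the
alternative. Significance uses the Bonferroni threshold α/L.

Nei's D_A between insertion-frequency profiles x, y over L diallelic
loci is 1 − (1/L)Σ_l(√(x_l y_l) + √((1−x_l)(1−y_l))); it accepts a
frequency table directly so published reference-population frequencies
can be compared without genotypes. F_st is the Weir–Cockerham (1984) θ,
combined across loci as the ratio of summed variance components (more
stable than averaging per-locus ratios when per-locus variance is
small); it is reported unclamped (slightly negative values are expected
for undifferentiated populations) except inside distance matrices, where
negatives are floored at zero to keep the matrix a valid dissimilarity.

## Trees and ordination

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q-criterion
and the standard branch-length formulas; ties in the Q argmin are broken
lexicographically on the joined label pair so output is platform-stable,
and negative branch lengths are kept by default (an option clamps them to
zero and transfers the deficit to the sibling branch). NJ is exact on
additive matrices, which the tests exploit. Ordination is classical
(Torgerson) metric MDS: double-center the squared distances,
eigendecompose, embed on the top axes with positive eigenvalues; negative
eigenvalues (non-Euclidean input, as F_st matrices can be) are dropped
with a logged warning, and the embedding dimension is reduced if fewer
positive axes exist than requested. Metric scaling was chosen over
stress-majorization variants for determinism and because the embeddings
it produces are exact whenever the input is Euclidean. A silhouette-style
score against group centroids quantifies how well labelled groups
separate in an embedding.

## Admixture model

`structure_fit` is a Gibbs sampler for the admixture model on unphased
diallelic data with per-allele-copy assignment variables: each copy picks
a cluster z with probability Q[i,·] and an allele from that cluster's
insertion frequency. Updates are conjugate — categorical z given (Q, P),
Beta(1 + counts) for cluster frequencies, Dirichlet(α + counts) for Q
rows. Defaults: burn-in 10,000 and 10,000 retained sweeps (the burn-in
matches the published protocol the package emulates; the retained length
is this package's choice), posterior means reported.

The Dirichlet concentration α is inferred by default with a Metropolis
random-walk step (Uniform(0, 10) prior, proposal sd 0.05), as the
reference STRUCTURE implementation does. This matters: with α fixed at 1
the posterior mean ancestry of genuinely unadmixed individuals plateaus
around 0.87 in two-population test data at F_st = 0.2 (the misassignment
of allele copies common to both clusters feeds back into the frequency
estimates), whereas inferred α shrinks below 0.1 for separated
populations and memberships concentrate near 1 — matching how the
reference tool behaves. A numeric α fixes it for users who want the
plain symmetric-prior variant. No label-switching correction is applied
within a chain (desk-scale separable data do not switch in practice);
`align_runs` greedily matches cluster columns across independent chains
by Q-column correlation. The complete-data log-likelihood is traced every
sweep for convergence checks (the tests apply a Geweke-style early/late
mean comparison).

## Synthetic data

The generators produce exactly the structures the analyses assume, so
every stage is testable without external genotype deposits:

- `simulate_hwe_population`: genotypes from (p² + Fpq, 2pq(1−F), q² + Fpq)
  with inbreeding F (F = 0 is HWE). Locus frequencies are given explicitly
  or drawn Uniform(0.1, 0.9) — a range typical of markers ascertained for
  forensic informativeness.
- `dongxiang_like_panel`: an HWE panel at the published 30-locus
  insertion frequencies with n = 169, the stand-in for the study's
  deposited genotypes throughout the test suite.
- `simulate_balding_nichols`: population frequencies drawn
  Beta(p(1−c)/c, (1−p)(1−c)/c) around an ancestral p at a target F_st = c;
  HWE within populations. This provides the ground truth for the θ
  estimator and clustering tests.
- `simulate_admixed`: each allele copy picks a cluster by the
  individual's Q row, then an allele by that cluster's frequency.
- `simulate_ld_pair`: 2n haplotypes drawn i.i.d. from four haplotype
  frequencies and paired randomly into unphased two-locus genotypes.

All generators require explicit seeds and are bit-reproducible. What the
synthetic data does **not** emulate: genotyping error and allelic
dropout, missingness patterns, relatedness/pedigree structure, linked
loci beyond the explicit two-locus generator, and ascertainment of loci
on real allele-frequency spectra. Tests passing on this synthetic data
therefore validate the estimators and their sampling behavior under the
stated models, not robustness to those real-data artifacts.

## Numerical and scale choices

- Reporting precision for table output is 4 decimals (round-half-even),
  matching forensic summary conventions; internal computation is double
  precision throughout.
- Exact-test tie comparison uses 1e−12 relative slack; EM tolerance
  1e−10; distance-matrix symmetry tolerance 1e−12; Q rows sum to 1
  within 1e−9.
- Stochastic test and validation runs are scaled to desk size: e.g., θ
  recovery uses 500 individuals/population at 500 loci; the clustering
  check uses two populations of 100 at 100 loci with 2,000 + 2,000
  sweeps (a scaled-down run of the 10,000-sweep default protocol); the
  type-I-error simulation uses 10,000 replicates at n = 169. These sizes
  are the package's validation choices and are stated in the tests.

## Known limitations

- Strictly diallelic: no STR/multi-allelic statistics, no VCF
  coordinate anchoring (panel loci are named, not positioned).
- Differentiation testing is per-locus exact/permutation; no
  hierarchical variance-component decomposition across population groups.
- MDS is metric-only; no non-metric stress optimization.
- The admixture sampler is the uncorrelated-frequency variant; no
  F-model (correlated frequencies), no linkage model, no bootstrap or
  ΔK-style model choice across K.
- NJ trees carry no bootstrap support values.
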