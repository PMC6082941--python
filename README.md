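# indelpanel

Population-genetic and forensic-efficiency analysis of diallelic
insertion/deletion (InDel) marker panels — the marker class behind kits
such as the 30-locus Qiagen DIPplex — for forensic geneticists and
population-genetics practitioners who need the full panel workflow in one
scriptable package.

Given a genotype matrix of II/ID/DD calls with population labels, the
package computes:

- **Per-locus forensic efficiency**: insertion/deletion allele
  frequencies, match probability MP = Σ_g(count_g/n)² over observed
  genotype classes, discrimination power DP = 1 − MP, polymorphism
  information content PIC = 1 − (p² + q²) − 2p²q², power of exclusion
  PE = Ho²(1 − 2Ho(1−Ho)²), typing paternity index TPI = 1/(2(1−Ho)),
  observed heterozygosity Ho and Nei's unbiased expected heterozygosity
  He = (2n/(2n−1))·2pq — plus the panel-wide cumulative match
  probability CMP = Π MP_l and combined power of exclusion
  CPE = 1 − Π(1 − PE_l), accumulated in log space.
- **Equilibrium screens**: the Levene–Haldane exact Hardy–Weinberg test
  (chi-square cross-check included) with Bonferroni correction, and
  pairwise linkage disequilibrium via EM haplotype-frequency estimation
  (D, D′, r²) over all L(L−1)/2 locus pairs.
- **Interpopulation structure**: locus-by-locus differentiation tests
  (Fisher exact on allele counts, or permutation tests on locus-wise θ),
  Nei's D_A distance, Weir–Cockerham F_st (θ), neighbor-joining trees,
  classical metric MDS, and a STRUCTURE-style admixture-model Gibbs
  sampler producing per-individual ancestry proportions (Q matrices).
- **Synthetic data**: seeded generators for HWE populations (with
  inbreeding F), Balding–Nichols multi-population structure at a target
  F_st, admixed individuals with given Q, and two-locus haplotype
  structure — so every analysis stage can be validated without access to
  restricted genotype deposits.

Formats: CSV/TSV genotype tables, GenePop, PHYLIP square distance
matrices, Newick trees, population × locus frequency tables.

## Worked example

Simulate a Hardy–Weinberg panel at the published allele frequencies of a
30-locus reference survey (n = 169) and summarize it:

```python
from indelpanel.simulate import dongxiang_like_panel
from indelpanel.forensic import profile_table

gm = dongxiang_like_panel(seed=7)        # 169 individuals x 30 loci
prof = profile_table(gm)
print(prof.table.head(5)[["locus", "p_ins", "MP", "DP", "PIC", "PE",
                          "TPI", "Ho", "He", "hwe_p"]].round(4).to_string(index=False))
print("CMP %.4e  CPE %.4f" % (prof.cmp, prof.cpe))
```

```
  locus  p_ins     MP     DP    PIC     PE    TPI     Ho     He  hwe_p
 HLD 77 0.4379 0.4079 0.5921 0.3711 0.2294 1.0974 0.5444 0.4937 0.2115
 HLD 45 0.6834 0.4189 0.5811 0.3391 0.1429 0.8989 0.4438 0.4340 0.8592
HLD 131 0.3994 0.3909 0.6091 0.3647 0.1799 0.9826 0.4911 0.4812 0.8727
 HLD 70 0.6302 0.4046 0.5954 0.3575 0.1799 0.9826 0.4911 0.4675 0.6201
  HLD 6 0.4852 0.3684 0.6316 0.3748 0.1749 0.9713 0.4852 0.5010 0.7582
CMP 5.3634e-12  CPE 0.9930
```

Each row is one locus: the estimated insertion frequency `p_ins` drifts
around its simulation input by binomial sampling noise at n = 169; `MP`
near 0.4 means two random individuals match at that locus ~40% of the
time, and the exact HWE p-values (`hwe_p`) are all unremarkable, as they
should be for data simulated under equilibrium. Across all 30 loci the
panel's cumulative match probability is ~5×10⁻¹² (one random match in
~2×10¹¹) and the combined power of exclusion is ~0.993.

The same workflow from the shell:

```sh
indelpanel summary genotypes.csv --out table.tsv
indelpanel hwe genotypes.csv --alpha 0.05
indelpanel ld genotypes.csv --r2 0.8
indelpanel distance genotypes.csv --metric fst --out fst.phylip --tsv fst.tsv
indelpanel tree genotypes.csv --metric da --out tree.nwk
indelpanel mds genotypes.csv --metric fst --dims 2 --out coords.tsv
indelpanel structure genotypes.csv --k 2..7 --seed 1 --out qdir/
indelpanel run --config run.yaml      # all stages + JSON manifest
```

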