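# barypop

PCA-free, missingness-robust genetic ancestry inference for genotyped
cohorts.

`barypop` places each subject in a *fixed* coordinate system defined by
genetic distances to reference populations, instead of the dataset-relative
axes a PCA produces. Because the coordinate system never depends on who else
is in the dataset, results are directly comparable across studies and
genotyping platforms, and subjects with very different genotyped SNP sets —
even >95% missing — can be analyzed together without imputation. The target
users are cohort curators and GWAS analysts who need harmonized,
reproducible continental-ancestry labels and admixture proportions across
heterogeneous datasets.

## The method

Given a panel of *S* ≈ 10,000 unlinked, autosomal, biallelic, high-MAF
"fingerprint" SNPs with reference-allele frequencies *p_jl* in five
reference populations *j* (European, African, East Asian, South Asian,
Mexican/Latino), the distance from subject *i* to population *j* is the
per-SNP mean negative log likelihood of its genotypes *g_il* ∈ {0, 1, 2}
under Hardy–Weinberg equilibrium:

```
D_ij = -(1/S') Σ_l [ g_il ln p_jl + (2 - g_il) ln q_jl + g_il (2 - g_il) ln 2 ]
```

summed over only the *S′* SNPs with genotype calls — missing SNPs are
skipped, never imputed.

The triple (D_i1, D_i2, D_i3) is a point **Q** in 3-space. The expected
triples of three anchor groups E, F, A (trusted European, African and East
Asian subjects) form a triangle; a rigid transform maps it to the z = 0
plane with side FA parallel to the x-axis. The barycentric coordinates
(λ_e, λ_f, λ_a) of **Q** in that triangle, clamped at zero and
renormalized, are the ancestry proportions (P_e, P_f, P_a). To normalize
for missing genotypes the triangle is rebuilt per subject from the expected
distances *restricted to that subject's genotyped subset*, and the
resulting barycentric coordinates are mapped back onto the full-panel
reference triangle, giving the **GD1/GD2** scores. **GD3** is the
out-of-plane coordinate of **Q** (it separates four-way admixture from
two-way European/Asian admixture) and **GD4 = D_i5 − D_i4**
(Latin-American minus South-Asian distance) is intrinsically
missingness-robust because the ln 2 heterozygote term cancels in the
difference. A nine-way population label (PopID 1–9) follows from published
cutoff rules on (P_e, P_f, P_a) and two quadratic curves in the (GD1, GD4)
plane; every cutoff is configurable.

The real reference panel is derived from controlled-access data, so the
package ships a generator for synthetic panels and cohorts with the same
statistical structure (Balding–Nichols population differentiation, HWE
genotypes, random or platform-structured missingness), used by the test
suite and the validation script.

## Worked example

```sh
barypop simulate --snps 10000 --seed 7 --panel-out panel.tsv \
    --cohort 3:1,0,0 --cohort 3:0.6,0.3,0.1 \
    --out-prefix cohort --missing-rate 0.2
barypop compute --panel panel.tsv --plink cohort --out scores.tsv
barypop plot --scores scores.tsv --axes gd1,gd2 --panel panel.tsv --out gd12.png
```

This simulates a 10,000-SNP panel, three pure-European subjects and three
60/30/10 European/African/East-Asian admixed subjects with 20% of calls
missing, then scores them. `scores.tsv` contains (abridged):

```
subject_id  s_prime      gd1      gd2      p_e      p_f      p_a  pop_id            label
  sim_g0_0     8003 0.261033 0.379493 0.990754 0.009124 0.000122       1         European
  sim_g0_1     8029 0.259765 0.378846 0.987622 0.012378 0.000000       1         European
  sim_g0_2     8015 0.263022 0.384495 1.000000 0.000000 0.000000       1         European
  sim_g1_0     8014 0.203469 0.231523 0.604445 0.310395 0.085160       5 Latin American 1
  sim_g1_1     8015 0.209654 0.224514 0.586146 0.307517 0.106337       5 Latin American 1
  sim_g1_2     7960 0.207906 0.228955 0.597739 0.305163 0.097097       5 Latin American 1
```

`s_prime` is the number of genotyped panel SNPs (~8,000 of 10,000 after
20% missingness). The pure-European subjects sit at the E vertex of the
reference triangle (P_e ≈ 1, PopID 1); the admixed subjects recover their
simulated 0.6/0.3/0.1 proportions and fall under the European cluster in
(GD1, GD2), where the cutoff rules label them Latin American 1 — the
region of European/African admixture with a small Asian-like component.

The library API mirrors the CLI: `load_panel`, `load_plink_cohort` /
`load_vcf_cohort`, `compute_cohort_scores`, `classify_scores`,
`plot_scores`, and the `simulate_*` generators.

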