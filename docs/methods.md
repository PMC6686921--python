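# Methods

## Model

Subjects are modeled as draws from Hardy–Weinberg equilibrium at (possibly
admixed) allele frequencies, independently across a fixed panel of *S*
unlinked, autosomal, biallelic fingerprint SNPs. For subject *i* and
reference population *j* with reference/alternate allele frequencies
*p_jl*, *q_jl* at SNP *l*, the genetic distance is the per-SNP mean
negative log genotype likelihood

D_ij = −(1/S′) Σ_l [ g_il ln p_jl + (2 − g_il) ln q_jl + g_il(2 − g_il) ln 2 ],

in nats per SNP, over the S′ genotyped SNPs. Three assumptions matter:

- **HWE within populations.** D_ij is a genotype cross-entropy; it is
  minimized in expectation when the subject's true frequencies equal
  population *j*'s (cross-entropy ≥ entropy).
- **No linkage between panel SNPs.** Per-SNP terms are treated as
  independent; the fingerprint panel is selected to make this hold.
- **Missingness independent of genotype at the retained SNPs.** Skipping
  missing SNPs and renormalizing by S′ is unbiased per SNP, whether the
  missing set is random or platform-structured, because the normalization
  triangle (below) is rebuilt on exactly the same SNP subset.

## Normalization and scores

Expected distances from anchor groups E, F, A (allele frequencies *u_rl*)
to the first three reference populations are computed per SNP as

c_rjl = −[ u² ln p² + 2uv ln(2pq) + v² ln q² ],

precomputed once per panel (S × 9 values) so any subset's expected
distances are masked means. The full-panel means give the reference
triangle ΔEFA₀; a subject's genotyped subset T gives ΔEFA_T. Both are
rigidly mapped to the z = 0 plane under a fixed convention: origin at V_F,
A on the positive x-axis, E with y > 0, ẑ = normalized
(V_A−V_F)×(V_E−V_F). The convention (which the method leaves open) fixes
the sign of GD3 and makes output deterministic.

Barycentric coordinates of the subject's point in ΔEFA_T are computed as
3×3 determinant ratios; they are affine weights summing to 1 by
construction. Mapped back onto ΔEFA₀ they give GD1/GD2. Because the same
subset T defines both the subject's distances and the triangle vertices,
E[λ] for a subject drawn from an anchor group is exactly the corresponding
unit vector under *any* missingness mask — this is the source of the
method's centroid stability under heavy and non-random missingness, which
the acceptance script measures directly. Proportions clamp negative λ at
zero and renormalize; GD4 = D₅ − D₄ is computed on the genotyped subset
without re-mapping (the heterozygote ln 2 term cancels in the difference,
so only frequency ratios enter and no normalization is needed).

A subtlety worth recording: for *admixed* subjects the expected
heterozygosity exceeds the mixture of anchor-group heterozygosities
(concavity of 2f(1−f)), which shifts the expected point along (1,1,1).
That direction is nearly orthogonal to the triangle plane — edge vectors
are differences of near-symmetric cross-entropies, so their component sums
nearly cancel — hence the shift loads almost entirely on GD3 rather than
biasing the proportions. This is simultaneously why proportions recover
admixture to ~0.01 and why GD3 distinguishes four-way admixture from
two-way European/Asian admixture with similar (GD1, GD2).

## Classification

PopID 1–9 follows the proportion cutoffs evaluated in printed row order
(P_e ≥ 0.87 → European; P_f ≥ 0.95 → African; P_a ≥ 0.95 → East Asian;
0.40 ≤ P_f < 0.95 ∧ P_a < 0.13 → African American; P_f < 0.40 ∧
P_e < 0.87 ∧ P_a < 0.13 ∧ P_f ≥ P_a → Latin American 1; P_a ≥ 0.13 ∧
P_f ≥ 0.13 → Other), with the remaining region (P_f < 0.13 ∧ P_f < P_a)
resolved on the (GD1, GD4) plane: South Asian if
GD4 > 5(GD1 − 1.69)² + 0.042, else Asian-Pacific Islander if
GD1 > 30·GD4² + 1.73, else Latin American 2 if GD4 < 0. The ordering makes
boundary ties deterministic; a dense-grid test verifies the rules cover
the simplex exactly once. Two genuinely open points were decided here and
exposed as configuration: the South-Asian curve is tested before the
Asian-Pacific curve in their (small) overlap region, and the residual case
(GD4 ≥ 0, neither curve) defaults to Asian-Pacific Islander
(`CutoffConfig.residual_pop_id`), consistent with that sub-cluster being
continuous with the Asian-Pacific cluster in real data. The quadratic
curve constants were calibrated on real repository-scale cohorts; on
synthetic panels the (GD1, GD4) geometry differs, so classification tests
on simulated data exercise PopIDs 1–3, 5 and the rule logic, not the curve
placement.

## Tunable parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `epsilon` | 1e-6 | Frequency clamp into [ε, 1−ε]; bounds any per-SNP log term by −2 ln ε ≈ 27.6 nats. The panel's handling of monomorphic SNPs is unspecified upstream, so clamping is this package's choice. |
| `DEGENERACY_RTOL` | 1e-9 | Subset triangles with \|det\| ≤ 1e-9 × perimeter² flag the subject (`unstable_frame`, proportions withheld) instead of aborting the run; tiny genotyped subsets can be near-collinear. |
| `LOW_SNP_WARN` | 1000 | S′ below this gets a `low_snps` flag (placement dispersion grows as 1/√S′). |
| `HIGH_CONFIDENCE_SNPS` | 4000 | S′ at or above this is annotated `high_confidence`, the conventional reporting threshold. |
| `CutoffConfig` | printed values | Every classification constant, including `residual_pop_id`. |
| `drop_ambiguous` | True | A/T and C/G SNPs are dropped at harmonization; frequency-based strand resolution is unsafe at the panel's high MAFs. |

## Synthetic data

`simulate_panel` draws ancestral frequencies uniform on
[maf_floor, 1 − maf_floor] (default 0.2, matching a high-MAF fingerprint
panel) and drifts each of the five populations independently under
Balding–Nichols Beta sampling with F = (0.12, 0.16, 0.16, 0.12, 0.10) for
EUR/AFR/EAS/SAS/LAT — magnitudes typical of continental differentiation at
ancestry-informative markers, fixed once as the study conditions. Anchor
groups default to the first three population frequencies
(`anchor_jitter` re-drifts them to emulate anchor subsets).
`simulate_subjects` draws Binomial(2, f) genotypes at the α-mixture of
panel frequencies; `apply_missingness` implements MCAR and shared-subset
("platform") masks.

What the simulator does *not* emulate: linkage disequilibrium, realistic
site-frequency spectra, genotyping error, batch effects correlated with
genotype, or the real panel's empirical inter-population geometry (the
five populations drift independently here, whereas real SAS/LAT groups
are themselves admixture-structured). Passing tests therefore demonstrate
the estimator's statistical properties under its own model — unbiasedness,
missingness robustness, oracle-exact kernels — not the field accuracy of
the published cutoff curves on real cohorts. Absolute GD values depend on
the panel, so scores from different panels (including published ones) are
not numerically comparable; within one panel they are.

## Numerical choices

- Natural logs throughout; float64; naive fixed-order summation (S ≤ 10⁴
  keeps accumulated error ≪ 1e-10, verified against likelihood-product
  oracles at 1e-10 and a linear-system barycentric oracle at 1e-9).
- Per-subject reductions are vector (not batched-matrix) operations so a
  subject's scores are bit-identical regardless of cohort composition —
  cross-dataset comparability holds exactly, not just statistically. Cost
  stays linear in subjects × SNPs (~1 s per 1,000 subjects at S = 10⁴).
- Validation problem sizes (10⁴ oracle instances; n = 500 recovery
  cohorts; n = 1000/group robustness cohorts at S = 3,433; 1k/2k/4k
  scaling series) were chosen to hold Monte-Carlo error well below each
  criterion's tolerance while keeping the whole suite under a minute.

## Known limitations

- Three ancestry vertices only: populations outside the E/F/A span load on
  GD3 and the proportions project them onto the triangle; a fourth
  (e.g. Native American) vertex would need a tetrahedron and is out of
  scope.
- Below a few hundred genotyped SNPs, placement dispersion dominates:
  calls are still unbiased but the nine-way purity cutoffs (e.g.
  P_e ≥ 0.87) misclassify dispersed pure subjects; the `low_snps` flag
  marks this regime.
- No genotype-error model: a subject whose calls are systematically
  miscoded (e.g. unresolved strand flips on ambiguous SNPs) shifts toward
  the triangle centroid.
- VCF input must carry diploid GT fields; dosages/GP are not supported.
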