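# Methods

## Scope and model

The package analyses a balanced full-factorial omics experiment: `n` samples
described by `p` features (normalized intensities), each sample labelled by
categorical factors (the motivating design: maturation state × exposure
duration × toxicant concentration, 2×2×3 with 3 replicates, n = 36,
p = 189). The analysis chain is

1. **QC filtering / merging / scaling** — pooled-QC re-injections estimate a
   per-feature coefficient of variation (sample SD over mean, ddof = 1);
   features with CV strictly above the threshold (default 0.35) are
   discarded, a CV exactly at the threshold is kept. Metabolites annotated
   on several LC-MS platforms are kept once: lowest QC CV wins, ties broken
   by higher median intensity, then by a fixed platform priority (HILIC−,
   HILIC+, RPLC−, RPLC+ — descending annotation counts in the motivating
   study). The merged matrix is unit-variance scaled; scaling statistics use
   biological samples only, because including the QC pool (which sits at the
   grand mean by construction) would shrink the apparent between-group
   variance. Filtering happens per platform before merging, so a metabolite's
   candidate copies are already QC-vetted when de-duplication compares them.

2. **ANOVA partition** — the centered matrix splits into effect matrices
   (level means for mains; cell means minus parent mains for two-way
   interactions) plus residual. Balance makes the pieces mutually orthogonal
   and the sums of squares additive, so contribution percentages
   100·SS_f/SS_total sum to 100. Only exact balance is accepted; the
   partition is not unique otherwise. The three-way interaction is not
   modeled by default (the motivating analysis reports mains and two-way
   terms only) and is pooled into the residual; callers can add any term
   list via `StudyDesign.effects`.

3. **Consensus kernel OPLS** — blocks are the effect matrices *augmented
   with the residual* (X_f + E) plus a pure-residual block. Augmentation is
   essential, not cosmetic: the residual lies in the orthocomplement of the
   design-contrast span, so with pure blocks the residual kernel annihilates
   the response (K_E·Y = 0) and the residual would have salience exactly
   zero on every predictive component, making any structure-vs-noise ratio
   degenerate. With augmentation, a null effect's block is statistically a
   copy of the residual block, which is what anchors its RSR near 1.
   Kernels K_b = Z_bZ_bᵀ are Frobenius-normalized so no block dominates by
   scale; the consensus kernel is their unweighted mean (deterministic fit;
   iterative block re-weighting is deliberately not implemented).
   Predictive scores are eigenvectors of K·Y·Yᵀ·K (equivalently, left
   singular vectors of K·Y scaled by singular values), ordered by singular
   value; the response Y holds one orthonormal contrast basis per term
   (levels − 1 columns per main, products of parent contrasts for
   interactions; q = 9 for the 2×2×3 model). Orthogonal components are
   leading eigenvectors of the kernel projected onto the orthocomplement of
   span([Y, T_pred]), hence exactly uncorrelated with every design
   contrast. Default one orthogonal component; `n_ortho="auto"` adds
   components while each explains ≥1% of consensus-kernel variance. Signs
   are fixed by making each component's largest-|loading| feature positive,
   so repeated fits are bit-identical. Saliences λ_{b,c} =
   tᵀK_b t / Σ_b′ tᵀK_b′ t (non-negative for PSD kernels; tiny negative
   numerators from round-off are clipped); each predictive component is
   associated with the block of maximal salience, ties going to the lower
   component index, and an effect that never dominates is assigned its
   best-salience component and flagged.

4. **Effect statistics** —
   * *Contribution*: the ANOVA SS fraction (percent). A salience-weighted
     alternative was considered and rejected: the SS fraction is the
     quantity that sums to 100% across terms plus residual, as the
     motivating study's table does.
   * *RSR*: per feature j, the ratio of the augmented block's mean square to
     the residual's, aggregated by the median over features:
     RSR_f = med_j [(SS_{f,j}+SS_{E,j})/(df_f+df_E)] / [SS_{E,j}/df_E],
     df_f = Π(levels−1) over the term's factors, df_E = n−1−Σdf. The
     residual block scores exactly 1 on any input; a null effect sits just
     below 1 (the median of a ratio whose numerator adds df_f noise
     dimensions); structure raises it monotonically. Two alternatives were
     measured during design and rejected. A salience-weighted sum over
     predictive components inherits component-selection bias — components
     are chosen to maximize design covariance, so even pure noise yields
     ratios far above 1 — and its permutation power is poor. A global
     (feature-summed) mean-square ratio is unbiased but noise-limited: its
     permutation null has heavy tails driven by permuted contrasts aligning
     with the noise matrix's top eigendirections (a sample-space, many-
     features-at-once event), and on the calibrated reference data roughly
     10 of 10⁴ permutations beat the observed concentration statistic. The
     per-feature median is immune to that alignment mechanism (a few
     features moving together cannot shift it) while every feature carries
     the effect, and the observed concentration statistic clears its
     permutation null maximum by ≈11 null standard deviations at 10⁴ draws.
   * *Permutation p*: the tested term's labels (joint cell labels for an
     interaction) are reshuffled within strata of the factors outside the
     term. This preserves the balanced factorial exactly — an unrestricted
     label shuffle would break balance and the unique partition with it —
     and realizes the term-specific exchangeability null for mains; for an
     interaction the within-stratum shuffle also breaks the parent mains'
     alignment, so the interaction test is a joint null (the parent
     structure re-enters the permuted mains' estimates, not the tested
     term's). p = 100·(r+1)/(n_perm+1) on the percent scale, never zero,
     floor 100/(n_perm+1) ≈ 0.01% at the reference depth of 10⁴. The
     permuted statistic is computed through a decompose-only path that is
     algebraically identical to refitting the whole model (the RSR depends
     only on the ANOVA blocks); the identity is asserted in the tests.
   * *VIP²*: p·Σ_c λ_{f,c}·SS_c·w²_{j,c} / Σ_c λ_{f,c}·SS_c over predictive
     components, with w_c the unit-normalized loading vector and SS_c the
     component's consensus-kernel variance; orthogonal components are
     excluded (importance is defined on predictive structure). Mean over
     features is exactly 1; the selection rule keeps VIP² strictly above
     the threshold (default 1.1), sorted descending.

5. **Joint over-representation** — proteins pass at max(FC, 1/FC) >
   threshold (two-sided on the ratio scale, so down-regulation counts) and
   p below threshold; each omics' hit list is tested per pathway with the
   hypergeometric upper tail P(X ≥ k) after intersecting pathway members
   with the declared universe, BH-FDR corrected across pathways; the joint
   table ranks by min(p_metab, p_prot) — the simplest rule that lets a
   pathway strong in either omics surface, matching how the two evidence
   columns are read side by side. Universes are configurable; the default
   is all surviving annotated metabolites and all quantified proteins.
   Absolute enrichment p-values depend on the (proprietary) universe of the
   original analysis tool and are not reproduction targets; the statistic,
   correction and table format are.

## Synthetic data

`synthdata.generate` emulates the study conditions: the 2×2×3×3 design
(36 samples), four platform tables of 33/36/58/62 annotated features,
8 pooled-QC injections (the study injected a QC about every six samples),
lognormal per-feature baselines (median 10⁵ counts, log-SD 1), biological
variation at 20% CV, and QC CVs drawn lognormal around a 10% median — the
repeatability of well-behaved annotated LC-MS features. Each modeled term
receives one random level-contrast pattern per responsive feature, purified
by the same projections the decomposer uses, so generator and model agree on
what each effect is by construction.

In calibration mode (default) the noise is projected onto the residual
subspace and every term's pattern is rescaled so the realized SS fractions
hit the targets exactly; the default targets are the motivating study's
printed contributions. Those print at one decimal and sum to 99.9%, so the
0.1-point rounding deficit is spread equally over the seven terms (1/70 of
a point each) to make exact calibration well-posed. When every feature is
responsive to every term (the default) the calibration is applied per
feature column — each column individually carries the target fractions and
unit variance — which makes the realized fractions invariant under
unit-variance scaling and under dropping features. With responsive subsets
declared, the rescaling is global per term and exactness holds for the full
matrix only. Non-calibrated mode (`calibrate=False`) leaves the noise
unprojected — the correct choice for null simulations, where leakage of
noise into effect estimates *is* the null behaviour being tested.

What the generator does not emulate: intensity-dependent (heteroscedastic)
noise, correlated features, missing values, injection-order drift, batch
structure, or chromatographic artefacts. Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under the
study's design and variance structure, not robustness to those real-data
pathologies — the preprocessing that handles them (alignment, normalization,
drift correction) is upstream of this package's scope.

`generate_qc_stress_table` builds a raw-style unfiltered table in which a
chosen fraction of features (default 90%) has QC CVs far above the cut
(CV 1.2 vs 0.05 for stable features, 8 QC injections), reproducing the
order-of-magnitude reduction the repeatability filter achieves on real
untargeted peak tables (≈10% retained). `generate_proteins` plants a chosen
number of regulated proteins (|log FC| uniform between log 1.5 and log 3,
p between 10⁻⁶ and 10⁻²) in a null background tight enough (log-FC SD 0.05)
that essentially only planted proteins pass the selection thresholds.
`generate_pathways` surrounds one planted, hit-enriched map (60% overlap by
default) with uniform random maps.

## Numerical choices and degenerate inputs

Tolerances: ANOVA reconstruction and SS additivity hold to 1e-10 relative;
block orthogonality to 1e-8 relative; VIP² mean-1 and the residual RSR of 1
are exact identities. Zero-variance features abort unit-variance scaling
with the feature named; features with zero QC mean are removed as
"degenerate"; an all-zero block, an empty universe or hit list, q > n−1
contrasts, unbalanced designs, and interactions without their parent mains
are errors, not warnings. Duplicate-resolution CVs are compared after
rounding to 1e-9 so float noise cannot defeat the documented tie-breaks.
Written tables use `repr(float)` so a write→read round trip is bit-exact.

## Known limitations

* RSR magnitudes are not claimed to match the original MATLAB
  implementation numerically (its exact formula is unpublished); the
  implemented ratio reproduces the published invariants — residual exactly
  1, null effects near 1, monotone growth with effect size, and the
  published ordering across effects — and its permutation test attains the
  published significance floor on calibrated data.
* Only balanced full factorials with terms up to two-way interactions are
  supported; no missing data, no mixed/random effects, no Type-II/III SS.
* The interaction permutation tests a joint null (see above); a
  residual-permutation variant for sharper interaction nulls would be the
  natural extension.
* Enrichment assumes a plain hypergeometric null; topology-aware methods
  and metabolite ID mapping across ontologies are out of scope.
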