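# Methods

## Star-allele model and diplotype calling

The genotyping model is a targeted panel: 11 biallelic variant assays plus
copy-number assays for whole-gene deletion/duplication. A star allele is a
named haplotype identified by a characteristic set of panel variants that
must carry the alternate base. The shipped definition table covers
*1–*7, *9, *10, *17 and *41; each non-reference allele is keyed by one
canonical defining variant (*4→1846G>A, *3→2549delA, *6→1707delT,
*7→2935A>C, *9→2613delAGA, *10→100C>T, *17→1023C>T, *41→2988G>A) and *2 by
its two-variant signature (2850C>T + 4180G>C). 1661G>C is tracked on the
panel but defines no allele here: it occurs on several haplotypes and is
uninformative for this allele set. *5 is the whole-gene deletion and is
carried by copy number, not variant states. The table is YAML-configurable
so a laboratory can substitute its own assay design; definitions are
validated on load (unique star names, known variant ids, mandatory *1).

The caller enumerates all allele pairs (≤ 66 with the shipped table) and
keeps those whose implied alternate-allele dosage matches every called
variant. One copy forces a hemizygous match (carried variants read hom-alt)
against *5; zero copies is *5/*5; three or more copies sets the duplication
flag while matching proceeds on the base pair. Among consistent pairs the
assignment with the largest total number of defining variants wins
(`match_priority`, so specific alleles beat *1); equally specific
alternatives are reported in `ambiguous_alternatives`, never dropped. A
no-call excludes the alleles defined by that variant and flags the result
low-confidence. With the shipped one-variant-per-allele table every
realizable diplotype is uniquely recoverable; the round-trip property is
tested exhaustively against an independent enumeration oracle.

Phenotype classification maps the sorted pair of activity classes
(EM = functional: *1, *2; IM = reduced: *9, *10, *17, *41; PM = null:
*3–*7) to the seven ordered categories; a duplication of two EM alleles is
ultra-rapid (EM/UM). A duplication involving a non-EM allele has no
category in this scheme and raises an explicit indeterminate-UM error
rather than guessing — the combination does not occur in the reference
cohort and the scheme is silent about it.

## Metabolite panel

Thirteen analytes (ng/ml): tamoxifen, NDM-Tam, the isobaric sums
(Z)-endoxifen + 3-OH-NDM-Tam and (Z)-4-OH-Tam + 3-OH-Tam, (E)-endoxifen,
4′-OH-Tam, 4′-OH-NDM-Tam, Tam-N-oxide, three glucuronides, and both
α-OH-Tam isomers. The isobaric sums are carried as single analytes
end-to-end; since the 3-isomers circulate several-fold lower, the sums are
read as (Z)-endoxifen and (Z)-4-OH-Tam. Quantitation status: within the
calibration linearity range → quantified; below its lower end (LOLR) with
signal-to-noise > 10 → estimated concentration; otherwise not detected.
Not-detected values contribute 0 ng/ml to sums (including the MR
denominator) but are excluded from location/scale summaries, which carry a
separate not-detected count. Whether estimated values enter the summary
moments is a switch (`include_estimated`, default on).

The low-exposure rule excludes patients whose tamoxifen is below 10 % of
the cohort mean — an adherence filter. The mean is computed once over the
full input cohort and the rule runs in a single pass deliberately: the
cutoff is a property of the cohort as sampled. Re-application to the output
can exclude further patients when the mean shifts; this is documented and
tested rather than iterated.

## Metabolic ratio and efficacy cutoff

MR = (Z)-endoxifen / Σ(other 12 analytes), tamoxifen included in the
denominator. Sanity anchor: at the reference panel means the denominator is
434.05 ng/ml, and 6 ng/ml ÷ 0.0146 ≈ 411 ng/ml is only consistent with a
tamoxifen-inclusive denominator. Two reference levels are kept distinct
because both are used: 5.97 ng/ml for below-threshold prevalence and the
rounded 6.0 ng/ml at which the MR cutoff is read off a simple linear
regression. The regression direction (MR on concentration, with intercept)
is the package default; the reverse direction is implemented and selectable
(`direction="conc_on_mr"`), as the source analysis specifies only "simple
linear regression". Boundary handling is strict (<) for "below" on both
axes, following the low-concentration wording; boundary values count as
above.

## Association battery

* **Hardy–Weinberg**: 1-df Pearson χ² of observed genotype counts against
  p², 2pq, q² from the observed allele frequencies, no continuity
  correction. A monomorphic variant is in equilibrium by convention
  (χ² = 0, p = 1). On assay-level data, hemizygous deletion carriers read
  hom-alt and mildly perturb the counts; the test is applied to the counts
  as assayed.
* **Indicator OLS**: outcome ~ six category indicators, EM/EM reference,
  fitted with statsmodels. The intercept is the reference-group mean and
  each coefficient that group's mean difference — an identity used as the
  test oracle. Two-sided Student-*t* p-values; the global Bonferroni
  threshold 0.05/(12 × 6) is embedded in every serialized result.
  Singleton groups are retained (they contribute to residual df); a
  constant outcome raises a zero-residual-variance error.
* **Spearman/AS 89**: r from midranks. For n ≤ 9 without ties the exact
  permutation distribution of S = Σd² is enumerated; otherwise the
  published AS 89 Edgeworth expansion is evaluated on the smaller tail via
  the S → S_max − S reflection (where the series is accurate) and doubled.
  The expansion was validated against R 4.3.3 `cor.test` (which uses AS 89
  in this regime): agreement to < 10⁻⁶ relative in the moderate tail; R
  adds refinements beyond the published series, so deep-tail values can
  differ by up to ~10⁻³ absolute. Deep in the tail the published series
  breaks down numerically (it can go negative); the implementation then
  falls back to the Student-*t* approximation, which is the standard
  tie-tolerant form. With ties the Edgeworth form is applied to the
  pseudo-statistic S = (1 − r)·n(n² − 1)/6 implied by the midrank r. The
  exact-n cutoff (9) is a documented constant.
* **Genotype encoding**: the ordinal score for rank correlation is the
  category rank 0–6 by default; a functional-allele-count encoding
  (PM = 0, IM = 0.5, EM = 1 per allele, EM/UM = 3) is provided as an
  alternative since the source encoding is not fixed by the analysis
  description.
* **Contingency χ²**: Pearson, df = (2−1)(k−1), no continuity correction;
  expected cells < 1 set a warning flag. The threshold-by-genotype table is
  2 × k over the categories present in the cohort.

The twelve outcomes are ten concentrations — all analytes except tamoxifen
itself and the two trace analytes undetected in much of the cohort
((E)-endoxifen, (Z)-α-OH-Tam) — plus the two metabolic ratios
((Z)-endoxifen and (Z)-4-OH-Tam).

## Synthetic cohort generator

The generator's defaults encode the study conditions the pipeline assumes:

* **Cohort**: 285 enrolled patients; a 6/285 low-exposure fraction whose
  whole panel is scaled by 0.05 (non-adherence), exercising the exclusion
  and leaving ≈ 279 analysable patients.
* **Genotypes**: two alleles drawn i.i.d. per patient (Hardy–Weinberg by
  construction) from frequencies derived by chromosome counting over the
  shipped reference composition (558 alleles), with *4 and *41 pinned to
  their published 0.223 and 0.077 and the remainder renormalized; *7 and
  *9 are retained at zero frequency. Duplication is applied only to EM/EM
  pairs at 0.165, chosen so the EM/UM category is ≈ 6.5 % of patients.
  The resulting category mix matches the reference cohort to within ~2
  percentage points — the residual gap is the reference cohort's own small
  departure from Hardy–Weinberg proportions.
* **Concentrations**: each analyte is log-normal with arithmetic-mean
  target M = base mean × category multiplier and mu = ln M − σ²/2. The
  (Z)-endoxifen multipliers encode the reference group means 7.3 / 4.9 /
  2.3 / 1.8 ng/ml (EM/EM, EM/PM, IM/PM, PM/PM); the unpublished categories
  (EM/UM 8.0, EM/IM 4.5, IM/IM 2.5 ng/ml) were fixed once so the overall
  mean is ≈ 5.5 ng/ml and the below-threshold ordering of EM/IM vs EM/PM
  matches the reference fractions (72 % vs 61 %). NDM-Tam and
  4′-OH-NDM-Tam decrease with CYP2D6 function, the 4-OH-NDM-Tam
  glucuronide increases, and (Z)-4-OH-Tam drops mainly in PM/PM
  (1.5 vs 2.7 ng/ml) — the five genotype-dependent analytes.
* **Exposure factor**: a per-patient log-normal factor (σ = 0.25, unit
  mean) scales the whole panel, modelling dose/adherence/absorption
  variability. Ratios cancel it exactly, which is why the MR carries more
  genotype information than any absolute concentration; without it that
  empirical pattern cannot arise. Per-analyte residual spreads are set so
  the total spread (√(σ²ₐ + 0.25²)) reproduces the reference coefficients
  of variation.
* **Truncation**: draws below a per-analyte detection floor become
  not-detected; between the floor and the LOLR they are flagged estimated.
  Floors and LOLR bounds were chosen so not-detected counts approximate
  the reference panel (e.g. ≈ 42 % for (Z)-α-OH-Tam, ≈ 89 % for
  (E)-endoxifen).

All randomness flows through one seeded `numpy` generator; a fixed seed
yields byte-identical output tables.

**What the generator does not emulate.** Concentrations are conditionally
log-normal given category and exposure; real panels show heavier tails,
co-medication effects (CYP2D6 inhibitors), assay batch structure, and
correlated measurement error, none of which are modelled. Consequently the
synthetic below-threshold prevalence runs a few percentage points above the
reference ≈ 60 %, and the genotype r² for (Z)-endoxifen concentration lands
near 0.30–0.35 (reference 0.27). Passing tests therefore demonstrate
correct recovery of the *configured* structure, not distributional realism
of any particular patient population.

## Numerical and design notes

* Problem sizes: the default test suite runs cohorts of 100–100 000
  patients and 200 null replicates of n = 279; the whole suite completes in
  well under a minute except the replicate study (~10 s).
* Exclusion boundary: a patient exactly at 10 % of the mean is retained
  (strict < excludes).
* Diplotype canonical order sorts star names numerically (*1/*4, never
  *4/*1); classification is symmetric by construction and tested.
* The MR denominator uses not-detected = 0; a panel whose denominator is 0
  is degenerate and rejected.
* OLS singularity is detected via residual sum of squares below 10⁻¹⁰ of
  total variation.

## Known limitations

* **Family-wise error under skewed nulls.** With all genotype multipliers
  removed, the battery's Bonferroni-corrected Student-*t* contrasts exceed
  the nominal 5 % family-wise rate (~16 % over 200 replicates): log-normal
  outcomes with near-singleton groups (IM/IM draws n ≈ 1–3) are
  anti-conservative in the 6.9×10⁻⁴ tail. A control experiment with
  Gaussian outcomes and the identical group structure yields exactly the
  nominal rate (10/200), confirming the effect is a property of t-tests on
  skewed data, not of the implementation. The corresponding acceptance
  test is kept at the nominal bound and fails by design; interpret
  borderline significances on heavily skewed outcomes with caution.
* Duplications co-occurring with reduced/null alleles are rejected rather
  than categorized.
* Hybrid/structural alleles beyond whole-gene deletion and duplication
  (e.g. *36, *13) and activity-score phenotype systems are out of scope.
* The AS 89 approximation with heavy ties relies on the midrank
  pseudo-statistic; for primary inference on heavily tied ordinal data the
  Student-*t* form (also implemented as the deep-tail guard) is the more
  defensible reference.
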