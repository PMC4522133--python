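# tamoxmr

CYP2D6 star-allele genotyping and (Z)-endoxifen-directed tamoxifen
metabolism analysis.

## The problem

Tamoxifen is a prodrug: its clinical activity in estrogen-receptor-positive
breast cancer depends on conversion — chiefly by the polymorphic enzyme
CYP2D6 — to the active metabolite (Z)-endoxifen. Patients whose steady-state
plasma (Z)-endoxifen stays below ~5.97 ng/ml are unlikely to benefit from
standard 20 mg/day dosing. Two questions follow for a pharmacogenomics or
therapeutic-drug-monitoring group:

1. Given a targeted CYP2D6 genotyping panel (11 variants plus gene
   copy-number assays), what star-allele diplotype and metabolizer category
   does each patient carry?
2. How well does that category predict (Z)-endoxifen exposure and the
   *metabolic ratio* (MR) — the (Z)-endoxifen concentration divided by the
   sum of the other 12 measured tamoxifen compounds — which indexes
   endoxifen-directed metabolism independently of absolute drug exposure?

`tamoxmr` implements the full analysis as a tested, reusable library: panel
curation with lower-linearity (LOLR) quantitation rules and a 10 %-of-mean
low-exposure exclusion; diplotype calling by exhaustive allele-pair
enumeration; the seven-category phenotype scheme
(PM/PM < IM/PM < IM/IM < EM/PM < EM/IM < EM/EM < EM/UM); the MR and its
regression-derived cutoff at the 6 ng/ml level; and the association battery:

* per-variant Hardy–Weinberg χ² (1 df, no continuity correction);
* indicator-variable OLS per outcome, EM/EM reference, so each coefficient
  is a group-mean difference in ng/ml, with Student-*t* tests under a
  global Bonferroni threshold α/(12 outcomes × 6 groups) = 0.05/72 ≈ 6.9×10⁻⁴;
* Spearman rank correlation (midranks) with AS 89 p-values — exact
  permutation for n ≤ 9 without ties, the published Edgeworth expansion
  otherwise — and r² as variance explained;
* Pearson χ² contingency checks of threshold-by-genotype and
  threshold-by-MR concordance.

A calibrated synthetic-cohort generator (Hardy–Weinberg star-allele
sampling, genotype-conditional log-normal concentrations with a shared
per-patient exposure factor, LOLR truncation, low-exposure outliers) makes
every stage testable without patient-level data.

## Worked example

```python
from tamoxmr import GeneratorConfig, generate_cohort, run_pipeline

cohort = generate_cohort(GeneratorConfig(seed=2015))
res = run_pipeline(cohort.genotypes, cohort.panels)
print(res.cutoff_fit.cutoff)
print(res.association.ols["z_endoxifen"].contrasts)
```

Running `python examples/04_association_battery.py` prints (abridged):

```
(Z)-endoxifen, EM/EM reference mean 7.57 ng/ml
group  n  coefficient  standard_error  t_statistic  p_value  significant
PM/PM 21      -5.8610          0.6214      -9.4312   0.0000         True
IM/PM 16      -5.1147          0.6970      -7.3386   0.0000         True
EM/PM 88      -2.8621          0.3790      -7.5525   0.0000         True
...
z_endoxifen      Spearman r = +0.594, r2 = 0.35, p = 2.12e-28 (as89_approx)
mr_z_endoxifen   Spearman r = +0.637, r2 = 0.41, p = 1.28e-33 (as89_approx)
```

Each coefficient is that group's mean (Z)-endoxifen minus the EM/EM mean:
carriers of one null allele (EM/PM) average ~2.9 ng/ml less, and two null
alleles (PM/PM) ~5.9 ng/ml less, than fully functional metabolizers — all
far beyond the 6.9×10⁻⁴ Bonferroni bar. The metabolic ratio explains more
of the genotype signal (r² 0.41 vs 0.35) because dividing by the remaining
compounds cancels between-patient exposure differences.

The other examples cover diplotype calling from raw panel calls
(`01`), the reference cohort's genotype-frequency table (`02`), and the MR
cutoff with threshold-concordance quadrants (`03`).

A thin CLI wraps the same functions:

```sh
tamoxmr simulate --n-patients 285 --seed 2015 --out-dir sim
tamoxmr run-all sim/genotypes.tsv sim/concentrations.tsv --out-dir report
```

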