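"""Synthetic cohort generator for the genotype -> metabolite pipeline.

Generates cohorts with the statistical structure the analysis assumes, so
that every stage is exercisable without patient data:

* star-allele genotypes in Hardy-Weinberg equilibrium at configurable allele
  frequencies (defaults derived from the shipped reference cohort's
  chromosome counts, with *4 and *41 pinned to their published 0.223 and
  0.077 frequencies and the remainder renormalised);
* gene duplications applied only to fully functional (EM/EM) allele pairs,
  at a rate tuned so the ultra-rapid category is ~6.5 % of patients;
* per-analyte log-normal steady-state concentrations whose category
  multipliers reproduce the reference group means for the CYP2D6-dependent
  analytes ((Z)-endoxifen 7.3/4.9/2.3/1.8 ng/ml for EM/EM, EM/PM, IM/PM,
  PM/PM) and whose overall means match the reference panel summary; a
  shared per-patient exposure factor (dose/adherence/absorption
  variability, log-normal with unit mean) scales the whole panel, so
  metabolic ratios cancel it — the mechanism that makes the MR more
  genotype-informative than any absolute concentration;
* lower-linearity (LOLR) truncation producing "estimated" and not-detected
  statuses, and a small fraction of low-exposure (non-adherent) patients to
  exercise the 10 %-of-mean exclusion rule.

All randomness flows through one :class:`numpy.random.Generator` seeded from
``GeneratorConfig.seed``; a fixed seed yields byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metabolites import ANALYTES, Measurement, PatientPanel, Status
from .star_allele import (
    Activity,
    AlleleTable,
    CopyNumberCall,
    Diplotype,
    VariantState,
    allele_frequencies,
    classify_phenotype,
    default_allele_definitions,
    load_reference_cohort,
    DELETION_ALLELE,
)

__all__ = [
    "AnalyteModel",
    "GeneratorConfig",
    "SimulatedCohort",
    "default_allele_frequencies",
    "default_analyte_models",
    "sample_genotypes",
    "simulate_assay_calls",
    "sample_concentrations",
    "generate_cohort",
]

#: Published allele frequencies kept fixed in the defaults.
_PINNED_FREQUENCIES = {"*4": 0.223, "*41": 0.077}


def default_allele_frequencies() -> dict[str, float]:
    """Default star-allele frequencies.

    Derived at runtime by chromosome counting over the shipped reference
    cohort (558 alleles), then overriding *4 and *41 with their published
    frequencies and renormalising the remaining alleles to sum to one.
    *7 and *9 are retained at zero frequency (defined on the panel, absent
    from the reference cohort).
    """
    counted = allele_frequencies(load_reference_cohort()).to_dict()
    counted.setdefault("*7", 0.0)
    counted.setdefault("*9", 0.0)
    other_mass = 1.0 - sum(_PINNED_FREQUENCIES.values())
    other_sum = sum(v for k, v in counted.items() if k not in _PINNED_FREQUENCIES)
    freqs = {}
    for star, f in counted.items():
        if star in _PINNED_FREQUENCIES:
            freqs[star] = _PINNED_FREQUENCIES[star]
        else:
            freqs[star] = f * other_mass / other_sum
    return dict(sorted(freqs.items()))


@dataclass(frozen=True)
class AnalyteModel:
    """Log-normal concentration model for one analyte.

    ``base_mean`` is the arithmetic-mean target (ng/ml) for the reference
    EM/EM category (equal to the overall target when ``multipliers`` is
    None); ``sigma_log`` the analyte-specific (residual) log-scale spread —
    the total within-category spread is sqrt(sigma_log^2 +
    exposure_sigma_log^2); ``multipliers`` scale the
    category mean for CYP2D6-dependent analytes.  ``detect_floor`` is the
    level below which the instrument reports nothing (not detected) and
    ``lolr`` the calibration linearity range: draws between the floor and
    the LOLR are flagged as estimated concentrations.
    """

    base_mean: float
    sigma_log: float
    multipliers: Mapping[str, float] | None = None
    detect_floor: float | None = None
    lolr: tuple[float, float] = (0.0, float("inf"))

    def mean_for(self, category: str) -> float:
        if self.multipliers is None:
            return self.base_mean
        return self.base_mean * self.multipliers[category]


def _increasing(pmpm, impm, imim, empm, emim, emem, emum):
    return {
        "PM/PM": pmpm, "IM/PM": impm, "IM/IM": imim, "EM/PM": empm,
        "EM/IM": emim, "EM/EM": emem, "EM/UM": emum,
    }


def default_analyte_models() -> dict[str, AnalyteModel]:
    """Per-analyte defaults calibrated to the reference panel summary.

    The (Z)-endoxifen multipliers encode the reference group means
    7.3 / 4.9 / 2.3 / 1.8 ng/ml (EM/EM, EM/PM, IM/PM, PM/PM); the categories
    without a published mean (EM/UM 8.0, EM/IM 4.5, IM/IM 2.5) are chosen so
    the overall mean is ~5.5 ng/ml and the below-threshold ordering of
    categories matches the reference below-threshold fractions.  NDM-Tam and
    4'-OH-NDM-Tam decrease with CYP2D6 function, the 4-OH-NDM-Tam
    glucuronide increases, and (Z)-4-OH-Tam decreases only mildly except in
    PM/PM (1.5 vs 2.7 ng/ml).

    The residual ``sigma_log`` values are chosen so that, combined with the
    default exposure spread (0.25), the total log-scale spread matches the
    reference panel's coefficients of variation.
    """
    return {
        "tamoxifen": AnalyteModel(173.5, 0.27, None, None, (10.0, 500.0)),
        "ndm_tam": AnalyteModel(
            219.0, 0.29,
            _increasing(1.25, 1.20, 1.15, 1.12, 1.05, 1.0, 0.95),
            None, (10.0, 1000.0),
        ),
        "z_endoxifen": AnalyteModel(
            7.3, 0.37,
            _increasing(1.8 / 7.3, 2.3 / 7.3, 2.5 / 7.3, 4.9 / 7.3,
                        4.5 / 7.3, 1.0, 8.0 / 7.3),
            None, (0.5, 50.0),
        ),
        "z_4oh_tam": AnalyteModel(
            2.7, 0.37,
            _increasing(1.5 / 2.7, 0.72, 0.78, 0.87, 0.95, 1.0, 1.05),
            None, (0.1, 20.0),
        ),
        "e_endoxifen": AnalyteModel(0.0143, 0.97, None, 0.03, (0.4, 5.0)),
        "4p_oh_tam": AnalyteModel(3.13, 0.33, None, None, (0.2, 20.0)),
        "4p_oh_ndm_tam": AnalyteModel(
            3.57, 0.37,
            _increasing(1.25, 1.20, 1.15, 1.12, 1.05, 1.0, 0.95),
            0.15, (0.5, 20.0),
        ),
        "tam_n_oxide": AnalyteModel(13.47, 0.46, None, None, (1.0, 100.0)),
        "e_4oh_tam_o_gluc": AnalyteModel(0.23, 0.60, None, 0.03, (0.08, 5.0)),
        "ez_4oh_ndm_tam_gluc": AnalyteModel(
            1.35, 0.71,
            _increasing(0.40, 0.50, 0.55, 0.75, 0.85, 1.0, 1.10),
            0.05, (0.1, 20.0),
        ),
        "ez_tam_n_gluc": AnalyteModel(0.32, 0.76, None, 0.03, (0.08, 5.0)),
        "e_a_oh_tam": AnalyteModel(0.36, 0.43, None, 0.11, (0.55, 5.0)),
        "z_a_oh_tam": AnalyteModel(0.026, 0.49, None, 0.02, (0.08, 5.0)),
    }


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort.

    285 patients are enrolled, of whom a ~2.1 % low-exposure fraction
    (non-adherent; whole panel scaled by ``low_exposure_scale``) exercises
    the 10 %-of-mean exclusion, leaving ~279 analysable patients.  The
    duplication probability applies only to EM/EM allele pairs and makes the
    ultra-rapid category ~6.5 % of patients.
    """

    n_patients: int = 285
    seed: int = 2015
    allele_frequencies: dict[str, float] = field(
        default_factory=default_allele_frequencies
    )
    analyte_models: dict[str, AnalyteModel] = field(
        default_factory=default_analyte_models
    )
    duplication_probability: float = 0.165
    exposure_sigma_log: float = 0.25
    low_exposure_fraction: float = 6.0 / 285.0
    low_exposure_scale: float = 0.05

    def __post_init__(self) -> None:
        total = sum(self.allele_frequencies.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.allele_frequencies.values()):
            raise ValueError("allele frequencies must be non-negative")
        missing = set(ANALYTES) - set(self.analyte_models)
        if missing:
            raise ValueError(f"analyte models missing for {sorted(missing)}")
        for a, m in self.analyte_models.items():
            if m.sigma_log <= 0 or m.base_mean <= 0:
                raise ValueError(f"invalid model for {a}")
            if m.multipliers is not None and any(
                v <= 0 for v in m.multipliers.values()
            ):
                raise ValueError(f"non-positive multiplier for {a}")
        if self.exposure_sigma_log < 0:
            raise ValueError("exposure_sigma_log must be non-negative")
        if not (0 <= self.low_exposure_fraction < 1):
            raise ValueError("low_exposure_fraction must be in [0, 1)")
        if not (0 <= self.duplication_probability <= 1):
            raise ValueError("duplication_probability must be in [0, 1]")

    def digest(self) -> str:
        payload = {
            "n_patients": self.n_patients,
            "seed": self.seed,
            "allele_frequencies": self.allele_frequencies,
            "analyte_models": {
                a: {
                    "base_mean": m.base_mean,
                    "sigma_log": m.sigma_log,
                    "multipliers": dict(m.multipliers) if m.multipliers else None,
                    "detect_floor": m.detect_floor,
                    "lolr": list(m.lolr),
                }
                for a, m in sorted(self.analyte_models.items())
            },
            "duplication_probability": self.duplication_probability,
            "exposure_sigma_log": self.exposure_sigma_log,
            "low_exposure_fraction": self.low_exposure_fraction,
            "low_exposure_scale": self.low_exposure_scale,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def sample_genotypes(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> list[Diplotype]:
    """Draw each patient's two alleles i.i.d. (Hardy-Weinberg by construction).

    Duplication is applied, with ``cfg.duplication_probability``, only when
    both alleles are EM class, so the result is always classifiable under
    the seven-category scheme.
    """
    defs = default_allele_definitions()
    stars = list(cfg.allele_frequencies)
    probs = np.asarray([cfg.allele_frequencies[s] for s in stars])
    probs = probs / probs.sum()
    draws = rng.choice(len(stars), size=(cfg.n_patients, 2), p=probs)
    dup_draws = rng.random(cfg.n_patients)
    out = []
    for i in range(cfg.n_patients):
        a, b = stars[draws[i, 0]], stars[draws[i, 1]]
        both_em = (
            defs.activity(a) is Activity.EM and defs.activity(b) is Activity.EM
        )
        dup = bool(both_em and dup_draws[i] < cfg.duplication_probability)
        out.append(Diplotype(a, b, duplicated=dup))
    return out


def simulate_assay_calls(
    d: Diplotype, defs: AlleleTable | None = None
) -> tuple[dict[str, VariantState], CopyNumberCall]:
    """Emit the variant-state vector and copy number implied by a diplotype.

    This is the inverse of the caller and exists for round-trip testing: a
    homozygous deletion yields no-calls at every variant (no gene to
    assay); a hemizygous sample reports its carried variants as hom-alt.
    """
    defs = defs if defs is not None else default_allele_definitions()
    for star in (d.allele_a, d.allele_b):
        a = defs[star]
        if star not in ("*1", DELETION_ALLELE) and not a.defining_variants:
            raise ValueError(
                f"allele {star} has no defining variants; calls cannot be simulated"
            )
    dels = sum(s == DELETION_ALLELE for s in (d.allele_a, d.allele_b))
    if dels == 2:
        calls = {v: VariantState.NO_CALL for v in defs.panel_variants}
        return calls, CopyNumberCall(copies=0)
    copies = 1 if dels == 1 else (3 if d.duplicated else 2)
    calls = {}
    for v in defs.panel_variants:
        dosage = sum(
            v in defs[s].defining_variants for s in (d.allele_a, d.allele_b)
        )
        if dels == 1:
            calls[v] = VariantState.HOM_ALT if dosage else VariantState.HOM_REF
        else:
            calls[v] = (
                VariantState.HOM_REF,
                VariantState.HET,
                VariantState.HOM_ALT,
            )[dosage]
    return calls, CopyNumberCall(copies=copies)


def sample_concentrations(
    diplotypes: Sequence[Diplotype],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[list[PatientPanel], pd.DataFrame]:
    """Draw per-patient analyte panels conditional on metabolizer category.

    Each analyte is log-normal with the category-specific arithmetic mean
    M = base_mean x multiplier (mu = ln M - sigma^2/2), multiplied by a
    per-patient exposure factor shared across the whole panel (log-normal,
    unit mean) that models dose/adherence/absorption variability.  Draws
    below the detection floor become not-detected; draws between the floor
    and the LOLR are flagged estimated.  Low-exposure patients have their
    whole panel scaled down before status assignment.  Returns the panels
    plus a truth table (category, exposure, low-exposure flag, true
    (Z)-endoxifen mean).
    """
    defs = default_allele_definitions()
    categories = [classify_phenotype(d, defs).label for d in diplotypes]
    n = len(diplotypes)
    exp_sigma = cfg.exposure_sigma_log
    exposure = (
        rng.lognormal(mean=-exp_sigma**2 / 2.0, sigma=exp_sigma, size=n)
        if exp_sigma > 0
        else np.ones(n)
    )
    low_exposure = rng.random(n) < cfg.low_exposure_fraction

    panels: list[PatientPanel] = []
    truth_rows = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        cat = categories[i]
        measurements: dict[str, Measurement] = {}
        for analyte in ANALYTES:
            m = cfg.analyte_models[analyte]
            target_mean = m.mean_for(cat)
            mu = np.log(target_mean) - m.sigma_log**2 / 2.0
            conc = float(exposure[i]) * float(
                rng.lognormal(mean=mu, sigma=m.sigma_log)
            )
            if low_exposure[i]:
                conc *= cfg.low_exposure_scale
            if m.detect_floor is not None and conc < m.detect_floor:
                measurements[analyte] = Measurement(None, Status.NOT_DETECTED)
            elif conc < m.lolr[0]:
                measurements[analyte] = Measurement(
                    conc, Status.ESTIMATED_BELOW_LOLR
                )
            else:
                measurements[analyte] = Measurement(
                    conc, Status.QUANTIFIED, extrapolated=conc > m.lolr[1]
                )
        panels.append(PatientPanel(patient_id=pid, measurements=measurements))
        truth_rows.append(
            {
                "patient_id": pid,
                "diplotype": diplotypes[i].label(),
                "category": cat,
                "exposure_factor": float(exposure[i]),
                "low_exposure": bool(low_exposure[i]),
                "true_z_endoxifen_mean": cfg.analyte_models[
                    "z_endoxifen"
                ].mean_for(cat),
            }
        )
    return panels, pd.DataFrame(truth_rows)


@dataclass
class SimulatedCohort:
    """Generated tables plus provenance (seed and config digest)."""

    genotypes: pd.DataFrame
    concentrations: pd.DataFrame
    truth: pd.DataFrame
    diplotypes: list[Diplotype]
    panels: list[PatientPanel]
    manifest: dict


def generate_cohort(cfg: GeneratorConfig | None = None) -> SimulatedCohort:
    """Generate the full synthetic bundle in the pipeline's input schemas."""
    cfg = cfg if cfg is not None else GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    defs = default_allele_definitions()
    diplotypes = sample_genotypes(cfg, rng)
    panels, truth = sample_concentrations(diplotypes, cfg, rng)

    geno_rows = []
    for i, d in enumerate(diplotypes):
        calls, cn = simulate_assay_calls(d, defs)
        row: dict[str, object] = {"patient_id": f"P{i + 1:04d}"}
        row.update({v: calls[v].value for v in defs.panel_variants})
        row["copy_number"] = cn.copies
        geno_rows.append(row)
    genotypes = pd.DataFrame(geno_rows)

    conc_rows = []
    for p in panels:
        row = {"patient_id": p.patient_id}
        for a in ANALYTES:
            meas = p[a]
            row[a] = (
                "" if meas.concentration is None else f"{meas.concentration:.6g}"
            )
            row[f"{a}_status"] = meas.status.value
        conc_rows.append(row)
    concentrations = pd.DataFrame(conc_rows)

    manifest = {
        "seed": cfg.seed,
        "n_patients": cfg.n_patients,
        "config_digest": cfg.digest(),
    }
    return SimulatedCohort(
        genotypes=genotypes,
        concentrations=concentrations,
        truth=truth,
        diplotypes=diplotypes,
        panels=panels,
        manifest=manifest,
    )
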