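"""End-to-end orchestration: genotypes + concentrations -> report bundle.

Stages: diplotype calling and phenotype classification; per-variant
Hardy-Weinberg checks; low-exposure exclusion; panel summary; metabolic
ratios, MR cutoff, threshold/concordance groups; and the OLS + Spearman
association battery over ten metabolite concentrations and two metabolic
ratios.  Every run produces a manifest whose record counts reconcile
(input = retained + excluded) and which embeds the thresholds and the
Bonferroni plan so each report is auditable on its own.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    parse_genotype_row,
    read_concentration_table,
    read_genotype_table,
    write_concentration_table,
    write_tsv,
)
from .metabolites import (
    ANALYTES,
    LinearityRange,
    PatientPanel,
    exclude_low_exposure,
    summarize_cohort,
)
from .mr import (
    MRCutoffFit,
    QuadrantCounts,
    ThresholdConfig,
    below_threshold_by_category,
    classify_quadrants,
    compute_mr,
    derive_mr_cutoff,
)
from .simulate import GeneratorConfig, default_analyte_models, generate_cohort
from .star_allele import (
    AlleleTable,
    VariantState,
    call_diplotype,
    classify_phenotype,
    default_allele_definitions,
    genotype_frequency_table,
    load_allele_definitions,
)
from .stats import (
    AssociationSuite,
    BonferroniPlan,
    ContingencyResult,
    contingency_chisq,
    hwe_chisq,
    run_association_suite,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "ReconciliationError",
    "OUTCOME_CONCENTRATIONS",
    "run_pipeline",
    "run_pipeline_from_files",
    "write_report_bundle",
    "simulate_command",
]


class ReconciliationError(ValueError):
    """Patient ids do not match between the genotype and concentration tables."""

    def __init__(self, only_genotypes: set[str], only_concentrations: set[str]):
        self.only_genotypes = sorted(only_genotypes)
        self.only_concentrations = sorted(only_concentrations)
        super().__init__(
            "patient-id mismatch between tables: "
            f"{len(self.only_genotypes)} only in genotypes, "
            f"{len(self.only_concentrations)} only in concentrations"
        )


#: The ten concentration outcomes of the association battery: every analyte
#: except tamoxifen itself and the two trace analytes undetected in large
#: parts of the cohort ((E)-endoxifen, (Z)-a-OH-Tam).
OUTCOME_CONCENTRATIONS: tuple[str, ...] = (
    "ndm_tam",
    "z_endoxifen",
    "z_4oh_tam",
    "4p_oh_tam",
    "4p_oh_ndm_tam",
    "tam_n_oxide",
    "e_4oh_tam_o_gluc",
    "ez_4oh_ndm_tam_gluc",
    "ez_tam_n_gluc",
    "e_a_oh_tam",
)


@dataclass
class PipelineConfig:
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    plan: BonferroniPlan = field(default_factory=BonferroniPlan)
    encoding: str = "category_rank"
    mr_direction: str = "mr_on_conc"
    allele_definitions_path: str | None = None

    def allele_table(self) -> AlleleTable:
        if self.allele_definitions_path:
            return load_allele_definitions(self.allele_definitions_path)
        return default_allele_definitions()


@dataclass
class PipelineResult:
    diplotype_table: pd.DataFrame
    hwe_table: pd.DataFrame
    excluded_patients: list[str]
    genotype_frequencies: pd.DataFrame
    category_frequencies: pd.DataFrame
    panel_summary: pd.DataFrame
    patient_mr_table: pd.DataFrame
    cutoff_fit: MRCutoffFit
    quadrants: QuadrantCounts
    below_threshold: pd.DataFrame
    threshold_by_genotype: ContingencyResult
    threshold_vs_mr: ContingencyResult
    association: AssociationSuite
    manifest: dict


def _hwe_by_variant(genotype_df: pd.DataFrame, defs: AlleleTable) -> pd.DataFrame:
    rows = []
    for v in defs.panel_variants:
        col = genotype_df[v]
        counts = (
            int((col == "0/0").sum()),
            int((col == "0/1").sum()),
            int((col == "1/1").sum()),
        )
        res = hwe_chisq(counts)
        rows.append(
            {
                "variant": v,
                "n_hom_ref": counts[0],
                "n_het": counts[1],
                "n_hom_alt": counts[2],
                "alt_freq": 1.0 - res.allele_freq,
                "chi2": res.chi2,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def _outcome_matrix(panels: Sequence[PatientPanel]) -> pd.DataFrame:
    """The 12 association outcomes: 10 concentrations + 2 metabolic ratios.

    Not-detected analytes enter as 0 ng/ml, consistent with their treatment
    in the MR denominator.
    """
    data: dict[str, list[float]] = {a: [] for a in OUTCOME_CONCENTRATIONS}
    data["mr_z_endoxifen"] = []
    data["mr_z_4oh_tam"] = []
    for p in panels:
        for a in OUTCOME_CONCENTRATIONS:
            data[a].append(p[a].value_or_zero)
        total = sum(p[a].value_or_zero for a in ANALYTES)
        num_endo = p["z_endoxifen"].value_or_zero
        num_4oh = p["z_4oh_tam"].value_or_zero
        data["mr_z_endoxifen"].append(num_endo / (total - num_endo))
        data["mr_z_4oh_tam"].append(num_4oh / (total - num_4oh))
    return pd.DataFrame(data)


def run_pipeline(
    genotype_df: pd.DataFrame,
    panels: Sequence[PatientPanel],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run all stages on in-memory inputs (see module docstring)."""
    config = config if config is not None else PipelineConfig()
    defs = config.allele_table()

    geno_ids = set(genotype_df["patient_id"].astype(str))
    conc_ids = {p.patient_id for p in panels}
    if geno_ids != conc_ids:
        raise ReconciliationError(geno_ids - conc_ids, conc_ids - geno_ids)

    dip_rows = []
    diplotypes = {}
    for _, row in genotype_df.iterrows():
        calls, cn = parse_genotype_row(row, defs)
        d = call_diplotype(calls, cn, defs)
        cat = classify_phenotype(d, defs)
        pid = str(row["patient_id"])
        diplotypes[pid] = d
        dip_rows.append(
            {
                "patient_id": pid,
                "diplotype": d.label(),
                "duplicated": d.duplicated,
                "category": cat.label,
                "ambiguous": d.is_ambiguous,
                "alternatives": ";".join("/".join(p) for p in d.ambiguous_alternatives),
                "low_confidence": d.low_confidence,
            }
        )
    diplotype_table = pd.DataFrame(dip_rows)
    hwe_table = _hwe_by_variant(genotype_df, defs)

    retained, excluded = exclude_low_exposure(list(panels))
    retained_ids = [p.patient_id for p in retained]
    by_dip, by_cat = genotype_frequency_table(
        [diplotypes[pid] for pid in retained_ids], defs
    )
    panel_summary = summarize_cohort(retained)

    categories = [
        diplotype_table.set_index("patient_id").loc[pid, "category"]
        for pid in retained_ids
    ]
    mrs = [compute_mr(p) for p in retained]
    conc = np.array([p["z_endoxifen"].value_or_zero for p in retained])
    mr_values = np.array([m.mr for m in mrs])

    cutoff_fit = derive_mr_cutoff(
        conc, mr_values, config.thresholds, direction=config.mr_direction
    )
    quadrants = classify_quadrants(conc, mr_values, config.thresholds, cutoff_fit.cutoff)
    below = below_threshold_by_category(categories, conc, config.thresholds)

    patient_mr_table = pd.DataFrame(
        {
            "patient_id": retained_ids,
            "category": categories,
            "z_endoxifen": conc,
            "mr": mr_values,
            "below_threshold": conc < config.thresholds.endoxifen_threshold,
            "below_mr_cutoff": mr_values < cutoff_fit.cutoff,
        }
    )

    # Qualitative checks: low/adequate (Z)-endoxifen against MR cutoff, and
    # against the metabolizer categories present in the cohort.
    low_c = conc < config.thresholds.cutoff_reference_level
    low_m = mr_values < cutoff_fit.cutoff
    threshold_vs_mr = contingency_chisq(
        [
            [int((low_c & low_m).sum()), int((low_c & ~low_m).sum())],
            [int((~low_c & low_m).sum()), int((~low_c & ~low_m).sum())],
        ]
    )
    cat_series = pd.Series(categories)
    below_eff = conc < config.thresholds.endoxifen_threshold
    cats_present = [c for c in cat_series.unique()]
    table = [
        [int(below_eff[(cat_series == c).to_numpy()].sum()) for c in cats_present],
        [int((~below_eff)[(cat_series == c).to_numpy()].sum()) for c in cats_present],
    ]
    # drop columns with zero margin to keep the chi-square well defined
    keep = [i for i in range(len(cats_present)) if table[0][i] + table[1][i] > 0]
    threshold_by_genotype = contingency_chisq(
        [[table[0][i] for i in keep], [table[1][i] for i in keep]]
    )

    outcomes = _outcome_matrix(retained)
    association = run_association_suite(
        outcomes, categories, plan=config.plan, encoding=config.encoding
    )

    manifest = {
        "software": {"name": "tamoxmr", "version": __version__},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "thresholds": {
            "endoxifen_threshold": config.thresholds.endoxifen_threshold,
            "cutoff_reference_level": config.thresholds.cutoff_reference_level,
            "mr_cutoff": cutoff_fit.cutoff,
        },
        "bonferroni_plan": config.plan.to_dict(),
        "encoding": config.encoding,
        "record_counts": {
            "input_patients": len(panels),
            "retained_patients": len(retained),
            "excluded_low_exposure": len(excluded),
        },
        "excluded_patient_ids": excluded,
        "skipped_outcomes": association.skipped_outcomes,
    }
    assert (
        manifest["record_counts"]["input_patients"]
        == manifest["record_counts"]["retained_patients"]
        + manifest["record_counts"]["excluded_low_exposure"]
    )

    return PipelineResult(
        diplotype_table=diplotype_table,
        hwe_table=hwe_table,
        excluded_patients=excluded,
        genotype_frequencies=by_dip,
        category_frequencies=by_cat,
        panel_summary=panel_summary,
        patient_mr_table=patient_mr_table,
        cutoff_fit=cutoff_fit,
        quadrants=quadrants,
        below_threshold=below,
        threshold_by_genotype=threshold_by_genotype,
        threshold_vs_mr=threshold_vs_mr,
        association=association,
        manifest=manifest,
    )


def run_pipeline_from_files(
    genotype_tsv: str | Path,
    concentration_tsv: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config if config is not None else PipelineConfig()
    defs = config.allele_table()
    genotype_df = read_genotype_table(genotype_tsv, defs)
    linearity = {
        a: LinearityRange(m.lolr[0], m.lolr[1])
        for a, m in default_analyte_models().items()
    }
    panels = read_concentration_table(concentration_tsv, linearity=linearity)
    return run_pipeline(genotype_df, panels, config)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_report_bundle(result: PipelineResult, out_dir: str | Path) -> dict:
    """Write the TSV/JSON report set; returns the manifest with file digests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(result.diplotype_table, out / "diplotypes.tsv")
    write_tsv(result.hwe_table, out / "hwe.tsv")
    write_tsv(result.genotype_frequencies, out / "genotype_frequencies.tsv")
    write_tsv(result.category_frequencies, out / "category_frequencies.tsv")
    result.panel_summary.reset_index(names="analyte").to_csv(
        out / "panel_summary.tsv", sep="\t", index=False
    )
    write_tsv(result.patient_mr_table, out / "patient_mr.tsv")
    write_tsv(result.below_threshold, out / "below_threshold.tsv")
    write_tsv(result.association.to_frame(), out / "association.tsv")

    summary = {
        "mr_cutoff": result.cutoff_fit.cutoff,
        "cutoff_fit": {
            "intercept": result.cutoff_fit.intercept,
            "slope": result.cutoff_fit.slope,
            "direction": result.cutoff_fit.direction,
            "n": result.cutoff_fit.n,
        },
        "quadrants": {
            "both_above": result.quadrants.both_above,
            "both_below": result.quadrants.both_below,
            "low_conc_high_mr": result.quadrants.low_conc_high_mr,
            "high_conc_low_mr": result.quadrants.high_conc_low_mr,
        },
        "threshold_by_genotype_chi2": {
            "chi2": result.threshold_by_genotype.chi2,
            "df": result.threshold_by_genotype.df,
            "p_value": result.threshold_by_genotype.p_value,
        },
        "threshold_vs_mr_chi2": {
            "chi2": result.threshold_vs_mr.chi2,
            "df": result.threshold_vs_mr.df,
            "p_value": result.threshold_vs_mr.p_value,
        },
        "spearman": {
            oid: {"r": s.r, "r_squared": s.r_squared, "p_value": s.p_value}
            for oid, s in result.association.spearman.items()
        },
        "bonferroni_plan": result.association.plan.to_dict(),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    manifest = dict(result.manifest)
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
    }
    manifest["outputs"]["summary.json"] = _sha256(out / "summary.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def simulate_command(
    cfg: GeneratorConfig | None = None, out_dir: str | Path = "."
) -> dict:
    """Write a synthetic bundle (genotypes, concentrations, truth, manifest)."""
    cohort = generate_cohort(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(cohort.genotypes, out / "genotypes.tsv")
    write_tsv(cohort.concentrations, out / "concentrations.tsv")
    write_tsv(cohort.truth, out / "truth.tsv")
    manifest = dict(cohort.manifest)
    manifest["outputs"] = {
        name: _sha256(out / name)
        for name in ("genotypes.tsv", "concentrations.tsv", "truth.tsv")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
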