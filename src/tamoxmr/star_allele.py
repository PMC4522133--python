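"""CYP2D6 star-allele diplotype calling and metabolizer phenotype classification.

A *star allele* is a named CYP2D6 haplotype (e.g. ``*4``) identified on a
targeted genotyping panel by a characteristic set of variant calls; ``*1`` is
the default (wild-type) allele carrying none of the panel's alternate bases,
and ``*5`` is the whole-gene deletion, detected by copy number rather than by
variant states.  Each allele belongs to an activity class — EM (fully
functional), IM (reduced function) or PM (null) — and a patient's pair of
alleles (diplotype), together with a possible gene duplication, maps to one of
seven ordered metabolizer categories:

    PM/PM < IM/PM < IM/IM < EM/PM < EM/IM < EM/EM < EM/UM

EM/UM is the ultra-rapid category: a duplication of fully functional alleles.

The caller enumerates every allele pair consistent with the observed variant
states and copy number, prefers the most specific assignment (largest total
number of defining variants matched), and reports any equally specific
alternatives rather than dropping them.
"""

from __future__ import annotations

import enum
import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Activity",
    "VariantState",
    "CopyNumberCall",
    "AlleleDefinition",
    "AlleleTable",
    "Diplotype",
    "PhenotypeCategory",
    "ConfigurationError",
    "InconsistentCallsError",
    "CopyNumberQCError",
    "IndeterminateUMError",
    "load_allele_definitions",
    "default_allele_definitions",
    "call_diplotype",
    "classify_phenotype",
    "genotype_frequency_table",
    "load_reference_cohort",
]

DELETION_ALLELE = "*5"
DEFAULT_ALLELE = "*1"

#: The seven metabolizer categories in increasing order of enzyme function.
CATEGORY_ORDER = ("PM/PM", "IM/PM", "IM/IM", "EM/PM", "EM/IM", "EM/EM", "EM/UM")


class ConfigurationError(ValueError):
    """Raised for an invalid allele definition table."""


class InconsistentCallsError(ValueError):
    """Variant states consistent with no allele pair; carries the offending ids."""

    def __init__(self, conflicting_variants: Sequence[str]):
        self.conflicting_variants = list(conflicting_variants)
        super().__init__(
            "variant calls are inconsistent with every allele pair; "
            f"alternate calls at: {', '.join(self.conflicting_variants) or '(none)'}"
        )


class CopyNumberQCError(ValueError):
    """Copy-number assay failed QC; no diplotype can be assigned."""


class IndeterminateUMError(ValueError):
    """Gene duplication together with a reduced/null-function allele.

    The seven-category scheme only defines an ultra-rapid group for
    duplications of fully functional (EM) alleles; any other duplicated
    diplotype has no category and is reported explicitly instead of being
    guessed.
    """


class Activity(str, enum.Enum):
    """Enzyme activity class of a single allele."""

    EM = "EM"
    IM = "IM"
    PM = "PM"

    @property
    def order(self) -> int:
        return {"EM": 0, "IM": 1, "PM": 2}[self.value]


class VariantState(enum.Enum):
    HOM_REF = "0/0"
    HET = "0/1"
    HOM_ALT = "1/1"
    NO_CALL = "./."

    @property
    def alt_dosage(self) -> int | None:
        """Alternate-allele dosage implied by the call (None when no-call)."""
        return {"0/0": 0, "0/1": 1, "1/1": 2, "./.": None}[self.value]


@dataclass(frozen=True)
class CopyNumberCall:
    """Gene copy number from the CNV assay; 2 is the normal diploid state."""

    copies: int
    pass_qc: bool = True

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copy number must be non-negative")


@dataclass(frozen=True)
class AlleleDefinition:
    """One star allele: its defining variant set, activity class and priority.

    ``match_priority`` breaks ties between equally consistent assignments;
    by default it equals the number of defining variants, so a more specific
    allele is preferred over *1 (empty set).
    """

    star_name: str
    defining_variants: frozenset[str]
    activity: Activity
    is_deletion: bool = False
    match_priority: int | None = None

    @property
    def priority(self) -> int:
        if self.match_priority is not None:
            return self.match_priority
        return len(self.defining_variants)


@dataclass
class AlleleTable:
    """Validated collection of allele definitions plus the assay panel."""

    alleles: dict[str, AlleleDefinition]
    panel_variants: tuple[str, ...]

    def __post_init__(self) -> None:
        if DEFAULT_ALLELE not in self.alleles:
            raise ConfigurationError(
                f"default allele {DEFAULT_ALLELE} must be present in the table"
            )
        panel = set(self.panel_variants)
        if len(panel) != len(self.panel_variants):
            raise ConfigurationError("panel variant ids are not unique")
        for a in self.alleles.values():
            unknown = a.defining_variants - panel
            if unknown:
                raise ConfigurationError(
                    f"allele {a.star_name} references unknown variant(s): "
                    f"{sorted(unknown)}"
                )

    def __getitem__(self, star_name: str) -> AlleleDefinition:
        return self.alleles[star_name]

    def __len__(self) -> int:
        return len(self.alleles)

    def activity(self, star_name: str) -> Activity:
        return self.alleles[star_name].activity

    def non_deletion_alleles(self) -> list[AlleleDefinition]:
        return [a for a in self.alleles.values() if not a.is_deletion]


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Sort a star-name pair numerically (*1 < *2 < *10 < *41)."""

    def key(s: str) -> tuple[int, str]:
        digits = "".join(c for c in s if c.isdigit())
        return (int(digits) if digits else 0, s)

    return tuple(sorted((a, b), key=key))  # type: ignore[return-value]


@dataclass(frozen=True)
class Diplotype:
    """A pair of star alleles, stored in canonical order.

    ``ambiguous_alternatives`` lists any equally specific allele pairs that
    were also consistent with the raw calls; ``low_confidence`` flags a call
    made with one or more panel variants missing (no-call).
    """

    allele_a: str
    allele_b: str
    duplicated: bool = False
    ambiguous_alternatives: tuple[tuple[str, str], ...] = ()
    low_confidence: bool = False

    def __post_init__(self) -> None:
        a, b = _canonical_pair(self.allele_a, self.allele_b)
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def is_ambiguous(self) -> bool:
        return bool(self.ambiguous_alternatives)

    def label(self) -> str:
        base = f"{self.allele_a}/{self.allele_b}"
        return base + (" (xN)" if self.duplicated else "")


@dataclass(frozen=True)
class PhenotypeCategory:
    """One of the seven ordered metabolizer categories."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in CATEGORY_ORDER:
            raise ValueError(f"unknown phenotype category: {self.label}")

    @property
    def rank(self) -> int:
        return CATEGORY_ORDER.index(self.label)

    def __str__(self) -> str:
        return self.label


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("tamoxmr").joinpath("data", name)))


def load_allele_definitions(config_path: str | Path) -> AlleleTable:
    """Load and validate a star-allele definition table from YAML.

    The file must declare the assay ``panel`` (list of variant ids) and an
    ``alleles`` mapping of star name -> {activity, variants, deletion?,
    priority?}.  Duplicate star names, unknown variant ids within an allele,
    or a missing ``*1`` raise :class:`ConfigurationError`.
    """
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "alleles" not in raw or "panel" not in raw:
        raise ConfigurationError("definition file must contain 'panel' and 'alleles'")
    panel = tuple(str(v) for v in raw["panel"])
    alleles: dict[str, AlleleDefinition] = {}
    entries = raw["alleles"]
    if isinstance(entries, list):  # list-of-dicts form allows duplicate detection
        items = [(e["star_name"], e) for e in entries]
    else:
        items = list(entries.items())
    for star, spec in items:
        star = str(star)
        if star in alleles:
            raise ConfigurationError(f"duplicate allele name: {star}")
        variants = [str(v) for v in spec.get("variants", [])]
        if len(set(variants)) != len(variants):
            raise ConfigurationError(f"duplicate variant ids within allele {star}")
        alleles[star] = AlleleDefinition(
            star_name=star,
            defining_variants=frozenset(variants),
            activity=Activity(spec["activity"]),
            is_deletion=bool(spec.get("deletion", False)),
            match_priority=spec.get("priority"),
        )
    return AlleleTable(alleles=alleles, panel_variants=panel)


def default_allele_definitions() -> AlleleTable:
    """The shipped 11-allele definition table (*1-*7, *9, *10, *17, *41)."""
    return load_allele_definitions(_data_path("allele_definitions.yaml"))


def _expected_dosage(pair: tuple[AlleleDefinition, AlleleDefinition], variant: str) -> int:
    return int(variant in pair[0].defining_variants) + int(
        variant in pair[1].defining_variants
    )


def call_diplotype(
    calls: Mapping[str, VariantState],
    cn: CopyNumberCall,
    defs: AlleleTable,
) -> Diplotype:
    """Assign a star-allele diplotype from panel variant calls and copy number.

    Every allele pair consistent with the observed alternate-allele dosages is
    enumerated; among consistent pairs the one with the largest total number
    of defining variants (``match_priority``) is returned and equally specific
    alternatives are kept in ``ambiguous_alternatives``.  Copy number drives
    the deletion allele: 1 copy forces one allele to ``*5`` (hemizygous
    matching: any variant on the remaining allele reads hom-alt), 0 copies is
    ``*5/*5``, and >= 3 copies sets the duplication flag.

    Variants with a no-call are excluded from matching; alleles *defined by*
    such a variant are removed from the candidate set and the result is
    flagged ``low_confidence``.
    """
    if not cn.pass_qc:
        raise CopyNumberQCError("copy-number assay failed QC")
    unknown = set(calls) - set(defs.panel_variants)
    if unknown:
        raise ConfigurationError(f"calls at variants not on the panel: {sorted(unknown)}")

    no_calls = {v for v, s in calls.items() if s is VariantState.NO_CALL}
    observed = {v: s.alt_dosage for v, s in calls.items() if s is not VariantState.NO_CALL}
    low_confidence = bool(no_calls)

    if cn.copies == 0:
        return Diplotype(DELETION_ALLELE, DELETION_ALLELE, low_confidence=low_confidence)

    candidates = [
        a
        for a in defs.non_deletion_alleles()
        if not (a.defining_variants & no_calls)
    ]

    consistent: list[tuple[int, tuple[str, str]]] = []
    if cn.copies == 1:
        # Hemizygous: single non-deleted allele; carried variants read hom-alt.
        for a in candidates:
            ok = all(
                dosage == (2 if v in a.defining_variants else 0)
                for v, dosage in observed.items()
            )
            if ok:
                consistent.append((a.priority, _canonical_pair(a.star_name, DELETION_ALLELE)))
    else:
        for a, b in combinations_with_replacement(candidates, 2):
            ok = all(
                dosage == _expected_dosage((a, b), v) for v, dosage in observed.items()
            )
            if ok:
                consistent.append(
                    (a.priority + b.priority, _canonical_pair(a.star_name, b.star_name))
                )

    if not consistent:
        conflicting = sorted(v for v, dosage in observed.items() if dosage > 0)
        raise InconsistentCallsError(conflicting)

    best = max(p for p, _ in consistent)
    winners = sorted({pair for p, pair in consistent if p == best})
    primary, alternatives = winners[0], tuple(winners[1:])
    return Diplotype(
        primary[0],
        primary[1],
        duplicated=cn.copies >= 3,
        ambiguous_alternatives=alternatives,
        low_confidence=low_confidence,
    )


def classify_phenotype(d: Diplotype, defs: AlleleTable) -> PhenotypeCategory:
    """Map a diplotype to one of the seven metabolizer categories.

    The label is the sorted pair of the two alleles' activity classes
    (higher function first); a duplication of two EM-class alleles is the
    ultra-rapid EM/UM category.  A duplication combined with a non-EM allele
    has no category in this scheme and raises :class:`IndeterminateUMError`.
    """
    act_a = defs.activity(d.allele_a)
    act_b = defs.activity(d.allele_b)
    hi, lo = sorted((act_a, act_b), key=lambda a: a.order)
    if d.duplicated:
        if hi is Activity.EM and lo is Activity.EM:
            return PhenotypeCategory("EM/UM")
        raise IndeterminateUMError(
            f"duplication of {d.allele_a}/{d.allele_b} involves a non-EM allele; "
            "no ultra-rapid category is defined for this combination"
        )
    return PhenotypeCategory(f"{hi.value}/{lo.value}")


def genotype_frequency_table(
    diplotypes: Iterable[Diplotype],
    defs: AlleleTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-diplotype and per-category counts and percentages for a cohort.

    Returns ``(by_diplotype, by_category)`` frames; percentages are of the
    cohort size and sum to 100 within rounding.
    """
    defs = defs if defs is not None else default_allele_definitions()
    dips = list(diplotypes)
    if not dips:
        raise ValueError("empty cohort")
    n = len(dips)

    rows = []
    for d in dips:
        cat = classify_phenotype(d, defs)
        rows.append((d.label(), cat.label))
    df = pd.DataFrame(rows, columns=["diplotype", "category"])

    by_dip = (
        df.groupby(["category", "diplotype"]).size().rename("count").reset_index()
    )
    by_dip["percent"] = 100.0 * by_dip["count"] / n
    by_dip["category_rank"] = by_dip["category"].map(
        {c: i for i, c in enumerate(CATEGORY_ORDER)}
    )
    by_dip = by_dip.sort_values(
        ["category_rank", "count"], ascending=[False, False]
    ).drop(columns="category_rank").reset_index(drop=True)

    by_cat = df.groupby("category").size().rename("count").reindex(
        CATEGORY_ORDER, fill_value=0
    ).reset_index().rename(columns={"index": "category"})
    by_cat["percent"] = 100.0 * by_cat["count"] / n
    return by_dip, by_cat


def load_reference_cohort() -> list[Diplotype]:
    """Expand the shipped reference cohort composition into 279 diplotypes.

    The packaged table records the published genotype composition of a
    Polish breast-cancer cohort (29 distinct diplotype rows, n = 279).
    """
    df = pd.read_csv(_data_path("reference_cohort_diplotypes.tsv"), sep="\t")
    out: list[Diplotype] = []
    for _, row in df.iterrows():
        dup = str(row["duplicated"]) == "True"
        out.extend(
            [Diplotype(row["allele_a"], row["allele_b"], duplicated=dup)]
            * int(row["count"])
        )
    return out


def allele_frequencies(diplotypes: Iterable[Diplotype]) -> pd.Series:
    """Allele frequencies by direct chromosome counting (duplications count
    the duplicated pair once, i.e. two chromosomes per patient)."""
    counts: Counter[str] = Counter()
    total = 0
    for d in diplotypes:
        counts[d.allele_a] += 1
        counts[d.allele_b] += 1
        total += 2
    return pd.Series(counts, dtype=float).sort_index() / total
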