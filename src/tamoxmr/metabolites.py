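"""The 13-analyte steady-state tamoxifen metabolite panel.

One patient's panel holds plasma concentrations (ng/ml) for tamoxifen and 12
of its metabolites measured by UPLC-MS/MS.  Two entries are isobaric pairs
quantified as a single summed analyte because the isomers cannot be resolved
chromatographically: (Z)-endoxifen + 3-OH-NDM-Tam (carried here as
``z_endoxifen``) and (Z)-4-OH-Tam + 3-OH-Tam (``z_4oh_tam``).  The 3-isomers
circulate at several-fold lower levels than their 4-counterparts, so the sums
are conventionally read as the (Z)-endoxifen and (Z)-4-OH-Tam concentrations.

Quantitation status follows the calibration linearity range: values inside
the range are *quantified*; values below its lower end (LOLR) with adequate
signal-to-noise (> 10) are reported as *estimated* concentrations; anything
else is *not detected*.  Not-detected analytes contribute 0 ng/ml to
downstream sums (e.g. the metabolic-ratio denominator) but are excluded from
location/scale summaries, which report a separate not-detected count.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "ANALYTE_DISPLAY",
    "Status",
    "Measurement",
    "PatientPanel",
    "LinearityRange",
    "assign_status",
    "exclude_low_exposure",
    "summarize_cohort",
]

#: Closed set of panel analytes, in report order.  ``z_endoxifen`` and
#: ``z_4oh_tam`` are the two isobaric sums.
ANALYTES: tuple[str, ...] = (
    "tamoxifen",
    "ndm_tam",
    "z_endoxifen",
    "z_4oh_tam",
    "e_endoxifen",
    "4p_oh_tam",
    "4p_oh_ndm_tam",
    "tam_n_oxide",
    "e_4oh_tam_o_gluc",
    "ez_4oh_ndm_tam_gluc",
    "ez_tam_n_gluc",
    "e_a_oh_tam",
    "z_a_oh_tam",
)

ANALYTE_DISPLAY: dict[str, str] = {
    "tamoxifen": "Tamoxifen",
    "ndm_tam": "NDM-Tam",
    "z_endoxifen": "(Z)-Endoxifen + 3-OH-NDM-Tam",
    "z_4oh_tam": "(Z)-4-OH-Tam + 3-OH-Tam",
    "e_endoxifen": "(E)-Endoxifen",
    "4p_oh_tam": "4'-OH-Tam",
    "4p_oh_ndm_tam": "4'-OH-NDM-Tam",
    "tam_n_oxide": "Tam-N-oxide",
    "e_4oh_tam_o_gluc": "(E)-4-OH-Tam-O-gluc",
    "ez_4oh_ndm_tam_gluc": "(E/Z)-4-OH-NDM-Tam-gluc",
    "ez_tam_n_gluc": "(E/Z)-Tam-N-gluc",
    "e_a_oh_tam": "(E)-a-OH-Tam",
    "z_a_oh_tam": "(Z)-a-OH-Tam",
}


class Status(str, enum.Enum):
    QUANTIFIED = "quantified"
    ESTIMATED_BELOW_LOLR = "estimated_below_lolr"
    NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class Measurement:
    """A single analyte measurement: concentration (ng/ml) plus status.

    ``concentration`` is ``None`` iff status is not-detected; in sums a
    not-detected analyte contributes 0.  ``extrapolated`` marks a value above
    the upper end of the calibration linearity range (a warning, not an
    error).
    """

    concentration: float | None
    status: Status
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if (self.concentration is None) != (self.status is Status.NOT_DETECTED):
            raise ValueError("concentration is absent exactly when not detected")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be non-negative")

    @property
    def value_or_zero(self) -> float:
        return 0.0 if self.concentration is None else self.concentration


@dataclass(frozen=True)
class LinearityRange:
    """Calibration linearity range [lo, hi] for one analyte, ng/ml."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError("linearity range requires 0 <= lo < hi")


@dataclass
class PatientPanel:
    """All 13 analyte measurements for one patient."""

    patient_id: str
    measurements: dict[str, Measurement]

    def __post_init__(self) -> None:
        missing = set(ANALYTES) - set(self.measurements)
        extra = set(self.measurements) - set(ANALYTES)
        if missing or extra:
            raise ValueError(
                f"panel must cover exactly the {len(ANALYTES)} analytes "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )

    def __getitem__(self, analyte: str) -> Measurement:
        return self.measurements[analyte]

    @property
    def tamoxifen(self) -> Measurement:
        return self.measurements["tamoxifen"]


def assign_status(
    concentration: float | None,
    linearity_range: LinearityRange,
    sn_ratio: float | None = None,
) -> Measurement:
    """Classify a raw concentration against the calibration linearity range.

    Inside [lo, hi] -> quantified; below lo with S/N > 10 -> estimated
    (below-LOLR); absent, or below lo with inadequate S/N -> not detected.
    Above hi -> quantified but flagged extrapolated.
    """
    if concentration is None:
        return Measurement(None, Status.NOT_DETECTED)
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if concentration < linearity_range.lo:
        if sn_ratio is not None and sn_ratio > 10:
            return Measurement(concentration, Status.ESTIMATED_BELOW_LOLR)
        return Measurement(None, Status.NOT_DETECTED)
    if concentration > linearity_range.hi:
        return Measurement(concentration, Status.QUANTIFIED, extrapolated=True)
    return Measurement(concentration, Status.QUANTIFIED)


def exclude_low_exposure(
    cohort: Sequence[PatientPanel],
    fraction_of_mean: float = 0.10,
) -> tuple[list[PatientPanel], list[str]]:
    """Drop patients whose tamoxifen level indicates non-exposure.

    The mean tamoxifen concentration is computed once over the *full* input
    cohort; patients below ``fraction_of_mean`` (default 10 %) of that mean
    are excluded.  A single pass is performed deliberately — the cutoff is a
    property of the cohort as sampled, not of its filtered remainder — and
    the input ordering of retained patients is preserved.
    """
    if not cohort:
        raise ValueError("empty cohort")
    for p in cohort:
        if p.tamoxifen.status is Status.NOT_DETECTED:
            raise ValueError(f"patient {p.patient_id} has no tamoxifen measurement")
    mean_tam = float(np.mean([p.tamoxifen.value_or_zero for p in cohort]))
    cutoff = fraction_of_mean * mean_tam
    retained = [p for p in cohort if p.tamoxifen.value_or_zero >= cutoff]
    excluded = [p.patient_id for p in cohort if p.tamoxifen.value_or_zero < cutoff]
    return retained, excluded


def summarize_cohort(
    cohort: Sequence[PatientPanel],
    include_estimated: bool = True,
) -> pd.DataFrame:
    """Per-analyte summary: mean, sample SD, median, min, max, not-detected n.

    Not-detected measurements are counted separately and excluded from the
    moments.  ``include_estimated=False`` additionally drops below-LOLR
    estimated values from the moments (they still do not count as
    not-detected).  An analyte undetected in every patient yields NaN
    moments.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rows = {}
    for analyte in ANALYTES:
        ms = [p[analyte] for p in cohort]
        n_nd = sum(m.status is Status.NOT_DETECTED for m in ms)
        keep = [
            m.concentration
            for m in ms
            if m.status is Status.QUANTIFIED
            or (include_estimated and m.status is Status.ESTIMATED_BELOW_LOLR)
        ]
        if keep:
            arr = np.asarray(keep, dtype=float)
            rows[analyte] = {
                "mean": arr.mean(),
                "sd": arr.std(ddof=1) if arr.size > 1 else math.nan,
                "median": float(np.median(arr)),
                "min": arr.min(),
                "max": arr.max(),
                "n_not_detected": n_nd,
                "n": len(ms),
            }
        else:
            rows[analyte] = {
                "mean": math.nan,
                "sd": math.nan,
                "median": math.nan,
                "min": math.nan,
                "max": math.nan,
                "n_not_detected": n_nd,
                "n": len(ms),
            }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(list(ANALYTES))
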