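"""(Z)-endoxifen metabolic ratio, efficacy threshold, and concordance groups.

The metabolic ratio (MR) is the (Z)-endoxifen plasma concentration divided by
the sum of the other 12 measured compounds (tamoxifen included; not-detected
analytes contribute 0).  It indexes how strongly a patient's tamoxifen
metabolism is directed toward (Z)-endoxifen, independently of absolute drug
exposure.

Two reference levels are kept distinct on purpose: 5.97 ng/ml is the
(Z)-endoxifen efficacy threshold used for below-threshold prevalence, while
6.0 ng/ml is the rounded level at which the MR cutoff is read off a simple
linear regression of MR on concentration.  On the study data that regression
puts the MR cutoff at ~0.0146.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .metabolites import ANALYTES, PatientPanel
from .star_allele import CATEGORY_ORDER

__all__ = [
    "ThresholdConfig",
    "MRResult",
    "QuadrantCounts",
    "MRCutoffFit",
    "compute_mr",
    "derive_mr_cutoff",
    "classify_quadrants",
    "below_threshold_by_category",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Efficacy threshold (ng/ml) and the level at which the MR cutoff is read."""

    endoxifen_threshold: float = 5.97
    cutoff_reference_level: float = 6.0

    def __post_init__(self) -> None:
        if self.endoxifen_threshold <= 0 or self.cutoff_reference_level <= 0:
            raise ValueError("threshold levels must be strictly positive")


@dataclass(frozen=True)
class MRResult:
    """Metabolic ratio with its audit numerator/denominator (ng/ml)."""

    mr: float
    numerator: float
    denominator: float

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("MR denominator must be positive")


@dataclass(frozen=True)
class QuadrantCounts:
    """Concordance of the concentration threshold with the MR cutoff.

    ``both_above``/``both_below`` are the concordant quadrants;
    ``low_conc_high_mr`` is a low (Z)-endoxifen level despite an adequate
    metabolic profile, ``high_conc_low_mr`` the converse.
    """

    both_above: int
    both_below: int
    low_conc_high_mr: int
    high_conc_low_mr: int

    @property
    def total(self) -> int:
        return (
            self.both_above + self.both_below
            + self.low_conc_high_mr + self.high_conc_low_mr
        )

    @property
    def concordant(self) -> int:
        return self.both_above + self.both_below


@dataclass(frozen=True)
class MRCutoffFit:
    """Fitted line and the cutoff read at the reference level."""

    cutoff: float
    intercept: float
    slope: float
    direction: str
    n: int


def compute_mr(panel: PatientPanel) -> MRResult:
    """MR = (Z)-endoxifen / sum of the 12 remaining analytes.

    Not-detected analytes enter the denominator as 0.  A degenerate panel
    whose denominator is 0 raises ``ValueError``.
    """
    numerator = panel["z_endoxifen"].value_or_zero
    denominator = sum(
        panel[a].value_or_zero for a in ANALYTES if a != "z_endoxifen"
    )
    if denominator <= 0:
        raise ValueError(
            f"patient {panel.patient_id}: zero MR denominator (degenerate panel)"
        )
    return MRResult(mr=numerator / denominator, numerator=numerator, denominator=denominator)


def derive_mr_cutoff(
    concentrations: Sequence[float],
    mrs: Sequence[float],
    cfg: ThresholdConfig = ThresholdConfig(),
    direction: Literal["mr_on_conc", "conc_on_mr"] = "mr_on_conc",
    intercept: bool = True,
) -> MRCutoffFit:
    """MR cutoff from a simple linear regression of the MR-concentration cloud.

    Default direction regresses MR on concentration (with intercept) and reads
    the fitted MR at ``cfg.cutoff_reference_level`` (6 ng/ml).  The reverse
    direction fits concentration on MR and inverts the line at the reference
    level; both are ordinary least squares.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(mrs, dtype=float)
    if x.size != y.size:
        raise ValueError("concentration and MR vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points for the regression")
    if direction == "conc_on_mr":
        x, y = y, x
    if np.ptp(x) == 0:
        raise ValueError("singular fit: predictor is constant")
    if intercept:
        slope, icept = np.polyfit(x, y, 1)
    else:
        slope = float(x @ y / (x @ x))
        icept = 0.0
    if direction == "mr_on_conc":
        cutoff = icept + slope * cfg.cutoff_reference_level
    else:
        if slope == 0:
            raise ValueError("singular fit: zero slope, cannot invert")
        cutoff = (cfg.cutoff_reference_level - icept) / slope
    return MRCutoffFit(
        cutoff=float(cutoff),
        intercept=float(icept),
        slope=float(slope),
        direction=direction,
        n=int(np.asarray(concentrations).size),
    )


def classify_quadrants(
    concentrations: Sequence[float],
    mrs: Sequence[float],
    cfg: ThresholdConfig,
    cutoff: float,
) -> QuadrantCounts:
    """Assign each patient to one concordance quadrant.

    "Below" is strict (< reference level / < cutoff), mirroring the
    low-concentration wording; boundary values count as above.  The four
    counts partition the cohort.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    conc = np.asarray(concentrations, dtype=float)
    mr = np.asarray(mrs, dtype=float)
    if conc.size != mr.size:
        raise ValueError("concentration and MR vectors differ in length")
    low_c = conc < cfg.cutoff_reference_level
    low_m = mr < cutoff
    return QuadrantCounts(
        both_above=int(np.sum(~low_c & ~low_m)),
        both_below=int(np.sum(low_c & low_m)),
        low_conc_high_mr=int(np.sum(low_c & ~low_m)),
        high_conc_low_mr=int(np.sum(~low_c & low_m)),
    )


def below_threshold_by_category(
    categories: Sequence[str],
    concentrations: Sequence[float],
    cfg: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Fraction of patients below the efficacy threshold, per category.

    Uses the 5.97 ng/ml efficacy threshold (strict <).  Returns one row per
    category present, ordered by metabolizer rank, plus an ``overall`` row.
    """
    cats = pd.Series(categories, dtype="object")
    conc = np.asarray(concentrations, dtype=float)
    if len(cats) != conc.size:
        raise ValueError("categories and concentrations differ in length")
    below = conc < cfg.endoxifen_threshold
    rows = []
    for cat in CATEGORY_ORDER:
        mask = (cats == cat).to_numpy()
        if mask.sum() == 0:
            continue
        rows.append(
            {
                "category": cat,
                "n": int(mask.sum()),
                "n_below": int(below[mask].sum()),
                "fraction_below": float(below[mask].mean()),
            }
        )
    rows.append(
        {
            "category": "overall",
            "n": int(conc.size),
            "n_below": int(below.sum()),
            "fraction_below": float(below.mean()),
        }
    )
    return pd.DataFrame(rows)
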