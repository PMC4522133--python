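"""Association statistics: HWE chi-square, indicator-variable OLS contrasts,
Spearman correlation with AS 89 p-values, and contingency chi-square.

The genotype-concentration battery fits, for each outcome (10 metabolite
concentrations + 2 metabolic ratios), an ordinary-least-squares model with
the six non-reference metabolizer categories as indicator variables and
EM/EM as the reference.  Each coefficient is then exactly that group's mean
minus the EM/EM mean; Student-t tests on the coefficients are corrected for
multiplicity with a single Bonferroni threshold 0.05/(12 outcomes x 6
groups) = 6.9e-4.  Spearman rank correlation (midranks for ties) against an
ordinal genotype encoding summarises each outcome's variance explained (r2).

Spearman p-values use the AS 89 algorithm (Best & Roberts 1975): the exact
permutation distribution of S = sum of squared rank differences for small
samples without ties, and the published Edgeworth expansion otherwise.  The
Edgeworth series is evaluated on the smaller tail (via the S -> max-S
reflection), where it is accurate; in the extreme tail, where the series
breaks down numerically (it can go negative), the Student-t approximation
is used as a guard.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .star_allele import CATEGORY_ORDER

__all__ = [
    "BonferroniPlan",
    "HWEResult",
    "OLSContrastResult",
    "SpearmanResult",
    "ContingencyResult",
    "AssociationSuite",
    "hwe_chisq",
    "indicator_ols",
    "spearman_as89",
    "contingency_chisq",
    "run_association_suite",
    "encode_categories",
]

#: Largest n at which the exact permutation distribution of S is enumerated.
EXACT_N_CUTOFF = 9


@dataclass(frozen=True)
class BonferroniPlan:
    """Family-wise error control over outcomes x group contrasts."""

    alpha: float = 0.05
    n_outcomes: int = 12
    n_groups: int = 6

    @property
    def threshold(self) -> float:
        return self.alpha / (self.n_outcomes * self.n_groups)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_outcomes": self.n_outcomes,
            "n_groups": self.n_groups,
            "threshold": self.threshold,
        }


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    p_value: float
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    allele_freq: float


def hwe_chisq(counts: Sequence[int]) -> HWEResult:
    """One-degree-of-freedom Hardy-Weinberg chi-square from genotype counts.

    ``counts`` is (hom_ref, het, hom_alt).  Expected counts come from the
    observed allele frequencies (p^2, 2pq, q^2); no continuity correction.
    A monomorphic variant is in equilibrium by convention (chi2 = 0, p = 1).
    """
    obs = tuple(int(c) for c in counts)
    if len(obs) != 3 or any(c < 0 for c in obs):
        raise ValueError("counts must be three non-negative integers")
    n = sum(obs)
    if n == 0:
        raise ValueError("empty genotype table")
    p = (2 * obs[0] + obs[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        exp = (n * p * p, 2 * n * p * q, n * q * q)
        return HWEResult(0.0, 1, 1.0, obs, exp, p)
    exp = (n * p * p, 2 * n * p * q, n * q * q)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    return HWEResult(float(chi2), 1, float(sps.chi2.sf(chi2, 1)), obs, exp, p)


@dataclass
class OLSContrastResult:
    """Indicator-variable OLS of one outcome on metabolizer category.

    ``contrasts`` has one row per non-reference group: coefficient (that
    group's mean minus the reference mean), standard error, t, two-sided p,
    and a Bonferroni significance flag.
    """

    outcome_id: str
    reference: str
    reference_mean: float
    contrasts: pd.DataFrame
    residual_df: int
    plan: BonferroniPlan


def indicator_ols(
    values: Sequence[float],
    categories: Sequence[str],
    reference: str = "EM/EM",
    plan: BonferroniPlan = BonferroniPlan(),
    outcome_id: str = "outcome",
) -> OLSContrastResult:
    """Fit outcome ~ category indicators with the given reference group.

    The intercept estimates the reference-group mean and each indicator
    coefficient the difference of that group's mean from the reference.
    Two-sided Student-t p-values; significance at ``plan.threshold``.
    """
    y = np.asarray(values, dtype=float)
    cats = pd.Series(categories, dtype="object")
    if y.size != len(cats):
        raise ValueError("values and categories differ in length")
    groups = [c for c in CATEGORY_ORDER if c in set(cats)]
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} is empty or absent")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    others = [g for g in groups if g != reference]
    X = np.column_stack(
        [np.ones_like(y)] + [(cats == g).to_numpy(dtype=float) for g in others]
    )
    fit = sm.OLS(y, X).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    if (
        fit.df_resid <= 0
        or not np.isfinite(fit.bse[0])
        or fit.ssr < 1e-10 * max(tss, 1.0)
    ):
        raise ValueError("zero residual variance: outcome constant within groups")
    rows = []
    for i, g in enumerate(others, start=1):
        p = float(fit.pvalues[i])
        rows.append(
            {
                "group": g,
                "n": int((cats == g).sum()),
                "coefficient": float(fit.params[i]),
                "standard_error": float(fit.bse[i]),
                "t_statistic": float(fit.tvalues[i]),
                "p_value": p,
                "significant": bool(p < plan.threshold),
            }
        )
    return OLSContrastResult(
        outcome_id=outcome_id,
        reference=reference,
        reference_mean=float(fit.params[0]),
        contrasts=pd.DataFrame(rows),
        residual_df=int(fit.df_resid),
        plan=plan,
    )


class SpearmanMethod(str, enum.Enum):
    EXACT = "exact"
    AS89_APPROX = "as89_approx"


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    r_squared: float
    p_value: float
    n: int
    method: SpearmanMethod


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


# Edgeworth coefficients of the published AS 89 approximation.
_AS89_C = (
    0.2274, 0.2531, 0.1745, 0.0758, 0.1033, 0.3932,
    0.0879, 0.0151, 0.0072, 0.0831, 0.0267, 0.04567,
)


def _as89_upper(s: float, n: int) -> float:
    """Edgeworth approximation to P(S >= s) for Spearman's S, n > 9."""
    c1, c2, c3, c4, c5, c6, c7, c8, c9, c10, c11, c12 = _AS89_C
    b = 1.0 / n
    x = (6.0 * (s - 1.0) * b / (n * n - 1.0) - 1.0) * math.sqrt(1.0 / b - 1.0)
    y = x * x
    u = x * b * (
        c1 + b * (c2 + c3 * b)
        + y * (-c4 + b * (c5 + c6 * b)
               - y * b * (c7 + c8 * b
                          - y * (c9 - c10 * b
                                 + y * b * (c11 - c12 * y))))
    )
    return u / math.exp(y / 2.0) + float(sps.norm.sf(x))


def _t_approx_two_sided(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def _exact_two_sided(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided p by full enumeration of the n! rank permutations."""
    n = rx.size
    q = float(np.sum((rx - ry) ** 2))
    total = lo = hi = 0
    for perm in permutations(range(n)):
        s = float(np.sum((rx - ry[list(perm)]) ** 2))
        lo += s <= q + 1e-9
        hi += s >= q - 1e-9
        total += 1
    return min(1.0, 2.0 * min(lo / total, hi / total))


def spearman_as89(
    x: Sequence[float],
    y: Sequence[float],
    exact_cutoff: int = EXACT_N_CUTOFF,
) -> SpearmanResult:
    """Spearman rank correlation with an AS 89 two-sided p-value.

    r is computed from midranks (tie-aware).  For n <= ``exact_cutoff`` with
    no ties the exact permutation distribution of S is enumerated; otherwise
    the Edgeworth approximation is applied to the equivalent statistic
    S = (1 - r) n (n^2 - 1) / 6, doubling the smaller tail.  With ties this
    S is the tie-adjusted pseudo-statistic implied by the midrank r.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("input vectors differ in length")
    n = int(xa.size)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input vector: Spearman r undefined")
    rx, ry = _midranks(xa), _midranks(ya)
    r = float(np.corrcoef(rx, ry)[0, 1])

    has_ties = (np.unique(rx).size < n) or (np.unique(ry).size < n)
    if n <= exact_cutoff and not has_ties:
        p = _exact_two_sided(rx, ry)
        method = SpearmanMethod.EXACT
    else:
        s = (1.0 - r) * n * (n * n - 1) / 6.0
        mean_s = n * (n * n - 1) / 6.0
        max_s = n * (n * n - 1) / 3.0
        tail = _as89_upper(s, n) if s > mean_s else _as89_upper(max_s - s, n)
        p = 2.0 * tail
        # The published series loses validity deep in the tail (can go
        # negative or above the normal bound); fall back to the t form there.
        if not (0.0 < p <= 1.0) or p < 1e-12:
            p = _t_approx_two_sided(r, n)
        p = min(1.0, max(p, 0.0))
        method = SpearmanMethod.AS89_APPROX
    return SpearmanResult(
        r=r, r_squared=r * r, p_value=float(p), n=n, method=method
    )


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_warning: bool


def contingency_chisq(table: Sequence[Sequence[float]]) -> ContingencyResult:
    """Pearson chi-square for a 2 x k table, no continuity correction.

    Any expected cell below 1 sets a warning flag in the result rather than
    raising.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise ValueError("all row and column sums must be positive")
    chi2, p, df, exp = sps.chi2_contingency(t, correction=False)
    return ContingencyResult(
        chi2=float(chi2),
        df=int(df),
        p_value=float(p),
        expected=exp,
        low_expected_warning=bool((exp < 1).any()),
    )


def encode_categories(
    categories: Sequence[str],
    encoding: str = "category_rank",
) -> np.ndarray:
    """Ordinal genotype encoding for rank correlation.

    ``category_rank``: the fixed seven-category order PM/PM(0) .. EM/UM(6).
    ``functional_allele_count``: number of fully functional alleles implied
    by the category (UM counted as 3): PM/PM 0; IM/PM, IM/IM 0.5/1 scale —
    concretely PM=0, IM=0.5, EM=1 per allele, +1 for the duplication.
    """
    rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    if encoding == "category_rank":
        return np.asarray([rank[c] for c in categories], dtype=float)
    if encoding == "functional_allele_count":
        per_allele = {"PM": 0.0, "IM": 0.5, "EM": 1.0}
        out = []
        for c in categories:
            if c == "EM/UM":
                out.append(3.0)
            else:
                a, b = c.split("/")
                out.append(per_allele[a] + per_allele[b])
        return np.asarray(out, dtype=float)
    raise ValueError(f"unknown encoding: {encoding!r}")


@dataclass
class AssociationSuite:
    """Per-outcome OLS contrasts and Spearman results, plus the plan."""

    ols: dict[str, OLSContrastResult]
    spearman: dict[str, SpearmanResult]
    skipped_outcomes: list[str]
    plan: BonferroniPlan
    encoding: str

    def any_significant(self) -> bool:
        return any(
            bool(res.contrasts["significant"].any()) for res in self.ols.values()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for oid, res in self.ols.items():
            sp = self.spearman[oid]
            for _, c in res.contrasts.iterrows():
                rows.append(
                    {
                        "outcome": oid,
                        "group": c["group"],
                        "n": c["n"],
                        "coefficient": c["coefficient"],
                        "standard_error": c["standard_error"],
                        "t_statistic": c["t_statistic"],
                        "p_value": c["p_value"],
                        "significant": c["significant"],
                        "reference_mean": res.reference_mean,
                        "spearman_r": sp.r,
                        "spearman_r2": sp.r_squared,
                        "spearman_p": sp.p_value,
                    }
                )
        return pd.DataFrame(rows)


def run_association_suite(
    outcomes: pd.DataFrame,
    categories: Sequence[str],
    plan: BonferroniPlan = BonferroniPlan(),
    reference: str = "EM/EM",
    encoding: str = "category_rank",
) -> AssociationSuite:
    """Run the OLS + Spearman battery over all outcome columns.

    ``outcomes`` holds one column per outcome (concentrations and MRs) in
    patient order aligned with ``categories``.  A column that is missing
    entirely (all NaN) or constant is recorded under ``skipped_outcomes``
    rather than failing the batch.  The Bonferroni plan is applied globally.
    """
    cats = list(categories)
    if len(cats) != len(outcomes):
        raise ValueError("categories and outcome rows differ in length")
    genotype_score = encode_categories(cats, encoding)
    ols: dict[str, OLSContrastResult] = {}
    spearman: dict[str, SpearmanResult] = {}
    skipped: list[str] = []
    for col in outcomes.columns:
        y = outcomes[col].to_numpy(dtype=float)
        if np.isnan(y).all() or np.ptp(y[~np.isnan(y)]) == 0:
            skipped.append(col)
            continue
        if np.isnan(y).any():
            skipped.append(col)
            continue
        ols[col] = indicator_ols(y, cats, reference=reference, plan=plan, outcome_id=col)
        spearman[col] = spearman_as89(genotype_score, y)
    return AssociationSuite(
        ols=ols, spearman=spearman, skipped_outcomes=skipped, plan=plan,
        encoding=encoding,
    )
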