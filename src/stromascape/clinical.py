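"""Clinical statistics: composite IHC scores, contingency tests,
Kaplan-Meier / log-rank survival comparison, Cox proportional hazards,
and the wet-lab assay formulas.

The composite immunohistochemistry score multiplies a staining-area bin
(0-4) by an intensity grade (0-3), giving 0-12, categorized as negative
(0-2), low (3-5) or high (>= 6).  Contingency tables use Pearson's
chi-square without continuity correction; survival comparisons use the
product-limit estimator with the log-rank test, and multivariable
prognosis uses the Cox proportional hazards model (both via lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

__all__ = [
    "IHCScore",
    "ihc_composite_score",
    "pearson_chi_square",
    "km_logrank",
    "KmLogrankResult",
    "cox_ph",
    "assay_metrics",
]

# half-open area bins: [0,5], (5,25], (25,50], (50,75], (75,100]
_AREA_EDGES = (5.0, 25.0, 50.0, 75.0)


@dataclass(frozen=True)
class IHCScore:
    area_percent: float
    intensity_grade: int
    area_score: int
    composite: int
    category: str


def ihc_composite_score(area_percent: float, intensity_grade: int) -> IHCScore:
    """Composite IHC score: area bin (0-4) x intensity grade (0-3).

    Category: composite >= 6 -> "high", 3-5 -> "low", <= 2 -> "negative"
    (the dichotomized analyses treat high as score >= 6).
    """
    if not 0 <= area_percent <= 100:
        raise ValueError("area_percent must be in [0, 100]")
    if intensity_grade not in (0, 1, 2, 3):
        raise ValueError("intensity_grade must be an integer 0-3")
    area_score = int(np.searchsorted(_AREA_EDGES, area_percent, side="left"))
    composite = area_score * intensity_grade
    if composite >= 6:
        category = "high"
    elif composite >= 3:
        category = "low"
    else:
        category = "negative"
    return IHCScore(
        area_percent=float(area_percent),
        intensity_grade=int(intensity_grade),
        area_score=area_score,
        composite=composite,
        category=category,
    )


def pearson_chi_square(
    table: pd.DataFrame | np.ndarray, yates_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c table; returns (stat, dof, p).

    No continuity correction by default.  Zero row/column margins raise.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(arr, correction=yates_correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class KmLogrankResult:
    curves: dict[str, pd.DataFrame]  # per group: time, survival, at_risk
    statistic: float
    p_value: float


def km_logrank(records: pd.DataFrame, groups: pd.Series) -> KmLogrankResult:
    """Product-limit curves per group plus the log-rank test.

    ``records`` needs ``time`` and ``event`` columns aligned with
    ``groups``.  Two groups use the standard two-sample log-rank
    statistic (chi-square, 1 df); more use its multivariate extension.
    """
    groups = pd.Series(groups).astype(str)
    if len(groups) != len(records):
        raise ValueError("groups must align with records")
    if records["event"].sum() < 1:
        raise ValueError("need >= 1 event")
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 non-empty groups")

    curves = {}
    for lab in labels:
        mask = (groups == lab).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(records["time"][mask], records["event"][mask], label=lab)
        ev = kmf.event_table
        curves[lab] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_[lab].to_numpy(),
                "at_risk": ev["at_risk"].reindex(
                    kmf.survival_function_.index
                ).to_numpy(),
            }
        )

    if len(labels) == 2:
        m0 = (groups == labels[0]).to_numpy()
        res = logrank_test(
            records["time"][m0],
            records["time"][~m0],
            records["event"][m0],
            records["event"][~m0],
        )
    else:
        res = multivariate_logrank_test(records["time"], groups, records["event"])
    return KmLogrankResult(
        curves=curves, statistic=float(res.test_statistic), p_value=float(res.p_value)
    )


def cox_ph(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Cox proportional hazards fit; per-covariate HR, 95% CI and Wald p.

    ``records`` needs ``time``, ``event`` and the covariate columns.
    Constant covariates are rejected as non-identifiable; convergence
    failures surface with the solver's diagnostics.
    """
    if records["event"].sum() < 1:
        raise ValueError("need >= 1 event")
    for c in covariates:
        if records[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant: non-identifiable")
    cph = CoxPHFitter()
    df = records[["time", "event", *covariates]].copy()
    df["event"] = df["event"].astype(int)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit did not converge: {err}") from err
    out = pd.DataFrame(
        {
            "HR": np.exp(cph.params_),
            "ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0]),
            "ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1]),
            "p_value": cph.summary["p"],
        }
    )
    out.index.name = "covariate"
    return out


def assay_metrics(kind: str, **inputs: float) -> float:
    """Wet-lab assay formulas.

    - ``volume``: 0.5 x length x width^2 (mm^3)
    - ``wound``: (1 - current_area / initial_area) x 100 (%)
    - ``colony``: colonies / seeded_cells x 100 (%)
    """
    if kind == "volume":
        length, width = inputs["length"], inputs["width"]
        if length <= 0 or width <= 0:
            raise ValueError("length and width must be positive")
        return 0.5 * length * width**2
    if kind == "wound":
        initial, current = inputs["initial_area"], inputs["current_area"]
        if initial <= 0:
            raise ValueError("initial area must be positive")
        healing = (1.0 - current / initial) * 100.0
        if healing < 0:
            warnings.warn("current wound area exceeds initial; negative healing")
        return healing
    if kind == "colony":
        colonies, seeded = inputs["colonies"], inputs["seeded_cells"]
        if seeded <= 0:
            raise ValueError("seeded cell count must be positive")
        return colonies / seeded * 100.0
    raise ValueError(f"unknown assay kind {kind!r}")
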