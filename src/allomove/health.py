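"""Composite stress index scoring from individual health assessments.

The index follows the allostatic-load convention: nine markers of health,
condition and endocrine stress are each scored on a small fixed weight
scale, and the per-individual total is rescaled by the number of markers
that could actually be measured for that individual, yielding an index in
[0, 2] (in practice close to [0, 1]) that is comparable across individuals
with different amounts of missing data.

The nine dimensions and their weights:

==============================  =======================================
(i)    healed scars             yes = 0.5, no = 0
(ii)   fresh wounds             yes = 2,   no = 0  (unrelated to capture)
(iii)  ectoparasites            yes = 1,   no = 0
(iv)   predators sighted        yes = 1; the dimension only exists when
                                predators were present at capture
(v)    accompanying calf        yes = 1, no = 0; females only
(vi)   body condition           1 if the half-girth regression residual
                                is negative (below-average condition)
(vii)  cortisol                 1 if above the cohort upper quartile
(viii) DHEA-S                   1 if below the cohort lower quartile
(ix)   cortisol:DHEA ratio      1 if above the cohort upper quartile
==============================  =======================================

Body condition is the residual of half axillary girth regressed on
standard length plus optional age-class and sex terms, with the predictor
subset chosen by AIC.  Hormone cut-points are cohort quartiles (cortisol
and the cortisol:DHEA ratio upper quartiles mark acute stress; the DHEA-S
lower quartile marks chronic stress), with paired start/end-of-handling
samples averaged before thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from allomove.datasets import SCORE_COLUMNS

__all__ = [
    "HealthRecord",
    "HormoneThresholds",
    "BodyConditionModel",
    "StressScoreBreakdown",
    "classify_age",
    "fit_body_condition",
    "hormone_thresholds",
    "score_components",
    "composite_stress_index",
    "complete_case_index",
    "round_half_away",
    "score_table",
]

#: Weight applied when a binary dimension is positive.
DIMENSION_WEIGHTS = {
    "healed_scars": 0.5,
    "fresh_wounds": 2.0,
    "ectoparasites": 1.0,
    "predators": 1.0,
    "calf": 1.0,
    "bci": 1.0,
    "cortisol": 1.0,
    "dhea_s": 1.0,
    "cort_dhea_ratio": 1.0,
}

ADULT_LENGTH_CM = 300.0


@dataclass
class HealthRecord:
    """One individual's raw health assessment, with explicit missingness.

    ``None`` marks a field that could not be collected.  Hormones accept
    either a single draw or a (start, end) pair taken at the beginning and
    end of handling; pairs are averaged before any thresholding.
    """

    id: str
    sex: str  # "M" or "F"
    standard_length: float  # cm
    axillary_girth: float | None = None  # cm
    healed_scars: bool | None = None
    fresh_wounds: bool | None = None
    ectoparasites: bool | None = None
    predators_sighted: bool | None = None
    calf_present: bool | None = None
    cortisol: float | tuple[float, float] | None = None  # ng/ml
    dhea: float | tuple[float, float] | None = None  # ng/ml
    dhea_s: float | tuple[float, float] | None = None  # ng/ml

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.standard_length > 0:
            raise ValueError("standard_length must be positive")
        for name in ("cortisol", "dhea", "dhea_s"):
            v = self.mean_hormone(name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def mean_hormone(self, name: str) -> float | None:
        """Mean of the one or two draws of a hormone, or None if unmeasured."""
        v = getattr(self, name)
        if v is None:
            return None
        if isinstance(v, (tuple, list)):
            vals = [x for x in v if x is not None]
            if not vals:
                return None
            return float(np.mean(vals))
        return float(v)


@dataclass(frozen=True)
class HormoneThresholds:
    """Cohort quartile cut-points used to flag endocrine stress."""

    cortisol_upper: float  # ng/ml; above = acute stress
    dhea_s_lower: float  # ng/ml; below = chronic stress
    cort_dhea_ratio_upper: float  # dimensionless; above = chronic stress

    def __post_init__(self) -> None:
        if min(self.cortisol_upper, self.dhea_s_lower, self.cort_dhea_ratio_upper) <= 0:
            raise ValueError("hormone thresholds must be positive")


@dataclass
class BodyConditionModel:
    """Best AIC regression of half axillary girth on length (+ age class, sex).

    ``residuals`` (cm, on the half-girth scale) are indexed by individual;
    a negative residual means below-average body condition.
    """

    selected_predictors: tuple[str, ...]
    coefficients: pd.Series
    residuals: pd.Series
    aic: float

    def residual_for(self, ind: str) -> float | None:
        if ind in self.residuals.index:
            return float(self.residuals.loc[ind])
        return None


@dataclass
class StressScoreBreakdown:
    """The nine per-dimension scores plus the derived totals for one animal.

    ``scores`` maps dimension name to its weighted score; dimensions that
    could not be assessed are absent from the map entirely (they do not
    enter the total or the denominator).
    """

    scores: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_scores(cls, scores: dict[str, float]) -> "StressScoreBreakdown":
        unknown = set(scores) - set(SCORE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown dimensions: {sorted(unknown)}")
        return cls(scores=dict(scores))

    @property
    def total_score(self) -> float:
        return float(sum(self.scores.values()))

    @property
    def n_dimensions(self) -> int:
        return len(self.scores)

    @property
    def csi(self) -> float:
        """Unrounded composite stress index (total over available dims)."""
        if self.n_dimensions == 0:
            raise ValueError(
                "no dimension of the stress index could be assessed; "
                "exclude this individual from the analysis"
            )
        return self.total_score / self.n_dimensions


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (so 0.125 -> 0.13 at 2 dp).

    Banker's rounding (the float default) would send 0.125 to 0.12, which
    does not match the published index values.
    """
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def classify_age(standard_length: float) -> str:
    """Age class from standard length: adult above 300 cm, else juvenile.

    An individual at exactly the boundary is classed juvenile.
    """
    if not standard_length > 0:
        raise ValueError("standard_length must be positive")
    return "adult" if standard_length > ADULT_LENGTH_CM else "juvenile"


def fit_body_condition(records: pd.DataFrame) -> BodyConditionModel:
    """Fit the body-condition regression and return per-individual residuals.

    ``records`` needs columns ``standard_length``, ``axillary_girth`` and
    ``sex`` (index = individual id).  The response is half axillary girth;
    every predictor subset containing standard length (optionally plus age
    class and sex, main effects only) is fit by OLS and the lowest-AIC
    model selected.  Rows with missing girth get no residual.
    """
    obs = records.dropna(subset=["axillary_girth"])
    if len(obs) < 2:
        raise ValueError("need at least 2 records with observed girth")
    y = obs["axillary_girth"].astype(float) / 2.0
    length = obs["standard_length"].astype(float)
    adult = length.map(lambda v: 1.0 if classify_age(v) == "adult" else 0.0)
    female = (obs["sex"] == "F").astype(float)
    candidates = {"length": length, "age_class": adult, "sex": female}

    best = None
    for subset in (
        ("length",),
        ("length", "age_class"),
        ("length", "sex"),
        ("length", "age_class", "sex"),
    ):
        X = sm.add_constant(pd.DataFrame({k: candidates[k] for k in subset}), has_constant="add")
        # degenerate cohorts (single sex, one age class) make the larger
        # subsets unidentifiable; the base length-only model always fits
        if subset != ("length",) and np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            continue
        fit = sm.OLS(y, X).fit()
        if best is None or fit.aic < best[1].aic:
            best = (subset, fit)
    subset, fit = best
    return BodyConditionModel(
        selected_predictors=subset,
        coefficients=fit.params,
        residuals=fit.resid,
        aic=float(fit.aic),
    )


def _quantile(values: np.ndarray, q: float, method: str) -> float:
    return float(np.quantile(np.asarray(values, dtype=float), q, method=method))


def hormone_thresholds(
    records: list[HealthRecord] | pd.DataFrame,
    method: str = "linear",
) -> HormoneThresholds:
    """Cohort quartile cut-points from the measured hormone values.

    Paired start/end draws are averaged per individual first.  ``method``
    is the quantile estimator passed to :func:`numpy.quantile` ("linear"
    interpolates between order statistics).  Requires at least 4 observed
    values per quantity; with fewer, supply fixed thresholds instead.
    """
    if isinstance(records, pd.DataFrame):
        cort = records["cortisol"].dropna().to_numpy(dtype=float)
        dhea = records["dhea"].dropna().to_numpy(dtype=float)
        dhea_s = records["dhea_s"].dropna().to_numpy(dtype=float)
        paired = records[["cortisol", "dhea"]].dropna()
        ratio = (paired["cortisol"] / paired["dhea"]).to_numpy(dtype=float)
    else:
        cort = np.array([r.mean_hormone("cortisol") for r in records], dtype=float)
        dhea = np.array([r.mean_hormone("dhea") for r in records], dtype=float)
        dhea_s = np.array([r.mean_hormone("dhea_s") for r in records], dtype=float)
        ratio = cort / dhea
        ratio = ratio[np.isfinite(ratio)]
        cort = cort[np.isfinite(cort)]
        dhea_s = dhea_s[np.isfinite(dhea_s)]
    for name, vals in (("cortisol", cort), ("dhea_s", dhea_s), ("cortisol:dhea", ratio)):
        if len(vals) < 4:
            raise ValueError(
                f"fewer than 4 observed {name} values; supply fixed thresholds"
            )
    return HormoneThresholds(
        cortisol_upper=_quantile(cort, 0.75, method),
        dhea_s_lower=_quantile(dhea_s, 0.25, method),
        cort_dhea_ratio_upper=_quantile(ratio, 0.75, method),
    )


def score_components(
    record: HealthRecord,
    thresholds: HormoneThresholds,
    bci_residual: float | None = None,
) -> StressScoreBreakdown:
    """Score the nine stress dimensions for one individual.

    Any dimension whose underlying datum is missing is left out of the
    breakdown (missingness is modelled via the rescaled denominator, never
    raised as an error).  The predator dimension exists only when predators
    were actually sighted at capture; the calf dimension only for females.
    """
    scores: dict[str, float] = {}

    def flag(dim: str, value: bool | None) -> None:
        if value is not None:
            scores[dim] = DIMENSION_WEIGHTS[dim] if value else 0.0

    flag("healed_scars", record.healed_scars)
    flag("fresh_wounds", record.fresh_wounds)
    flag("ectoparasites", record.ectoparasites)
    # Predators: dimension only included when present (score 1), never 0.
    if record.predators_sighted:
        scores["predators"] = DIMENSION_WEIGHTS["predators"]
    if record.sex == "F":
        flag("calf", record.calf_present)
    if bci_residual is not None:
        scores["bci"] = DIMENSION_WEIGHTS["bci"] if bci_residual < 0 else 0.0
    cort = record.mean_hormone("cortisol")
    dhea = record.mean_hormone("dhea")
    dhea_s = record.mean_hormone("dhea_s")
    if cort is not None:
        scores["cortisol"] = (
            DIMENSION_WEIGHTS["cortisol"] if cort > thresholds.cortisol_upper else 0.0
        )
    if dhea_s is not None:
        scores["dhea_s"] = (
            DIMENSION_WEIGHTS["dhea_s"] if dhea_s < thresholds.dhea_s_lower else 0.0
        )
    if cort is not None and dhea is not None and dhea > 0:
        scores["cort_dhea_ratio"] = (
            DIMENSION_WEIGHTS["cort_dhea_ratio"]
            if cort / dhea > thresholds.cort_dhea_ratio_upper
            else 0.0
        )
    return StressScoreBreakdown(scores=scores)


def composite_stress_index(breakdown: StressScoreBreakdown, decimals: int = 2) -> float:
    """Composite stress index: total score over available dimensions.

    Returned rounded to ``decimals`` places, ties away from zero, matching
    the convention of the published per-individual values.
    """
    return round_half_away(breakdown.csi, decimals)


def complete_case_index(
    scores: pd.DataFrame, fields: tuple[str, ...] | list[str]
) -> pd.Series:
    """Alternative index over a fixed dimension subset measured for everyone.

    ``scores`` is a per-parameter score table (as from
    :func:`allomove.datasets.narwhal_cohort`).  Every chosen field must be
    observed for every individual; offenders are listed in the error.
    """
    fields = tuple(fields)
    unknown = set(fields) - set(SCORE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown dimensions: {sorted(unknown)}")
    sub = scores[list(fields)]
    missing = sub[sub.isna().any(axis=1)].index.tolist()
    if missing:
        raise ValueError(f"missing values in chosen fields for: {missing}")
    out = sub.sum(axis=1) / len(fields)
    return out.map(lambda v: round_half_away(v)).rename("csi_complete_case")


def score_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Totals, dimension counts and CSI for a per-parameter score table.

    Mirrors the published summary table layout: the nine score columns
    followed by Total Score, # Dims and CSI (2 dp, ties away from zero).
    """
    rows = {}
    for ind, row in scores.iterrows():
        avail = {c: row[c] for c in SCORE_COLUMNS if c in row and np.isfinite(row[c])}
        bd = StressScoreBreakdown.from_scores(avail)
        rows[ind] = {
            **{c: row.get(c, np.nan) for c in SCORE_COLUMNS},
            "total_score": bd.total_score,
            "n_dims": bd.n_dimensions,
            "csi": composite_stress_index(bd),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
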