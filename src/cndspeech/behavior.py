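"""Synthetic listener cohort and behavioral statistics.

The generator emulates a cross-sectional adult cohort (ages 18-80) with
age-progressive standard (0.25-8 kHz) and extended-high-frequency
(9-16 kHz) pure-tone averages and a word-recognition score for
time-compressed, reverberant words (WRS_65%). Its default effect sizes
were derived in closed form from a variance budget so that the
population age-score correlation is about -0.62 and the adjusted R^2 of
the regression WRS_65% ~ Age + PTA_St + PTA_EHF is about 0.41 — the
calibration targets for this cohort; the defaults are population
parameters, not data.

Word scores are clipped to [0, 100]%; with the default effect sizes the
clip binds for well under 2% of simulated listeners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CohortParams:
    """Generating model:
    pta = intercept + slope * (age - 18) + N(0, sd)  for each PTA, and
    wrs65 = beta0 + beta_age*age + beta_st*pta_st + beta_ehf*pta_ehf + eps.
    """

    beta0: float = 71.0  # intercept on the raw (uncentered) scale
    beta_age: float = -0.383  # %/year
    beta_st: float = -0.10  # %/dB HL
    beta_ehf: float = -0.216  # %/dB HL
    noise_sd: float = 12.9  # residual SD, percent points
    pta_st_intercept: float = 0.0  # dB HL at age 18
    pta_st_slope: float = 0.25  # dB/year
    pta_st_sd: float = 7.0
    pta_ehf_intercept: float = 5.0
    pta_ehf_slope: float = 0.80
    pta_ehf_sd: float = 12.0
    age_range: tuple = (18.0, 80.0)
    clip: bool = True

    def __post_init__(self):
        for sd in (self.noise_sd, self.pta_st_sd, self.pta_ehf_sd):
            if sd < 0:
                raise ValueError("noise SDs must be non-negative")


def synth_cohort(n: int, params: CohortParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Simulate a cohort of ``n`` listeners (age, pta_st, pta_ehf, wrs65)."""
    if n < 10:
        raise ValueError("cohort size must be at least 10")
    if params is None:
        params = CohortParams()
    rng = np.random.default_rng(seed)
    lo, hi = params.age_range
    age = rng.uniform(lo, hi, n)
    rel = age - 18.0
    pta_st = params.pta_st_intercept + params.pta_st_slope * rel + rng.normal(0, params.pta_st_sd, n)
    pta_ehf = params.pta_ehf_intercept + params.pta_ehf_slope * rel + rng.normal(0, params.pta_ehf_sd, n)
    wrs = (params.beta0 + params.beta_age * age + params.beta_st * pta_st
           + params.beta_ehf * pta_ehf + rng.normal(0, params.noise_sd, n))
    if params.clip:
        wrs = np.clip(wrs, 0.0, 100.0)
    return pd.DataFrame({"age": age, "pta_st": pta_st, "pta_ehf": pta_ehf, "wrs65": wrs})


def correlate_age_wrs(records: pd.DataFrame):
    """Pearson correlation between age and WRS_65% with two-sided p."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    age = records["age"].to_numpy()
    wrs = records["wrs65"].to_numpy()
    if np.ptp(age) == 0 or np.ptp(wrs) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(age, wrs)
    return float(r), float(p)


@dataclass(frozen=True)
class RegressionResult:
    params: pd.Series  # intercept + raw coefficients
    std_betas: pd.Series  # standardized coefficients
    adj_r2: float
    pvalues: pd.Series
    n: int


def fit_wrs_regression(records: pd.DataFrame,
                       predictors=("age", "pta_st", "pta_ehf")) -> RegressionResult:
    """OLS of WRS_65% on age and the two pure-tone averages, with
    standardized betas and adjusted R^2."""
    import statsmodels.api as sm

    if len(records) <= 10:
        raise ValueError("need more than 10 records")
    X = records.loc[:, list(predictors)].to_numpy()
    y = records["wrs65"].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise ValueError("predictors are collinear (rank-deficient design)")
    model = sm.OLS(y, sm.add_constant(pd.DataFrame(X, columns=predictors))).fit()
    sd_y = y.std(ddof=1)
    std_betas = pd.Series(
        {p: model.params[p] * records[p].std(ddof=1) / sd_y for p in predictors}
    )
    return RegressionResult(
        params=model.params, std_betas=std_betas, adj_r2=float(model.rsquared_adj),
        pvalues=model.pvalues, n=len(records),
    )


@dataclass(frozen=True)
class SurvivalMap:
    """Piecewise-linear mapping from age (years) to percent auditory-nerve
    survival; must be non-increasing with values in (0, 100]."""

    ages: np.ndarray
    survival_percent: np.ndarray
    source: str = "declared default"

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        surv = np.asarray(self.survival_percent, dtype=float)
        if ages.ndim != 1 or ages.shape != surv.shape or len(ages) < 2:
            raise ValueError("map needs matching 1-D age/survival arrays (>= 2 points)")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(np.diff(surv) > 0):
            raise ValueError("survival must be non-increasing with age")
        if np.any(surv <= 0) or np.any(surv > 100):
            raise ValueError("survival must lie in (0, 100]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "survival_percent", surv)


def default_survival_map() -> SurvivalMap:
    """Linear decline from 100% at birth to 25% at age 90 — a declared
    approximation to published human age-survival histopathology, fully
    configurable and never asserted as ground truth."""
    return SurvivalMap(np.array([0.0, 90.0]), np.array([100.0, 25.0]))


def age_to_survival(age, survival_map: SurvivalMap | None = None):
    """Percent auditory-nerve survival at the given age(s) by piecewise-linear
    interpolation; ages outside the map domain raise."""
    if survival_map is None:
        survival_map = default_survival_map()
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < survival_map.ages[0]) or np.any(age_arr > survival_map.ages[-1]):
        raise ValueError("age outside the survival-map domain")
    out = np.interp(age_arr, survival_map.ages, survival_map.survival_percent)
    return float(out) if np.isscalar(age) else out


def overlay_model_vs_human(reports: dict, cohort: pd.DataFrame,
                           survival_map: SurvivalMap | None = None,
                           snr_bin: str = "10..0") -> pd.DataFrame:
    """Joint table for the model-vs-human overlay: decoder accuracy per CND
    profile at fiber-count survival abscissas, plus human word scores at
    age-mapped survival abscissas.

    ``reports`` maps profile name -> (EvalReport, CNDProfile) or an
    EvalReport with a ``.profile`` attribute resolvable via the named
    profiles.
    """
    from cndspeech.neurogram import make_profile

    rows = []
    for name, rep in reports.items():
        if isinstance(rep, tuple):
            report, profile = rep
        else:
            report, profile = rep, make_profile(name)
        acc = report.per_snr_bin.get(snr_bin, report.accuracy)
        rows.append(("model", name, profile.survival_percent, acc))
    if not rows:
        raise ValueError("no decoder reports supplied")
    surv = age_to_survival(cohort["age"].to_numpy(), survival_map)
    for s, w in zip(surv, cohort["wrs65"].to_numpy()):
        rows.append(("human", "", float(s), float(w)))
    return pd.DataFrame(rows, columns=["source", "profile", "survival_percent", "score"])
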