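"""Multilevel regression of hazardous use with a hospital random intercept.

Patients are nested within hospitals, so the binary hazardous-use outcome is
modelled with a hospital random intercept and patient-level fixed effects:
age group (reference <18), gender (reference female), region (reference
east; a hospital attribute entered as a patient-level covariate),
over-indication use, annual out-patient visits and number of distinct
doctors visited.

The default family is a *linear probability model* — identity link, so each
coefficient is a risk difference per covariate unit — estimated by REML via
:class:`statsmodels.regression.mixed_linear_model.MixedLM`.  A logistic
variant (variational Bayes mixed GLM) is provided for sensitivity analysis.
Confidence intervals are Wald-type at 95%; estimation is deterministic.

With a handful of hospitals, a between-hospital covariate such as region is
weakly identified next to the random intercept; the fit succeeds but the
region coefficients carry wide intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionResult", "build_design", "fit_multilevel"]

AGE_REF = "<18"
GENDER_REF = "female"
REGION_REF = "east"

FIXED_EFFECTS = [
    "age_18_64",
    "age_65_plus",
    "male",
    "region_central",
    "region_west",
    "over_indication",
    "n_visits",
    "n_distinct_doctors",
]


@dataclass
class RegressionResult:
    family: str
    params: pd.DataFrame  # index covariate; columns beta, se, ci_low, ci_high
    random_intercept_var: float
    n_used: int
    n_dropped_missing: int
    dropped_covariates: list[str] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        bad = self.params[
            (self.params["ci_low"] > self.params["beta"])
            | (self.params["beta"] > self.params["ci_high"])
        ]
        if len(bad):
            raise ValueError(f"inconsistent CI bounds for {list(bad.index)}")


def build_design(
    cohort: pd.DataFrame,
    region_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Encode the model covariates; drop patients with missing values.

    `cohort` needs one row per patient with columns ``hazardous``,
    ``hospital_id``, ``n_visits``, ``n_distinct_doctors``, ``over_indication``
    and either (``age_group``, ``gender``, ``region``) or the raw
    ``age_years``/``gender`` plus a `region_map` from hospital to region.

    Returns the design table and the number of patients dropped for
    missingness.  Covariates constant across the cohort are dropped with a
    warning (rank protection).
    """
    df = cohort.copy()
    if "age_group" not in df.columns:
        from .cohort_stats import age_group

        df["age_group"] = [age_group(a) for a in df["age_years"]]
    if "region" not in df.columns:
        if region_map is None:
            raise ValueError("need a region column or a hospital_id -> region map")
        df["region"] = df["hospital_id"].map(region_map)

    n0 = len(df)
    missing = (
        df["age_group"].isin(["unknown"])
        | df["age_group"].isna()
        | ~df["gender"].isin(["female", "male"])
        | df["over_indication"].isna()
        | df["region"].isna()
    )
    df = df[~missing]
    n_dropped = n0 - len(df)

    design = pd.DataFrame(
        {
            "patient_id": df["patient_id"].values,
            "hospital_id": df["hospital_id"].values,
            "hazardous": df["hazardous"].astype(int).values,
            "age_18_64": (df["age_group"] == "18-64").astype(int).values,
            "age_65_plus": (df["age_group"] == ">=65").astype(int).values,
            "male": (df["gender"] == "male").astype(int).values,
            "region_central": (df["region"] == "central").astype(int).values,
            "region_west": (df["region"] == "west").astype(int).values,
            "over_indication": df["over_indication"].astype(int).values,
            "n_visits": df["n_visits"].astype(float).values,
            "n_distinct_doctors": df["n_distinct_doctors"].astype(float).values,
        }
    )
    design.attrs["n_dropped_missing"] = n_dropped
    return design, n_dropped


def fit_multilevel(
    design: pd.DataFrame,
    family: str = "linear_probability",
    n_dropped_missing: int | None = None,
) -> RegressionResult:
    """Fit the hospital-random-intercept model on a design table.

    Parameters
    ----------
    design : output of :func:`build_design` (extra covariate columns beyond
        the standard fixed effects are allowed and included).
    family : ``linear_probability`` (identity link, REML) or ``logistic``
        (variational Bayes mixed GLM; coefficients on the log-odds scale).
    """
    if family not in ("linear_probability", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    groups = design["hospital_id"]
    if groups.nunique() < 2:
        raise ValueError(
            "only one hospital in the design: a random intercept is not "
            "identifiable; fit a fixed-effect (single-level) model instead"
        )
    if design["hazardous"].sum() < 1:
        raise ValueError("no hazardous outcomes in the design")
    if n_dropped_missing is None:
        n_dropped_missing = int(design.attrs.get("n_dropped_missing", 0))

    covariates = [
        c for c in design.columns
        if c not in ("patient_id", "hospital_id", "hazardous")
    ]
    dropped = [c for c in covariates if design[c].nunique() <= 1]
    for c in dropped:
        warnings.warn(f"covariate {c!r} is constant across the cohort; dropped")
    covariates = [c for c in covariates if c not in dropped]

    y = design["hazardous"].astype(float)
    X = sm.add_constant(design[covariates].astype(float), has_constant="add")

    if family == "linear_probability":
        model = sm.MixedLM(y, X, groups=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary RE-variance warnings
            # deterministic optimizer cascade; REML profiles the RE variance,
            # which often sits at the boundary for a near-zero hospital effect
            fit = model.fit(reml=True, method=["bfgs", "powell", "nm"], maxiter=500)
        beta = fit.fe_params
        se = fit.bse_fe
        re_var = float(fit.cov_re.iloc[0, 0])
        converged = bool(fit.converged)
    else:
        model = sm.BinomialBayesMixedGLM.from_formula(
            "hazardous ~ " + " + ".join(covariates),
            {"hospital": "0 + C(hospital_id)"},
            design,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit_vb()
        k = len(covariates) + 1
        beta = pd.Series(fit.fe_mean[:k], index=["const", *covariates])
        se = pd.Series(fit.fe_sd[:k], index=["const", *covariates])
        re_var = float(np.exp(2 * fit.vcp_mean[0]))
        converged = True

    z = 1.959963984540054  # 97.5% normal quantile
    params = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "ci_low": beta - z * se,
            "ci_high": beta + z * se,
        }
    )
    if not converged:
        raise RuntimeError(
            f"mixed-model fit did not converge after {getattr(fit, 'niter', '?')} iterations"
        )
    return RegressionResult(
        family=family,
        params=params,
        random_intercept_var=re_var,
        n_used=len(design),
        n_dropped_missing=n_dropped_missing,
        dropped_covariates=dropped,
        converged=converged,
    )
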