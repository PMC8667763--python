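"""Mixed-effects summaries of endotype mean trajectories.

Each endotype's mean mHLA-DR trend over the first week is modelled on the
transformed scale as a quadratic fixed effect of time per endotype, with a
patient-level random intercept and random slope of time:

    y_ij = b0_g + b1_g t_ij + b2_g t_ij^2 + u0_i + u1_i t_ij + e_ij

fitted by REML (statsmodels MixedLM). Time is centered at day 4 before
fitting to decorrelate (1, t, t^2); coefficients are reported back on the
uncentered day scale. Confidence bands propagate fixed-effects uncertainty
only (parametric simulation from the coefficient sampling distribution) and
are back-transformed to AB/C through the inverse marker transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["TrendFit", "TrendBand", "fit_trend", "predict_band", "compare_cohort_trends"]

logger = logging.getLogger(__name__)

_CENTER_DAY = 4.0

# maps centered-basis coefficients (a, b, c) for a + b*tc + c*tc^2, tc = t - 4,
# onto uncentered (beta0, beta1, beta2)
_UNCENTER = np.array([[1.0, -_CENTER_DAY, _CENTER_DAY**2], [0.0, 1.0, -2.0 * _CENTER_DAY], [0.0, 0.0, 1.0]])


@dataclass
class TrendFit:
    """Per-endotype quadratic fixed effects with random-effect variances."""

    coefficients: dict  # endotype -> (beta0, beta1, beta2), uncentered day scale
    vcov: dict  # endotype -> 3x3 covariance of those coefficients
    var_intercept: float
    var_slope: float
    cov_intercept_slope: float
    var_resid: float
    converged: bool
    n_obs: int
    n_patients: int

    def predict(self, endotype: str, times) -> np.ndarray:
        b0, b1, b2 = self.coefficients[endotype]
        t = np.asarray(times, dtype=float)
        return b0 + b1 * t + b2 * t * t


@dataclass
class TrendBand:
    """Mean curve with a 95% fixed-effects confidence band on the AB/C scale."""

    endotype: str
    times: np.ndarray
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    n_draws: int


def _fit_with_fallbacks(model):
    """REML fit trying a cascade of optimizers; returns the first converged
    result (or the last attempt if none converge)."""
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                result = model.fit(reml=True, method=method, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
                continue
            if result.converged:
                break
    if result is None:  # pragma: no cover
        raise RuntimeError("mixed-model fit failed under every optimizer")
    return result


def _prepare(long_data: pd.DataFrame, value_col: str) -> pd.DataFrame:
    df = long_data.copy()
    df["tc"] = df["day"] - _CENTER_DAY
    df["tc2"] = df["tc"] ** 2
    df = df.rename(columns={value_col: "y"}) if value_col != "y" else df
    return df


def fit_trend(
    long_data: pd.DataFrame,
    value_col: str = "mhla_dr_t",
    endotype_col: str = "endotype",
    patient_col: str = "patient_id",
) -> TrendFit:
    """REML fit of the per-endotype quadratic mixed model.

    ``long_data`` needs columns patient_id, endotype, day, and the value
    column (transformed scale). A singular random-effects covariance triggers
    a logged refit with independent intercept and slope.
    """
    df = _prepare(long_data, value_col)
    df = df.rename(columns={endotype_col: "endotype", patient_col: "patient"})
    formula = "y ~ 0 + C(endotype) + C(endotype):tc + C(endotype):tc2"

    def _fit(re_formula, vc_formula):
        model = smf.mixedlm(formula, df, groups=df["patient"], re_formula=re_formula, vc_formula=vc_formula)
        return _fit_with_fallbacks(model)

    result = _fit("~tc", None)
    cov_re = np.asarray(result.cov_re)
    singular = cov_re.shape == (2, 2) and (
        np.linalg.det(cov_re) <= 0 or min(np.diag(cov_re)) <= 1e-12 * max(np.diag(cov_re).max(), 1e-300)
    )
    if singular:
        logger.warning("random-effects covariance singular; refitting with independent intercept and slope")
        result = _fit("1", {"slope": "0 + tc"})

    params = result.fe_params
    cov_fe = result.cov_params().loc[params.index, params.index]
    endotypes = sorted(df["endotype"].unique())
    coefficients, vcov = {}, {}
    for g in endotypes:
        names = [f"C(endotype)[{g}]", f"C(endotype)[{g}]:tc", f"C(endotype)[{g}]:tc2"]
        beta_c = params[names].to_numpy()
        cov_c = cov_fe.loc[names, names].to_numpy()
        coefficients[g] = tuple(_UNCENTER @ beta_c)
        vcov[g] = _UNCENTER @ cov_c @ _UNCENTER.T

    cov_re = np.asarray(result.cov_re)
    if cov_re.shape == (2, 2):
        # uncenter: the fitted random intercept lives at day 4 (tc = 0);
        # report the day-0 intercept variance b0 = b0c - 4*b1
        vi_c, vs, cov_c = float(cov_re[0, 0]), float(cov_re[1, 1]), float(cov_re[0, 1])
        var_i = vi_c - 2 * _CENTER_DAY * cov_c + _CENTER_DAY**2 * vs
        var_s = vs
        cov_is = cov_c - _CENTER_DAY * vs
    else:
        var_i = float(cov_re[0, 0]) if cov_re.size else 0.0
        var_s = float(sum(result.vcomp)) if len(result.vcomp) else 0.0
        cov_is = 0.0
    return TrendFit(
        coefficients=coefficients,
        vcov=vcov,
        var_intercept=var_i,
        var_slope=var_s,
        cov_intercept_slope=cov_is,
        var_resid=float(result.scale),
        converged=bool(result.converged),
        n_obs=len(df),
        n_patients=df["patient"].nunique(),
    )


def predict_band(
    fit: TrendFit,
    endotype: str,
    times,
    n_draws: int = 2000,
    seed: int = 0,
    inverse=None,
) -> TrendBand:
    """95% fixed-effects confidence band by parametric simulation.

    Coefficient vectors are drawn from N(estimate, vcov); each draw's
    quadratic is evaluated on the day grid, back-transformed (``inverse``,
    e.g. the fitted Box-Cox inverse; identity when omitted), and pointwise
    2.5/97.5 percentiles taken. The central curve is the back-transformed
    point prediction.
    """
    if not fit.converged:
        raise ValueError("cannot draw bands from a non-converged fit")
    times = np.asarray(times, dtype=float)
    inverse = inverse if inverse is not None else (lambda y: y)
    rng = np.random.default_rng(seed)
    beta = np.asarray(fit.coefficients[endotype])
    draws = rng.multivariate_normal(beta, fit.vcov[endotype], size=n_draws, method="svd")
    basis = np.vander(times, 3, increasing=True)  # columns 1, t, t^2
    curves = inverse(draws @ basis.T)
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    mean = np.asarray(inverse(fit.predict(endotype, times)))
    return TrendBand(endotype=endotype, times=times, mean=mean, lo95=lo, hi95=hi, n_draws=n_draws)


def compare_cohort_trends(
    long_data: pd.DataFrame,
    value_col: str = "mhla_dr_t",
    endotype_col: str = "endotype",
    patient_col: str = "patient_id",
    cohort_col: str = "cohort",
) -> pd.DataFrame:
    """Test cohort-by-time interactions on the mean trajectory per endotype.

    Augments the trend model with per-endotype cohort main and interaction
    terms and reports Wald t tests for the cohort contrasts. Degrees of
    freedom use the residual approximation df = n_patients - n_fixed (the
    REML variance-parameter covariance needed for a Satterthwaite correction
    is not exposed by the fitting backend; the approximation is logged).
    Endotypes present in only one cohort are skipped with a log entry.
    """
    df = _prepare(long_data, value_col)
    df = df.rename(columns={endotype_col: "endotype", patient_col: "patient", cohort_col: "cohort"})
    counts = df.groupby(["endotype", "cohort"]).size().unstack(fill_value=0)
    if counts.shape[1] < 2:
        raise ValueError("need two cohorts to compare")
    keep = counts.index[(counts > 0).all(axis=1)]
    skipped = sorted(set(counts.index) - set(keep))
    if skipped:
        logger.warning("endotypes absent in one cohort skipped: %s", skipped)
    df = df[df["endotype"].isin(keep)]

    formula = (
        "y ~ 0 + C(endotype) + C(endotype):tc + C(endotype):tc2 "
        "+ C(endotype):C(cohort) + C(endotype):C(cohort):tc + C(endotype):C(cohort):tc2"
    )
    model = smf.mixedlm(formula, df, groups=df["patient"], re_formula="~tc")
    result = _fit_with_fallbacks(model)

    n_fixed = len(result.fe_params)
    dof = max(df["patient"].nunique() - n_fixed, 1)
    logger.info("cohort comparison uses residual df approximation: df = %d", dof)

    rows = []
    for name, est in result.fe_params.items():
        if "C(cohort)" not in name:
            continue
        se = float(result.bse_fe[name])
        endo = name.split("C(endotype)[", 1)[1].split("]", 1)[0]
        if name.endswith(":tc"):
            term = "cohort:t"
        elif name.endswith(":tc2"):
            term = "cohort:t2"
        else:
            term = "cohort"
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), dof)
        rows.append((endo, term, float(est), se, dof, float(t), float(p)))
    return pd.DataFrame(rows, columns=["endotype", "term", "estimate", "se", "df", "t", "p"])
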