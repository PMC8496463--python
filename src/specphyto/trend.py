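"""Population wavelength trends via linear mixed-effects models.

Each photosynthetic parameter is modelled independently as

    value ~ 1 + wl_t + (1 + wl_t | station),   wl_t = wavelength - 440 nm,

so the intercept is the population value at 440 nm and the slope the change
per nm.  Fixed effects are reported from the REML fit; likelihood-ratio
tests for the random terms compare ML fits of nested models (full vs.
random-intercept-only vs. no random effects).  Detrending subtracts only the
fixed-effect population line, leaving station departures (random effects +
residual) for the multivariate stages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .constants import WL_ORIGIN
from .errors import FitError, ValidationError


@dataclass
class LMEMFit:
    """Fitted wavelength trend for one parameter."""

    parameter: str
    beta0: float                # intercept at 440 nm
    beta1: float                # slope per nm of transposed wavelength
    se_beta0: float
    se_beta1: float
    p_beta0: float
    p_beta1: float
    re_sd_intercept: float
    re_sd_slope: float
    re_corr: float
    lrt_intercept_chi2: float
    lrt_intercept_p: float
    lrt_slope_chi2: float
    lrt_slope_p: float
    method: str                 # "reml" | "ols-degenerate"
    converged: bool = True
    singular: bool = False

    def population_line(self, wavelength) -> np.ndarray:
        wlt = np.asarray(wavelength, dtype=float) - WL_ORIGIN
        return self.beta0 + self.beta1 * wlt

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "parameter", "beta0", "se_beta0", "p_beta0",
            "beta1", "se_beta1", "p_beta1",
            "re_sd_intercept", "re_sd_slope", "re_corr",
            "lrt_intercept_chi2", "lrt_intercept_p",
            "lrt_slope_chi2", "lrt_slope_p", "method", "singular")}


# Internal covariate rescaling: the transposed wavelength spans 0-185 nm,
# which puts random-slope variances ~8 orders of magnitude below intercept
# variances and defeats the likelihood optimizers.  Fits run on wl_t/185
# (span 0-1); coefficients are converted back to per-nm units on report.
WL_SCALE = 185.0


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    required = {"station", "wavelength", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"long table missing columns {sorted(missing)}")
    df = table.dropna(subset=["value"]).copy()
    if df["station"].nunique() < 2:
        raise ValidationError("need >= 2 stations to fit a mixed model")
    if df["wavelength"].nunique() < 2:
        raise ValidationError("need >= 2 wavelengths to fit a trend")
    df["wl_t"] = df["wavelength"].astype(float) - WL_ORIGIN
    df["wl_s"] = df["wl_t"] / WL_SCALE
    df["ones"] = 1.0
    return df


_OPTIMIZERS = (["lbfgs"], ["powell"], ["bfgs"], ["nm"], ["cg"])


def _fit_mixed(model, reml: bool):
    """Fit a MixedLM, retrying across optimizers.

    A variance component estimated at exactly zero can make the observed
    information singular for one optimizer's endpoint but not another's.
    """
    last = None
    for method in _OPTIMIZERS:
        try:
            return model.fit(reml=reml, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
    raise FitError(f"mixed-model fit failed with all optimizers: {last}")


def _ols_pvalues(res) -> tuple:
    return (float(res.params["Intercept"]), float(res.params["wl_t"]),
            float(res.bse["Intercept"]), float(res.bse["wl_t"]),
            float(res.pvalues["Intercept"]), float(res.pvalues["wl_t"]))


def fit_lmem(table: pd.DataFrame, parameter: str = "") -> LMEMFit:
    """Fit the per-parameter wavelength trend.

    ``table`` is a long frame with columns station, wavelength, value.
    Degenerate data (residuals numerically zero around the OLS line) are
    reported from the OLS fit with all random-effect terms at zero.  A
    singular full fit falls back to uncorrelated random intercept and slope
    and is flagged.
    """
    df = _prepare(table)

    ols = smf.ols("value ~ wl_t", data=df).fit()
    scale = float(np.mean(df["value"] ** 2)) or 1.0
    if float(ols.ssr) < 1e-16 * scale * len(df):
        b0, b1, se0, se1, p0, p1 = _ols_pvalues(ols)
        return LMEMFit(parameter=parameter, beta0=b0, beta1=b1,
                       se_beta0=se0, se_beta1=se1, p_beta0=p0, p_beta1=p1,
                       re_sd_intercept=0.0, re_sd_slope=0.0, re_corr=0.0,
                       lrt_intercept_chi2=0.0, lrt_intercept_p=1.0,
                       lrt_slope_chi2=0.0, lrt_slope_p=1.0,
                       method="ols-degenerate")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ wl_s", df, groups=df["station"],
                            re_formula="~wl_s")
        res = _fit_mixed(model, reml=True)
        singular = not _re_cov_ok(res)
        if singular:
            model = smf.mixedlm(
                "value ~ wl_s", df, groups=df["station"],
                vc_formula={"icpt": "0 + ones", "slp": "0 + wl_s"})
            res = _fit_mixed(model, reml=True)

        # ML fits for the likelihood-ratio tests of the random terms.
        ll_full = _fit_mixed(
            smf.mixedlm("value ~ wl_s", df, groups=df["station"],
                        re_formula="~wl_s"), reml=False).llf
        ll_int = _fit_mixed(
            smf.mixedlm("value ~ wl_s", df, groups=df["station"],
                        re_formula="~1"), reml=False).llf
        ll_ols = float(ols.llf)

    chi2_slope = max(2.0 * (ll_full - ll_int), 0.0)
    chi2_int = max(2.0 * (ll_int - ll_ols), 0.0)
    # df: random slope adds a variance and a covariance; intercept adds one
    # variance.  p-values from the plain chi-square reference (conservative
    # for variance components on the boundary).
    p_slope = float(stats.chi2.sf(chi2_slope, df=2))
    p_int = float(stats.chi2.sf(chi2_int, df=1))

    sd_int, sd_slope, corr = _re_summary(res)
    sd_slope /= WL_SCALE
    fe = res.fe_params
    bse = res.bse_fe
    # t-based p-values with residual-based df.
    dof = max(len(df) - df["station"].nunique() - 2, 1)
    tvals = fe / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    return LMEMFit(
        parameter=parameter,
        beta0=float(fe["Intercept"]), beta1=float(fe["wl_s"]) / WL_SCALE,
        se_beta0=float(bse["Intercept"]), se_beta1=float(bse["wl_s"]) / WL_SCALE,
        p_beta0=float(pvals[list(fe.index).index("Intercept")]),
        p_beta1=float(pvals[list(fe.index).index("wl_s")]),
        re_sd_intercept=sd_int, re_sd_slope=sd_slope, re_corr=corr,
        lrt_intercept_chi2=chi2_int, lrt_intercept_p=p_int,
        lrt_slope_chi2=chi2_slope, lrt_slope_p=p_slope,
        method="reml", converged=bool(res.converged), singular=singular)


def _re_cov_ok(res) -> bool:
    """True if the random-effect covariance is usable (PD, converged)."""
    if not res.converged:
        return False
    cov = np.asarray(res.cov_re)
    if cov.shape[0] < 2:
        return True
    try:
        eigvals = np.linalg.eigvalsh(cov)
    except np.linalg.LinAlgError:
        return False
    # Correlation pinned at +-1 indicates a singular fit.
    if cov[0, 0] > 0 and cov[1, 1] > 0:
        corr = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        if abs(corr) > 0.9999:
            return False
    return bool(eigvals.min() >= -1e-12 * max(eigvals.max(), 1.0))


def _re_summary(res) -> tuple[float, float, float]:
    cov = np.asarray(res.cov_re)
    if cov.size >= 4:
        sd_int = float(np.sqrt(max(cov[0, 0], 0.0)))
        sd_slope = float(np.sqrt(max(cov[1, 1], 0.0)))
        corr = (float(cov[0, 1] / (sd_int * sd_slope))
                if sd_int > 0 and sd_slope > 0 else 0.0)
        return sd_int, sd_slope, corr
    # Variance-component (uncorrelated) parameterisation.
    vcomp = dict(zip(res.model.exog_vc.names, np.asarray(res.vcomp)))
    sd_int = float(np.sqrt(max(vcomp.get("icpt", 0.0), 0.0)))
    sd_slope = float(np.sqrt(max(vcomp.get("slp", 0.0), 0.0)))
    return sd_int, sd_slope, 0.0


def detrend(table: pd.DataFrame, fit: LMEMFit) -> pd.DataFrame:
    """Subtract the fixed-effect population line from the observations.

    Only the population trend (beta0 + beta1 * wl_t) is removed, not the
    station-level predictions, so the detrended values retain each station's
    departure from the population.
    """
    df = table.copy()
    df["detrended"] = df["value"] - fit.population_line(df["wavelength"])
    return df


def fit_all(long_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit and detrend every parameter of a tidy long table.

    ``long_table`` has columns station, wavelength, parameter, value.
    Returns (trend table in one-row-per-parameter layout, detrended long
    table).
    """
    fits, pieces = [], []
    for name, group in long_table.groupby("parameter", sort=False):
        fit = fit_lmem(group, parameter=name)
        fits.append(fit.to_dict())
        pieces.append(detrend(group, fit))
    return pd.DataFrame(fits), pd.concat(pieces, ignore_index=True)
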