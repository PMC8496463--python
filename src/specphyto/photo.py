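"""Fluorescence-derived photophysiology.

From O-I1 induction kinetics and rapid light curves (RLC) this module derives
the wavelength-dependent functional absorption cross section of PSII
(Sigma(II), nm2), quantum yields, relative and absolute electron transport
rates, fits the Eilers-Peeters photosynthesis-irradiance model and the NPQ
light response, and computes the spectral photoacclimation indices.

Core relations (relative fluorescence units throughout):

    Y(II)   = (Fm' - F) / Fm'
    Fv/Fm   = (Fm - F0) / Fm          (dark step of the RLC)
    r.ETR   = Y(II) * PAR * 0.5
    Sigma   = 1 / (tau * L * PAR)     (PAR in mol quanta m-2 s-1)
    PAR(II) = Sigma * L * PAR          (quanta PSII-1 s-1)
    ETR(II) = PAR(II) * Y(II) / (Fv/Fm)
    NPQ     = Fm / Fm' - 1

The Eilers-Peeters model P(E) = E / (a E^2 + b E + c) yields
alpha = 1/c, ETRmax = 1/(b + 2 sqrt(a c)), Eop = sqrt(c/a), Ek = ETRmax/alpha.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import (
    AVOGADRO,
    M2_TO_NM2,
    NPQ_EVAL_HIGH,
    NPQ_EVAL_LOW,
    TAU_MAX,
    TAU_MIN,
    UMOL_TO_MOL,
)
from .errors import FitError, ValidationError

log = logging.getLogger("specphyto")

# Sigma(II) [nm2] * PARII_FACTOR * PAR [umol quanta m-2 s-1]
# = quanta absorbed per PSII per second.
PARII_FACTOR = AVOGADRO * UMOL_TO_MOL / M2_TO_NM2


@dataclass
class InductionCurve:
    """One O-I1 fluorescence rise (~1 ms actinic pulse)."""

    wavelength: int
    times: np.ndarray            # s
    fluorescence: np.ndarray     # relative units
    actinic_par: float           # umol quanta m-2 s-1
    subsample: int = 1
    repeat: int = 1
    station: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size < 10:
            raise ValidationError("induction curve needs >= 10 time points")
        if not self.actinic_par > 0:
            raise ValidationError("actinic_par must be > 0")


@dataclass
class RapidLightCurve:
    """One 14-step PE protocol for one wavelength and replicate.

    ``steps`` is an ordered array of (par, f, fm_prime) with a dark first
    step (par = 0) from which F0/Fm and hence Fv/Fm are read.
    """

    wavelength: int
    replicate: int
    par: np.ndarray
    f: np.ndarray
    fm_prime: np.ndarray
    station: str | None = None

    def __post_init__(self):
        self.par = np.asarray(self.par, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.fm_prime = np.asarray(self.fm_prime, dtype=float)
        if self.par[0] != 0:
            raise ValidationError("first RLC step must be at PAR = 0 (dark)")
        if np.any(np.diff(self.par) <= 0):
            raise ValidationError("PAR steps must be strictly increasing")
        if np.any(self.fm_prime <= 0):
            raise ValidationError("fm_prime must be > 0 at every step")
        if np.any(self.f <= 0) or np.any(self.f > self.fm_prime):
            raise ValidationError("require 0 < F <= Fm' at every step")


@dataclass
class EPFit:
    """Eilers-Peeters coefficients and the derived PE parameters."""

    a: float
    b: float
    c: float
    alpha: float
    etr_max: float
    e_op: float
    e_k: float
    unit_system: str        # "relative" | "absolute"
    residual_ss: float

    def predict(self, e):
        e = np.asarray(e, dtype=float)
        return e / (self.a * e**2 + self.b * e + self.c)


@dataclass
class NPQFit:
    """Fitted NPQ light response and its back-calculated values."""

    model: str              # "michaelis_menten" | "linear_origin" | "zero"
    npq_max: float | None
    k_half: float | None
    slope: float | None
    npq300: float
    npq1200: float
    residual_ss: float = np.nan

    def predict(self, e):
        e = np.asarray(e, dtype=float)
        if self.model == "michaelis_menten":
            return self.npq_max * e / (self.k_half + e)
        if self.model == "linear_origin":
            return self.slope * e
        return np.zeros_like(e)


@dataclass
class PhotoParamSet:
    """The derived parameter roster for one station x wavelength."""

    station: str
    wavelength: int
    fvfm: float
    sigma_nm2: float
    r_alpha: float
    alpha_ii: float
    r_etrmax: float
    etrmax_ii: float
    r_ek: float
    ek_ii: float
    r_eop: float
    eop_ii: float
    npq300: float
    npq1200: float
    sigma_var: float = np.nan   # subsample variance, kept for QC
    npq_model: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "station", "wavelength", "fvfm", "sigma_nm2",
            "r_alpha", "alpha_ii", "r_etrmax", "etrmax_ii",
            "r_ek", "ek_ii", "r_eop", "eop_ii",
            "npq300", "npq1200", "sigma_var", "npq_model")}


def params_to_frame(params: list[PhotoParamSet]) -> pd.DataFrame:
    return pd.DataFrame([p.to_dict() for p in params])


# ---------------------------------------------------------------------------
# Induction kinetics and Sigma(II)
# ---------------------------------------------------------------------------

def _fit_single_induction(curve: InductionCurve) -> float:
    """Tau from one repeat: F(t) = Fo + (Fi1 - Fo)(1 - exp(-t/tau))."""
    t, f = curve.times, curve.fluorescence
    rise = f[-1] - f[0]
    if rise <= 0 or np.ptp(f) < 1e-12 * max(abs(f[-1]), 1.0):
        raise FitError("no rise in induction curve")

    def model(t, fo, fi1, tau):
        return fo + (fi1 - fo) * (1.0 - np.exp(-t / tau))

    tau0 = max(t[-1] / 5.0, 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            model, t, f, p0=[f[0], f[-1], tau0],
            bounds=([0, 0, 1e-8], [np.inf, np.inf, 1.0]),
            maxfev=10000, xtol=1e-15, ftol=1e-15)
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"induction fit did not converge: {exc}") from exc
    return float(popt[2])


def fit_tau(curves: list[InductionCurve]) -> float:
    """Mean tau (s) over (typically three) consecutive repeats.

    All repeats must share wavelength, subsample and actinic PAR.  A tau
    outside the plausible (1e-5, 5e-3) s window raises ``FitError``.
    """
    if not curves:
        raise ValidationError("no induction curves given")
    keys = {(c.wavelength, c.subsample, c.actinic_par) for c in curves}
    if len(keys) != 1:
        raise ValidationError(
            "repeats must share wavelength, subsample and actinic PAR")
    tau = float(np.mean([_fit_single_induction(c) for c in curves]))
    if not (TAU_MIN < tau < TAU_MAX):
        raise FitError(f"tau={tau:.3e} s outside plausible range "
                       f"({TAU_MIN:g}, {TAU_MAX:g}) s")
    return tau


def aggregate_tau(curves: list[InductionCurve]) -> tuple[float, float]:
    """Per-sample mean and variance of tau over subsamples.

    Repeats within a subsample are averaged first (``fit_tau``); the
    subsample means are then aggregated.  Variance uses ddof=1.
    """
    by_sub: dict[int, list[InductionCurve]] = {}
    for c in curves:
        by_sub.setdefault(c.subsample, []).append(c)
    taus = [fit_tau(group) for _, group in sorted(by_sub.items())]
    var = float(np.var(taus, ddof=1)) if len(taus) > 1 else np.nan
    return float(np.mean(taus)), var


def sigma_psii(tau: float, par: float) -> float:
    """Functional absorption cross section of PSII, nm2.

    Sigma = 1 / (tau * L * PAR) with PAR converted from umol to mol quanta
    m-2 s-1; the m2 result is returned in nm2.
    """
    if not (tau > 0 and par > 0):
        raise ValidationError("tau and par must be > 0")
    sigma_m2 = 1.0 / (tau * AVOGADRO * par * UMOL_TO_MOL)
    return sigma_m2 * M2_TO_NM2


# ---------------------------------------------------------------------------
# Rapid light curve step derivation
# ---------------------------------------------------------------------------

def derive_steps(rlc: RapidLightCurve, sigma: float) -> tuple[float, pd.DataFrame]:
    """Per-step derived quantities from one RLC.

    Returns (Fv/Fm, frame) where the frame has columns par, y_ii, r_etr,
    par_ii, etr_ii, npq.  Fm and F0 are taken from the dark first step; all
    zero-PAR rates are exactly 0.
    """
    if not sigma > 0:
        raise ValidationError("sigma must be > 0")
    f0, fm = float(rlc.f[0]), float(rlc.fm_prime[0])
    fvfm = (fm - f0) / fm
    y = (rlc.fm_prime - rlc.f) / rlc.fm_prime
    r_etr = y * rlc.par * 0.5
    par_ii = sigma * PARII_FACTOR * rlc.par
    etr_ii = par_ii * y / fvfm
    npq = fm / rlc.fm_prime - 1.0
    frame = pd.DataFrame({
        "par": rlc.par, "y_ii": y, "r_etr": r_etr,
        "par_ii": par_ii, "etr_ii": etr_ii, "npq": npq,
    })
    return float(fvfm), frame


# ---------------------------------------------------------------------------
# Eilers-Peeters PE fitting
# ---------------------------------------------------------------------------

def _ep_derived(a: float, b: float, c: float) -> dict:
    return {
        "alpha": 1.0 / c,
        "etr_max": 1.0 / (b + 2.0 * np.sqrt(a * c)),
        "e_op": np.sqrt(c / a),
        "e_k": c / (b + 2.0 * np.sqrt(a * c)),
    }


def ep_coefficients(alpha: float, etr_max: float, e_op: float) -> tuple[float, float, float]:
    """Invert (alpha, ETRmax, Eop) to Eilers-Peeters (a, b, c).

    Requires Ek = ETRmax/alpha < Eop/2 so that b > 0.
    """
    if min(alpha, etr_max, e_op) <= 0:
        raise ValidationError("alpha, etr_max and e_op must be > 0")
    c = 1.0 / alpha
    a = c / e_op**2
    b = 1.0 / etr_max - 2.0 * np.sqrt(a * c)
    if b < 0:
        raise ValidationError(
            "inconsistent PE parameters: require Ek <= Eop/2 (b >= 0)")
    return a, b, c


def fit_pe(e: np.ndarray, p: np.ndarray, unit_system: str = "relative",
           n_starts: int = 6, seed: int = 0) -> EPFit:
    """Fit the Eilers-Peeters model by multi-start bounded least squares.

    Points from replicate curves are pooled as-is.  A data-driven start
    (initial slope, observed maximum, position of the maximum) is refined by
    trust-region least squares; additional perturbed starts (seeded) guard
    against local minima.  Coefficients are constrained positive.
    """
    e = np.asarray(e, dtype=float)
    p = np.asarray(p, dtype=float)
    mask = e > 0
    if np.unique(e[mask]).size < 6:
        raise ValidationError("need >= 6 distinct positive irradiance levels")
    e_fit, p_fit = e[mask], p[mask]

    # Data-driven initial values.
    order = np.argsort(e_fit)
    e_s, p_s = e_fit[order], p_fit[order]
    with np.errstate(divide="ignore", invalid="ignore"):
        low_slopes = p_s[:3] / e_s[:3]
    alpha0 = float(np.nanmedian(low_slopes))
    pmax0 = float(np.max(p_s))
    if alpha0 <= 0 or pmax0 <= 0:
        raise FitError("non-positive initial slope or maximum; cannot fit")
    i_max = int(np.argmax(p_s))
    eop0 = float(e_s[i_max]) if i_max < len(e_s) - 1 else 2.0 * float(e_s[-1])
    c0 = 1.0 / alpha0
    a0 = c0 / eop0**2
    b0 = max(1.0 / pmax0 - 2.0 * np.sqrt(a0 * c0), 1e-3 / pmax0)
    # Parameterisation (log c, log b, log Eop) with a = c / Eop^2 keeps all
    # coefficients positive and lets Eop be box-bounded: beyond ~10x the
    # observed irradiance range the optimum is not identifiable.
    eop_cap = 10.0 * float(e_s[-1])
    x0 = np.log([c0, b0, min(eop0, eop_cap * 0.99)])
    lower = [-np.inf, -np.inf, np.log(float(e_s[0]))]
    upper = [np.inf, np.inf, np.log(eop_cap)]

    def residuals(x):
        c, b, eop = np.exp(x)
        a = c / eop**2
        return e_fit / (a * e_fit**2 + b * e_fit + c) - p_fit

    rng = np.random.default_rng(seed)
    best = None
    starts = [x0] + [np.clip(x0 + rng.normal(scale=0.7, size=3), lower, upper)
                     for _ in range(n_starts - 1)]
    for start in starts:
        try:
            sol = optimize.least_squares(
                residuals, start, method="trf", bounds=(lower, upper),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000)
        except Exception:
            continue
        ss = float(np.sum(sol.fun**2))
        if best is None or ss < best[0]:
            best = (ss, sol.x)
    if best is None:
        raise FitError("Eilers-Peeters fit failed from all starts")
    ss, x_best = best
    c, b, eop_hat = (float(v) for v in np.exp(x_best))
    a = c / eop_hat**2
    d = _ep_derived(a, b, c)
    return EPFit(a=a, b=b, c=c, unit_system=unit_system, residual_ss=ss, **d)


# ---------------------------------------------------------------------------
# NPQ light-response fitting
# ---------------------------------------------------------------------------

def _aicc(n: int, ss: float, k: int) -> float:
    """Small-sample corrected AIC for a Gaussian residual model."""
    k = k + 1  # + residual variance
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(ss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_npq(e: np.ndarray, npq: np.ndarray) -> NPQFit:
    """Fit the NPQ-vs-PAR response and back-calculate NPQ300 / NPQ1200.

    Both a Michaelis-Menten saturation model NPQ = NPQmax E / (Khalf + E)
    and a linear regression forced through the origin are fitted; the model
    with the lower corrected AIC is kept.  The MM candidate is disqualified
    when its fit fails or yields non-positive parameters.  If all NPQ <= 0
    an identically-zero model is returned.
    """
    e = np.asarray(e, dtype=float)
    npq = np.asarray(npq, dtype=float)
    if e.size < 5:
        raise ValidationError("need >= 5 points to fit NPQ response")
    if np.any(e < 0):
        raise ValidationError("PAR must be >= 0")
    if np.all(npq <= 0):
        return NPQFit(model="zero", npq_max=None, k_half=None, slope=None,
                      npq300=0.0, npq1200=0.0, residual_ss=float(np.sum(npq**2)))

    n = e.size
    # Linear through origin (closed form).
    slope = float(np.sum(e * npq) / np.sum(e * e))
    ss_lin = float(np.sum((slope * e - npq) ** 2))

    # Michaelis-Menten.
    mm = None
    try:
        m0 = max(float(np.max(npq)) * 1.5, 1e-3)
        half = 0.5 * float(np.max(npq))
        above = e[npq >= half]
        k0 = float(above[0]) if above.size else float(np.median(e[e > 0]))
        popt, _ = optimize.curve_fit(
            lambda x, m, k: m * x / (k + x), e, npq, p0=[m0, max(k0, 1.0)],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000, xtol=1e-15, ftol=1e-15)
        m_fit, k_fit = float(popt[0]), float(popt[1])
        if m_fit > 0 and k_fit > 0:
            ss_mm = float(np.sum((m_fit * e / (k_fit + e) - npq) ** 2))
            mm = (m_fit, k_fit, ss_mm)
    except Exception:
        mm = None

    use_mm = mm is not None and _aicc(n, mm[2], 2) < _aicc(n, ss_lin, 1)
    if use_mm:
        m_fit, k_fit, ss_mm = mm
        return NPQFit(
            model="michaelis_menten", npq_max=m_fit, k_half=k_fit, slope=None,
            npq300=m_fit * NPQ_EVAL_LOW / (k_fit + NPQ_EVAL_LOW),
            npq1200=m_fit * NPQ_EVAL_HIGH / (k_fit + NPQ_EVAL_HIGH),
            residual_ss=ss_mm)
    return NPQFit(
        model="linear_origin", npq_max=None, k_half=None, slope=slope,
        npq300=slope * NPQ_EVAL_LOW, npq1200=slope * NPQ_EVAL_HIGH,
        residual_ss=ss_lin)


# ---------------------------------------------------------------------------
# Station x wavelength parameter assembly
# ---------------------------------------------------------------------------

def derive_photo_params(
    rlcs: list[RapidLightCurve],
    sigma: float,
    sigma_var: float = np.nan,
    seed: int = 0,
) -> PhotoParamSet:
    """Full parameter set for one station x wavelength.

    The replicate RLCs (typically three) are pooled as points into single
    relative (r.ETR vs PAR), absolute (ETR(II) vs PAR(II)) and NPQ fits;
    Fv/Fm is the mean of the replicate dark steps.
    """
    if not rlcs:
        raise ValidationError("no rapid light curves given")
    wavelength = rlcs[0].wavelength
    station = rlcs[0].station or ""
    fvfms, frames = [], []
    for rlc in rlcs:
        fvfm, frame = derive_steps(rlc, sigma)
        fvfms.append(fvfm)
        frames.append(frame)
    pooled = pd.concat(frames, ignore_index=True)
    fvfm = float(np.mean(fvfms))

    fit_rel = fit_pe(pooled["par"], pooled["r_etr"], "relative", seed=seed)
    fit_abs = fit_pe(pooled["par_ii"], pooled["etr_ii"], "absolute", seed=seed)
    light = pooled["par"] > 0
    npq_fit = fit_npq(pooled.loc[light, "par"], pooled.loc[light, "npq"])

    return PhotoParamSet(
        station=station, wavelength=wavelength, fvfm=fvfm, sigma_nm2=sigma,
        r_alpha=fit_rel.alpha, alpha_ii=fit_abs.alpha,
        r_etrmax=fit_rel.etr_max, etrmax_ii=fit_abs.etr_max,
        r_ek=fit_rel.e_k, ek_ii=fit_abs.e_k,
        r_eop=fit_rel.e_op, eop_ii=fit_abs.e_op,
        npq300=npq_fit.npq300, npq1200=npq_fit.npq1200,
        sigma_var=sigma_var, npq_model=npq_fit.model)


# ---------------------------------------------------------------------------
# Spectral photoacclimation indices
# ---------------------------------------------------------------------------

EK_PAIRS = ((625, 440), (540, 440), (540, 625))


def spectral_indices(params: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Per-station photoacclimation indices.

    From the tidy parameter table (one row per station x wavelength) and the
    station record table, computes Ek,440/Eavg (relative and absolute units)
    and the Ek wavelength ratios 625/440, 540/440 and 540/625 (both unit
    systems), joined with the matching light-quality ratios, Zeu/Zumixl and
    TSS.  Stations missing a needed wavelength are omitted.
    """
    wide_r = params.pivot(index="station", columns="wavelength", values="r_ek")
    wide_a = params.pivot(index="station", columns="wavelength", values="ek_ii")
    rows = []
    for st in wide_r.index:
        if st not in stations.index:
            continue
        if 440 not in wide_r.columns or pd.isna(wide_r.loc[st, 440]):
            log.warning("station %s lacks the 440 nm anchor; omitted", st)
            continue
        rec = stations.loc[st]
        row: dict = {"station": st}
        for num, den in EK_PAIRS:
            for tag, wide in (("r", wide_r), ("ii", wide_a)):
                col = f"ek_{tag}_{num}_{den}"
                if num not in wide.columns or den not in wide.columns or \
                        pd.isna(wide.loc[st].get(num)) or pd.isna(wide.loc[st].get(den)):
                    row[col] = np.nan
                else:
                    row[col] = wide.loc[st, num] / wide.loc[st, den]
        row["ek_r_440_over_eavg"] = wide_r.loc[st, 440] / rec["e_avg"]
        row["ek_ii_440_over_eavg"] = wide_a.loc[st, 440] / rec["e_avg"]
        row["ratio_rb"] = rec["ratio_rb"]
        row["ratio_gb"] = rec["ratio_gb"]
        row["ratio_gr"] = rec["ratio_gr"]
        row["zeu_over_zumixl"] = rec["z_eu"] / rec["z_umixl"]
        row["tss"] = rec["tss"]
        row["stratified"] = bool(rec["stratified"])
        rows.append(row)
    if not rows:
        raise ValidationError(
            "no station carries the 440 nm anchor wavelength")
    return pd.DataFrame(rows).set_index("station")


def index_regression(indices: pd.DataFrame, x: str, y: str,
                     stratified: bool | None = None) -> dict:
    """OLS line and Pearson correlation between two index columns.

    ``stratified`` restricts to (non-)stratified stations when given.
    """
    df = indices
    if stratified is not None:
        df = df[df["stratified"] == stratified]
    df = df[[x, y]].dropna()
    if len(df) < 3:
        raise ValidationError("need >= 3 stations for a regression")
    slope, intercept, r, p, stderr = stats.linregress(df[x], df[y])
    return {"x": x, "y": y, "n": int(len(df)), "slope": float(slope),
            "intercept": float(intercept), "r": float(r), "p": float(p),
            "stderr": float(stderr)}
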