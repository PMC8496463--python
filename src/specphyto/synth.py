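"""Synthetic field-campaign generator with known ground truth.

Emulates the four measurement streams of a multi-wavelength variable
fluorescence campaign: rapid light curves (triplicate per station and
wavelength), O-I1 induction kinetics (six subsamples x three repeats),
vertical light profiles (PAR + hyperspectral) and density profiles, together
with the station table of abiotic and biotic variables.

The population wavelength trends of the generated photosynthetic parameters
default to the field-campaign scale (Fv/Fm around 0.61 falling slightly with
wavelength, Sigma(II) from ~6 to ~1.6 nm2, rising relative alpha and Ek,
falling NPQ).  Per-station departures are Gaussian random intercepts and
slopes.  Every generated value is stored in the truth table so the full
downstream pipeline can be verified against it; with all noise terms at zero
the round trip is exact up to fitting tolerances.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import TAU_MAX, TAU_MIN, WAVELENGTHS, WL_ORIGIN
from .errors import ValidationError
from .light import DensityProfile, LightProfile, StationRecord
from .photo import PARII_FACTOR, InductionCurve, RapidLightCurve, ep_coefficients

# 14-step actinic ladder, umol quanta m-2 s-1, dark step first.
DEFAULT_PAR_STEPS = (
    0, 25, 50, 100, 150, 225, 325, 450, 625, 850, 1150, 1450, 1750, 2000)

# Actinic intensity driving the O-I1 rise.
INDUCTION_PAR = 1000.0
INDUCTION_DURATION = 1e-3   # s
INDUCTION_DT = 2e-5         # s

# Population wavelength trends (intercept at 440 nm, slope per nm).
DEFAULT_POPULATION = {
    "fvfm": (0.61, -0.00012),
    "sigma_nm2": (6.08, -0.0241),
    "r_alpha": (0.21, 0.00029),
    "r_ek": (200.94, 1.39),
    "r_eop": (1998.9, -1.69),
    "npq_max": (3.155, -0.01402),
}

# Per-station Gaussian departures (intercept sd, slope sd).
DEFAULT_RANDOM_SDS = {
    "fvfm": (0.015, 0.0),
    "sigma_nm2": (0.12, 0.0),
    "r_alpha": (0.006, 0.0),
    "r_ek": (12.0, 0.25),
    "r_eop": (80.0, 0.0),
    "npq_max": (0.15, 0.0),
}

# Half-saturation of the NPQ light response (umol quanta m-2 s-1).
DEFAULT_NPQ_K_HALF = 751.8

# Additive fluorescence noise (relative units, Fm ~ 1) and multiplicative
# light-profile noise.  The measuring protocol tunes gain for a good
# signal-to-noise ratio at Ft ~ 0.5, so fluorescence noise is well below 1%
# of Fm; larger values make the yield at saturating light (Y ~ 0.05)
# meaningless.
DEFAULT_NOISE = {"rlc": 0.003, "induction": 0.003, "light": 0.03}


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic campaign.

    ``params`` has one row per station x wavelength with the true values of
    every derived photophysiological parameter (relative and absolute units,
    EP triple, NPQ parameters, tau).  ``stations`` holds the true light-field
    and abiotic settings per station.
    """

    seed: int
    wavelengths: tuple
    population: dict
    random_effect_sds: dict
    noise_sd: dict
    npq_k_half: float
    params: pd.DataFrame
    stations: pd.DataFrame
    par_steps: tuple = DEFAULT_PAR_STEPS
    fm_dark: float = 1.0

    def validate(self) -> None:
        p = self.params
        for col in ("ep_a", "ep_b", "ep_c"):
            if not np.all(p[col] > 0):
                raise ValidationError(f"non-positive EP coefficient in field {col}")
        if not np.all((p["fvfm"] > 0) & (p["fvfm"] <= 0.7)):
            raise ValidationError("field fvfm outside (0, 0.7]")
        if not np.all((p["tau"] > TAU_MIN) & (p["tau"] < TAU_MAX)):
            raise ValidationError(
                f"field tau outside ({TAU_MIN:g}, {TAU_MAX:g}) s")


@dataclass
class CampaignBundle:
    """Raw-table bundle produced by :func:`simulate_campaign`."""

    truth: SyntheticTruth
    rlcs: list                 # RapidLightCurve
    inductions: list           # InductionCurve
    light_profiles: list       # LightProfile (PAR cast + spectral casts)
    density_profiles: list     # DensityProfile
    station_records: list      # StationRecord (abiotic/biotic truth echo)

    def rlc_frame(self) -> pd.DataFrame:
        rows = []
        for rlc in self.rlcs:
            for k in range(rlc.par.size):
                rows.append((rlc.station, rlc.wavelength, rlc.replicate, k,
                             rlc.par[k], rlc.f[k], rlc.fm_prime[k]))
        return pd.DataFrame(rows, columns=[
            "station", "wavelength", "replicate", "step", "par", "f", "fm_prime"])

    def induction_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.inductions:
            for t, fl in zip(c.times, c.fluorescence):
                rows.append((c.station, c.wavelength, c.subsample, c.repeat,
                             c.actinic_par, t, fl))
        return pd.DataFrame(rows, columns=[
            "station", "wavelength", "subsample", "repeat",
            "actinic_par", "time_s", "fluorescence"])

    def light_frame(self) -> pd.DataFrame:
        rows = []
        for prof in self.light_profiles:
            if prof.par is not None:
                for z, v in zip(prof.depths, prof.par):
                    rows.append((prof.station, float(z), prof.replicate, "PAR", v))
            if prof.spectral is not None:
                for i, z in enumerate(prof.depths):
                    for wl, v in zip(prof.wavelengths, prof.spectral[i]):
                        rows.append((prof.station, float(z), prof.replicate,
                                     f"{wl:g}", v))
        return pd.DataFrame(rows, columns=[
            "station", "depth_m", "replicate", "wavelength_nm", "value"])

    def density_frame(self) -> pd.DataFrame:
        rows = []
        for prof in self.density_profiles:
            for z, rho in zip(prof.depths, prof.density):
                rows.append((prof.station, float(z), rho))
        return pd.DataFrame(rows, columns=["station", "depth_m", "density"])

    def station_frame(self) -> pd.DataFrame:
        from .light import records_to_frame
        return records_to_frame(self.station_records)


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _station_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def generate_truth(
    seed: int,
    n_stations: int = 19,
    wavelengths: tuple = WAVELENGTHS,
    population: dict | None = None,
    random_effect_sds: dict | None = None,
    noise_sd: dict | None = None,
    npq_k_half: float = DEFAULT_NPQ_K_HALF,
    stratified_fraction: float = 0.35,
    ek_zeu_coupling: float = 2.0,
) -> SyntheticTruth:
    """Draw a ground-truth campaign configuration.

    Per-station parameter values follow the population line plus Gaussian
    station effects, then are projected into the jointly feasible region
    (2 alpha <= Fv/Fm so yields stay below Fv/Fm; Ek <= 0.45 Eop so the
    EP coefficient b stays positive).
    """
    if n_stations < 2:
        raise ValidationError("field n_stations must be >= 2")
    bad = set(wavelengths) - set(WAVELENGTHS)
    if bad:
        raise ValidationError(
            f"field wavelengths contains unknown values {sorted(bad)}; "
            f"allowed: {WAVELENGTHS}")
    pop = dict(DEFAULT_POPULATION, **(population or {}))
    sds = dict(DEFAULT_RANDOM_SDS, **(random_effect_sds or {}))
    noise = dict(DEFAULT_NOISE, **(noise_sd or {}))

    rng = np.random.default_rng(seed)
    stations = _station_ids(n_stations)

    # Station random effects, one (intercept, slope) pair per parameter.
    re = {
        name: rng.normal(0.0, 1.0, size=(n_stations, 2))
        * np.asarray(sds[name])
        for name in pop
    }

    st_frame = _draw_station_settings(rng, stations, stratified_fraction)

    # Couple the Ek station departures to light availability: clearer water
    # (deeper euphotic layer) pushes a station's Ek above the population
    # line, emulating photoacclimation to the light climate.
    z_eu = 4.6 / st_frame["kd_par"].to_numpy()
    z_score = (z_eu - z_eu.mean()) / z_eu.std()
    re["r_ek"][:, 0] += ek_zeu_coupling * sds["r_ek"][0] * z_score

    rows = []
    for i, st in enumerate(stations):
        for wl in wavelengths:
            wlt = wl - WL_ORIGIN

            def value(name):
                b0, b1 = pop[name]
                return b0 + b1 * wlt + re[name][i, 0] + re[name][i, 1] * wlt

            fvfm = float(np.clip(value("fvfm"), 0.30, 0.70))
            sigma = float(max(value("sigma_nm2"), 0.30))
            alpha = float(np.clip(value("r_alpha"), 0.02, 0.47 * fvfm))
            eop = float(max(value("r_eop"), 600.0))
            ek = float(np.clip(value("r_ek"), 20.0, 0.45 * eop))
            etrmax = ek * alpha
            a, b, c = ep_coefficients(alpha, etrmax, eop)
            npq_max = float(max(value("npq_max"), 0.05))
            tau = 1.0 / (sigma * PARII_FACTOR * INDUCTION_PAR)
            kappa = sigma * PARII_FACTOR
            npq300 = npq_max * 300.0 / (npq_k_half + 300.0)
            npq1200 = npq_max * 1200.0 / (npq_k_half + 1200.0)
            rows.append({
                "station": st, "wavelength": wl, "fvfm": fvfm,
                "sigma_nm2": sigma, "tau": tau,
                "r_alpha": alpha, "r_etrmax": etrmax, "r_ek": ek, "r_eop": eop,
                "alpha_ii": 2 * alpha / fvfm,
                "etrmax_ii": 2 * kappa * etrmax / fvfm,
                "ek_ii": kappa * ek, "eop_ii": kappa * eop,
                "npq_max": npq_max, "k_half": npq_k_half,
                "npq300": npq300, "npq1200": npq1200,
                "ep_a": a, "ep_b": b, "ep_c": c,
            })
    params = pd.DataFrame(rows)

    truth = SyntheticTruth(
        seed=seed, wavelengths=tuple(wavelengths), population=pop,
        random_effect_sds=sds, noise_sd=noise, npq_k_half=npq_k_half,
        params=params, stations=st_frame)
    truth.validate()
    return truth


def _draw_station_settings(rng, stations, stratified_fraction):
    """Per-station light field and abiotic/biotic settings."""
    st_rows = []
    for i, st in enumerate(stations):
        kd = float(np.exp(rng.uniform(np.log(0.08), np.log(0.45))))
        i0 = float(rng.uniform(300.0, 1500.0))
        bottom = float(np.round(rng.uniform(15.0, 60.0) * 2) / 2)
        stratified = bool(rng.random() < stratified_fraction)
        if stratified:
            z_mix = float(np.round(rng.uniform(5.0, min(20.0, bottom - 3.0)) * 2) / 2)
            density_step = float(rng.uniform(0.15, 0.35))
        else:
            z_mix = bottom
            density_step = 0.0
        st_rows.append({
            "station": st, "kd_par": kd, "i0": i0, "bottom_depth": bottom,
            "stratified": stratified, "z_umixl": z_mix,
            "density_step": density_step, "rho_surface": float(rng.uniform(1025.0, 1027.0)),
            "spec_blue": float(rng.uniform(0.6, 1.2)),
            "spec_green": float(rng.uniform(1.2, 1.8)),
            "spec_red": float(rng.uniform(0.5, 1.0)),
            "tss": float(rng.uniform(0.0, 12.0)),
            "salinity": float(rng.uniform(33.0, 35.3)),
            "temperature": float(rng.uniform(9.5, 12.0)),
            "din": float(np.exp(rng.normal(np.log(3.0), 0.8))),
            "po4": float(rng.uniform(0.1, 1.5)),
            "si": float(rng.uniform(0.3, 2.0)),
            "biomass_brown": float(np.exp(rng.normal(np.log(3.0), 0.4))),
            "biomass_haptophytes": float(np.exp(rng.normal(np.log(2.0), 0.4))),
            "biomass_cryptophytes": float(np.exp(rng.normal(np.log(0.5), 0.4))),
            "biomass_cyanobacteria": float(np.exp(rng.normal(np.log(0.2), 0.4))),
        })
    return pd.DataFrame(st_rows).set_index("station")


# ---------------------------------------------------------------------------
# Individual stream simulators
# ---------------------------------------------------------------------------

def simulate_induction(
    tau: float,
    f_o: float,
    f_i1: float,
    par: float = INDUCTION_PAR,
    dt: float = INDUCTION_DT,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    duration: float = INDUCTION_DURATION,
    wavelength: int = 440,
    subsample: int = 1,
    repeat: int = 1,
    station: str | None = None,
) -> InductionCurve:
    """One O-I1 rise: F(t) = Fo + (Fi1 - Fo)(1 - exp(-t/tau)).

    The single saturating exponential is the package's measurement model of
    light-driven QA reduction during a 1 ms actinic pulse.
    """
    if not tau > 0:
        raise ValidationError("tau must be > 0")
    if not 0 < f_o < f_i1:
        raise ValidationError("require 0 < f_o < f_i1")
    if dt >= duration:
        raise ValidationError("dt must be smaller than the pulse duration")
    if dt > 5e-5:
        raise ValidationError("dt must be <= 50 us")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    f = f_o + (f_i1 - f_o) * (1.0 - np.exp(-t / tau))
    if noise_sd > 0:
        f = np.maximum(f + rng.normal(0.0, noise_sd, size=f.shape), 1e-6)
    return InductionCurve(wavelength=wavelength, times=t, fluorescence=f,
                          actinic_par=par, subsample=subsample, repeat=repeat,
                          station=station)


def simulate_rlc(
    ep: tuple[float, float, float],
    fvfm: float,
    npq_model,
    par_steps=DEFAULT_PAR_STEPS,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    fm: float = 1.0,
    wavelength: int = 440,
    replicate: int = 1,
    station: str | None = None,
) -> RapidLightCurve:
    """One rapid light curve constructed from an Eilers-Peeters truth.

    Steps carry (PAR, F, Fm') with Fm'(E) = Fm / (1 + NPQ(E)),
    Y(E) = r.ETR_EP(E) / (0.5 E) for E > 0, Y(0) = Fv/Fm and
    F = Fm' (1 - Y).  ``npq_model`` is any callable E -> NPQ(E) >= 0.
    """
    a, b, c = ep
    if min(a, b, c) <= 0:
        raise ValidationError(f"non-positive EP coefficient in field ep={ep}")
    par = np.asarray(par_steps, dtype=float)
    if par[0] != 0:
        raise ValidationError("first PAR step must be 0 (dark)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    y = np.empty_like(par)
    y[0] = fvfm
    e = par[1:]
    y[1:] = 2.0 / (a * e**2 + b * e + c)   # = (E/(aE^2+bE+c)) / (0.5 E)
    if np.any(y <= 0) or np.any(y >= 1) or np.any(y[1:] > fvfm * (1 + 1e-12)):
        raise ValidationError(
            "inconsistent truth: implied Y(II) outside (0, 1) or above Fv/Fm")

    npq = np.asarray([0.0] + [float(npq_model(ei)) for ei in e])
    if np.any(npq < 0):
        raise ValidationError("npq_model must be non-negative")
    fm_prime = fm / (1.0 + npq)
    f = fm_prime * (1.0 - y)
    if noise_sd > 0:
        fm_prime = np.maximum(fm_prime + rng.normal(0, noise_sd, fm_prime.shape),
                              1e-3)
        f = np.clip(f + rng.normal(0, noise_sd, f.shape), 1e-4,
                    fm_prime * (1 - 1e-6))
    return RapidLightCurve(wavelength=wavelength, replicate=replicate,
                           par=par, f=f, fm_prime=fm_prime, station=station)


def _mm_model(npq_max: float, k_half: float):
    return lambda e: npq_max * e / (k_half + e)


def _spectrum_shape(wavelengths: np.ndarray, blue: float, green: float,
                    red: float) -> np.ndarray:
    """Smooth surface spectrum through band-level control points."""
    ctrl_wl = np.array([400.0, 450.0, 530.0, 610.0, 700.0])
    ctrl_v = np.array([blue, blue, green, red, red])
    return np.interp(wavelengths, ctrl_wl, ctrl_v)


def simulate_light_profile(
    settings: pd.Series,
    station: str,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
) -> list[LightProfile]:
    """PAR cast plus triplicate hyperspectral casts for one station."""
    kd, i0 = settings["kd_par"], settings["i0"]
    bottom = settings["bottom_depth"]
    depths = np.arange(0.0, bottom + 1e-9, 1.0)
    par = i0 * np.exp(-kd * depths)
    if noise_sd > 0:
        par = par * np.exp(rng.normal(0, noise_sd, par.shape))
    profiles = [LightProfile(depths=depths, par=par, replicate=1, station=station)]

    wl = np.arange(400.0, 700.0 + 1e-9, 3.0)
    s0 = _spectrum_shape(wl, settings["spec_blue"], settings["spec_green"],
                         settings["spec_red"])
    # Spectral attenuation: strongest in red, weakest in green.
    kd_spec = kd * np.interp(wl, [400.0, 530.0, 700.0], [1.2, 0.9, 1.5])
    spec_depths = np.arange(0.5, 2.51, 0.5)
    for rep in (1, 2, 3):
        spectral = s0[None, :] * np.exp(-kd_spec[None, :] * spec_depths[:, None])
        if noise_sd > 0:
            spectral = spectral * np.exp(
                rng.normal(0, noise_sd, spectral.shape))
        profiles.append(LightProfile(
            depths=spec_depths, wavelengths=wl, spectral=spectral,
            replicate=rep, station=station))
    return profiles


def simulate_density_profile(settings: pd.Series, station: str) -> DensityProfile:
    """Two-layer density profile with the true pycnocline at z_umixl."""
    bottom = settings["bottom_depth"]
    depths = np.arange(0.0, bottom + 1e-9, 0.5)
    rho = np.full_like(depths, settings["rho_surface"])
    if settings["stratified"]:
        rho = rho + settings["density_step"] * (depths >= settings["z_umixl"])
    return DensityProfile(depths=depths, density=rho, station=station)


# ---------------------------------------------------------------------------
# Campaign assembly
# ---------------------------------------------------------------------------

def simulate_campaign(
    truth: SyntheticTruth | None = None,
    n_stations: int = 19,
    wavelengths: tuple = WAVELENGTHS,
    seed: int = 0,
    **truth_kwargs,
) -> CampaignBundle:
    """Generate the full raw-table bundle for one campaign.

    Either pass a prebuilt ``truth`` or let one be drawn from ``seed``.
    Every station gets triplicate RLCs per wavelength, six induction
    subsamples (three repeats each) per wavelength, one PAR profile with
    triplicate spectral casts, and one density profile.
    """
    if truth is None:
        truth = generate_truth(seed, n_stations=n_stations,
                               wavelengths=wavelengths, **truth_kwargs)
    truth.validate()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x5eed]))
    noise = truth.noise_sd

    rlcs, inductions, light_profiles, density_profiles, records = [], [], [], [], []
    indexed = truth.params.set_index(["station", "wavelength"])

    for st, settings in truth.stations.iterrows():
        for wl in truth.wavelengths:
            row = indexed.loc[(st, wl)]
            npq_model = _mm_model(row["npq_max"], row["k_half"])
            for rep in (1, 2, 3):
                rlcs.append(simulate_rlc(
                    (row["ep_a"], row["ep_b"], row["ep_c"]), row["fvfm"],
                    npq_model, truth.par_steps, noise_sd=noise["rlc"],
                    seed=rng, fm=truth.fm_dark, wavelength=wl,
                    replicate=rep, station=st))
            f_i1 = truth.fm_dark * 0.75
            f_o = truth.fm_dark * (1.0 - row["fvfm"]) * 0.9
            for sub in range(1, 7):
                for rep in (1, 2, 3):
                    inductions.append(simulate_induction(
                        row["tau"], f_o, f_i1, par=INDUCTION_PAR,
                        noise_sd=noise["induction"], seed=rng,
                        wavelength=wl, subsample=sub, repeat=rep, station=st))
        light_profiles.extend(simulate_light_profile(
            settings, st, rng, noise_sd=noise["light"]))
        density_profiles.append(simulate_density_profile(settings, st))
        records.append(_station_record(st, settings))

    return CampaignBundle(truth=truth, rlcs=rlcs, inductions=inductions,
                          light_profiles=light_profiles,
                          density_profiles=density_profiles,
                          station_records=records)


def _station_record(station: str, s: pd.Series) -> StationRecord:
    """Truth-echo station record with exact light-climate descriptors."""
    from .light import averaged_light, band_ratios, euphotic_depth

    kd = float(s["kd_par"])
    noise_free = simulate_light_profile(s, station, np.random.default_rng(0),
                                        noise_sd=0.0)
    rb, gb, gr = band_ratios([p for p in noise_free if p.spectral is not None])
    return StationRecord(
        ratio_rb=rb, ratio_gb=gb, ratio_gr=gr,
        station=station, tss=float(s["tss"]), salinity=float(s["salinity"]),
        temperature=float(s["temperature"]), din=float(s["din"]),
        po4=float(s["po4"]), si=float(s["si"]),
        par_2m=float(s["i0"] * np.exp(-2.0 * kd)),
        kd_par=kd, z_eu=euphotic_depth(kd), z_umixl=float(s["z_umixl"]),
        stratified=bool(s["stratified"]),
        e_avg=averaged_light(float(s["i0"]), kd, float(s["z_umixl"])),
        biomass={
            "brown": float(s["biomass_brown"]),
            "haptophytes": float(s["biomass_haptophytes"]),
            "cryptophytes": float(s["biomass_cryptophytes"]),
            "cyanobacteria": float(s["biomass_cyanobacteria"]),
        })
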