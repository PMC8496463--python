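"""Pipeline orchestration: raw streams -> parameters -> LMEM -> PTA -> RDA.

``run_pipeline`` executes the full chain on either a synthetic campaign
(generated from the config seed) or a directory of raw CSV streams, writing
every stage's outputs plus a manifest to a run directory when requested.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .constants import PTA_PARAMETERS
from .errors import SpecphytoError, ValidationError
from .io import (read_density_profiles, read_light_profiles, read_raw_pam,
                 write_csv)
from .light import (LightProfile, attenuation_coefficient, averaged_light,
                    band_ratios, euphotic_depth, mixed_layer)
from .ordination import forward_select
from .photo import (InductionCurve, aggregate_tau, derive_photo_params,
                    index_regression, params_to_frame, sigma_psii,
                    spectral_indices)
from .pta import build_stack, pta
from .synth import simulate_campaign
from .trend import fit_all

log = logging.getLogger("specphyto")

ABIOTIC_CANDIDATES = [
    "tss", "salinity", "temperature", "din", "po4", "si", "par_2m",
    "kd_par", "z_eu", "z_umixl", "e_avg", "ratio_rb", "ratio_gb", "ratio_gr",
]
BIOTIC_CANDIDATES = [
    "biomass_brown", "biomass_haptophytes", "biomass_cryptophytes",
    "biomass_cyanobacteria",
]


@dataclass
class PipelineResult:
    config: PipelineConfig
    stations: pd.DataFrame
    params: pd.DataFrame
    trend_table: pd.DataFrame
    detrended: pd.DataFrame
    pta_result: object
    rda_results: dict          # wavelength -> {"abiotic": RDAResult, ...}
    indices: pd.DataFrame
    regressions: list
    manifest: dict = field(default_factory=dict)
    truth: object = None


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def station_records_from_profiles(
    light_profiles: list,
    density_profiles: list,
    station_table: pd.DataFrame,
) -> pd.DataFrame:
    """Recompute the light-climate descriptors from the raw profiles.

    ``station_table`` supplies the directly measured fields (TSS, CTD
    surface values, nutrients, biomasses); Kd(PAR), Zeu, Zumixl,
    stratification, Eavg and the band ratios are derived here.
    """
    by_station_par: dict[str, LightProfile] = {}
    by_station_spec: dict[str, list] = {}
    for prof in light_profiles:
        if prof.par is not None:
            by_station_par[prof.station] = prof
        if prof.spectral is not None:
            by_station_spec.setdefault(prof.station, []).append(prof)
    by_station_rho = {p.station: p for p in density_profiles}

    rows = []
    for st in station_table.index:
        rec = station_table.loc[st].to_dict()
        rec["station"] = st
        par_prof = by_station_par.get(st)
        if par_prof is not None:
            kd = attenuation_coefficient(par_prof)
            rec["kd_par"] = kd
            rec["z_eu"] = euphotic_depth(kd)
            i0 = float(par_prof.par[0])
            rho_prof = by_station_rho.get(st)
            if rho_prof is not None:
                z_umixl, stratified = mixed_layer(rho_prof)
                rec["z_umixl"] = z_umixl
                rec["stratified"] = stratified
                rec["e_avg"] = averaged_light(i0, kd, z_umixl)
        spec = by_station_spec.get(st)
        if spec:
            rb, gb, gr = band_ratios(spec)
            rec.update(ratio_rb=rb, ratio_gb=gb, ratio_gr=gr)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("station")


def sigma_table(inductions: list[InductionCurve]) -> pd.DataFrame:
    """Per station x wavelength: tau (mean over subsamples) and Sigma(II)."""
    groups: dict[tuple, list] = {}
    for c in inductions:
        groups.setdefault((c.station, c.wavelength), []).append(c)
    rows = []
    for (st, wl), curves in sorted(groups.items()):
        tau, tau_var = aggregate_tau(curves)
        par = curves[0].actinic_par
        rows.append({
            "station": st, "wavelength": wl, "tau": tau, "tau_var": tau_var,
            "sigma_nm2": sigma_psii(tau, par),
            "sigma_var": (sigma_psii(tau, par) / tau) ** 2 * tau_var
            if np.isfinite(tau_var) else np.nan,
        })
    return pd.DataFrame(rows)


def derive_all_params(rlcs: list, sigmas: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """PhotoParamSet table from grouped RLCs and the Sigma(II) table."""
    sig = sigmas.set_index(["station", "wavelength"])
    groups: dict[tuple, list] = {}
    for rlc in rlcs:
        groups.setdefault((rlc.station, rlc.wavelength), []).append(rlc)
    params = []
    for (st, wl), curves in sorted(groups.items()):
        if (st, wl) not in sig.index:
            log.warning("no Sigma(II) for station=%s wavelength=%s; skipped",
                        st, wl)
            continue
        row = sig.loc[(st, wl)]
        params.append(derive_photo_params(
            curves, float(row["sigma_nm2"]),
            sigma_var=float(row["sigma_var"]), seed=seed))
    return params_to_frame(params)


def params_long_table(params: pd.DataFrame, ek_unit: str = "absolute") -> pd.DataFrame:
    """Melt the parameter table into the 8-parameter long layout.

    The generic "ek" column carries r_ek or ek_ii according to ``ek_unit``.
    """
    df = params.copy()
    df["ek"] = df["ek_ii"] if ek_unit == "absolute" else df["r_ek"]
    value_cols = [c for c in PTA_PARAMETERS]
    long = df.melt(id_vars=["station", "wavelength"], value_vars=value_cols,
                   var_name="parameter", value_name="value")
    return long


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _load_raw(raw_dir: Path):
    rlcs, rejects = read_raw_pam(raw_dir / "rlc.csv")
    if rejects.shape[0]:
        log.warning("raw PAM table: %d rejected rows", rejects.shape[0])
    ind = pd.read_csv(raw_dir / "induction.csv")
    inductions = []
    keys = ["station", "wavelength", "subsample", "repeat", "actinic_par"]
    for key, g in ind.groupby(keys, sort=False):
        st, wl, sub, rep, par = key
        g = g.sort_values("time_s")
        inductions.append(InductionCurve(
            wavelength=int(wl), times=g["time_s"].to_numpy(),
            fluorescence=g["fluorescence"].to_numpy(), actinic_par=float(par),
            subsample=int(sub), repeat=int(rep), station=str(st)))
    light_profiles = read_light_profiles(raw_dir / "light.csv")
    density_profiles = read_density_profiles(raw_dir / "density.csv")
    station_table = pd.read_csv(raw_dir / "stations.csv").set_index("station")
    return rlcs, inductions, light_profiles, density_profiles, station_table


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute derive -> fit -> LMEM/detrend -> PTA -> RDA -> indices."""
    config.validate()
    truth = None
    if config.raw_dir:
        stage = "read-raw"
        rlcs, inductions, light_profiles, density_profiles, station_table = \
            _load_raw(Path(config.raw_dir))
    else:
        stage = "simulate"
        bundle = simulate_campaign(
            n_stations=config.n_stations,
            wavelengths=tuple(config.wavelengths),
            seed=config.seed, noise_sd=config.noise_sd or None)
        truth = bundle.truth
        rlcs, inductions = bundle.rlcs, bundle.inductions
        light_profiles = bundle.light_profiles
        density_profiles = bundle.density_profiles
        station_table = bundle.station_frame().drop(
            columns=["kd_par", "z_eu", "z_umixl", "stratified", "e_avg",
                     "ratio_rb", "ratio_gb", "ratio_gr"], errors="ignore")

    try:
        stage = "light-climate"
        stations = station_records_from_profiles(
            light_profiles, density_profiles, station_table)

        stage = "sigma"
        sigmas = sigma_table(inductions)

        stage = "derive-params"
        params = derive_all_params(rlcs, sigmas, seed=config.seed)

        stage = "population-trend"
        long = params_long_table(params, config.ek_unit)
        trend_table, detrended = fit_all(long)

        stage = "pta"
        stack = build_stack(detrended, scale=config.pta_scale)
        for st in stack.dropped_stations:
            log.warning("PTA: station %s dropped (incomplete cells)", st)
        pta_result = pta(stack)

        stage = "rda"
        rda_results = {}
        wide = detrended.pivot_table(index="station",
                                     columns=["wavelength", "parameter"],
                                     values="detrended")
        for wl in stack.wavelengths:
            y = wide[wl].dropna()
            expl = stations.loc[y.index]
            pools = (
                {"all": ABIOTIC_CANDIDATES + BIOTIC_CANDIDATES}
                if config.combined_candidate_pool
                else {"abiotic": ABIOTIC_CANDIDATES, "biotic": BIOTIC_CANDIDATES})
            rda_results[wl] = {
                name: forward_select(
                    y, expl[[c for c in cols if c in expl.columns]],
                    alpha=config.selection_alpha, nperm=config.selection_nperm,
                    seed=config.seed + wl, response_id=f"{wl}nm-{name}")
                for name, cols in pools.items()
            }

        stage = "indices"
        indices = spectral_indices(params, stations)
        regressions = []
        for x, y_col, strat in (
                ("zeu_over_zumixl", "ek_r_440_over_eavg", True),
                ("zeu_over_zumixl", "ek_ii_440_over_eavg", True),
                ("ratio_rb", "ek_ii_625_440", None),
                ("tss", "ek_ii_625_440", None)):
            try:
                regressions.append(index_regression(indices, x, y_col,
                                                    stratified=strat))
            except ValidationError as exc:
                log.warning("regression %s ~ %s skipped: %s", y_col, x, exc)
    except SpecphytoError as exc:
        raise type(exc)(f"stage '{stage}': {exc}") from exc

    manifest = _manifest(config)
    result = PipelineResult(
        config=config, stations=stations, params=params,
        trend_table=trend_table, detrended=detrended, pta_result=pta_result,
        rda_results=rda_results, indices=indices, regressions=regressions,
        manifest=manifest, truth=truth)
    if out_dir is not None:
        write_result(result, Path(out_dir))
    return result


def _manifest(config: PipelineConfig) -> dict:
    cfg_yaml = config.to_yaml()
    return {
        "software": "specphyto",
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "config": cfg_yaml,
        "seed": config.seed,
    }


def write_result(result: PipelineResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_csv(result.stations.reset_index(), out_dir / "stations.csv")
    write_csv(result.params, out_dir / "params.csv")
    write_csv(result.trend_table, out_dir / "trend.csv")
    write_csv(result.detrended, out_dir / "detrended.csv")
    write_csv(result.indices.reset_index(), out_dir / "indices.csv")
    with open(out_dir / "pta.json", "w") as fh:
        json.dump(result.pta_result.to_dict(), fh, indent=1)
    with open(out_dir / "rda.json", "w") as fh:
        json.dump({str(wl): {name: res.to_dict() for name, res in sets.items()}
                   for wl, sets in result.rda_results.items()}, fh, indent=1)
    with open(out_dir / "regressions.json", "w") as fh:
        json.dump(result.regressions, fh, indent=1)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1)


def write_campaign(bundle, out_dir: Path) -> None:
    """Serialise a synthetic campaign to the raw CSV stream dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_csv(bundle.rlc_frame(), out_dir / "rlc.csv")
    write_csv(bundle.induction_frame(), out_dir / "induction.csv")
    write_csv(bundle.light_frame(), out_dir / "light.csv")
    write_csv(bundle.density_frame(), out_dir / "density.csv")
    write_csv(bundle.station_frame().reset_index(), out_dir / "stations.csv")
    write_csv(bundle.truth.params, out_dir / "truth_params.csv")
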