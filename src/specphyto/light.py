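"""Underwater light-climate descriptors.

Turns vertical PAR, hyperspectral irradiance and density profiles into the
station-level descriptors used as explanatory variables downstream: the
diffuse attenuation coefficient Kd(PAR), euphotic depth Zeu, upper-mixed-layer
depth Zumixl with a stratification flag, the vertically averaged irradiance
Eavg in the mixed layer, and the three spectral-band quality ratios
R/B, G/B and G/R.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    BAND_BLUE,
    BAND_GREEN,
    BAND_RED,
    EUPHOTIC_LN_FRACTION,
    STRATIFICATION_THRESHOLD,
    SURFACE_BAND,
)
from .errors import ValidationError


@dataclass
class LightProfile:
    """A vertical light profile for one station.

    Parameters
    ----------
    depths : array of m, strictly increasing, >= 0
    par : PAR (umol quanta m-2 s-1) at each depth; may be None if only
        spectral data were recorded.
    wavelengths : spectral grid in nm (typically 400-700 at 3 nm), or None.
    spectral : matrix (n_depths x n_wavelengths) of downwelling quantum
        irradiance (umol quanta m-2 s-1 nm-1), or None.
    replicate : cast replicate id.
    """

    depths: np.ndarray
    par: np.ndarray | None = None
    wavelengths: np.ndarray | None = None
    spectral: np.ndarray | None = None
    replicate: int = 1
    station: str | None = None

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 1 or self.depths.size < 1:
            raise ValidationError("depths must be a 1-d array")
        if np.any(np.diff(self.depths) <= 0):
            raise ValidationError("depths must be strictly increasing")
        if np.any(self.depths < 0):
            raise ValidationError("depths must be non-negative")
        if self.par is not None:
            self.par = np.asarray(self.par, dtype=float)
            if self.par.shape != self.depths.shape:
                raise ValidationError("par must match depths in length")
            if np.any(self.par < 0):
                raise ValidationError("irradiance must be non-negative")
        if self.spectral is not None:
            self.spectral = np.atleast_2d(np.asarray(self.spectral, dtype=float))
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.spectral.shape != (self.depths.size, self.wavelengths.size):
                raise ValidationError("spectral must be (n_depths, n_wavelengths)")
            if np.any(self.spectral < 0):
                raise ValidationError("irradiance must be non-negative")


@dataclass
class DensityProfile:
    """A vertical seawater density profile (kg m-3) for one station."""

    depths: np.ndarray
    density: np.ndarray
    station: str | None = None

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValidationError("depths must be strictly increasing")
        if self.density.shape != self.depths.shape:
            raise ValidationError("density must match depths in length")


@dataclass
class StationRecord:
    """Explanatory variables for one sampling location."""

    station: str
    tss: float = np.nan          # time since sunrise, h
    salinity: float = np.nan     # PSU
    temperature: float = np.nan  # deg C
    din: float = np.nan          # umol L-1
    po4: float = np.nan          # umol L-1
    si: float = np.nan           # umol L-1
    par_2m: float = np.nan       # umol quanta m-2 s-1
    kd_par: float = np.nan       # m-1
    z_eu: float = np.nan         # m
    z_umixl: float = np.nan      # m
    stratified: bool = False
    e_avg: float = np.nan        # umol quanta m-2 s-1
    ratio_rb: float = np.nan
    ratio_gb: float = np.nan
    ratio_gr: float = np.nan
    biomass: dict = field(default_factory=dict)  # group -> ug Chla L-1

    def to_dict(self) -> dict:
        d = {
            "station": self.station,
            "tss": self.tss,
            "salinity": self.salinity,
            "temperature": self.temperature,
            "din": self.din,
            "po4": self.po4,
            "si": self.si,
            "par_2m": self.par_2m,
            "kd_par": self.kd_par,
            "z_eu": self.z_eu,
            "z_umixl": self.z_umixl,
            "stratified": self.stratified,
            "e_avg": self.e_avg,
            "ratio_rb": self.ratio_rb,
            "ratio_gb": self.ratio_gb,
            "ratio_gr": self.ratio_gr,
        }
        for group, value in self.biomass.items():
            d[f"biomass_{group}"] = value
        return d


def records_to_frame(records: list[StationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records]).set_index("station")


def attenuation_coefficient(profile: LightProfile) -> float:
    """Diffuse attenuation coefficient Kd(PAR), m-1.

    With exactly two usable depths this is [ln(I0) - ln(Iz)] / Z.  With more
    depths the negative least-squares slope of ln(PAR) on depth is returned,
    which reduces to the two-point form when only two depths are available.
    """
    if profile.par is None:
        raise ValidationError("profile has no PAR data")
    usable = profile.par > 0
    if np.count_nonzero(usable) < profile.par.size:
        raise ValidationError("all PAR values among used depths must be > 0")
    z = profile.depths
    if z.size < 2:
        raise ValidationError("need at least 2 depths to fit attenuation")
    log_par = np.log(profile.par)
    slope = np.polyfit(z, log_par, 1)[0]
    return float(-slope)


def euphotic_depth(kd_par: float) -> float:
    """Euphotic depth Zeu = 4.6 / Kd(PAR), the 1% light depth, in m."""
    if not kd_par > 0:
        raise ValidationError("kd_par must be > 0 (degenerate profile?)")
    return EUPHOTIC_LN_FRACTION / kd_par


def averaged_light(i0: float, kd_par: float, z_umixl: float) -> float:
    """Vertically averaged irradiance in the mixed layer.

    Eavg = I0 (1 - exp(-Kd Zumixl)) / (Kd Zumixl); tends to I0 as the
    optical depth Kd*Zumixl tends to 0.
    """
    if not (i0 > 0 and kd_par > 0 and z_umixl > 0):
        raise ValidationError("i0, kd_par and z_umixl must all be > 0")
    tau = kd_par * z_umixl
    # -expm1 keeps the small-optical-depth limit accurate.
    return float(i0 * (-np.expm1(-tau)) / tau)


def mixed_layer(
    profile: DensityProfile,
    surface_band: tuple[float, float] = SURFACE_BAND,
    threshold: float = STRATIFICATION_THRESHOLD,
) -> tuple[float, bool]:
    """Upper-mixed-layer depth and stratification flag.

    The column is stratified if the bottom density exceeds the 0-1.5 m
    surface-layer mean by strictly more than 0.086 kg m-3 (the boundary value
    counts as mixed).  When mixed, Zumixl is the bottom depth; when
    stratified, Zumixl is the shallowest depth where the density excess over
    the surface mean first exceeds the threshold.
    """
    lo, hi = surface_band
    in_band = (profile.depths >= lo) & (profile.depths <= hi)
    if not np.any(in_band):
        raise ValidationError("no depths within the surface band")
    surface_mean = float(np.mean(profile.density[in_band]))
    bottom_depth = float(profile.depths[-1])
    excess = profile.density - surface_mean
    stratified = bool(excess[-1] > threshold)
    if not stratified:
        return bottom_depth, False
    crossing = np.nonzero(excess > threshold)[0][0]
    return float(profile.depths[crossing]), True


def _band_integral(wavelengths: np.ndarray, spectrum: np.ndarray,
                   band: tuple[float, float]) -> float:
    lo, hi = band
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    if np.count_nonzero(mask) < 2:
        raise ValidationError(f"spectral grid does not cover band {band}")
    return float(np.trapezoid(spectrum[mask], wavelengths[mask]))


def band_ratios(
    profiles: LightProfile | list[LightProfile],
    z_max: float = 2.5,
) -> tuple[float, float, float]:
    """Light-quality ratios (R/B, G/B, G/R) from hyperspectral profiles.

    Per depth, blue/green/red are trapezoid quantum integrals over
    410-490 / 480-580 / 600-700 nm (blue and green overlap by construction).
    Ratios are averaged over replicate casts at each depth, then over all
    depths down to ``z_max``.
    """
    if isinstance(profiles, LightProfile):
        profiles = [profiles]
    rows = []
    for prof in profiles:
        if prof.spectral is None:
            raise ValidationError("profile carries no spectral data")
        for i, z in enumerate(prof.depths):
            if z > z_max:
                continue
            spec = prof.spectral[i]
            b = _band_integral(prof.wavelengths, spec, BAND_BLUE)
            g = _band_integral(prof.wavelengths, spec, BAND_GREEN)
            r = _band_integral(prof.wavelengths, spec, BAND_RED)
            if b <= 0 or g <= 0 or r <= 0:
                raise ValidationError(
                    f"degenerate spectrum at depth {z} m: a band integrates to 0"
                )
            rows.append((round(float(z), 6), r / b, g / b, g / r))
    if not rows:
        raise ValidationError(f"no depth within z_max={z_max} m")
    df = pd.DataFrame(rows, columns=["depth", "rb", "gb", "gr"])
    per_depth = df.groupby("depth").mean()
    means = per_depth.mean()
    return float(means["rb"]), float(means["gb"]), float(means["gr"])
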