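"""Readers and writers for the delimited-text interchange formats.

CSV is the interchange format throughout; numeric output keeps 12+
significant digits so regression tests can compare exactly.  The raw PAM
reader is deliberately permissive about dialect (delimiter, decimal comma,
header spelling) because instrument exports vary.
"""
from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .light import DensityProfile, LightProfile
from .photo import PARII_FACTOR, RapidLightCurve

FLOAT_FORMAT = "%.12g"


def write_csv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Raw multi-color PAM tables
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "wavelength": "wavelength",
    "wavelength_nm": "wavelength",
    "par": "par",
    "f": "f",
    "fluorescence": "f",
    "fluorescence_f": "f",
    "fm": "fm_prime",
    "fm_fm": "fm_prime",
    "fm_prime": "fm_prime",
    "fmprime": "fm_prime",
    "yield": "yield_",
    "yieldmax": "yield_max",
    "par_ii": "par_ii",
    "parii": "par_ii",
    "etr_ii": "etr_ii",
    "etrii": "etr_ii",
    "npq": "npq",
    "station": "station",
    "location": "station",
    "replicate": "replicate",
    "zero_offset": "zero_offset",
    "zerooffset": "zero_offset",
    "y_npq": "y_npq",
    "y_npq_max": "y_npq_max",
}


def _normalise_header(name: str) -> str:
    s = name.strip().lower()
    s = s.replace("’", "'")
    s = re.sub(r"\(([^)]*)\)", r"_\1", s)   # "fm (fm')" -> "fm _fm'"
    s = s.replace("'", "").replace("/", "_")
    s = re.sub(r"[^a-z0-9]+", "_", s).strip("_")
    s = re.sub(r"_+", "_", s)
    return s


def _sniff(text: str) -> tuple[str, str]:
    """Detect (delimiter, decimal) from the raw text."""
    header = text.splitlines()[0] if text else ""
    counts = {d: header.count(d) for d in (",", ";", "\t")}
    delim = max(counts, key=counts.get)
    if counts[delim] == 0:
        delim = ","
    decimal = "."
    if delim in (";", "\t"):
        body = "\n".join(text.splitlines()[1:50])
        if re.search(r"\d,\d", body):
            decimal = ","
    return delim, decimal


def read_raw_pam(path) -> tuple[list[RapidLightCurve], pd.DataFrame]:
    """Read a raw multi-color PAM step table into RapidLightCurve objects.

    Mandatory columns (any recognised spelling): wavelength, PAR, F, Fm'.
    A zero-offset column, if present, is subtracted from F and Fm'.  Rows
    that cannot form a valid curve step (e.g. Fm' < F, non-finite values)
    are routed to the rejects frame with a reason, never silently dropped.
    Curves are grouped by station/wavelength/replicate when those columns
    exist; otherwise replicates are split wherever PAR restarts at its
    minimum.
    """
    text = Path(path).read_text()
    delim, decimal = _sniff(text)
    df = pd.read_csv(_io.StringIO(text), sep=delim, decimal=decimal)
    df.columns = [_COLUMN_ALIASES.get(_normalise_header(c), _normalise_header(c))
                  for c in df.columns]
    mandatory = ["wavelength", "par", "f", "fm_prime"]
    absent = [c for c in mandatory if c not in df.columns]
    if absent:
        raise ValidationError(f"missing mandatory column(s): {absent}")

    if "zero_offset" in df.columns:
        df["f"] = df["f"] - df["zero_offset"]
        df["fm_prime"] = df["fm_prime"] - df["zero_offset"]

    rejects = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        vals = row[["par", "f", "fm_prime"]]
        if not np.isfinite(vals.astype(float)).all():
            rejects.append((i, "non-finite value"))
            keep[df.index.get_loc(i)] = False
        elif row["fm_prime"] < row["f"]:
            rejects.append((i, "Fm' < F"))
            keep[df.index.get_loc(i)] = False
        elif row["fm_prime"] <= 0 or row["f"] <= 0:
            rejects.append((i, "non-positive fluorescence"))
            keep[df.index.get_loc(i)] = False
    clean = df[keep]
    rejects_frame = pd.DataFrame(rejects, columns=["row", "reason"])

    group_cols = [c for c in ("station", "wavelength", "replicate")
                  if c in clean.columns]
    curves = []
    for key, group in clean.groupby(group_cols, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        info = dict(zip(group_cols, key))
        par = group["par"].to_numpy(dtype=float)
        # Split on PAR restarts if replicates are not labelled.
        breaks = np.nonzero(np.diff(par) < 0)[0] + 1
        pieces = np.split(np.arange(len(par)), breaks)
        for rep_i, idx in enumerate(pieces, start=1):
            sub = group.iloc[idx]
            curves.append(RapidLightCurve(
                wavelength=int(info["wavelength"]),
                replicate=int(info.get("replicate", rep_i)),
                par=sub["par"].to_numpy(dtype=float),
                f=sub["f"].to_numpy(dtype=float),
                fm_prime=sub["fm_prime"].to_numpy(dtype=float),
                station=str(info.get("station")) if "station" in info else None))
    return curves, rejects_frame


def sigma_from_par_ii(par_ii: float, par: float) -> float:
    """Back-compute Sigma(II) (nm2) from a deposited PAR(II) column."""
    if not (par_ii > 0 and par > 0):
        raise ValidationError("par_ii and par must be > 0")
    return par_ii / (PARII_FACTOR * par)


# ---------------------------------------------------------------------------
# Long-format profile tables
# ---------------------------------------------------------------------------

def read_light_profiles(path) -> list[LightProfile]:
    """Read long-format light profiles.

    Columns: station, depth_m, replicate, wavelength_nm (or the literal
    "PAR"), value.
    """
    df = pd.read_csv(path)
    required = {"station", "depth_m", "replicate", "wavelength_nm", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"light profile table missing {sorted(missing)}")
    profiles = []
    for (st, rep), group in df.groupby(["station", "replicate"], sort=False):
        par_rows = group[group["wavelength_nm"].astype(str).str.upper() == "PAR"]
        spec_rows = group[group["wavelength_nm"].astype(str).str.upper() != "PAR"]
        if len(par_rows):
            par_rows = par_rows.sort_values("depth_m")
            profiles.append(LightProfile(
                depths=par_rows["depth_m"].to_numpy(),
                par=par_rows["value"].to_numpy(),
                replicate=int(rep), station=str(st)))
        if len(spec_rows):
            spec_rows = spec_rows.copy()
            spec_rows["wl"] = spec_rows["wavelength_nm"].astype(float)
            wide = spec_rows.pivot_table(index="depth_m", columns="wl",
                                         values="value").sort_index()
            profiles.append(LightProfile(
                depths=wide.index.to_numpy(),
                wavelengths=wide.columns.to_numpy(),
                spectral=wide.to_numpy(),
                replicate=int(rep), station=str(st)))
    return profiles


def read_density_profiles(path) -> list[DensityProfile]:
    df = pd.read_csv(path)
    required = {"station", "depth_m", "density"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"density table missing {sorted(missing)}")
    out = []
    for st, group in df.groupby("station", sort=False):
        group = group.sort_values("depth_m")
        out.append(DensityProfile(depths=group["depth_m"].to_numpy(),
                                  density=group["density"].to_numpy(),
                                  station=str(st)))
    return out
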