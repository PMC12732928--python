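"""Readers and writers for the plain-text interchange formats.

Formats:

* SAXS: 3-column whitespace/CSV text (q [1/A], I, sigma) with '#' comments;
  q given in 1/nm must be declared explicitly via ``q_units`` — the reader
  never guesses units.
* MALDI: CSV with header ``mz[,intensity]`` (two-column headerless plain
  text also accepted).
* AFM: whitespace numeric matrix (nm) plus a YAML sidecar carrying
  ``pixel_size_nm``; single-channel grayscale TIFF with an explicit
  nm-per-px argument.
* ITC: trace CSV ``time_s,power_uw`` plus an injection schedule CSV
  ``index,time_s[,volume_ul]``.
* Reports: JSON.

Text round-trips preserve numeric values to >= 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .afm import HeightMap
from .itc import Thermogram
from .maldi import PeakList
from .saxs import ScatteringProfile

__all__ = [
    "FormatError",
    "read_saxs", "write_saxs",
    "read_peaks", "write_peaks",
    "read_heightmap", "write_heightmap", "read_heightmap_tiff",
    "read_thermogram", "write_thermogram",
    "write_json_report", "read_json_report",
]

PathLike = Union[str, Path]

_FMT = "%.17g"  # full float64 precision: text round trips are exact


class FormatError(ValueError):
    """Malformed input file; the message names the offending row."""


def _parse_float_table(path: PathLike, n_cols_min: int, n_cols_max: int,
                       sep=None, skip_header_names=()) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split() if sep is None \
                else line.split(sep)
            if lineno == 1 and any(p.strip().lower() in skip_header_names
                                   for p in parts):
                continue
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value on line {lineno}: {raw!r}")
            if not (n_cols_min <= len(vals) <= n_cols_max):
                raise FormatError(
                    f"{path}: expected {n_cols_min}-{n_cols_max} columns on "
                    f"line {lineno}, got {len(vals)}")
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    width = max(len(r) for r in rows)
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: inconsistent column counts")
    return np.array(rows, dtype=float)


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------


def read_saxs(path: PathLike, q_units: str = "1/A") -> ScatteringProfile:
    """Read a 3-column (q, I[, sigma]) text profile.

    ``q_units`` must be "1/A" or "1/nm"; nm^-1 input is converted to the
    package-standard 1/A. There is deliberately no unit auto-detection.
    """
    if q_units not in ("1/A", "1/nm"):
        raise ValueError('q_units must be "1/A" or "1/nm" (explicit, '
                         "never guessed)")
    arr = _parse_float_table(path, 2, 3, skip_header_names={"q", "i"})
    q = arr[:, 0]
    if q_units == "1/nm":
        q = q / 10.0
    sigma = arr[:, 2] if arr.shape[1] == 3 else None
    return ScatteringProfile(q=q, I=arr[:, 1], sigma=sigma)


def write_saxs(path: PathLike, profile: ScatteringProfile,
               header: str = "") -> None:
    cols = [profile.q, profile.I]
    names = "q_invA I"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        names += " sigma"
    head = (header + "\n" if header else "") + names
    np.savetxt(path, np.column_stack(cols), fmt=_FMT, header=head)


# ---------------------------------------------------------------------------
# MALDI peaks
# ---------------------------------------------------------------------------


def read_peaks(path: PathLike) -> PeakList:
    arr = _parse_float_table(path, 1, 2, skip_header_names={"mz", "m/z"})
    intensity = arr[:, 1] if arr.shape[1] == 2 else None
    return PeakList(mz=arr[:, 0], intensity=intensity)


def write_peaks(path: PathLike, peaks: PeakList) -> None:
    df = pd.DataFrame({"mz": peaks.mz})
    if peaks.intensity is not None:
        df["intensity"] = peaks.intensity
    df.to_csv(path, index=False, float_format=_FMT)


# ---------------------------------------------------------------------------
# AFM height maps
# ---------------------------------------------------------------------------


def _sidecar_path(path: PathLike) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".yaml")


def read_heightmap(path: PathLike,
                   pixel_size: Optional[float] = None) -> HeightMap:
    """Read a whitespace matrix of heights (nm) + its YAML sidecar."""
    try:
        heights = np.loadtxt(path, comments="#")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_nm")
    if pixel_size is None:
        raise FormatError(f"{path}: pixel size not given and no sidecar "
                          f"{sidecar.name} with pixel_size_nm found")
    return HeightMap(heights=np.atleast_2d(heights), pixel_size=float(pixel_size),
                     metadata=meta)


def write_heightmap(path: PathLike, hm: HeightMap) -> None:
    np.savetxt(path, hm.heights, fmt=_FMT)
    meta = {"pixel_size_nm": float(hm.pixel_size), **hm.metadata}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_heightmap_tiff(path: PathLike, pixel_size: float) -> HeightMap:
    """Read a single-channel grayscale TIFF as heights in nm."""
    import tifffile

    heights = np.asarray(tifffile.imread(path), dtype=float)
    if heights.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel image, "
                          f"got shape {heights.shape}")
    return HeightMap(heights=heights, pixel_size=float(pixel_size))


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------


def read_thermogram(trace_path: PathLike, injections_path: PathLike,
                    temperature_c: float = 25.0) -> Thermogram:
    trace = _parse_float_table(trace_path, 2, 2,
                               skip_header_names={"time_s", "time"})
    inj = _parse_float_table(injections_path, 1, 3,
                             skip_header_names={"index", "time_s"})
    times = inj[:, 1] if inj.shape[1] >= 2 else inj[:, 0]
    return Thermogram(time=trace[:, 0], power=trace[:, 1],
                      injection_times=times, temperature_c=temperature_c)


def write_thermogram(trace_path: PathLike, injections_path: PathLike,
                     tg: Thermogram) -> None:
    pd.DataFrame({"time_s": tg.time, "power_uw": tg.power}).to_csv(
        trace_path, index=False, float_format=_FMT)
    pd.DataFrame({"index": np.arange(len(tg.injection_times)),
                  "time_s": tg.injection_times}).to_csv(
        injections_path, index=False, float_format=_FMT)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    if hasattr(obj, "__dataclass_fields__"):
        import dataclasses
        return _to_jsonable(dataclasses.asdict(obj))
    return obj


def write_json_report(path: PathLike, payload: dict) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(payload), indent=2,
                                     sort_keys=True) + "\n")


def read_json_report(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
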