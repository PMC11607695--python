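"""Raw sensor streams -> per-minute observation table.

Converts 50-Hz tri-axial acceleration, 1-Hz depth and 1-min GPS into the five
per-minute quantities the behavioural classifier and the energetics models
consume: vectorial dynamic body acceleration (VeDBA), wingbeat frequency,
dive fraction, step length and a colony-presence indicator.

VeDBA at each sample is the Euclidean norm of the three dynamic components,
where the dynamic component of an axis is the raw signal minus its "static"
(postural/gravitational) part, estimated as a centred 3-s running mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

__all__ = [
    "vedba_series",
    "smooth_and_sum",
    "wingbeat_frequency",
    "dive_fraction",
    "interpolate_track",
    "step_and_colony",
    "haversine_km",
    "build_minutes",
]


def _check_monotone(t: np.ndarray) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(f"timestamps not strictly increasing; first offence at index {bad[0] + 1}")


def vedba_series(accel: pd.DataFrame, fs: float = 50.0,
                 static_window_s: float = 3.0) -> pd.DataFrame:
    """Per-sample VeDBA (g) from tri-axial acceleration.

    ``accel`` needs columns ``t`` (seconds), ``ax``, ``ay``, ``az`` (g).
    The static component per axis is a centred running mean over
    ``static_window_s``; the window is truncated at the record edges so every
    sample keeps a value and the minute grid stays aligned with the other
    sensors.
    """
    t = np.asarray(accel["t"], dtype=float)
    if t.size < int(fs * static_window_s):
        raise ValueError("need at least one full static window of samples")
    _check_monotone(t)
    win = max(int(round(fs * static_window_s)), 1)
    sq = np.zeros(t.size)
    for ax in ("ax", "ay", "az"):
        a = pd.Series(np.asarray(accel[ax], dtype=float))
        if a.abs().max() >= 16:
            warnings.warn(f"axis {ax} exceeds 16 g sensor range", stacklevel=2)
        static = a.rolling(win, center=True, min_periods=1).mean()
        sq += (a - static).to_numpy() ** 2
    return pd.DataFrame({"t": t, "vedba": np.sqrt(sq)})


def smooth_and_sum(vedba: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """1-s mean VeDBA, then per-minute DBA sums.

    Returns ``(seconds, minutes)``: per-second means indexed by integer
    second, and per-minute sums of the 1-s means with a ``partial`` flag on
    minutes with fewer than 60 seconds of data.
    """
    sec = np.floor(vedba["t"].to_numpy()).astype(np.int64)
    per_sec = (pd.DataFrame({"sec": sec, "v": vedba["vedba"].to_numpy()})
               .groupby("sec", sort=True)["v"].mean().reset_index())
    minute = per_sec["sec"] // 60
    g = per_sec.groupby(minute, sort=True)["v"]
    minutes = pd.DataFrame({"minute": g.sum().index.astype(np.int64),
                            "dba": g.sum().to_numpy(),
                            "n_sec": g.count().to_numpy()})
    minutes["partial"] = minutes["n_sec"] < 60
    return per_sec.rename(columns={"v": "vedba_1s"}), minutes


def wingbeat_frequency(z: np.ndarray, t: np.ndarray, fs: float = 50.0,
                       window_s: float = 30.0, stride_s: float = 1.0,
                       assign: str = "center") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dominant non-DC spectral frequency of the heave axis.

    An FFT is taken over sliding ``window_s`` windows (stride ``stride_s``);
    the peak frequency of each window is recorded at the window's start
    second.  The per-minute value is the median (50th quantile) of the
    windows attributed to that minute: with ``assign="center"`` (default) a
    window belongs to the minute containing its centre, with
    ``assign="overlap"`` to every minute it overlaps.  Centre assignment
    halves the spectral bleed of flapping bouts into adjacent non-flight
    minutes.  An all-constant window has no non-DC peak and reports 0 Hz
    with a flag.

    Returns ``(windows, minutes)`` data frames.
    """
    if assign not in ("center", "overlap"):
        raise ValueError(f"unknown window assignment {assign!r}")
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    nwin = int(round(window_s * fs))
    stride = max(int(round(stride_s * fs)), 1)
    if z.size < nwin:
        raise ValueError("record shorter than one FFT window")
    starts = np.arange(0, z.size - nwin + 1, stride)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    peak = np.empty(starts.size)
    flat = np.zeros(starts.size, dtype=bool)
    # chunked batched FFT keeps memory bounded on multi-hour records
    chunk = 4096
    view = np.lib.stride_tricks.sliding_window_view(z, nwin)[::stride]
    for i in range(0, starts.size, chunk):
        block = view[i:i + chunk]
        mag = np.abs(np.fft.rfft(block, axis=1))
        mag[:, 0] = 0.0  # drop DC
        idx = mag.argmax(axis=1)
        peak[i:i + chunk] = freqs[idx]
        flat[i:i + chunk] = mag.max(axis=1) <= 1e-12
    peak[flat] = 0.0
    t_start = t[starts]
    windows = pd.DataFrame({"t_start": t_start, "peak_hz": peak, "flat": flat})

    first_min = int(t[0] // 60)
    last_min = int(t[-1] // 60)
    rows = []
    for m in range(first_min, last_min + 1):
        lo, hi = 60.0 * m, 60.0 * (m + 1)
        if assign == "center":
            mid = t_start + window_s / 2.0
            sel = (mid >= lo) & (mid < hi)
            if not sel.any():  # record edges: fall back to overlap
                sel = (t_start < hi) & (t_start + window_s > lo)
        else:
            sel = (t_start < hi) & (t_start + window_s > lo)
        rows.append((m, float(np.median(peak[sel])) if sel.any() else np.nan))
    minutes = pd.DataFrame(rows, columns=["minute", "wingbeat_hz"])
    return windows, minutes


def dive_fraction(depth: pd.DataFrame, wet_threshold_m: float = 0.1) -> pd.DataFrame:
    """Proportion of each minute spent underwater according to the 1-Hz depth sensor."""
    d = np.asarray(depth["depth"], dtype=float)
    t = np.asarray(depth["t"], dtype=float)
    if (d < -0.5).any():
        warnings.warn("depth readings below -0.5 m: check sensor zero", stacklevel=2)
    minute = (t // 60).astype(np.int64)
    wet = d > wet_threshold_m
    g = pd.DataFrame({"minute": minute, "wet": wet}).groupby("minute", sort=True)["wet"]
    return pd.DataFrame({"minute": g.mean().index, "dive_frac": g.mean().to_numpy()})


def interpolate_track(gps: pd.DataFrame, max_gap_s: float = 600.0) -> pd.DataFrame:
    """Regularize GPS fixes onto exact 60-s ticks (piecewise-linear in time).

    ``gps`` needs ``t`` (seconds) plus either ``lon``/``lat`` (degrees) or
    planar ``x_km``/``y_km``.  Minutes farther than ``max_gap_s`` from any
    fix are flagged.  A correlated-random-walk smoother is deliberately not
    the default: linear interpolation is deterministic and sufficient at
    1-min resolution.
    """
    if len(gps) < 2:
        raise ValueError("need at least 2 GPS fixes to interpolate")
    t = np.asarray(gps["t"], dtype=float)
    _check_monotone(t)
    cols = ("lon", "lat") if "lon" in gps.columns else ("x_km", "y_km")
    t0 = 60.0 * np.ceil(t[0] / 60.0)
    ticks = np.arange(t0, t[-1] + 1e-9, 60.0)
    out = {"t": ticks}
    for c in cols:
        out[c] = np.interp(ticks, t, np.asarray(gps[c], dtype=float))
    nearest = np.minimum(np.abs(ticks[:, None] - t[None, :]).min(axis=1), np.inf) \
        if t.size < 20000 else np.array([np.abs(t - tk).min() for tk in ticks])
    df = pd.DataFrame(out)
    df["minute"] = (ticks // 60).astype(np.int64)
    df["gap"] = nearest > max_gap_s
    return df


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (km) on the sphere of mean Earth radius."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, dtype=float),
                                              np.asarray(lat1, dtype=float),
                                              np.asarray(lon2, dtype=float),
                                              np.asarray(lat2, dtype=float)))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _dist_km(track: pd.DataFrame, ref=None) -> np.ndarray:
    """Distance of each track point from ``ref`` (or between consecutive points)."""
    if "lon" in track.columns:
        lon, lat = track["lon"].to_numpy(float), track["lat"].to_numpy(float)
        if ref is not None:
            return haversine_km(lon, lat, ref[0], ref[1])
        return haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    x, y = track["x_km"].to_numpy(float), track["y_km"].to_numpy(float)
    if ref is not None:
        return np.hypot(x - ref[0], y - ref[1])
    return np.hypot(np.diff(x), np.diff(y))


def step_and_colony(track: pd.DataFrame, colony_point,
                    r_in_km: float = 0.5, r_out_km: float = 1.0) -> pd.DataFrame:
    """Per-minute step length (m) and colony-presence indicator.

    Colony indicator: 1 at distances <= ``r_in_km`` from the colony, 0 at
    distances > ``r_out_km``; the intermediate band maps to 0 by convention
    (positions there are treated as at sea).  Step length is the distance
    between consecutive 1-min positions; the first minute has no predecessor
    and is reported as NaN.
    """
    dist = _dist_km(track, ref=colony_point)
    colony = (dist <= r_in_km).astype(int)
    step = np.empty(len(track))
    step[0] = np.nan
    if len(track) > 1:
        step[1:] = _dist_km(track) * 1000.0
    return pd.DataFrame({"minute": track["minute"].to_numpy(),
                         "colony": colony, "step_m": step,
                         "dist_colony_km": dist})


def build_minutes(accel: pd.DataFrame, depth: pd.DataFrame, gps: pd.DataFrame,
                  colony_point, fs: float = 50.0, static_window_s: float = 3.0,
                  wingbeat_window_s: float = 30.0, wet_threshold_m: float = 0.1,
                  r_in_km: float = 0.5, r_out_km: float = 1.0) -> pd.DataFrame:
    """Full raw-streams -> MinuteRecord table for one deployment.

    Output columns: ``minute, colony, wingbeat_hz, dive_frac, step_m, dba``
    (plus QC flags).  Minutes present in some streams but not others carry
    NaN in the missing streams; the classifier marginalizes them.
    """
    v = vedba_series(accel, fs=fs, static_window_s=static_window_s)
    _, dba_min = smooth_and_sum(v)
    _, wb_min = wingbeat_frequency(accel["az"].to_numpy(), accel["t"].to_numpy(),
                                   fs=fs, window_s=wingbeat_window_s)
    dive = dive_fraction(depth, wet_threshold_m=wet_threshold_m)
    track = interpolate_track(gps)
    sc = step_and_colony(track, colony_point, r_in_km=r_in_km, r_out_km=r_out_km)
    out = (dba_min[["minute", "dba", "partial"]]
           .merge(wb_min, on="minute", how="outer")
           .merge(dive, on="minute", how="outer")
           .merge(sc[["minute", "colony", "step_m"]], on="minute", how="outer")
           .sort_values("minute").reset_index(drop=True))
    return out
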