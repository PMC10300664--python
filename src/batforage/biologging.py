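"""Acoustic-GPS logger processing: resampled georeferenced tracks.

The logger records a GPS fix (time, WGS84 lat/lon, altitude above sea
level) nominally every 5 s plus a continuous stream of pulse-onset
timestamps.  This module turns those into a 1 s track with above-ground
altitude (ASL minus terrain elevation from a DEM), ground speed, habitat
label, and geolocated attack events (feeding-buzz ends matched to the
nearest track sample).

Geodesy is haversine on a mean sphere: at the few-hundred-meter scales of
a foraging bout the spherical error is orders of magnitude below GPS noise.
Negative above-ground altitudes are retained, not clipped — the altitudinal
GPS error exceeds the horizontal one, and the share of negative altitudes
is itself a quantity of interest (a lower bound on the altitude error).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .formats import AsciiGrid

__all__ = [
    "EARTH_RADIUS_M",
    "haversine_m",
    "resample_track",
    "ground_speed",
    "altitude_agl",
    "annotate_habitat",
    "locate_attacks",
    "negative_altitude_share",
    "build_geotrack",
]

#: WGS84 mean-sphere radius, m
EARTH_RADIUS_M = 6_371_008.8

#: integer codes used in the categorical habitat raster
HABITAT_CODES = {0: "river", 1: "mountain", 2: "urban"}
HABITAT_NAMES = {v: k for k, v in HABITAT_CODES.items()}


def haversine_m(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_M) -> np.ndarray:
    """Great-circle distance in meters between WGS84 points (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return radius * 2 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def resample_track(fixes: pd.DataFrame, interval_s: float = 1.0) -> pd.DataFrame:
    """Linearly interpolate GPS fixes onto a regular 1 s grid.

    Lat/lon are interpolated directly in degrees (track spans are small);
    the grid runs from the first to the last fix and is never extrapolated.
    Gaps in the 5 s cadence are bridged linearly.
    """
    if len(fixes) < 2:
        raise ValueError("resampling needs at least 2 GPS fixes")
    t = fixes["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("fix times must be strictly increasing")
    grid = np.arange(np.ceil(t[0] / interval_s) * interval_s,
                     t[-1] + 1e-9, interval_s)
    out = pd.DataFrame({"time_s": grid})
    for col in ("lat", "lon", "alt_asl_m"):
        out[col] = np.interp(grid, t, fixes[col].to_numpy(float))
    return out


def ground_speed(fixes: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Ground speed per 1 s sample from consecutive raw fixes.

    Speed is the haversine distance between consecutive *raw* fixes divided
    by elapsed time, assigned to all 1 s samples in that interval.
    Computing on raw fixes rather than interpolated points avoids
    spuriously smooth speeds.
    """
    if len(fixes) < 2:
        raise ValueError("ground speed needs at least 2 fixes")
    t = fixes["time_s"].to_numpy(float)
    d = haversine_m(fixes["lat"].to_numpy()[:-1], fixes["lon"].to_numpy()[:-1],
                    fixes["lat"].to_numpy()[1:], fixes["lon"].to_numpy()[1:])
    v = d / np.diff(t)
    # sample i gets the speed of the fix interval containing it
    which = np.clip(np.searchsorted(t, track["time_s"].to_numpy(float),
                                    side="right") - 1, 0, len(v) - 1)
    return v[which]


def altitude_agl(track: pd.DataFrame, dem: AsciiGrid) -> pd.DataFrame:
    """Above-ground altitude: ASL minus bilinearly interpolated terrain.

    Negative values are retained (they measure altitudinal GPS error), and
    samples outside the DEM raise an error naming the offending sample.
    """
    ground = dem.bilinear(track["lon"].to_numpy(float),
                          track["lat"].to_numpy(float))
    out = track.copy()
    out["ground_m"] = ground
    out["alt_agl_m"] = out["alt_asl_m"].to_numpy(float) - ground
    return out


def annotate_habitat(track: pd.DataFrame, habitat: AsciiGrid) -> pd.Series:
    """Nearest-cell categorical habitat lookup for every track sample."""
    codes = habitat.nearest(track["lon"].to_numpy(float),
                            track["lat"].to_numpy(float))
    codes = np.rint(codes).astype(int)
    unknown = set(np.unique(codes)) - set(HABITAT_CODES)
    if unknown:
        raise ValueError(f"habitat raster contains unknown codes {sorted(unknown)}")
    return pd.Series([HABITAT_CODES[c] for c in codes], index=track.index,
                     name="habitat")


def locate_attacks(track: pd.DataFrame, buzzes) -> pd.DataFrame:
    """Match each feeding buzz to the track sample nearest its end time.

    Ties (a buzz ending exactly midway between samples) break toward the
    earlier sample.  Attack events inherit position, altitude and habitat
    from their matched sample — never re-interpolated.  Buzzes outside the
    track span are returned flagged unmatched rather than dropped.
    """
    t = track["time_s"].to_numpy(float)
    rows = []
    for i, buzz in enumerate(buzzes):
        end = float(buzz.end_s if hasattr(buzz, "end_s") else buzz["end_s"])
        if end < t[0] or end > t[-1]:
            rows.append({"buzz_id": i, "time_s": np.nan, "matched": False})
            continue
        d = np.abs(t - end)
        j = int(np.argmin(d))  # argmin takes the first (earlier) minimum on ties
        row = {"buzz_id": i, "time_s": t[j], "matched": True}
        for col in ("lat", "lon", "alt_asl_m", "alt_agl_m", "ground_m", "habitat"):
            if col in track:
                row[col] = track[col].iloc[j]
        rows.append(row)
    return pd.DataFrame(rows)


def negative_altitude_share(agl: np.ndarray | pd.Series) -> tuple[int, float]:
    """Count and percentage of samples with above-ground altitude below zero."""
    agl = np.asarray(agl, dtype=float)
    n_neg = int(np.sum(agl < 0))
    return n_neg, n_neg / len(agl) * 100.0


def build_geotrack(fixes: pd.DataFrame, events: np.ndarray | pd.DataFrame,
                   dem: AsciiGrid, habitat: AsciiGrid,
                   buzz_params=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full logger pipeline: fixes + event stream → GeoTrack + attack events.

    Detects feeding buzzes in the event stream, resamples the fixes to 1 s,
    attaches ground altitude, speed and habitat, and flags the samples
    matched to buzz ends as attacks.
    """
    from .callpulse import BuzzRuleParams, detect_feeding_buzzes

    if isinstance(events, pd.DataFrame):
        events = events["time_s"].to_numpy(float)
    buzzes = detect_feeding_buzzes(np.asarray(events, float),
                                   buzz_params or BuzzRuleParams())
    track = resample_track(fixes)
    track = altitude_agl(track, dem)
    track["speed_ms"] = ground_speed(fixes, track)
    track["habitat"] = annotate_habitat(track, habitat)
    attacks = locate_attacks(track, buzzes)
    track["attack"] = False
    matched = attacks[attacks["matched"]]
    idx = track["time_s"].searchsorted(matched["time_s"].to_numpy(float))
    track.loc[track.index[idx], "attack"] = True
    return track, matched.reset_index(drop=True)
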