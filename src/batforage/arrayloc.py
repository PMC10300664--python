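"""3D source localization from a four-microphone Y-array.

A central microphone plus three outer microphones give three independent
time differences of arrival (TDOAs).  Each TDOA constrains the source to a
hyperboloid; the source position is recovered by nonlinear least squares on
the three TDOA residuals.  Because the microphones are coplanar, every
solution has a mirror image below the array plane with identical TDOAs; the
solver is constrained to the upper half-space (microphones point up, bats
fly above the array).

Positions are expressed in an array-local right-handed frame with the
central microphone at the origin and z up.  Localization quality degrades
with range relative to the ~1 m baseline (geometric dilution), which is why
tracks are gated at a 47 m validity radius: inside it, the range error from
sample-clock TDOA quantization stays below the ~40 cm wingspan of the
animal being tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

__all__ = [
    "MicArrayGeometry",
    "TDOASet",
    "LocalizationResult",
    "forward_tdoa",
    "estimate_tdoa",
    "localize",
    "assemble_track",
    "distance_to_attack",
    "SPEED_OF_SOUND",
    "VALID_RANGE_M",
]

#: default speed of sound, m/s at ~20 °C; configurable everywhere it is used
SPEED_OF_SOUND = 343.0

#: validity radius of the array, m — localization is reported but flagged beyond it
VALID_RANGE_M = 47.0


@dataclass(frozen=True)
class MicArrayGeometry:
    """Positions of the four microphones in the array-local frame.

    The central microphone must sit at the origin and the three outer
    microphones must not be collinear (otherwise the TDOA system is
    degenerate in one horizontal direction).
    """

    positions: np.ndarray  # (4, 3) meters
    central: int = 0

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (4, 3):
            raise ValueError(f"expected 4 microphones with 3D positions, got {pos.shape}")
        object.__setattr__(self, "positions", pos)
        if not np.allclose(pos[self.central], 0.0, atol=1e-9):
            raise ValueError("central microphone must be at the origin")
        outer = np.delete(pos, self.central, axis=0)
        v1, v2 = outer[1] - outer[0], outer[2] - outer[0]
        if np.linalg.norm(np.cross(v1, v2)) < 1e-9:
            raise ValueError("outer microphones are collinear")

    @classmethod
    def y_array(cls, arm_length_m: float = 1.0) -> "MicArrayGeometry":
        """Planar Y-shaped array: central mic at the origin, three arms 120° apart."""
        angles = np.deg2rad([90.0, 210.0, 330.0])
        outer = np.stack(
            [arm_length_m * np.cos(angles), arm_length_m * np.sin(angles),
             np.zeros(3)], axis=1)
        return cls(positions=np.vstack([np.zeros(3), outer]), central=0)

    @property
    def outer(self) -> np.ndarray:
        return np.delete(self.positions, self.central, axis=0)

    @property
    def max_baseline(self) -> float:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return float(np.linalg.norm(d, axis=-1).max())


@dataclass
class TDOASet:
    """Arrival-time differences (outer − central) for one pulse."""

    delays_s: np.ndarray          # (3,)
    quality: np.ndarray           # (3,) peak normalized correlation per pair
    pulse_id: int | None = None
    localizable: bool = True
    note: str = ""

    def __post_init__(self):
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)


@dataclass
class LocalizationResult:
    position: np.ndarray            # (3,) m
    residual: float                 # RMS TDOA residual, s
    converged: bool
    in_range: bool = field(init=False)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.in_range = bool(np.linalg.norm(self.position) <= VALID_RANGE_M)


def forward_tdoa(position: np.ndarray, geometry: MicArrayGeometry,
                 c: float = SPEED_OF_SOUND) -> np.ndarray:
    """Exact TDOAs (outer − central) for a source at *position*: (|r_i| − |r_c|)/c."""
    p = np.asarray(position, dtype=float)
    r_c = np.linalg.norm(p - geometry.positions[geometry.central])
    r_i = np.linalg.norm(p[None, :] - geometry.outer, axis=1)
    return (r_i - r_c) / c


def estimate_tdoa(window: np.ndarray, sample_rate: float,
                  geometry: MicArrayGeometry | None = None,
                  central: int = 0,
                  min_quality: float = 0.3,
                  max_delay_s: float | None = None,
                  pulse_id: int | None = None) -> TDOASet:
    """Estimate the three TDOAs of one pulse by normalized cross-correlation.

    *window* is (n_samples, 4) containing the pulse on all channels.  Each
    outer channel is correlated against the central one; the correlation
    peak is refined by parabolic interpolation of the three samples around
    it, giving sub-sample delay resolution.  The peak normalized
    correlation coefficient is kept as a per-pair quality score; if any
    pair falls below *min_quality* the pulse is flagged unlocalizable (but
    still returned, never dropped silently).

    *max_delay_s* bounds the lag search; it defaults to the maximum
    baseline over the speed of sound when *geometry* is given.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 4:
        raise ValueError("window must be (n_samples, 4); 4 channels required")
    if max_delay_s is None and geometry is not None:
        max_delay_s = geometry.max_baseline / SPEED_OF_SOUND * 1.5
    ref = window[:, central] - window[:, central].mean()
    n = len(ref)
    delays = np.zeros(3)
    quality = np.zeros(3)
    others = [ch for ch in range(4) if ch != central]
    for k, ch in enumerate(others):
        sig = window[:, ch] - window[:, ch].mean()
        corr = signal.correlate(sig, ref, mode="full")
        norm = np.linalg.norm(sig) * np.linalg.norm(ref)
        if norm == 0:
            quality[k] = 0.0
            continue
        corr = corr / norm
        lags = np.arange(-(n - 1), n)
        if max_delay_s is not None:
            max_lag = int(np.ceil(max_delay_s * sample_rate))
            keep = np.abs(lags) <= max_lag
            corr, lags = corr[keep], lags[keep]
        i = int(np.argmax(corr))
        quality[k] = float(corr[i])
        # parabolic interpolation of the peak for sub-sample resolution
        if 0 < i < len(corr) - 1:
            y0, y1, y2 = corr[i - 1], corr[i], corr[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        delays[k] = (lags[i] + delta) / sample_rate
    ok = bool(np.all(quality >= min_quality))
    note = "" if ok else f"correlation quality below {min_quality} on a pair"
    return TDOASet(delays_s=delays, quality=quality, pulse_id=pulse_id,
                   localizable=ok, note=note)


def _grid_starts(geometry: MicArrayGeometry, c: float, tdoas: np.ndarray,
                 spacing: float = 5.0,
                 half_extent: float = 50.0, z_max: float = 50.0,
                 n_best: int = 4) -> np.ndarray:
    """Coarse multi-start grid over the upper half-space, ranked by TDOA misfit."""
    ax = np.arange(-half_extent, half_extent + 1e-9, spacing)
    az = np.arange(spacing, z_max + 1e-9, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, az, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    r_c = np.linalg.norm(pts, axis=1)
    r_i = np.linalg.norm(pts[:, None, :] - geometry.outer[None, :, :], axis=2)
    pred = (r_i - r_c[:, None]) / c
    misfit = np.sum((pred - tdoas[None, :]) ** 2, axis=1)
    order = np.argsort(misfit)[:n_best]
    return pts[order]


def localize(tdoas: TDOASet | np.ndarray, geometry: MicArrayGeometry,
             c: float = SPEED_OF_SOUND,
             grid_spacing: float = 5.0) -> LocalizationResult:
    """Recover the 3D source position from one TDOA set.

    Minimizes the sum of squared differences between predicted and observed
    TDOAs by trust-region least squares, started from the best cells of a
    coarse grid over the upper half-space (the hyperbolic intersection has
    local minima at long range with a small array).  The solution is
    constrained to z ≥ 0; the z < 0 mirror solution is never returned.
    """
    obs = tdoas.delays_s if isinstance(tdoas, TDOASet) else np.asarray(tdoas, float)
    if obs.shape != (3,) or not np.all(np.isfinite(obs)):
        raise ValueError("localize needs 3 finite delays")
    if isinstance(tdoas, TDOASet) and not tdoas.localizable:
        return LocalizationResult(position=np.full(3, np.nan), residual=np.inf,
                                  converged=False)

    def resid(p):
        return forward_tdoa(p, geometry, c) - obs

    best = None
    for start in _grid_starts(geometry, c, obs, spacing=grid_spacing):
        sol = optimize.least_squares(
            resid, start, bounds=([-np.inf, -np.inf, 0.0], np.inf),
            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    # a solution pinned to the array plane with large residual means no
    # upper-half-space position is consistent with the delays
    converged = bool(best.success) and rms < 0.5 * geometry.max_baseline / c
    return LocalizationResult(position=best.x, residual=rms, converged=converged)


def assemble_track(times: np.ndarray, positions: np.ndarray,
                   residuals: np.ndarray | None = None,
                   range_gate_m: float = VALID_RANGE_M) -> pd.DataFrame:
    """Order per-pulse positions in time and derive speed and altitude.

    Speed is the central finite difference of position over time
    (``np.gradient``, 3-point); altitude is the z coordinate; ``in_range``
    flags pulses within *range_gate_m* of the central microphone.  A track
    with a single localized pulse is returned with speed NaN and the
    ``speed_defined`` attribute set to False rather than raising.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(times) != len(positions):
        raise ValueError("times and positions disagree in length")
    if len(times) == 0:
        raise ValueError("empty track")
    order = np.argsort(times, kind="stable")
    times, positions = times[order], positions[order]
    if residuals is None:
        residuals = np.zeros(len(times))
    else:
        residuals = np.asarray(residuals, dtype=float)[order]
    if len(times) >= 2:
        vel = np.gradient(positions, times, axis=0)
        speed = np.linalg.norm(vel, axis=1)
        speed_defined = True
    else:
        speed = np.full(len(times), np.nan)
        speed_defined = False
    track = pd.DataFrame({
        "time_s": times,
        "x_m": positions[:, 0],
        "y_m": positions[:, 1],
        "z_m": positions[:, 2],
        "speed_ms": speed,
        "altitude_m": positions[:, 2],
        "in_range": np.linalg.norm(positions, axis=1) <= range_gate_m,
        "residual": residuals,
    })
    track.attrs["speed_defined"] = speed_defined
    return track


def distance_to_attack(track: pd.DataFrame, buzz) -> pd.DataFrame:
    """3D distance from each pulse position to the attack point of a buzz.

    The attack point is the position of the last localized pulse whose time
    falls inside the buzz ``[start_s, end_s]`` window.  Distances are
    reported for all pulses at or before the attack.
    """
    start = float(buzz.start_s if hasattr(buzz, "start_s") else buzz["start_s"])
    end = float(buzz.end_s if hasattr(buzz, "end_s") else buzz["end_s"])
    t = track["time_s"].to_numpy()
    if end < t[0] or end > t[-1] + 1e-9:
        raise ValueError("buzz end falls outside the track time span")
    inside = (t >= start) & (t <= end + 1e-9)
    if not inside.any():
        raise ValueError("no localized pulse inside the buzz; attack point undefined")
    attack_idx = int(np.flatnonzero(inside)[-1])
    attack_pos = track.loc[track.index[attack_idx], ["x_m", "y_m", "z_m"]].to_numpy(float)
    pos = track[["x_m", "y_m", "z_m"]].to_numpy(float)
    dist = np.linalg.norm(pos - attack_pos[None, :], axis=1)
    out = track.loc[t <= t[attack_idx], ["time_s"]].copy()
    out["distance_to_attack_m"] = dist[t <= t[attack_idx]]
    return out
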