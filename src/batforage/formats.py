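"""Shared file formats: multichannel WAV, headered CSV tables, ESRI ASCII grids, GeoJSON.

All on-disk artifacts of the pipeline are plain text except the audio, which
is PCM WAV.  Tables carry explicit headers and are validated against a schema
on read so that a stage fails loudly on the offending file rather than
propagating misaligned columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AsciiGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_wav",
    "write_wav",
    "read_table",
    "write_table",
    "track_to_geojson",
    "SCHEMAS",
]

#: required columns for each pipeline table
SCHEMAS: dict[str, list[str]] = {
    "fixes": ["time_s", "lat", "lon", "alt_asl_m"],
    "events": ["time_s"],
    "pulses": [
        "start_s", "end_s", "duration_ms", "ipi_ms",
        "f_min_khz", "f_peak_khz", "bandwidth_khz", "peak_db", "call_type",
    ],
    "buzzes": ["start_s", "end_s", "n_pulses", "mean_ipi_ms", "duration_ms"],
    "track": ["time_s", "x_m", "y_m", "z_m", "speed_ms", "altitude_m",
              "in_range", "residual"],
    "geotrack": ["time_s", "lat", "lon", "alt_asl_m", "ground_m",
                 "alt_agl_m", "speed_ms", "habitat", "attack"],
    "attacks": ["time_s", "lat", "lon", "alt_agl_m", "habitat", "buzz_id"],
}


class SchemaError(ValueError):
    """A table's columns do not match the expected schema."""


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a headered CSV and validate it against a named schema."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; know {sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        extra = [c for c in df.columns if c not in required]
        raise SchemaError(
            f"{path}: schema {schema!r} missing columns {missing}"
            + (f"; extra columns {extra}" if extra else "")
        )
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a CSV; if *schema* is given, check the columns first."""
    if schema is not None:
        missing = [c for c in SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise SchemaError(f"refusing to write {schema!r} without {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# WAV

def write_wav(path: str | Path, data: np.ndarray, sample_rate: int) -> None:
    """Write an (n_samples, n_channels) float array as float32 PCM WAV."""
    data = np.asarray(data)
    if data.ndim == 1:
        data = data[:, None]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(path, int(sample_rate), data.astype(np.float32))


def read_wav(path: str | Path, n_channels: int | None = None) -> tuple[np.ndarray, int]:
    """Read a WAV file to (samples, channels) float64, optionally enforcing a channel count."""
    sample_rate, data = wavfile.read(path)
    if data.ndim == 1:
        data = data[:, None]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    data = data.astype(np.float64)
    if n_channels is not None and data.shape[1] != n_channels:
        raise ValueError(
            f"{path}: {n_channels} channels required, found {data.shape[1]}"
        )
    return data, sample_rate


# ---------------------------------------------------------------------------
# ESRI ASCII grid

@dataclass(frozen=True)
class AsciiGrid:
    """A regular grid in the ESRI ASCII-grid dialect.

    ``values[0]`` is the northernmost row (ESRI convention).  ``xll``/``yll``
    are the coordinates of the lower-left *corner*; cell centers sit half a
    cell in.  Coordinates may be geographic degrees or local meters — the
    grid is agnostic.
    """

    xll: float
    yll: float
    cellsize: float
    values: np.ndarray  # (nrows, ncols), north row first
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer cell edges."""
        return (
            self.xll,
            self.xll + self.ncols * self.cellsize,
            self.yll,
            self.yll + self.nrows * self.cellsize,
        )

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def _center_axes(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (np.arange(self.nrows) + 0.5) * self.cellsize
        return xs, ys  # ys ascending (south→north)

    def nearest(self, x, y) -> np.ndarray:
        """Nearest-cell lookup (categorical data must not be interpolated)."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        inside = self.contains(x, y)
        if not inside.all():
            bad = int(np.flatnonzero(~inside)[0])
            raise ValueError(
                f"sample {bad} at ({x[bad]:.6f}, {y[bad]:.6f}) lies outside "
                f"the grid extent {self.extent}"
            )
        col = np.clip(((x - self.xll) / self.cellsize).astype(int), 0, self.ncols - 1)
        row_s = np.clip(((y - self.yll) / self.cellsize).astype(int), 0, self.nrows - 1)
        row = self.nrows - 1 - row_s  # values stored north-first
        return self.values[row, col]

    def bilinear(self, x, y) -> np.ndarray:
        """Bilinear interpolation between cell centers, clamped at the border."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        inside = self.contains(x, y)
        if not inside.all():
            bad = int(np.flatnonzero(~inside)[0])
            raise ValueError(
                f"sample {bad} at ({x[bad]:.6f}, {y[bad]:.6f}) lies outside "
                f"the grid extent {self.extent}"
            )
        xs, ys = self._center_axes()
        south_first = self.values[::-1]  # rows ascending in y
        fx = np.clip((x - xs[0]) / self.cellsize, 0.0, self.ncols - 1.0)
        fy = np.clip((y - ys[0]) / self.cellsize, 0.0, self.nrows - 1.0)
        i0 = np.clip(fx.astype(int), 0, self.ncols - 2) if self.ncols > 1 else np.zeros_like(fx, int)
        j0 = np.clip(fy.astype(int), 0, self.nrows - 2) if self.nrows > 1 else np.zeros_like(fy, int)
        tx = fx - i0
        ty = fy - j0
        v00 = south_first[j0, i0]
        v01 = south_first[j0, np.minimum(i0 + 1, self.ncols - 1)]
        v10 = south_first[np.minimum(j0 + 1, self.nrows - 1), i0]
        v11 = south_first[np.minimum(j0 + 1, self.nrows - 1),
                          np.minimum(i0 + 1, self.ncols - 1)]
        return (v00 * (1 - tx) * (1 - ty) + v01 * tx * (1 - ty)
                + v10 * (1 - tx) * ty + v11 * tx * ty)


def write_ascii_grid(grid: AsciiGrid, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> AsciiGrid:
    """Parse an ESRI ASCII grid, validating the header against the body."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: malformed grid header, missing {req!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if len(rows) != nrows:
        raise ValueError(f"{path}: header declares nrows={nrows} but body has {len(rows)} rows")
    if any(len(r) != ncols for r in rows):
        raise ValueError(f"{path}: header declares ncols={ncols} but a body row disagrees")
    return AsciiGrid(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        values=np.asarray(rows, dtype=float),
        nodata=header.get("nodata_value", -9999.0),
    )


# ---------------------------------------------------------------------------
# GeoJSON

def track_to_geojson(geotrack: pd.DataFrame, attacks: pd.DataFrame | None = None,
                     path: str | Path | None = None) -> dict:
    """Export a georeferenced track (and attack points) as a GeoJSON FeatureCollection."""
    line = {
        "type": "Feature",
        "properties": {"kind": "track", "n_samples": int(len(geotrack))},
        "geometry": {
            "type": "LineString",
            "coordinates": [
                [float(lon), float(lat), float(alt)]
                for lon, lat, alt in zip(geotrack["lon"], geotrack["lat"],
                                         geotrack["alt_asl_m"])
            ],
        },
    }
    features = [line]
    if attacks is not None:
        for _, row in attacks.iterrows():
            features.append({
                "type": "Feature",
                "properties": {
                    "kind": "attack",
                    "time_s": float(row["time_s"]),
                    "habitat": str(row["habitat"]),
                    "alt_agl_m": float(row["alt_agl_m"]),
                },
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row["lon"]), float(row["lat"])],
                },
            })
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(collection, fh)
    return collection
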