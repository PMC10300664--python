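"""End-to-end pipeline: simulate → localize → calls/buzzes → track → stats.

Each stage reads/writes the plain-text formats in :mod:`batforage.formats`
and appends to a machine-readable run log (seeds, parameters, row counts),
so a run is reproducible from its output directory alone.  Any stage
failure propagates with the stage name attached.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, arrayloc, biologging, callpulse, formats, habstats, synthio
from .config import PipelineConfig


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


def _log(outdir: Path, record: dict) -> None:
    path = outdir / "run_log.json"
    log = []
    if path.exists():
        log = json.loads(path.read_text())
    log.append(record)
    path.write_text(json.dumps(log, indent=1, default=str))


def run_simulate(config: PipelineConfig) -> dict:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene = synthio.SceneConfig(
        sample_rate=config.sample_rate, noise_db=config.noise_db,
        c=config.speed_of_sound,
        gps_interval_s=config.gps_interval_s,
        gps_alt_sigma_m=config.gps_alt_sigma_m,
        gps_dropout=config.gps_dropout,
        attack_rates=dict(config.attack_rates),
        geometry=arrayloc.MicArrayGeometry.y_array(config.array_arm_m),
    )
    scale = config.sim_minutes / sum(synthio.DEFAULT_MINUTES.values())
    minutes = {h: m * scale for h, m in synthio.DEFAULT_MINUTES.items()}
    session = synthio.simulate_logging_session(
        seed=config.seed, minutes=minutes, scene=scene)
    formats.write_table(session["fixes"], outdir / "fixes.csv", "fixes")
    formats.write_table(session["events"], outdir / "events.csv", "events")
    formats.write_table(session["truth"], outdir / "truth.csv")
    formats.write_ascii_grid(session["dem"], outdir / "dem.asc")
    formats.write_ascii_grid(session["habitat_grid"], outdir / "habitat.asc")
    _log(outdir, {"stage": "simulate", "version": __version__,
                  "seed": config.seed,
                  "n_fixes": len(session["fixes"]),
                  "n_events": len(session["events"]),
                  "n_attacks_true": len(session["attacks_true"])})
    return session


def run_localize(config: PipelineConfig) -> pd.DataFrame:
    outdir = Path(config.output_dir)
    if config.audio_path is None or not Path(config.audio_path).exists():
        raise StageError(f"localize: audio file not found: {config.audio_path}")
    audio, fs = formats.read_wav(config.audio_path, n_channels=4)
    geometry = arrayloc.MicArrayGeometry.y_array(config.array_arm_m)
    pulses = callpulse.detect_pulses(audio[:, 0], fs,
                                     snr_floor_db=config.snr_floor_db,
                                     edge_db=config.edge_db)
    times, positions, residuals = [], [], []
    pad = int(0.01 * fs)
    for _, row in pulses.iterrows():
        i0 = max(0, int(row["start_s"] * fs) - pad)
        i1 = min(len(audio), int(row["end_s"] * fs) + pad)
        tdoas = arrayloc.estimate_tdoa(audio[i0:i1], fs, geometry=geometry)
        if not tdoas.localizable:
            continue
        loc = arrayloc.localize(tdoas, geometry, c=config.speed_of_sound)
        if not loc.converged:
            continue
        times.append(row["start_s"])
        positions.append(loc.position)
        residuals.append(loc.residual)
    if not times:
        raise StageError("localize: no pulse could be localized")
    track = arrayloc.assemble_track(np.array(times), np.array(positions),
                                    np.array(residuals),
                                    range_gate_m=config.range_gate_m)
    formats.write_table(track, outdir / "array_track.csv", "track")
    _log(outdir, {"stage": "localize", "n_pulses": len(pulses),
                  "n_localized": len(track)})
    return track


def run_calls(config: PipelineConfig) -> pd.DataFrame:
    outdir = Path(config.output_dir)
    if config.audio_path is None or not Path(config.audio_path).exists():
        raise StageError(f"calls: audio file not found: {config.audio_path}")
    audio, fs = formats.read_wav(config.audio_path, n_channels=4)
    pulses = callpulse.detect_pulses(audio[:, 0], fs,
                                     snr_floor_db=config.snr_floor_db,
                                     edge_db=config.edge_db)
    train = callpulse.extract_features(audio[:, 0], pulses, fs,
                                       edge_db=config.edge_db)
    formats.write_table(train, outdir / "pulses.csv", "pulses")
    _log(outdir, {"stage": "calls", "n_pulses": len(train)})
    return train


def run_buzz(config: PipelineConfig, train: pd.DataFrame | None = None) -> pd.DataFrame:
    outdir = Path(config.output_dir)
    params = callpulse.BuzzRuleParams(
        min_pulses=config.buzz_min_pulses,
        ipi_threshold_ms=config.buzz_ipi_threshold_ms,
        merge_gap_ms=config.buzz_merge_gap_ms)
    if train is None:
        if config.events_path is None or not Path(config.events_path).exists():
            raise StageError(f"buzz: event stream not found: {config.events_path}")
        events = formats.read_table(config.events_path, "events")
        buzzes = callpulse.detect_feeding_buzzes(
            events["time_s"].to_numpy(float), params)
    else:
        buzzes = callpulse.detect_feeding_buzzes(train, params)
    table = callpulse.buzzes_to_table(buzzes)
    formats.write_table(table, outdir / "buzzes.csv", "buzzes")
    _log(outdir, {"stage": "buzz", "n_buzzes": len(table)})
    return table


def run_track(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    outdir = Path(config.output_dir)
    for name, path in (("fixes", config.fixes_path), ("events", config.events_path),
                       ("DEM", config.dem_path), ("habitat", config.habitat_path)):
        if path is None or not Path(path).exists():
            raise StageError(f"track: {name} file not found: {path}")
    fixes = formats.read_table(config.fixes_path, "fixes")
    events = formats.read_table(config.events_path, "events")
    dem = formats.read_ascii_grid(config.dem_path)
    habitat = formats.read_ascii_grid(config.habitat_path)
    params = callpulse.BuzzRuleParams(
        min_pulses=config.buzz_min_pulses,
        ipi_threshold_ms=config.buzz_ipi_threshold_ms,
        merge_gap_ms=config.buzz_merge_gap_ms)
    track, attacks = biologging.build_geotrack(fixes, events, dem, habitat,
                                               buzz_params=params)
    formats.write_table(track, outdir / "geotrack.csv", "geotrack")
    attacks_out = attacks.rename(columns={})
    formats.write_table(attacks_out, outdir / "attacks.csv")
    formats.track_to_geojson(track, attacks, outdir / "track.geojson")
    n_neg, pct_neg = biologging.negative_altitude_share(track["alt_agl_m"])
    _log(outdir, {"stage": "track", "n_samples": len(track),
                  "n_attacks": len(attacks),
                  "n_negative_agl": n_neg, "pct_negative_agl": round(pct_neg, 1)})
    return track, attacks


def run_stats(config: PipelineConfig, track: pd.DataFrame | None = None,
              attacks: pd.DataFrame | None = None) -> dict:
    outdir = Path(config.output_dir)
    if track is None:
        track = formats.read_table(outdir / "geotrack.csv", "geotrack")
    if attacks is None:
        attacks = pd.read_csv(outdir / "attacks.csv")
    summary = habstats.summarize_habitats(track, attacks)
    formats.write_table(summary, outdir / "habitat_summary.csv")
    results = {"summary": summary}
    y_attack = track["attack"].to_numpy(float)
    fit_a = habstats.fit_attack_model(y_attack, track["habitat"].to_numpy())
    fit_h = habstats.fit_altitude_model(
        track["alt_agl_m"].to_numpy(float), track["habitat"].to_numpy(),
        habstats.SubsampleSpec(config.subsample_altitude_n, config.seed))
    fit_v = habstats.fit_speed_model(
        track["speed_ms"].to_numpy(float), track["habitat"].to_numpy(),
        habstats.SubsampleSpec(config.subsample_speed_n, config.seed))
    report_lines = []
    for fit in (fit_a, fit_h, fit_v):
        formats.write_table(fit.estimates, outdir / f"model_{fit.model}_estimates.csv")
        formats.write_table(fit.contrasts, outdir / f"model_{fit.model}_contrasts.csv")
        results[fit.model] = fit
        report_lines.append(f"model {fit.model}: overall {fit.overall}; note: {fit.note}")
    (outdir / "stats_report.txt").write_text("\n".join(report_lines) + "\n")
    _log(outdir, {"stage": "stats",
                  "attack_overall_p": fit_a.overall["p"],
                  "altitude_overall_p": fit_h.overall["p"],
                  "speed_overall_p": fit_v.overall["p"]})
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the config has inputs for; 'simulate' fills in the rest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    try:
        if config.fixes_path is None:
            run_simulate(config)
            config.fixes_path = str(outdir / "fixes.csv")
            config.events_path = str(outdir / "events.csv")
            config.dem_path = str(outdir / "dem.asc")
            config.habitat_path = str(outdir / "habitat.asc")
        if config.audio_path is not None:
            results["array_track"] = run_localize(config)
            results["pulses"] = run_calls(config)
            results["buzzes"] = run_buzz(config, results["pulses"])
        track, attacks = run_track(config)
        results["geotrack"], results["attacks"] = track, attacks
        results["stats"] = run_stats(config, track, attacks)
    except StageError:
        raise
    except Exception as exc:
        stage = sys.exc_info()[2].tb_frame.f_globals.get("__name__", "?")
        raise StageError(f"pipeline failed ({stage}): {exc}") from exc
    return results
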