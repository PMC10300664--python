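"""Pipeline configuration: one YAML file, defaults at the study's values.

Every numeric default is the analysis' operating value: −15 dB pulse/spectral
edges, the 0.60 kHz/ms QCF sweep-rate boundary, the feeding-buzz rule
(≥5 pulses, IPI < 20 ms, 100 ms merge gap), the 47 m array validity radius,
balanced subsamples of 76 (speed) and 40 (altitude) points per habitat, and
1000 bootstrap replicates.  A config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # paths (any may be None when the stage is skipped or simulated)
    audio_path: str | None = None
    fixes_path: str | None = None
    events_path: str | None = None
    dem_path: str | None = None
    habitat_path: str | None = None
    output_dir: str = "out"

    # acoustic analysis
    sample_rate: int = 250_000          # Hz; must exceed 4x the highest call frequency
    edge_db: float = 15.0               # pulse/spectral edges relative to peak
    snr_floor_db: float = 12.0          # detection floor above the noise median
    qcf_sweep_rate: float = 0.60        # kHz/ms boundary; at or below -> QCF

    # feeding-buzz rule
    buzz_min_pulses: int = 5
    buzz_ipi_threshold_ms: float = 20.0
    buzz_merge_gap_ms: float = 100.0

    # localization
    speed_of_sound: float = 343.0       # m/s at ~20 C
    array_arm_m: float = 1.0
    range_gate_m: float = 47.0          # validity radius of the array

    # statistics
    subsample_speed_n: int = 76
    subsample_altitude_n: int = 40
    bootstrap_B: int = 1000

    # simulation
    seed: int = 0
    sim_minutes: float = 43.5
    gps_interval_s: float = 5.0
    gps_alt_sigma_m: float = 10.0
    gps_dropout: float = 0.0
    noise_db: float = -40.0
    attack_rates: dict = field(default_factory=lambda: {
        "river": 3.28, "mountain": 2.96, "urban": 1.0})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
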