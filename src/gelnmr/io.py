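"""File formats and pipeline configuration.

All tabular outputs are UTF-8 comma-separated text with unit-suffixed
column names; metadata (package version, seed, config hash, acquisition
settings) is embedded as leading ``# key=value`` comment lines so every
output file is self-describing and reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synth import AcquisitionSpec, MagnetizationCurve, NMRDProfile

__all__ = [
    "PipelineConfig",
    "load_config",
    "config_hash",
    "write_profile_csv",
    "read_profile_csv",
    "write_curve_csv",
    "read_curve_csv",
    "write_json",
    "read_json",
]

PROFILE_COLUMNS = ["frequency_MHz", "R1_per_s", "rel_error"]
CURVE_COLUMNS = ["time_s", "amplitude"]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (synthetic generation -> fits -> reports).

    The CPMG validation decays default to 256 echoes so that the long T2
    component of each gel is sampled over two time constants; the emulated
    benchtop acquisition (128 echoes) remains available via
    ``cpmg_n_echoes``.
    """

    samples: list = field(default_factory=lambda: ["SUC", "SBF10", "SCG40", "SCG60"])
    temperatures: list = field(default_factory=lambda: [25.0, 4.0])
    reference: str = "SUC"
    seed: int = 0
    outdir: str = "gelnmr_out"
    # dispersion simulation
    f_min_hz: float = 1e4
    f_max_hz: float = 2e7
    n_frequencies: int = 30
    extra_frequencies_hz: list = field(default_factory=lambda: [5e8])
    noise_fraction: float = 0.02
    # CPMG simulation
    cpmg_echo_time_s: float = 100e-6
    cpmg_n_echoes: int = 256
    cpmg_noise_sd: float = 0.01
    # fitting protocol
    n_multistart: int = 8
    downweight_window_hz: list | None = None
    # T2 analysis
    n_t2_components: int = 2
    ilt_regularization: float = 0.1
    # quality metrics
    quality_input: str | None = None
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# CSV with embedded '# key=value' metadata
# ---------------------------------------------------------------------------

def _write_csv(path, df: pd.DataFrame, meta: dict):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# gelnmr_version={__version__}"]
    lines += [f"# {k}={v}" for k, v in meta.items()]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path):
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    return df, meta


def write_profile_csv(profile: NMRDProfile, path, extra_meta: dict | None = None):
    df = pd.DataFrame(
        {
            "frequency_MHz": profile.frequency_hz / 1e6,
            "R1_per_s": profile.R1,
            "rel_error": profile.relative_error,
        }
    )
    meta = {
        "sample": profile.sample_id,
        "temperature_C": profile.temperature_C,
        **(extra_meta or {}),
    }
    _write_csv(path, df, meta)


def read_profile_csv(path) -> NMRDProfile:
    df, meta = _read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return NMRDProfile(
        sample_id=meta.get("sample", Path(path).stem),
        temperature_C=float(meta.get("temperature_C", "nan")),
        frequency_hz=df["frequency_MHz"].to_numpy() * 1e6,
        R1=df["R1_per_s"].to_numpy(),
        relative_error=df["rel_error"].to_numpy(),
    )


def write_curve_csv(curve: MagnetizationCurve, path, extra_meta: dict | None = None):
    df = pd.DataFrame({"time_s": curve.times, "amplitude": curve.amplitudes})
    spec = curve.spec
    meta = {
        "sequence": spec.sequence,
        "n_points": spec.n_points,
        "echo_time_s": spec.echo_time,
        "n_echoes": spec.n_echoes,
        "relaxation_period_s": spec.relaxation_period,
        **(extra_meta or {}),
    }
    _write_csv(path, df, meta)


def read_curve_csv(path) -> MagnetizationCurve:
    df, meta = _read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    spec = AcquisitionSpec(
        sequence=meta.get("sequence", "CPMG"),
        n_points=int(float(meta.get("n_points", 22))),
        echo_time=float(meta.get("echo_time_s", 100e-6)),
        n_echoes=int(float(meta.get("n_echoes", len(df)))),
        relaxation_period=float(meta.get("relaxation_period_s", 0.3)),
    )
    return MagnetizationCurve(
        spec=spec,
        times=df["time_s"].to_numpy(),
        amplitudes=df["amplitude"].to_numpy(),
    )


def write_json(path, payload: dict):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
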