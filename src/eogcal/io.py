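"""CSV/JSON readers and writers for recordings, gaze data and calibrations.

All CSV files are comma-separated UTF-8 with a required header and '.'
decimal separator; floats are serialized with 12 significant digits so
write -> read round-trips are bit-stable at double precision for these
schemas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import AffineParams, GazeDataset, QuadrantParams, QuadrantTransform
from .evaluation import ViewingGeometry
from .signals import BandpassSpec, ThresholdPair, TwoChannelRecording

__all__ = [
    "FLOAT_FORMAT",
    "write_signal_csv",
    "read_signal_csv",
    "write_gazing_csv",
    "read_gazing_csv",
    "write_calibration_json",
    "read_calibration_json",
    "load_signal_config",
    "load_geometry_config",
]

FLOAT_FORMAT = "%.12g"

SIGNAL_COLUMNS = ["time_s", "ch1_v", "ch2_v"]
GAZING_COLUMNS = ["target_x_px", "target_y_px", "raw_x", "raw_y", "label"]
_QUADRANT_FIELDS = ["tx", "ty", "m1", "m2", "theta_rad", "sx", "sy"]


def write_signal_csv(path: str | Path, rec: TwoChannelRecording) -> None:
    df = pd.DataFrame({"time_s": rec.t, "ch1_v": rec.ch1, "ch2_v": rec.ch2})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_signal_csv(path: str | Path, fs: float | None = None) -> TwoChannelRecording:
    """Read a two-channel recording; fs is inferred from the time column
    unless given explicitly."""
    df = pd.read_csv(path)
    missing = set(SIGNAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing signal CSV columns {sorted(missing)}")
    t = df["time_s"].to_numpy(float)
    if fs is None:
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    return TwoChannelRecording(
        t=t, ch1=df["ch1_v"].to_numpy(float), ch2=df["ch2_v"].to_numpy(float), fs=fs
    )


def write_gazing_csv(path: str | Path, data: GazeDataset) -> None:
    df = pd.DataFrame(
        {
            "target_x_px": data.targets[:, 0],
            "target_y_px": data.targets[:, 1],
            "raw_x": data.raw[:, 0],
            "raw_y": data.raw[:, 1],
            "label": data.labels,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_gazing_csv(path: str | Path) -> GazeDataset:
    df = pd.read_csv(path)
    missing = set(GAZING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing gazing CSV columns {sorted(missing)}")
    for col in GAZING_COLUMNS[:4]:
        bad = df.index[~np.isfinite(df[col].to_numpy(float))]
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(f"{path}: non-finite value in column {col!r} at line {bad[0] + 2}")
    return GazeDataset(
        targets=df[["target_x_px", "target_y_px"]].to_numpy(float),
        raw=df[["raw_x", "raw_y"]].to_numpy(float),
        labels=[str(l) for l in df["label"]],
    )


def write_calibration_json(path: str | Path, params: AffineParams | QuadrantParams) -> None:
    if isinstance(params, AffineParams):
        payload = {
            "method": "proposed",
            "Tx": params.tx,
            "Ty": params.ty,
            "m1": params.m1,
            "m2": params.m2,
            "theta_rad": params.theta,
            "s1": params.s1,
            "s2": params.s2,
            "s3": params.s3,
            "s4": params.s4,
        }
    elif isinstance(params, QuadrantParams):
        payload = {
            "method": "quadrant",
            "quadrants": [
                {k: getattr(q, k if k != "theta_rad" else "theta") for k in _QUADRANT_FIELDS}
                for q in params.quadrants
            ],
        }
    else:
        raise TypeError(f"unsupported calibration type {type(params).__name__}")
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_calibration_json(path: str | Path) -> AffineParams | QuadrantParams:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    method = payload.get("method")
    if method == "proposed":
        return AffineParams(
            tx=payload["Tx"],
            ty=payload["Ty"],
            m1=payload["m1"],
            m2=payload["m2"],
            theta=payload["theta_rad"],
            s1=payload["s1"],
            s2=payload["s2"],
            s3=payload["s3"],
            s4=payload["s4"],
        )
    if method == "quadrant":
        quads = payload["quadrants"]
        if len(quads) != 4:
            raise ValueError(f"{path}: quadrant calibration needs 4 transforms, got {len(quads)}")
        return QuadrantParams(
            quadrants=tuple(
                QuadrantTransform(
                    tx=q["tx"], ty=q["ty"], m1=q["m1"], m2=q["m2"],
                    theta=q["theta_rad"], sx=q["sx"], sy=q["sy"],
                )
                for q in quads
            )
        )
    raise ValueError(f"{path}: unknown calibration method {method!r}")


def load_signal_config(path: str | Path) -> tuple[ThresholdPair, BandpassSpec, float]:
    """Load threshold/filter settings: (thresholds, band-pass spec, fs)."""
    cfg = json.loads(Path(path).read_text(encoding="utf-8"))
    th = ThresholdPair(th_plus=cfg["th_plus"], th_minus=cfg["th_minus"])
    spec = BandpassSpec(
        f_low=cfg.get("f_low", 1.06), f_high=cfg.get("f_high", 4.97), order=cfg.get("order", 2)
    )
    return th, spec, float(cfg.get("fs", 1000.0))


def load_geometry_config(path: str | Path) -> tuple[ViewingGeometry, dict]:
    """Load viewing geometry and grid layout from a config JSON."""
    cfg = json.loads(Path(path).read_text(encoding="utf-8"))
    geom = ViewingGeometry(
        distance_cm=cfg.get("distance_cm", 35.0),
        pixel_pitch_mm=cfg.get("pixel_pitch_mm", 0.25),
    )
    grid_cfg = cfg.get("grid", {})
    return geom, {
        "n_directions": int(grid_cfg.get("directions", 8)),
        "eccentricities": tuple(grid_cfg.get("eccentricities_px", (100.0, 200.0, 300.0))),
    }
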