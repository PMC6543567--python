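"""File formats: 8-bit PNG images, JSON profiles/results, CSV tables."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .calibration import CameraCalibration
from .geometry import Rect
from .reader import StripReadResult
from .scale import BinEdges, ProteinLevel
from .synthetic import GroundTruth


def save_image_png(path, image: np.ndarray) -> None:
    """Write a float [0, 1] RGB image as 8-bit PNG."""
    arr = np.asarray(image, dtype=float)
    data = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="RGB").save(path)


def load_image_png(path) -> np.ndarray:
    """Read a PNG into a float [0, 1] RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=float) / 255.0


def save_calibration(path, calibration: CameraCalibration) -> None:
    payload = {
        "gains": list(calibration.gains),
        "reference_hue_deg": calibration.reference_hue_deg,
        "tolerance_deg": calibration.tolerance_deg,
        "verified": calibration.verified,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(path) -> CameraCalibration:
    payload = json.loads(Path(path).read_text())
    return CameraCalibration(
        gains=tuple(payload["gains"]),
        reference_hue_deg=float(payload["reference_hue_deg"]),
        tolerance_deg=float(payload.get("tolerance_deg", 5.0)),
        verified=bool(payload.get("verified", False)),
    )


def save_edges(path, edges: BinEdges) -> None:
    Path(path).write_text(json.dumps({"edges_deg": list(edges.edges_deg)}, indent=2))


def load_edges(path) -> BinEdges:
    payload = json.loads(Path(path).read_text())
    return BinEdges(tuple(payload["edges_deg"]))


def save_titration(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, columns=["level", "hue_deg"])


def load_titration(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"level": str, "hue_deg": float})


def save_ground_truth(path, truth: GroundTruth, extra: dict | None = None) -> None:
    payload = {
        "pad_bbox": dataclasses.asdict(truth.pad_bbox),
        "hue_deg": truth.hue_deg,
        "level": truth.level.label if truth.level is not None else None,
    }
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2))


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    level = payload.get("level")
    return GroundTruth(
        pad_bbox=Rect(**payload["pad_bbox"]),
        hue_deg=float(payload["hue_deg"]),
        level=ProteinLevel.from_label(level) if level else None,
    )


def result_to_dict(result: StripReadResult) -> dict:
    return {
        "grand_mean_hue_deg": result.hue.grand_mean_deg,
        "per_frame_means": list(result.hue.per_frame_means_deg),
        "n_frames": result.hue.n_frames,
        "n_samples": result.hue.n_samples,
        "level": result.level.label,
        "category": result.category.label,
        "calibration_passed": result.calibration_passed,
        "timestamp": result.timestamp.isoformat(),
    }


def save_result(path, result: StripReadResult) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result), indent=2))
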