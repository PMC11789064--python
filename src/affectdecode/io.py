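"""File formats: ratings CSV, feature-bank manifest + NPY arrays, JSON records.

A feature bank on disk is a directory with a ``manifest.json`` naming the
model, provenance, image ids, and an ordered list of layer records (id,
width, relative depth, array file, SHA-256 checksum), plus one ``.npy``
array per layer.  Readers validate rather than coerce: checksum, shape,
and schema violations raise with the offending row/file named.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bank import FeatureBank, LayerFeatures, flatten_features
from .reliability import RATING_COLUMNS, ReliabilityReport, validate_ratings

__all__ = [
    "read_ratings",
    "write_ratings",
    "read_feature_bank",
    "write_feature_bank",
    "write_reliability_report",
    "write_json",
    "config_hash",
]


def read_ratings(path: str | Path, scale: tuple[float, float] = (0.0, 7.0)) -> pd.DataFrame:
    """Read and validate a long-format ratings CSV."""
    path = Path(path)
    table = pd.read_csv(path, dtype={"respondent_id": str, "image_id": str})
    return validate_ratings(table, scale=scale)


def write_ratings(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.loc[:, list(RATING_COLUMNS)].to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_feature_bank(bank: FeatureBank, directory: str | Path) -> Path:
    """Write a bank as manifest.json + one .npy per layer."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for layer in bank.layers:
        fname = f"{layer.layer_id}.npy"
        np.save(directory / fname, layer.array)
        records.append(
            {
                "layer_id": layer.layer_id,
                "depth": layer.depth,
                "width": int(layer.width),
                "file": fname,
                "sha256": _sha256(directory / fname),
            }
        )
    manifest = {
        "model_id": bank.model_id,
        "provenance": bank.provenance,
        "image_ids": list(bank.image_ids),
        "layers": records,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return directory


def read_feature_bank(directory: str | Path) -> FeatureBank:
    """Read a bank directory; checksums and shapes are verified, multi-axis
    arrays are flattened row-wise to images x D."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    n = len(manifest["image_ids"])
    layers = []
    for rec in manifest["layers"]:
        fpath = directory / rec["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest lists {rec['file']} but the file is absent")
        digest = _sha256(fpath)
        if digest != rec["sha256"]:
            raise ValueError(f"checksum mismatch for {rec['file']}")
        arr = flatten_features(np.load(fpath))
        if arr.shape != (n, rec["width"]):
            raise ValueError(
                f"layer {rec['layer_id']!r}: array shape {arr.shape} does not match "
                f"manifest ({n}, {rec['width']})"
            )
        layers.append(LayerFeatures(rec["layer_id"], rec["depth"], arr))
    return FeatureBank(
        model_id=manifest["model_id"],
        image_ids=list(manifest["image_ids"]),
        layers=layers,
        provenance=manifest.get("provenance", "external"),
    )


def write_reliability_report(report: ReliabilityReport, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "reliability.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    report.r_mm1.rename_axis("respondent_id").reset_index().to_csv(
        directory / "mm1.csv", index=False
    )
    return directory


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)
    return path


def config_hash(params: dict) -> str:
    """Stable short hash of a parameter dict, recorded in every run output."""
    canon = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
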