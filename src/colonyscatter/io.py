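"""File formats, run configuration, and model persistence.

Everything the CLI writes is plain and inspectable: scatter patterns as
single-channel 8/16-bit TIFF or PNG, features as CSV tables keyed by the
(n, m) moment indices, trained models as JSON, and run configurations as
YAML/JSON that round-trip losslessly and reject unknown keys.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .classify import SVMHyperparams, TrainedModel
from .features import FeatureVector
from .phantoms import BAD_PARAMS, GOOD_PARAMS, PhantomParams
from .scattering import OpticalConfig, ScatterPattern

__all__ = [
    "FeatureConfig",
    "MorphometryConfig",
    "RunConfig",
    "read_pattern_image",
    "write_pattern_image",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class FeatureConfig:
    n_max: int = 17
    n_selected: int = 161
    log_compress: bool = True


@dataclass(frozen=True)
class MorphometryConfig:
    z_step_um: float = 2.0
    stack_noise_sd: float = 0.0
    oct4_fraction_good: float = 0.9
    oct4_fraction_bad: float = 0.5
    n_per_class: int = 18


def _from_dict(cls, data: dict):
    """Build a (nested) dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    types = {f.name: f.type for f in dataclasses.fields(cls)}
    nested = {
        "good_phantom": PhantomParams,
        "bad_phantom": PhantomParams,
        "optics": OpticalConfig,
        "features": FeatureConfig,
        "classifier": SVMHyperparams,
        "morphometry": MorphometryConfig,
    }
    for key, value in data.items():
        if key in nested and isinstance(value, dict):
            kwargs[key] = _from_dict(nested[key], value)
        elif isinstance(value, list) and "tuple" in str(types.get(key, "")):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration: every stage's parameter block + seed."""

    good_phantom: PhantomParams = GOOD_PARAMS
    bad_phantom: PhantomParams = BAD_PARAMS
    optics: OpticalConfig = OpticalConfig()
    features: FeatureConfig = FeatureConfig()
    classifier: SVMHyperparams = SVMHyperparams()
    morphometry: MorphometryConfig = MorphometryConfig()
    seed: int = 0
    output_dir: str = "runs"
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return _to_plain(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Pattern images
# ---------------------------------------------------------------------------

def write_pattern_image(pattern: ScatterPattern, path: str | Path, bit_depth: int = 16) -> None:
    """Write a scatter pattern as a single-channel 8- or 16-bit image.

    Intensities are scaled so the image maximum hits the top code value.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    intensity = np.asarray(pattern.intensity, dtype=float)
    peak = intensity.max()
    top = 2**bit_depth - 1
    scaled = np.zeros_like(intensity) if peak <= 0 else intensity / peak * top
    arr = np.round(scaled).astype(np.uint16 if bit_depth == 16 else np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_pattern_image(
    path: str | Path,
    pixel_pitch: float | None = None,
    config: OpticalConfig | None = None,
    label: str | None = None,
) -> ScatterPattern:
    """Read a single-channel 8/16-bit pattern image as non-negative floats.

    Metadata the file cannot carry (pixel pitch, optical config) falls
    back to package defaults with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"pattern image not found: {path}")
    arr = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else iio.imread(path)
    if arr.ndim != 2:
        raise IOError(
            f"expected a single-channel image, got shape {arr.shape} from {path}"
        )
    if pixel_pitch is None:
        pixel_pitch = 2.0
        warnings.warn(f"{path.name}: no pixel pitch supplied; assuming {pixel_pitch} um/px")
    if config is None:
        config = OpticalConfig()
    return ScatterPattern(
        intensity=np.asarray(arr, dtype=float),
        pixel_pitch_detector=float(pixel_pitch),
        config=config,
        label=label,
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _fid_str(fid) -> str:
    n, m = fid
    return f"n{n}_m{m}"


def _parse_fid(s: str) -> tuple[int, int]:
    try:
        n_part, m_part = s.split("_")
        return (int(n_part[1:]), int(m_part[1:]))
    except Exception as exc:  # noqa: BLE001 - rewrap any malformed header
        raise ValueError(f"malformed feature column name {s!r}") from exc


def write_feature_table(vectors: list[FeatureVector], path: str | Path) -> None:
    """Write feature vectors to CSV: source_id, label, then one (n, m) column each."""
    path = Path(path)
    if vectors:
        ids = vectors[0].feature_ids
        for v in vectors:
            if list(v.feature_ids) != list(ids):
                raise ValueError("all vectors must share the same feature ids")
        df = pd.DataFrame(
            np.vstack([v.values for v in vectors]), columns=[_fid_str(f) for f in ids]
        )
        df.insert(0, "label", [v.label if v.label is not None else "" for v in vectors])
        df.insert(0, "source_id", [v.source_id for v in vectors])
    else:
        df = pd.DataFrame(columns=["source_id", "label"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    """Read a feature CSV back into FeatureVectors.

    A table without a label column yields vectors with ``label=None``
    (labels are never fabricated).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed feature table {path}: {exc}") from exc
    feature_cols = [c for c in df.columns if c not in ("source_id", "label")]
    ids = [_parse_fid(c) for c in feature_cols]
    has_label = "label" in df.columns
    out = []
    for _, row in df.iterrows():
        label = None
        if has_label:
            raw = row["label"]
            label = None if (pd.isna(raw) or raw == "") else str(raw)
        out.append(
            FeatureVector(
                values=row[feature_cols].to_numpy(dtype=float),
                feature_ids=ids,
                source_id=str(row["source_id"]) if "source_id" in df.columns else "",
                label=label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model to portable JSON."""
    payload = {
        "kernel": model.kernel,
        "C": model.C,
        "gamma_value": model.gamma_value,
        "classes": model.classes,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "feature_ids": [list(f) for f in model.feature_ids] if model.feature_ids else None,
        "training_accuracy": model.training_accuracy,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    data = json.loads(Path(path).read_text())
    return TrainedModel(
        kernel=data["kernel"],
        C=data["C"],
        gamma_value=data["gamma_value"],
        classes=list(data["classes"]),
        support_vectors=np.array(data["support_vectors"], dtype=float),
        dual_coef=np.array(data["dual_coef"], dtype=float),
        intercept=float(data["intercept"]),
        scaler_mean=np.array(data["scaler_mean"], dtype=float),
        scaler_scale=np.array(data["scaler_scale"], dtype=float),
        feature_ids=(
            [tuple(f) for f in data["feature_ids"]] if data["feature_ids"] else None
        ),
        training_accuracy=float(data["training_accuracy"]),
    )
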