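"""Readers/writers for on-disk artifacts and run configuration.

Conventions: (row, col) coordinates, origin top-left; images are written as
16-bit grayscale PNG with intensities mapped from [0, 1]; label maps as 8-bit
indexed PNG whose palette follows the class legend; configuration as YAML
with strict (unknown keys rejected) schema; manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, UnidentifiedImageError

from .losses import LossConfig
from .model import ModelConfig
from .phantom import PhantomSpec
from .pipeline import AugmentSpec, SliceSpec
from .train import TrainConfig

__all__ = [
    "ClassLegend", "RunConfig", "read_image", "write_image", "read_labels",
    "write_labels", "write_overlay", "load_config", "save_config",
    "write_manifest", "read_manifest",
]

log = logging.getLogger(__name__)

# display colors per class (R, G, B), background first; the 10th entry is the
# fluid class used in the diseased-retina mode
_DEFAULT_COLORS = [
    (0, 0, 0), (228, 26, 28), (55, 126, 184), (77, 175, 74), (152, 78, 163),
    (255, 127, 0), (255, 255, 51), (166, 86, 40), (247, 129, 191),
    (0, 206, 209),
]

_NAMES_9 = ["BG", "NFL", "GCL+IPL", "INL", "OPL", "ONL+IS", "OS", "OPR", "RPE"]


@dataclass
class ClassLegend:
    """Mapping class id -> (name, display color); ids contiguous from 0."""

    names: list[str]
    colors: list[tuple[int, int, int]]

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("legend names must be unique")
        if len(self.colors) < len(self.names):
            raise ValueError("legend needs one color per class")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    @classmethod
    def default(cls, n_classes: int = 9) -> "ClassLegend":
        if n_classes == 9:
            names = list(_NAMES_9)
        elif n_classes == 10:
            names = _NAMES_9 + ["Fluid"]
        else:
            names = [f"class{i}" for i in range(n_classes)]
        colors = [_DEFAULT_COLORS[i % len(_DEFAULT_COLORS)]
                  for i in range(n_classes)]
        return cls(names=names, colors=colors)

    def palette(self) -> list[int]:
        flat = []
        for c in self.colors:
            flat.extend(c)
        return flat


class ReadError(IOError):
    pass


# ---- images ------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """8/16-bit grayscale PNG/TIFF -> float array in [0, 1]."""
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except (UnidentifiedImageError, OSError) as e:
        raise ReadError(f"cannot read image {path}: {e}") from e
    if img.mode in ("RGB", "RGBA", "P"):
        log.warning("converting %s-mode image %s to grayscale", img.mode, path)
        img = img.convert("L")
    arr = np.asarray(img)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def write_image(path, image: np.ndarray) -> None:
    """[0, 1] float raster -> 16-bit grayscale PNG (lossless at 16 bits)."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    quant = np.round(arr * 65535.0).astype(np.uint16)
    Image.fromarray(quant).save(Path(path), format="PNG")


# ---- label maps --------------------------------------------------------------

def read_labels(path, n_classes: int) -> np.ndarray:
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except (UnidentifiedImageError, OSError) as e:
        raise ReadError(f"cannot read label map {path}: {e}") from e
    arr = np.asarray(img, dtype=np.int64)
    if arr.ndim != 2:
        raise ValueError(f"label map {path} must be single-channel indexed")
    bad = np.unique(arr[arr >= n_classes])
    if bad.size:
        raise ValueError(
            f"label map {path} contains values >= n_classes={n_classes}: "
            f"{bad.tolist()}")
    return arr.astype(np.uint8)


def write_labels(path, labels: np.ndarray,
                 legend: ClassLegend | None = None) -> None:
    """Integer label map -> 8-bit indexed PNG with the legend's palette."""
    labels = np.asarray(labels)
    if labels.max() > 255:
        raise ValueError("label values exceed 8-bit range")
    legend = legend or ClassLegend.default(int(labels.max()) + 1)
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    img.putpalette(legend.palette())
    img.save(Path(path), format="PNG")


def write_overlay(path, labels: np.ndarray, legend: ClassLegend) -> None:
    """Colorized RGB rendering of a label map, same geometry as the input."""
    labels = np.asarray(labels)
    lut = np.zeros((256, 3), dtype=np.uint8)
    for i, c in enumerate(legend.colors):
        lut[i] = c
    rgb = lut[labels]
    Image.fromarray(rgb, mode="RGB").save(Path(path), format="PNG")


# ---- manifests ---------------------------------------------------------------

def write_manifest(path, entries: list[dict], meta: dict | None = None) -> None:
    with open(path, "w") as f:
        json.dump({"meta": meta or {}, "entries": entries}, f, indent=2)


def read_manifest(path) -> tuple[list[dict], dict]:
    with open(path) as f:
        data = json.load(f)
    return data["entries"], data.get("meta", {})


# ---- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """All knobs of a run, nested per pipeline stage."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    slicing: SliceSpec = field(default_factory=SliceSpec)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    class_names: list[str] | None = None

    def __post_init__(self):
        # a single loss/model record governs the run
        self.train.loss = self.loss
        self.train.model = self.model

    def legend(self) -> ClassLegend:
        if self.class_names:
            return ClassLegend(names=list(self.class_names),
                               colors=[_DEFAULT_COLORS[i % len(_DEFAULT_COLORS)]
                                       for i in range(len(self.class_names))])
        return ClassLegend.default(self.model.n_classes)


class ConfigSchemaError(ValueError):
    pass


_SECTIONS = {
    "phantom": PhantomSpec,
    "slicing": SliceSpec,
    "augment": AugmentSpec,
    "model": ModelConfig,
    "loss": LossConfig,
    "train": TrainConfig,
}
_TUPLE_FIELDS = {"fluid_axes", "contrast_range", "brightness_range",
                 "erase_area_range", "erase_aspect_range", "encoder_channels"}
# nested records configured through their own sections
_SKIP_FIELDS = {("train", "loss"), ("train", "model")}


def _build_section(name: str, cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields or (name, key) in _SKIP_FIELDS:
            raise ConfigSchemaError(
                f"unknown key {key!r} in section {name!r}; expected one of "
                f"{sorted(k for k in fields if (name, k) not in _SKIP_FIELDS)}")
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        if key == "class_weights" and value is not None:
            value = np.asarray(value, dtype=float)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigSchemaError(f"invalid section {name!r}: {e}") from e


def load_config(path) -> RunConfig:
    """YAML/JSON -> RunConfig with defaults for absent sections; unknown keys
    are rejected with an error naming the key."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ConfigSchemaError("configuration root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"class_names"}
    if unknown:
        raise ConfigSchemaError(
            f"unknown configuration sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(name, cls, raw.get(name) or {})
    names = raw.get("class_names")
    return RunConfig(class_names=names, **kwargs)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(path, rc: RunConfig) -> None:
    doc = {}
    for name in _SECTIONS:
        section = _to_plain(getattr(rc, name))
        if name == "train":
            section.pop("loss", None)
            section.pop("model", None)
        doc[name] = section
    if rc.class_names:
        doc["class_names"] = list(rc.class_names)
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)
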