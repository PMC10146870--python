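"""Synthetic layered OCT B-scan phantoms with exact ground-truth label maps.

The generator emulates the structure of retinal spectral-domain OCT B-scans:
a stack of horizontal tissue layers with smooth, anatomically ordered
boundaries, a foveal thinning pit, multiplicative speckle noise, vertical
vessel-shadow attenuation, and (optionally) dark intraretinal fluid pockets
labeled as their own class.  Every image comes with a pixel-exact label map,
so the whole training/evaluation pipeline is testable without real data.

Class convention: 0 = background (vitreous above / choroid-sclera below),
1..n_layers = retinal layers in anatomical top-to-bottom order,
n_layers+1 = accumulated fluid (only when ``fluid_enabled``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhantomSpec", "PhantomPair", "generate_phantom", "generate_dataset"]


class PhantomConfigError(ValueError):
    """A phantom specification violates one of its invariants."""


def _default_thickness() -> list[float]:
    # eight bands, inner (thin NFL) to outer (RPE), in pixels at 128-row scale
    return [8.0, 12.0, 8.0, 7.0, 14.0, 6.0, 6.0, 8.0]


def _default_intensities() -> list[float]:
    # mean reflectivity per layer: bright NFL, dark nuclear layers, bright RPE
    return [0.80, 0.45, 0.60, 0.40, 0.25, 0.65, 0.50, 0.90]


@dataclass
class PhantomSpec:
    """Geometry, optics and noise parameters of one synthetic B-scan."""

    height: int = 128
    width: int = 128
    n_layers: int = 8
    layer_mean_thickness: list[float] = field(default_factory=_default_thickness)
    boundary_smoothness: float = 3.0      # low-frequency undulation amplitude, px
    foveal_dip_depth: float = 10.0        # 0 disables
    foveal_dip_width: float = 20.0        # Gaussian sigma, px
    layer_intensities: list[float] = field(default_factory=_default_intensities)
    background_intensity: float = 0.05
    speckle_level: float = 0.25           # multiplicative gamma-noise scale
    vessel_count: int = 2
    vessel_width: float = 6.0
    vessel_attenuation: float = 0.45      # multiplier under a vessel shadow
    fluid_enabled: bool = False
    fluid_count: int = 2
    fluid_axes: tuple[float, float] = (6.0, 12.0)  # (row, col) semi-axes, px
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return self.n_layers + (2 if self.fluid_enabled else 1)

    @property
    def fluid_class(self) -> int | None:
        return self.n_layers + 1 if self.fluid_enabled else None

    def validate(self) -> None:
        if len(self.layer_intensities) != self.n_layers:
            raise PhantomConfigError(
                f"layer_intensities has {len(self.layer_intensities)} entries "
                f"but n_layers={self.n_layers}")
        if len(self.layer_mean_thickness) != self.n_layers:
            raise PhantomConfigError(
                f"layer_mean_thickness has {len(self.layer_mean_thickness)} "
                f"entries but n_layers={self.n_layers}")
        total = float(np.sum(self.layer_mean_thickness))
        if total >= self.height:
            raise PhantomConfigError(
                f"total layer thickness {total:.1f}px must be < height "
                f"{self.height}px (background must exist above and below)")
        for name in ("height", "width", "n_layers"):
            if getattr(self, name) <= 0:
                raise PhantomConfigError(f"{name} must be strictly positive")
        if any(t <= 0 for t in self.layer_mean_thickness):
            raise PhantomConfigError("layer thicknesses must be strictly positive")
        if self.speckle_level < 0:
            raise PhantomConfigError("speckle_level must be >= 0")
        if not 0.0 <= self.vessel_attenuation <= 1.0:
            raise PhantomConfigError("vessel_attenuation must lie in [0, 1]")


@dataclass
class PhantomPair:
    """A synthetic B-scan and its aligned ground-truth label map."""

    image: np.ndarray   # float64 (H, W) in [0, 1]
    labels: np.ndarray  # uint8 (H, W), values in [0, n_classes)
    seed: int

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValueError("image and labels must share height/width")


def _boundaries(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Sub-pixel boundary curves, shape (n_layers+1, width), ordered top-down.

    Each boundary is the cumulative layer thickness plus up to three
    random-phase low-frequency sinusoids whose total amplitude is bounded by
    ``boundary_smoothness``; the foveal pit is a Gaussian bump that compresses
    the inner layers near mid-width.
    """
    h, w, n = spec.height, spec.width, spec.n_layers
    x = np.arange(w)
    total = float(np.sum(spec.layer_mean_thickness))
    top_margin = (h - total) / 2.0

    # shared undulation of the whole retina
    def sinusoids(amplitude: float) -> np.ndarray:
        out = np.zeros(w)
        n_terms = 3
        amps = rng.uniform(0.3, 1.0, n_terms)
        amps *= amplitude / amps.sum()
        for a in amps:
            cycles = rng.uniform(0.5, 1.5)
            phase = rng.uniform(0, 2 * np.pi)
            out += a * np.sin(2 * np.pi * cycles * x / w + phase)
        return out

    base = top_margin + sinusoids(spec.boundary_smoothness)
    cum = np.concatenate([[0.0], np.cumsum(spec.layer_mean_thickness)])
    bounds = np.empty((n + 1, w))
    for l in range(n + 1):
        wobble = sinusoids(0.2 * spec.boundary_smoothness) if 0 < l < n + 1 else 0.0
        bounds[l] = base + cum[l] + wobble

    if spec.foveal_dip_depth > 0:
        cx = w / 2.0 + rng.uniform(-w / 16, w / 16)
        bump = spec.foveal_dip_depth * np.exp(-0.5 * ((x - cx) / spec.foveal_dip_width) ** 2)
        # inner boundaries sink toward the outer ones: the pit thins layers 1..n/2
        n_inner = max(2, n // 2)
        for l in range(n_inner + 1):
            bounds[l] += bump * (1.0 - l / (n_inner + 1))
    # enforce anatomical ordering after the dip
    bounds = np.maximum.accumulate(bounds, axis=0)
    return np.clip(bounds, 0, h)


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Generate one synthetic B-scan/label pair, deterministic in ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    bounds = _boundaries(spec, rng)

    rows = np.arange(h)[:, None]
    labels = np.zeros((h, w), dtype=np.uint8)
    for l in range(1, spec.n_layers + 1):
        inside = (rows >= np.round(bounds[l - 1])) & (rows < np.round(bounds[l]))
        labels[inside] = l

    image = np.full((h, w), spec.background_intensity, dtype=np.float64)
    for l in range(1, spec.n_layers + 1):
        image[labels == l] = spec.layer_intensities[l - 1]

    if spec.fluid_enabled:
        _add_fluid(spec, rng, labels, image, bounds)

    if spec.vessel_count > 0:
        _add_vessel_shadows(spec, rng, image, bounds)

    if spec.speckle_level > 0:
        shape = 1.0 / spec.speckle_level ** 2
        noise = rng.gamma(shape, scale=1.0 / shape, size=(h, w))
        image = image * noise
    image = np.clip(image, 0.0, 1.0)
    return PhantomPair(image=image, labels=labels, seed=spec.seed)


def _add_fluid(spec: PhantomSpec, rng: np.random.Generator,
               labels: np.ndarray, image: np.ndarray,
               bounds: np.ndarray) -> None:
    """Dark elliptical fluid pockets inside the outer-nuclear band."""
    h, w = labels.shape
    n = spec.n_layers
    # the band analogous to the outer nuclear layer: middle-outer layers
    lo_b, hi_b = max(1, n // 2), min(n - 1, n // 2 + 2)
    ar, ac = spec.fluid_axes
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    fluid_class = spec.fluid_class
    for _ in range(spec.fluid_count):
        col = int(rng.uniform(ac + 2, w - ac - 2))
        top = bounds[lo_b, col]
        bot = bounds[hi_b, col]
        if bot - top < 3:
            continue
        row = float(rng.uniform(top, bot))
        mask = ((rr - row) / ar) ** 2 + ((cc - col) / ac) ** 2 <= 1.0
        mask &= labels >= 1  # never outside the retina
        mask &= (rr >= bounds[0][None, :]) & (rr < bounds[n][None, :])
        labels[mask] = fluid_class
        image[mask] = spec.background_intensity * 1.5


def _add_vessel_shadows(spec: PhantomSpec, rng: np.random.Generator,
                        image: np.ndarray, bounds: np.ndarray) -> None:
    """Cosine-tapered vertical attenuation bands below the inner retina."""
    h, w = image.shape
    vw = spec.vessel_width
    rows = np.arange(h)[:, None]
    for _ in range(spec.vessel_count):
        center = rng.uniform(vw, w - vw)
        cols = np.arange(w)
        dist = np.abs(cols - center)
        taper = np.where(dist <= vw / 2,
                         0.5 * (1 + np.cos(np.pi * dist / (vw / 2))) / 1.0, 0.0)
        # attenuation factor per column, 1 outside the band
        factor = 1.0 - (1.0 - spec.vessel_attenuation) * taper
        # shadow starts just below the top of the inner retina (vessels sit
        # in the inner layers and shade everything deeper)
        start = bounds[1][None, :]
        shadow = np.where(rows >= start, factor[None, :], 1.0)
        image *= shadow


def generate_dataset(spec: PhantomSpec, n_images: int,
                     seed: int | None = None) -> tuple[list[PhantomPair], list[dict]]:
    """Generate ``n_images`` phantom pairs with per-image derived seeds.

    The i-th image uses seed ``base + i`` (base = ``seed`` if given, else
    ``spec.seed``); the manifest records each derived seed so any single image
    can be regenerated in isolation.
    """
    if n_images < 1:
        raise PhantomConfigError(f"n_images must be >= 1, got {n_images}")
    base = spec.seed if seed is None else seed
    pairs: list[PhantomPair] = []
    manifest: list[dict] = []
    for i in range(n_images):
        s = int(base) + i
        pair = generate_phantom(replace(spec, seed=s))
        pairs.append(pair)
        manifest.append({
            "index": i,
            "filename": f"phantom_{i:04d}",
            "seed": s,
            "n_classes": spec.n_classes,
        })
    return pairs, manifest
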