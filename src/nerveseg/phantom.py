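"""Synthetic ultrasound phantoms with known nerve geometry.

Real transverse ultrasound of the median nerve shows a hypoechoic (dark)
fascicular cross-section with a bright epineurial rim, embedded in layered
speckle-textured soft tissue. No clinical images ship with this package, so
this module synthesizes image–mask–tracing triplets that reproduce the
*statistical structure* the pipeline exercises — not the acoustics:

* a single elliptical nerve per frame, area drawn from a site-specific
  normal distribution (wrist: shallow, 9.8 ± 2.4 mm²; forearm: deeper,
  5.9 ± 1.5 mm²), boundary perturbed by a low-order Fourier series;
* horizontal tissue bands modulated by multiplicative correlated speckle
  (a smoothed Gaussian field);
* a simulated human rater that re-traces the true boundary with radial
  Gaussian jitter and an optional systematic inward/outward bias.

Everything is deterministic given a seed, pixel spacing is explicit
(default 0.1 mm/px), and the true polygon area in mm² is carried alongside
every sample so downstream CSA estimates can be checked against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .preprocess import Tracing, rasterize_polygon, write_tracing_csv

__all__ = [
    "PhantomSpec",
    "NerveGeometry",
    "RaterModel",
    "PhantomSample",
    "sample_nerve_geometry",
    "render_phantom",
    "rasterize_mask",
    "simulate_tracing",
    "generate_sample",
    "generate_dataset",
    "save_sample",
]

_N_VERTICES = 64
_MAX_RETRIES = 100
_MIN_CSA_MM2 = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance parameters of one phantom family."""

    site: str  # "wrist" | "forearm"
    image_height: int = 128
    image_width: int = 128
    pixel_spacing: float = 0.1  # mm / pixel, isotropic
    nerve_csa_mean: float = 9.8  # mm²
    nerve_csa_sd: float = 2.4  # mm²
    nerve_depth_range: tuple[float, float] = (0.22, 0.42)  # fraction of height
    nerve_aspect_range: tuple[float, float] = (1.2, 2.0)  # ellipse a/b
    boundary_irregularity: float = 0.06
    nerve_echo_level: float = 0.18
    rim_echo_level: float = 0.75
    background_bands: int = 3
    speckle_grain: float = 1.5  # px correlation length
    speckle_contrast: float = 0.35

    def __post_init__(self):
        if self.site not in ("wrist", "forearm"):
            raise ValueError("site must be 'wrist' or 'forearm'")
        if self.nerve_csa_mean <= 0 or self.nerve_csa_sd < 0 or self.pixel_spacing <= 0:
            raise ValueError("CSA mean must be > 0, SD >= 0, spacing > 0")
        lo, hi = self.nerve_depth_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("nerve_depth_range must be ordered within [0, 1]")

    @classmethod
    def default(cls, site: str, **overrides) -> "PhantomSpec":
        """Site presets: wrist = shallow/large CSA, forearm = deep/smaller."""
        if site == "wrist":
            base = cls(site="wrist")
        elif site == "forearm":
            base = cls(
                site="forearm",
                nerve_csa_mean=5.9,
                nerve_csa_sd=1.5,
                nerve_depth_range=(0.52, 0.75),
                background_bands=5,
            )
        else:
            raise ValueError("site must be 'wrist' or 'forearm'")
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class NerveGeometry:
    """Ground-truth nerve cross-section: boundary polygon and true area."""

    center: tuple[float, float]  # (x, y) pixels
    polygon: np.ndarray  # (M, 2) pixel coordinates, implicitly closed
    true_area: float  # mm², shoelace area x spacing²

    def __post_init__(self):
        p = np.asarray(self.polygon, dtype=float)
        if len(p) < 12:
            raise ValueError("nerve polygon needs >= 12 vertices")
        object.__setattr__(self, "polygon", p)


@dataclass(frozen=True)
class RaterModel:
    """Imperfect human tracer: radial jitter and systematic boundary offset."""

    vertex_jitter_sd: float = 0.05  # mm
    boundary_bias: float = 0.0  # mm; negative = under-tracing

    def __post_init__(self):
        if self.vertex_jitter_sd < 0:
            raise ValueError("vertex_jitter_sd must be >= 0")


@dataclass(frozen=True)
class PhantomSample:
    """One image–mask–tracing triplet with its provenance."""

    image: np.ndarray  # (H, W) float32 in [0, 1]
    mask: np.ndarray  # (H, W) bool, ground truth
    tracing: Tracing  # simulated manual tracing
    geometry: NerveGeometry
    spec: PhantomSpec
    seed: int
    sample_id: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def pixel_spacing(self) -> float:
        return self.spec.pixel_spacing


def _shoelace(p: np.ndarray) -> float:
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def sample_nerve_geometry(spec: PhantomSpec, rng: np.random.Generator) -> NerveGeometry:
    """Draw one nerve cross-section that fits inside the image.

    The area comes from Normal(csa_mean, csa_sd) truncated at 0.5 mm²; the
    ellipse aspect (a/b) is uniform over ``nerve_aspect_range``; the radius
    is perturbed by a low-order (2–4 cycles) Fourier series with relative
    amplitude ``boundary_irregularity``. Geometries that would leave the
    canvas are rejected and resampled up to a bounded retry count.
    """
    h, w, sp = spec.image_height, spec.image_width, spec.pixel_spacing
    margin = 2.0
    for _ in range(_MAX_RETRIES):
        area = rng.normal(spec.nerve_csa_mean, spec.nerve_csa_sd)
        if area < _MIN_CSA_MM2:
            continue
        area_px = area / sp**2
        aspect = rng.uniform(*spec.nerve_aspect_range)
        b = np.sqrt(area_px / (np.pi * aspect))
        a = aspect * b
        theta = np.linspace(0.0, 2 * np.pi, _N_VERTICES, endpoint=False)
        # low-order radial perturbation; zero-mean so the area is ~preserved
        pert = np.zeros_like(theta)
        if spec.boundary_irregularity > 0:
            for k in (2, 3, 4):
                amp = spec.boundary_irregularity * rng.uniform(0.0, 1.0) / np.sqrt(3)
                pert += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        rot = rng.uniform(-0.35, 0.35)
        ex = a * np.cos(theta) * (1.0 + pert)
        ey = b * np.sin(theta) * (1.0 + pert)
        dx = ex * np.cos(rot) - ey * np.sin(rot)
        dy = ex * np.sin(rot) + ey * np.cos(rot)
        depth = rng.uniform(*spec.nerve_depth_range)
        cy = depth * h
        cx = rng.uniform(0.3, 0.7) * w
        poly = np.column_stack([cx + dx, cy + dy])
        if (
            poly[:, 0].min() >= margin
            and poly[:, 0].max() <= w - 1 - margin
            and poly[:, 1].min() >= margin
            and poly[:, 1].max() <= h - 1 - margin
        ):
            return NerveGeometry(
                center=(float(cx), float(cy)),
                polygon=poly,
                true_area=_shoelace(poly) * sp**2,
            )
    raise ValueError(
        f"could not fit nerve (CSA ~ {spec.nerve_csa_mean} mm²) in "
        f"{h}x{w} canvas at {sp} mm/px after {_MAX_RETRIES} attempts"
    )


def _band_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Horizontal tissue layers with alternating base echogenicity."""
    h, w, nb = spec.image_height, spec.image_width, spec.background_bands
    if nb <= 1:
        return np.full((h, w), 0.45, dtype=np.float32)
    edges = np.linspace(0, h, nb + 1)
    edges[1:-1] += rng.uniform(-0.03 * h, 0.03 * h, size=nb - 1)
    rows = np.arange(h)
    base = np.full(h, 0.45, dtype=np.float32)
    for i in range(nb):
        level = 0.45 + (0.12 if i % 2 else -0.08) + rng.uniform(-0.04, 0.04)
        base[(rows >= edges[i]) & (rows < edges[i + 1])] = level
    return np.repeat(base[:, None], w, axis=1)


def render_phantom(geom: NerveGeometry, spec: PhantomSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Render the grayscale frame: bands + speckle + hypoechoic nerve + rim.

    Returns (H, W) float32 intensities in [0, 1]; quantization to 8 bits
    happens only at I/O.
    """
    h, w = spec.image_height, spec.image_width
    base = _band_field(spec, rng)
    mask = rasterize_mask(geom, h, w)
    rim = binary_dilation(mask, iterations=2) & ~mask
    base = base.copy()
    base[mask] = spec.nerve_echo_level
    base[rim] = spec.rim_echo_level
    if spec.speckle_contrast > 0:
        g = gaussian_filter(rng.standard_normal((h, w)), sigma=spec.speckle_grain)
        sd = g.std()
        if sd > 0:
            g /= sd
        img = base * (1.0 + spec.speckle_contrast * g)
    else:
        img = base
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def rasterize_mask(geom: NerveGeometry, height: int, width: int) -> np.ndarray:
    """Ground-truth binary mask: pixel centers inside the nerve polygon."""
    p = geom.polygon
    if (p[:, 0].min() < 0 or p[:, 0].max() > width - 1
            or p[:, 1].min() < 0 or p[:, 1].max() > height - 1):
        raise ValueError("nerve polygon outside canvas")
    return rasterize_polygon(p, height, width)


def simulate_tracing(geom: NerveGeometry, rater: RaterModel,
                     rng: np.random.Generator, pixel_spacing: float) -> Tracing:
    """Simulate a manual tracing of the nerve boundary.

    Each vertex moves radially (away from the centroid) by
    Normal(boundary_bias, vertex_jitter_sd) millimetres. If the jittered
    polygon self-intersects it is repaired by re-ordering vertices by angle
    around the centroid (convex-ordering fallback).
    """
    p = geom.polygon
    c = p.mean(axis=0)
    d = p - c
    r = np.hypot(d[:, 0], d[:, 1])
    shift_px = rng.normal(rater.boundary_bias, rater.vertex_jitter_sd, size=len(p)) / pixel_spacing
    scale = np.maximum((r + shift_px) / np.maximum(r, 1e-9), 0.05)
    traced = c + d * scale[:, None]
    if not _is_simple(traced):
        ang = np.arctan2(traced[:, 1] - c[1], traced[:, 0] - c[0])
        traced = traced[np.argsort(ang)]
    return Tracing(vertices=traced)


def _is_simple(poly: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return Polygon(poly).is_valid


def generate_sample(spec: PhantomSpec, seed: int, rater: RaterModel | None = None,
                    sample_id: str = "") -> PhantomSample:
    """One fully deterministic image–mask–tracing triplet from a seed."""
    rater = rater or RaterModel()
    rng = np.random.default_rng(seed)
    geom = sample_nerve_geometry(spec, rng)
    image = render_phantom(geom, spec, rng)
    mask = rasterize_mask(geom, spec.image_height, spec.image_width)
    tracing = simulate_tracing(geom, rater, rng, spec.pixel_spacing)
    return PhantomSample(
        image=image, mask=mask, tracing=tracing, geometry=geom, spec=spec,
        seed=seed, sample_id=sample_id or f"{spec.site}-{seed:06d}",
        provenance={"kind": "original", "params": {}},
    )


def generate_dataset(spec: PhantomSpec, n: int, seed: int,
                     rater: RaterModel | None = None) -> list[PhantomSample]:
    """n independent triplets; sample i uses child seed derived from (seed, i)."""
    seeds = np.random.SeedSequence(seed).generate_state(n) >> 1  # keep < 2**31
    return [
        generate_sample(spec, int(s), rater, sample_id=f"{spec.site}-{seed}-{i:04d}")
        for i, s in enumerate(seeds)
    ]


def save_sample(sample: PhantomSample, out_dir: str | Path, stem: str | None = None) -> None:
    """Write PNG image (8-bit), PNG mask {0,255}, tracing CSV, JSON sidecar."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or sample.sample_id
    iio.imwrite(out / f"{stem}.png",
                np.round(sample.image * 255).astype(np.uint8))
    iio.imwrite(out / f"{stem}_mask.png",
                np.where(sample.mask, 255, 0).astype(np.uint8))
    write_tracing_csv(sample.tracing, out / f"{stem}_trace.csv")
    sidecar = {
        "pixel_spacing": sample.spec.pixel_spacing,
        "site": sample.spec.site,
        "true_area": sample.geometry.true_area,
        "seed": sample.seed,
    }
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
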