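"""Synthetic abdominal phantom slices with paired organ/tumor masks.

The generator emulates the statistical structure of contrast CT slices of
the pancreas that the segmentation pipeline is sensitive to, without any
claim of anatomical realism:

* a small elongated organ (randomly placed/oriented ellipse with a smooth
  boundary perturbation) occupying a few percent of the slice — severe
  foreground/background class imbalance;
* a smaller tumor disc strictly inside the organ (some slices have none);
* three-level intensity contrast (background < organ < tumor, mimicking a
  portal-venous enhancement ordering on the normalized [0,1] scale) plus
  additive Gaussian noise, clipped to [0,1].

Everything is driven by a numpy Generator, so a case is bit-reproducible
from its seed on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 64
    organ_area_fraction: tuple[float, float] = (0.02, 0.06)
    aspect_ratio: tuple[float, float] = (2.0, 3.5)  # organ elongation
    boundary_wobble: float = 0.08  # relative radius perturbation amplitude
    tumor_radius_fraction: tuple[float, float] = (0.15, 0.5)  # of organ minor axis
    background_mean: float = 0.2
    organ_mean: float = 0.6
    tumor_mean: float = 0.8
    noise_sd: float = 0.05
    allow_no_tumor: float = 0.1  # probability of a tumor-free slice
    max_retries: int = 50

    def __post_init__(self) -> None:
        lo, hi = self.organ_area_fraction
        if not 0 < lo < hi < 0.5:
            raise ValueError("organ_area_fraction must be a small (lo, hi) range")
        if not 0.0 <= self.allow_no_tumor <= 1.0:
            raise ValueError("allow_no_tumor is a probability")


@dataclass
class PhantomCase:
    image: np.ndarray
    pancreas_mask: np.ndarray
    tumor_mask: np.ndarray
    case_id: str = "case"
    seed: int | None = None

    @property
    def has_tumor(self) -> bool:
        return bool(self.tumor_mask.any())


def _organ_mask(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample an elongated perturbed ellipse whose pixelated area
    fraction lands inside the configured range."""
    s = config.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    lo, hi = config.organ_area_fraction
    for _ in range(config.max_retries):
        frac = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
        ratio = rng.uniform(*config.aspect_ratio)
        area = frac * s * s
        b = np.sqrt(area / (np.pi * ratio))  # semi-minor axis, pixels
        a = ratio * b
        theta = rng.uniform(0, np.pi)
        margin = a * (1 + 2 * config.boundary_wobble) + 1
        if 2 * margin >= s:
            continue
        cy = rng.uniform(margin, s - margin)
        cx = rng.uniform(margin, s - margin)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        phi = np.arctan2(v / b, u / a)
        wobble = np.zeros_like(phi)
        for k in (2, 3, 4):
            amp = config.boundary_wobble * rng.uniform(0, 1) / k
            wobble += amp * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
        mask = (rho <= 1.0 + wobble).astype(np.uint8)
        got = mask.sum() / (s * s)
        if lo <= got <= hi and mask.any():
            return mask
    raise RuntimeError(
        f"could not realize an organ with area fraction in [{lo}, {hi}] on a "
        f"{s}×{s} grid within {config.max_retries} attempts; config infeasible")


def _tumor_mask(organ: np.ndarray, config: PhantomConfig,
                rng: np.random.Generator) -> np.ndarray:
    """A disc strictly inside the organ, sited via the distance transform."""
    s = config.image_size
    dist = distance_transform_edt(organ)
    minor_axis = 2.0 * np.sqrt(organ.sum() / (np.pi * np.mean(config.aspect_ratio)))
    radius = max(1.0, rng.uniform(*config.tumor_radius_fraction) * minor_axis)
    for _ in range(config.max_retries):
        eligible = np.argwhere(dist > radius)
        if eligible.size:
            cy, cx = eligible[rng.integers(len(eligible))]
            yy, xx = np.mgrid[0:s, 0:s]
            disc = ((yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2).astype(np.uint8)
            return disc
        radius *= 0.8
        if radius < 1.0:
            radius = 1.0
    raise RuntimeError("organ too thin to contain a tumor disc; config infeasible")


def generate_phantom(config: PhantomConfig, rng: np.random.Generator,
                     case_id: str = "case", seed: int | None = None) -> PhantomCase:
    """One slice: organ + (usually) tumor masks and the noisy image."""
    organ = _organ_mask(config, rng)
    if rng.uniform() < config.allow_no_tumor:
        tumor = np.zeros_like(organ)
    else:
        tumor = _tumor_mask(organ, config, rng)
    image = np.full(organ.shape, config.background_mean)
    image[organ == 1] = config.organ_mean
    image[tumor == 1] = config.tumor_mean
    image = image + rng.normal(0.0, config.noise_sd, size=organ.shape)
    image = np.clip(image, 0.0, 1.0)
    return PhantomCase(image=image, pancreas_mask=organ, tumor_mask=tumor,
                       case_id=case_id, seed=seed)


def generate_dataset(n: int, config: PhantomConfig | None = None,
                     seed: int = 0) -> list[PhantomCase]:
    """n cases with per-case seeds spawned from one master seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or PhantomConfig()
    children = np.random.SeedSequence(seed).spawn(n)
    cases = []
    for i, ss in enumerate(children):
        case_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(case_seed)
        cases.append(generate_phantom(config, rng, case_id=f"case{i:04d}",
                                      seed=case_seed))
    return cases


def corrupt_mask(mask: np.ndarray, flip_rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Flip each pixel independently with probability ``flip_rate`` — a
    controlled way to manufacture imperfect predictions for metric tests."""
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must lie in [0, 1]")
    mask = np.asarray(mask).astype(np.uint8)
    flips = rng.random(mask.shape) < flip_rate
    return (mask ^ flips.astype(np.uint8)).astype(np.uint8)
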