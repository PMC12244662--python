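"""Synthetic co-registered CT-like / MR-like head phantom pairs.

The generator emulates the complementarity the fusion method relies on:
CT renders dense structures (a bright elliptical skull ring, bone inserts)
over flat soft tissue, while MR renders the same geometry with a dark skull
but richly textured soft tissue and focal lesions.  Both images share one
geometry layer, so the pair is registered by construction, and the masks
are returned for assertions (ring recall, lesion localisation).

Everything is deterministic per (spec, seed); noise, texture and lesion
placement draw from independent RNG streams so toggling one knob leaves
the others' pixels untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "generate_pair",
    "analytic_front",
    "schaffer_problem",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Generator knobs for one registered CT/MR-like pair."""

    size: tuple[int, int] = (256, 256)
    seed: int = 0
    noise_sigma: float = 0.0
    skull_thickness: float = 0.06  # fraction of the image radius
    lesion_count: int = 2
    texture_scale: float = 8.0  # smoothing length of the MR soft-tissue texture

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError("phantom must be at least 32x32")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class Phantom:
    ct: np.ndarray
    mr: np.ndarray
    ring_mask: np.ndarray
    bone_mask: np.ndarray
    lesion_mask: np.ndarray
    brain_mask: np.ndarray


def _ellipse(yy, xx, cy, cx, ry, rx):
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Build one CT/MR-like pair plus its geometry masks."""
    h, w = spec.size
    ss = np.random.SeedSequence(spec.seed)
    rng_tex, rng_lesion, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.42 * h, 0.38 * w

    outer = _ellipse(yy, xx, cy, cx, ry, rx)
    t = spec.skull_thickness / 0.42  # thickness as a fraction of the radius
    inner = _ellipse(yy, xx, cy, cx, ry * (1 - t), rx * (1 - t))
    ring = outer & ~inner
    brain = inner

    # fixed bone inserts: two small dense ellipses near the skull base
    bone = _ellipse(yy, xx, cy + 0.28 * h, cx - 0.12 * w, 0.035 * h, 0.05 * w)
    bone |= _ellipse(yy, xx, cy + 0.28 * h, cx + 0.12 * w, 0.035 * h, 0.05 * w)
    bone &= brain

    # CT: bright skull and bone, flat mid-grey soft tissue, dark background
    ct = np.full((h, w), 0.05)
    ct[brain] = 0.35
    ct[ring] = 0.97
    ct[bone] = 0.92

    # MR: dark skull, textured soft tissue
    texture = rng_tex.standard_normal((h, w))
    texture = ndimage.gaussian_filter(texture, spec.texture_scale)
    texture = (texture - texture.min()) / max(np.ptp(texture), 1e-12)
    mr = np.full((h, w), 0.05)
    mr[brain] = 0.35 + 0.45 * texture[brain]
    mr[ring] = 0.03

    # lesions: bright focal blobs only in MR, inside the brain
    lesion = np.zeros((h, w), dtype=bool)
    for _ in range(spec.lesion_count):
        ly = cy + rng_lesion.uniform(-0.5, 0.5) * ry * (1 - t) * 0.8
        lx = cx + rng_lesion.uniform(-0.5, 0.5) * rx * (1 - t) * 0.8
        lr = rng_lesion.uniform(0.02, 0.05) * min(h, w)
        lesion |= _ellipse(yy, xx, ly, lx, lr, lr)
    lesion &= brain
    mr = np.where(lesion, 0.95, mr)

    if spec.noise_sigma > 0:
        ct = ct + rng_noise.normal(0, spec.noise_sigma, (h, w))
        mr = mr + rng_noise.normal(0, spec.noise_sigma, (h, w))
    ct = np.clip(ct, 0.0, 1.0)
    mr = np.clip(mr, 0.0, 1.0)
    return Phantom(ct, mr, ring, bone, lesion, brain)


def generate_pair(spec: PhantomSpec = PhantomSpec()) -> tuple[np.ndarray, np.ndarray]:
    """(CT-like, MR-like) images in [0, 1]; deterministic per (spec, seed)."""
    ph = generate_phantom(spec)
    return ph.ct, ph.mr


def analytic_front(problem_id: str = "sch", n_points: int = 100) -> np.ndarray:
    """True Pareto front samples of the analytic bi-objective toy problem.

    ``sch``: f1 = x**2, f2 = (x - 2)**2; the front is traced by x in [0, 2],
    sampled uniformly in the parameter.
    """
    if problem_id != "sch":
        raise ValueError(f"unknown problem id {problem_id!r}")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    t = np.linspace(0.0, 2.0, n_points)
    return np.column_stack([t**2, (t - 2.0) ** 2])


def schaffer_problem(x: np.ndarray) -> np.ndarray:
    """The toy bi-objective evaluator: x is 1-D in [-2, 4]."""
    v = float(np.asarray(x).ravel()[0])
    return np.array([v**2, (v - 2.0) ** 2])
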