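"""End-to-end fusion: decision decoding, bi-objective fitness, pixel merging.

The optimizer does not search per-pixel weights (2*H*W variables would be
intractable and would discard the constructive covariance weighting);
instead it searches a 6-dimensional reshaping of the covariance weight
maps:

    x = (w_idx1, w_idx2, g1, g2, gamma1, gamma2)

where the first two round to window sizes in {3, 5, 7, 9} and each final
weight map is ``wt_i = g_i * base_map(DI_i, W_i) ** gamma_i``.  The two
objectives, both minimised, are

* Fitness1 = 1 - (ENT/8 + FMI + Qabf)  (image quality; ENT is normalised
  by the 8-bit cap so the three terms share one scale), and
* a cost: a deterministic operation-count proxy (W1^2 + W2^2) * H * W by
  default, or measured wall-clock seconds.

Fused pixels come from the non-adaptive convex merge
``F = (I1*wt1 + I2*wt2) / (wt1 + wt2 + eps)``.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import compass, metrics, weights
from .optimizer import OptimizerConfig, run_vf_modpso

__all__ = [
    "FusionProblem",
    "FusionResult",
    "WINDOW_CHOICES",
    "decode_decision",
    "fuse_pixels",
    "fitness1",
    "fitness2",
    "fuse",
    "DECISION_BOUNDS",
    "DEFAULT_DECISION",
]

WINDOW_CHOICES = (3, 5, 7, 9)

#: (lo, hi) per decision component: two window indices, two gains, two exponents.
DECISION_BOUNDS = (
    (0.0, 3.0),
    (0.0, 3.0),
    (0.1, 10.0),
    (0.1, 10.0),
    (0.25, 4.0),
    (0.25, 4.0),
)

#: Baseline configuration: W=3 for both sources, unit gains and exponents.
DEFAULT_DECISION = (0.0, 0.0, 1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class FusionProblem:
    """A co-registered source pair plus the evaluation settings."""

    i1: np.ndarray
    i2: np.ndarray
    eps: float = 1e-12
    cost_model: str = "proxy"  # "proxy" | "wallclock"

    def __post_init__(self) -> None:
        i1 = np.asarray(self.i1, float)
        i2 = np.asarray(self.i2, float)
        if i1.shape != i2.shape:
            raise ValueError("source images must share one shape")
        if self.cost_model not in ("proxy", "wallclock"):
            raise ValueError("cost_model must be 'proxy' or 'wallclock'")


@dataclass
class FusionResult:
    fused: np.ndarray
    wt1: np.ndarray
    wt2: np.ndarray
    decision: np.ndarray
    objectives: np.ndarray  # (fitness1, cost)
    report: dict
    archive_positions: list = field(default_factory=list)
    archive_objectives: list = field(default_factory=list)
    log: object = None
    wallclock_s: float = 0.0


def decode_decision(x) -> tuple[int, int, float, float, float, float]:
    """(W1, W2, g1, g2, gamma1, gamma2) from a length-6 decision vector.

    Window indices are rounded to the nearest of {0,1,2,3} and mapped to
    {3,5,7,9}; out-of-bounds components are clipped with a warning.
    """
    x = np.asarray(x, float).ravel()
    if x.shape[0] != 6:
        raise ValueError("decision vector must have length 6")
    b = np.asarray(DECISION_BOUNDS, float)
    if np.any(x < b[:, 0]) or np.any(x > b[:, 1]):
        warnings.warn("decision vector out of bounds; clipping", stacklevel=2)
        x = np.clip(x, b[:, 0], b[:, 1])
    w1 = WINDOW_CHOICES[int(np.clip(np.rint(x[0]), 0, 3))]
    w2 = WINDOW_CHOICES[int(np.clip(np.rint(x[1]), 0, 3))]
    return w1, w2, float(x[2]), float(x[3]), float(x[4]), float(x[5])


def fuse_pixels(
    i1: np.ndarray,
    i2: np.ndarray,
    wt1: np.ndarray,
    wt2: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """Non-adaptive weighted pixel merge F = (I1 wt1 + I2 wt2)/(wt1 + wt2 + eps).

    Where both weights vanish the arithmetic mean is used, so every fused
    pixel is a convex combination of the two source pixels.
    """
    i1, i2 = np.asarray(i1, float), np.asarray(i2, float)
    wt1, wt2 = np.asarray(wt1, float), np.asarray(wt2, float)
    if not (i1.shape == i2.shape == wt1.shape == wt2.shape):
        raise ValueError("all four rasters must share one shape")
    if np.any(wt1 < 0) or np.any(wt2 < 0):
        raise ValueError("weights must be nonnegative")
    total = wt1 + wt2
    mean = 0.5 * (i1 + i2)
    # guard: degenerate pixels (total < eps) fall back to the mean; elsewhere
    # the plain ratio keeps the merge an exact convex combination
    safe = np.where(total < eps, 1.0, total)
    f = (i1 * wt1 + i2 * wt2) / safe
    return np.where(total < eps, mean, f)


def fitness1(fused: np.ndarray, i1: np.ndarray, i2: np.ndarray) -> float:
    """Quality objective 1 - (ENT/8 + FMI + Qabf); lower is better."""
    ent = metrics.entropy(fused) / 8.0
    f = metrics.fmi(fused, i1, i2)
    q = metrics.qabf(fused, i1, i2)
    return 1.0 - (ent + f + q)


def fitness2(
    w1: int, w2: int, shape: tuple[int, int], cost_model: str = "proxy",
    elapsed_s: float | None = None,
) -> float:
    """Cost objective: operation-count proxy (W1^2 + W2^2)*H*W, or seconds."""
    if cost_model == "wallclock":
        if elapsed_s is None:
            raise ValueError("wallclock cost model needs a measured time")
        return float(elapsed_s)
    return float((w1**2 + w2**2) * shape[0] * shape[1])


def _evaluator(problem: FusionProblem):
    """Decision-vector -> (fitness1, cost) closure with cached base maps."""
    i1 = np.asarray(problem.i1, float)
    i2 = np.asarray(problem.i2, float)
    e1 = compass.edge_strength_map(i1)
    e2 = compass.edge_strength_map(i2)
    d1, d2 = compass.detail_images(i1, i2, e1, e2)
    base = {
        w: (
            weights.pixel_weight_map(d1, weights.WindowSpec(w)),
            weights.pixel_weight_map(d2, weights.WindowSpec(w)),
        )
        for w in WINDOW_CHOICES
    }

    def weight_maps(x):
        w1, w2, g1, g2, gam1, gam2 = decode_decision(x)
        wt1 = g1 * base[w1][0] ** gam1
        wt2 = g2 * base[w2][1] ** gam2
        return w1, w2, wt1, wt2

    def evaluate(x):
        t0 = time.perf_counter()
        w1, w2, wt1, wt2 = weight_maps(x)
        fused = fuse_pixels(i1, i2, wt1, wt2, problem.eps)
        f1 = fitness1(fused, i1, i2)
        elapsed = time.perf_counter() - t0
        f2 = fitness2(w1, w2, i1.shape, problem.cost_model, elapsed)
        return np.array([f1, f2])

    return evaluate, weight_maps


def _knee_index(objs: np.ndarray) -> int:
    """Archive member nearest the ideal point in [0,1]-normalised objective space."""
    lo = objs.min(axis=0)
    span = objs.max(axis=0) - lo
    span[span <= 0] = 1.0
    z = (objs - lo) / span
    return int(np.argmin(np.sqrt((z**2).sum(axis=1))))


def fuse(problem: FusionProblem, cfg: OptimizerConfig | None = None) -> FusionResult:
    """Run the full pipeline and return the knee-point fusion.

    Compass edges -> detail images -> covariance weight maps are computed
    once per window size; the optimizer then searches the 6-parameter
    reshaping with the baseline decision (W=3, unit gains/exponents) warm-
    starting the swarm, and the archive member closest to the ideal point
    is fused and scored.
    """
    t0 = time.perf_counter()
    i1 = np.asarray(problem.i1, float)
    i2 = np.asarray(problem.i2, float)
    evaluate, weight_maps = _evaluator(problem)
    if cfg is None:
        cfg = OptimizerConfig(pop_size=16, max_iter=25, archive_capacity=16)
    cfg = replace(
        cfg,
        bounds=DECISION_BOUNDS,
        initial_positions=(np.array(DEFAULT_DECISION),),
    )
    archive, log = run_vf_modpso(evaluate, cfg)

    objs = archive.objs_array()
    k = _knee_index(objs)
    x_best = archive.positions[k]
    _, _, wt1, wt2 = weight_maps(x_best)
    fused = fuse_pixels(i1, i2, wt1, wt2, problem.eps)
    report = metrics.metric_report(fused, i1, i2)
    return FusionResult(
        fused=fused,
        wt1=wt1,
        wt2=wt2,
        decision=np.asarray(x_best, float),
        objectives=np.asarray(objs[k], float),
        report=report,
        archive_positions=[np.asarray(p) for p in archive.positions],
        archive_objectives=[np.asarray(o) for o in archive.objectives],
        log=log,
        wallclock_s=time.perf_counter() - t0,
    )
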