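"""Fusion-quality metrics and multi-objective performance indicators.

Image metrics (inputs are grayscale rasters in [0, 1], quantised to 256
levels for the histogram-based quantities):

* ``entropy`` — Shannon entropy in bits, in [0, 8].
* ``mutual_information`` — H(a) + H(b) - H(a, b) on the 256x256 joint
  histogram.
* ``fmi`` — feature mutual information: normalised MI between Sobel
  gradient-magnitude images of the fused result and each source.
* ``qabf`` — Xydeas–Petrović edge-information preservation, sigmoid model
  on gradient strength and orientation differences.
* ``ssim`` — mean structural similarity (11x11 Gaussian window, sigma 1.5).

Set indicators for the optimizer (objective vectors, all-minimised):

* ``igd`` — inverted generational distance to a reference front.
* ``hypervolume`` — measure dominated by a set and bounded by a reference
  point; exact sweep in 2-D, inclusion–exclusion for up to 4 objectives.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = [
    "entropy",
    "mutual_information",
    "fmi",
    "qabf",
    "ssim",
    "metric_report",
    "igd",
    "hypervolume",
]

_LEVELS = 256
_FMI_LEVELS = 64  # coarser feature histogram keeps the MI estimator bias low


def _quantize(img: np.ndarray, levels: int = _LEVELS) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    return np.clip(np.rint(img * (levels - 1)), 0, levels - 1).astype(np.int32)


def _hist_entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropy(img: np.ndarray, _levels: int = _LEVELS) -> float:
    """Shannon entropy of the 256-level intensity histogram, in bits [0, 8]."""
    q = _quantize(img, _levels)
    counts = np.bincount(q.ravel(), minlength=_levels).astype(float)
    return _hist_entropy(counts)


def mutual_information(a: np.ndarray, b: np.ndarray, _levels: int = _LEVELS) -> float:
    """MI in bits between two equally shaped rasters: H(a) + H(b) - H(a,b)."""
    qa, qb = _quantize(a, _levels), _quantize(b, _levels)
    if qa.shape != qb.shape:
        raise ValueError("images must share one shape")
    joint = np.bincount(
        (qa.ravel() * _levels + qb.ravel()), minlength=_levels * _levels
    ).astype(float)
    h_ab = _hist_entropy(joint)
    h_a = _hist_entropy(joint.reshape(_levels, _levels).sum(axis=1))
    h_b = _hist_entropy(joint.reshape(_levels, _levels).sum(axis=0))
    return max(0.0, h_a + h_b - h_ab)


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = ndimage.sobel(np.asarray(img, float), axis=1, mode="nearest")
    gy = ndimage.sobel(np.asarray(img, float), axis=0, mode="nearest")
    return np.hypot(gx, gy)


def _normalized(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def fmi(fused: np.ndarray, src1: np.ndarray, src2: np.ndarray) -> float:
    """Feature mutual information between fused and source gradient images.

    Gradient magnitudes are range-normalised and histogrammed at 64 levels
    (a coarser grid than the intensity metrics, keeping the estimator's
    finite-sample bias small on typical image sizes);
    per source the MI with the fused gradients is normalised by the mean of
    the two marginal entropies, then averaged over the sources.  Identical
    images give 1; images with no features (constant gradients) give 0.
    """
    gf = _normalized(_gradient_magnitude(fused))
    vals = []
    for src in (src1, src2):
        gs = _normalized(_gradient_magnitude(src))
        hf = entropy(gf, _FMI_LEVELS)
        hs = entropy(gs, _FMI_LEVELS)
        if hf + hs < 1e-12:
            vals.append(0.0)
        else:
            vals.append(2.0 * mutual_information(gf, gs, _FMI_LEVELS) / (hf + hs))
    return float(np.clip(np.mean(vals), 0.0, 1.0))


# Xydeas–Petrović sigmoid constants (strength, orientation)
_GAMMA_G, _KAPPA_G, _SIGMA_G = 0.9994, -15.0, 0.5
_GAMMA_A, _KAPPA_A, _SIGMA_A = 0.9879, -22.0, 0.8


def _edge_preservation(g_src, a_src, g_f, a_f):
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(g_src > g_f, g_f / g_src, g_src / g_f)
    ratio = np.nan_to_num(ratio, nan=0.0)
    ratio = np.where((g_src == 0) & (g_f == 0), 0.0, ratio)
    a_sim = 1.0 - np.abs(a_src - a_f) / (np.pi / 2)
    qg = _GAMMA_G / (1.0 + np.exp(_KAPPA_G * (ratio - _SIGMA_G)))
    qa = _GAMMA_A / (1.0 + np.exp(_KAPPA_A * (a_sim - _SIGMA_A)))
    return qg * qa


# normalisation so that perfect preservation (ratio=1, identical angles)
# scores exactly 1; the raw sigmoid product tops out below 1 otherwise
_Q_PERFECT = float(
    (_GAMMA_G / (1.0 + np.exp(_KAPPA_G * (1.0 - _SIGMA_G))))
    * (_GAMMA_A / (1.0 + np.exp(_KAPPA_A * (1.0 - _SIGMA_A))))
)


def qabf(fused: np.ndarray, src1: np.ndarray, src2: np.ndarray) -> float:
    """Edge-information preservation of the fused image, in [0, 1].

    Sobel gradient strength and orientation are compared per pixel between
    each source and the fused image through sigmoid preservation curves,
    weighted by the source gradient strengths, and normalised to score 1
    for perfect preservation.
    """
    f = np.asarray(fused, float)
    imgs = [np.asarray(src1, float), np.asarray(src2, float), f]
    if not (imgs[0].shape == imgs[1].shape == f.shape):
        raise ValueError("images must share one shape")
    grads, angles = [], []
    for im in imgs:
        gx = ndimage.sobel(im, axis=1, mode="nearest")
        gy = ndimage.sobel(im, axis=0, mode="nearest")
        grads.append(np.hypot(gx, gy))
        # orientation folded to (-pi/2, pi/2] as in the canonical formulation
        angles.append(np.arctan(gy / np.where(gx == 0, 1e-30, gx)))
    g1, g2, gf = grads
    a1, a2, af = angles
    q1 = _edge_preservation(g1, a1, gf, af) / _Q_PERFECT
    q2 = _edge_preservation(g2, a2, gf, af) / _Q_PERFECT
    denom = (g1 + g2).sum()
    if denom < 1e-12:
        return 0.0
    val = float((q1 * g1 + q2 * g2).sum() / denom)
    return float(np.clip(val, 0.0, 1.0))


def ssim(f: np.ndarray, i: np.ndarray) -> float:
    """Mean local structural similarity; Gaussian 11x11 window, sigma 1.5."""
    f, i = np.asarray(f, float), np.asarray(i, float)
    if f.shape != i.shape:
        raise ValueError("images must share one shape")
    return float(
        structural_similarity(
            f,
            i,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
        )
    )


def metric_report(fused: np.ndarray, src1: np.ndarray, src2: np.ndarray) -> dict:
    """All image-quality metrics for one fusion as a flat dict."""
    return {
        "ENT": entropy(fused),
        "MI": 0.5
        * (mutual_information(fused, src1) + mutual_information(fused, src2)),
        "FMI": fmi(fused, src1, src2),
        "Qabf": qabf(fused, src1, src2),
        "SSIM1": ssim(fused, src1),
        "SSIM2": ssim(fused, src2),
    }


def igd(approx: np.ndarray, reference: np.ndarray) -> float:
    """Inverted generational distance: mean over reference points of the
    Euclidean distance to the nearest approximation point."""
    A = np.atleast_2d(np.asarray(approx, float))
    P = np.atleast_2d(np.asarray(reference, float))
    if A.size == 0 or P.size == 0:
        raise ValueError("both sets must be nonempty")
    if A.shape[1] != P.shape[1]:
        raise ValueError("objective dimensions differ")
    d = np.sqrt(((P[:, None, :] - A[None, :, :]) ** 2).sum(axis=2))
    return float(d.min(axis=1).mean())


def hypervolume(points: np.ndarray, ref: np.ndarray) -> float:
    """Lebesgue measure of the region dominated by ``points``, bounded by ``ref``.

    Minimisation convention: only points strictly below the reference point
    in every objective contribute.  2-D uses an exact sweep; 3- and 4-D use
    inclusion–exclusion over the box corners.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    r = np.asarray(ref, float)
    m = r.shape[0]
    if pts.shape[1] != m:
        raise ValueError("dimension mismatch between points and reference")
    pts = pts[np.all(pts < r, axis=1)]
    if pts.shape[0] == 0:
        return 0.0
    if m == 2:
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        pts = pts[order]
        hv = 0.0
        best_y = r[1]
        for x, y in pts:
            if y < best_y:
                hv += (r[0] - x) * (best_y - y)
                best_y = y
        return float(hv)
    if m <= 4:
        # inclusion-exclusion over nondominated subsets of points
        keep = _nondominated_rows(pts)
        n = keep.shape[0]
        if n > 20:
            raise ValueError("inclusion–exclusion fallback limited to 20 points")
        hv = 0.0
        for size in range(1, n + 1):
            sign = (-1.0) ** (size + 1)
            for combo in itertools.combinations(range(n), size):
                corner = keep[list(combo)].max(axis=0)
                hv += sign * np.prod(np.maximum(r - corner, 0.0))
        return float(hv)
    raise ValueError("hypervolume supports at most 4 objectives")


def _nondominated_rows(pts: np.ndarray) -> np.ndarray:
    keep = []
    for i, p in enumerate(pts):
        dominated = False
        for j, q in enumerate(pts):
            if i != j and np.all(q <= p) and np.any(q < p):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return np.unique(pts[keep], axis=0)
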