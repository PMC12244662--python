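"""Eight-direction Sobel compass filtering and detail-image generation.

The first stage of the fusion pipeline: each co-registered source image is
filtered with the 3x3 Sobel kernel rotated in 45-degree steps, the maximum
absolute response defines a per-pixel edge-strength map, and each source's
edge map is subtracted from the *other* source to isolate the content that
is exclusive to one modality (the "detail image").
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "COMPASS_ANGLES",
    "build_compass_kernels",
    "compass_responses",
    "edge_strength_map",
    "detail_images",
]

#: Compass directions, degrees, in the order the kernels are returned.
COMPASS_ANGLES = (0, 45, 90, 135, 180, 225, 270, 315)

# Ring of the 8 off-center entries of the 0-degree Sobel kernel, walked
# clockwise from the top-left corner.  Rotating the kernel by 45 degrees
# is a one-step rotation of this ring.
_RING_INDEX = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
_RING_E0 = [-1, 0, 1, 2, 1, 0, -1, -2]


def build_compass_kernels() -> np.ndarray:
    """Return the eight 3x3 Sobel compass kernels as an (8, 3, 3) int array.

    Kernel ``k`` detects edges at ``COMPASS_ANGLES[k]``; the 0-degree kernel
    is the classic horizontal-gradient Sobel mask (strong response on
    vertical edges).  Opposite directions are negations of each other, so
    only four of the eight carry independent information.
    """
    kernels = np.zeros((8, 3, 3), dtype=int)
    for k in range(8):
        ring = np.roll(_RING_E0, k)
        for (i, j), v in zip(_RING_INDEX, ring):
            kernels[k, i, j] = v
    return kernels


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def compass_responses(img: np.ndarray, kernels: np.ndarray | None = None) -> np.ndarray:
    """Correlate the image with every compass kernel.

    Returns an (8, H, W) array of signed responses.  Borders are handled by
    replicate (edge-value) padding so the output keeps the input shape.
    Correlation, not flipped convolution, is used; for these antisymmetric
    kernels the difference is a sign flip that the downstream absolute value
    removes.
    """
    img = _validate_image(img)
    if kernels is None:
        kernels = build_compass_kernels()
    # difference form: response = sum_i k_i * (x_i - x_center); identical to
    # plain correlation for zero-sum kernels but exactly 0 on constant images
    padded = np.pad(img, 1, mode="edge")
    h, w = img.shape
    out = np.zeros((len(kernels), h, w), dtype=float)
    for k, kern in enumerate(kernels):
        for di in range(3):
            for dj in range(3):
                weight = float(kern[di, dj])
                if weight == 0.0:
                    continue
                out[k] += weight * (padded[di : di + h, dj : dj + w] - img)
    return out


def edge_strength_map(img: np.ndarray, kernels: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel maximum absolute compass response (nonnegative raster).

    Only the 0/45/90/135-degree masks are scanned; the remaining four are
    their negations, so the max over the four absolute responses equals the
    max over all eight signed responses.
    """
    responses = compass_responses(img, kernels)
    return np.max(np.abs(responses[:4]), axis=0)


def detail_images(
    i1: np.ndarray, i2: np.ndarray, e1: np.ndarray, e2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each source's edge map from the other source.

    ``DI1 = I2 - EI1`` and ``DI2 = I1 - EI2``, element-wise, with signed
    values preserved (no clamping): the windowed covariance of the next
    stage is shift-invariant, so negative intensities are harmless.
    """
    i1, i2 = np.asarray(i1, float), np.asarray(i2, float)
    e1, e2 = np.asarray(e1, float), np.asarray(e2, float)
    if not (i1.shape == i2.shape == e1.shape == e2.shape):
        raise ValueError("all four rasters must share one shape")
    return i2 - e1, i1 - e2
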