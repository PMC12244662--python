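"""Per-pixel fusion weights from windowed covariance eigen-sums.

A WxW window is slid over a detail image.  At each pixel the window matrix
``M`` (rows = observations, columns = variables) yields a horizontal
covariance matrix ``Ch = Mc' Mc / (W-1)`` (columns mean-centred) and a
vertical one ``Cv`` built from the transposed window.  The pixel weight is
the sum of the eigenvalues of both — equal to ``trace(Ch) + trace(Cv)``,
which is what the fast vectorised path computes; the eigendecomposition
route is retained for use as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindowSpec",
    "window_covariance",
    "directional_edge_strength",
    "pixel_weight_map",
]

_ALLOWED_W = (3, 5, 7, 9)


@dataclass(frozen=True)
class WindowSpec:
    """Side length of the sliding analysis window; replicate padding."""

    W: int = 3

    def __post_init__(self) -> None:
        if self.W not in _ALLOWED_W:
            raise ValueError(f"window side must be one of {_ALLOWED_W}, got {self.W}")


def _extract_window(detail: np.ndarray, center: tuple[int, int], W: int) -> np.ndarray:
    detail = np.asarray(detail, float)
    h = W // 2
    r, c = center
    if not (0 <= r < detail.shape[0] and 0 <= c < detail.shape[1]):
        raise ValueError(f"center {center} outside raster of shape {detail.shape}")
    padded = np.pad(detail, h, mode="edge")
    return padded[r : r + W, c : c + W]


def window_covariance(
    detail: np.ndarray, center: tuple[int, int], spec: WindowSpec = WindowSpec()
) -> np.ndarray:
    """Covariance matrix of the WxW window centred at ``center``.

    Columns are variables, rows observations; normalisation is by W-1.
    Symmetric positive semidefinite by construction.
    """
    M = _extract_window(detail, center, spec.W)
    M = M - M[spec.W // 2, spec.W // 2]  # pre-shift: exact zeros on flat windows
    Mc = M - M.mean(axis=0, keepdims=True)
    return (Mc.T @ Mc) / (spec.W - 1)


def directional_edge_strength(
    detail: np.ndarray, center: tuple[int, int], spec: WindowSpec = WindowSpec()
) -> tuple[float, float]:
    """(horizontal, vertical) eigen-sum edge strengths at one pixel.

    The horizontal strength sums the eigenvalues of the covariance of the
    window as-is; the vertical strength uses the transposed window (rows as
    variables).  Eigen-sum equals trace, so both are computed as traces.
    """
    M = _extract_window(detail, center, spec.W)
    M = M - M[spec.W // 2, spec.W // 2]
    es_h = float(((M - M.mean(axis=0, keepdims=True)) ** 2).sum() / (spec.W - 1))
    es_v = float(((M - M.mean(axis=1, keepdims=True)) ** 2).sum() / (spec.W - 1))
    return es_h, es_v


def pixel_weight_map(detail: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Weight raster: per pixel, trace(Ch) + trace(Cv) of its window.

    Vectorised over the whole image with a sliding-window view on the
    replicate-padded raster; exact (same arithmetic as the per-pixel
    window extraction, up to summation order).
    """
    detail = np.asarray(detail, float)
    if detail.ndim != 2:
        raise ValueError("detail image must be 2-D")
    W = spec.W
    h = W // 2
    padded = np.pad(detail, h, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, (W, W))  # (H, W_img, W, W)
    win = win - detail[:, :, None, None]  # pre-shift by the window center
    col_dev = win - win.mean(axis=2, keepdims=True)
    es_h = (col_dev**2).sum(axis=(2, 3)) / (W - 1)
    row_dev = win - win.mean(axis=3, keepdims=True)
    es_v = (row_dev**2).sum(axis=(2, 3)) / (W - 1)
    return es_h + es_v
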