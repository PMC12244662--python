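"""Image and report I/O plus the JSON run configuration.

Images are read from PNG/TIFF/PGM (8- or 16-bit grayscale, or RGB converted
by luminance) and normalised to [0, 1]; they are quantised back to 8 bits
only at write time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("gcfuse")

__all__ = ["read_image", "write_image", "RunConfig"]

_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path) -> np.ndarray:
    """Read a grayscale raster normalised to [0, 1].

    RGB(A) input is converted by luminance; 8-bit data is scaled by 255 and
    16-bit by 65535.  Raises ``IOError`` on unreadable files and
    ``ValueError`` for rasters smaller than 3x3.
    """
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface the path in the error
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
        scale = 255.0 if arr.max() <= 255 else 65535.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif arr.dtype == np.uint8:
        scale = 255.0
    else:
        scale = max(float(np.max(arr)), 1.0) if arr.size else 1.0
    img = np.asarray(arr, float) / scale
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image {path} must be 2-D and at least 3x3")
    return np.clip(img, 0.0, 1.0)


def write_image(img: np.ndarray, path) -> None:
    """Write a [0, 1] raster as an 8-bit grayscale file chosen by extension.

    Out-of-range values are clipped (with a logged warning); ``.pgm`` files
    use the binary P5 dialect.
    """
    import imageio.v3 as iio

    img = np.asarray(img, float)
    if img.min() < 0 or img.max() > 1:
        logger.warning("clipping out-of-range intensities before writing %s", path)
        img = np.clip(img, 0.0, 1.0)
    data = np.rint(img * 255).astype(np.uint8)
    iio.imwrite(path, data)


@dataclass(frozen=True)
class RunConfig:
    """JSON-serialisable defaults for a whole run.

    The stated study configuration is the default where one exists:
    1000 iterations, hypervolume convergence threshold 0.01, population
    diversity threshold 0.2, 3600 s time limit, 31 benchmark runs,
    window sizes {3,5,7,9}, Oustaloup constants N=2 and M=20, fractional
    order range [0.6, 1.0].
    """

    max_iter: int = 1000
    pop_size: int = 50
    archive_capacity: int = 50
    hv_threshold: float = 0.01
    diversity_threshold: float = 0.2
    time_limit_s: float = 3600.0
    runs: int = 31
    alpha_lo: float = 0.6
    alpha_hi: float = 1.0
    memory_depth: int = 4
    oustaloup_N: int = 2
    oustaloup_M: int = 20
    seed: int = 0
    cost_model: str = "proxy"
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
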