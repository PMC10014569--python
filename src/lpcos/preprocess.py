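"""Local luminosity and contrast normalization.

Fundus photographs suffer from slowly varying illumination (irregular
retinal surface, non-uniform lighting).  The normalization used here
divides every pixel by the arithmetic mean of its n-by-n neighbourhood,
which cancels any multiplicative gain field that varies slowly relative
to the window:

    N(x, y) = f(x, y) / mean_{n x n}(f)(x, y)

The raw ratio is unbounded (ratio 1 on flat background, > 1 on bright
structures); for use as a network channel it is clipped at a ceiling and
rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BinaryMask, FundusImage

__all__ = ["NormalizeConfig", "local_luminosity_normalize"]


@dataclass
class NormalizeConfig:
    """Window size and border policy for local mean estimation.

    window_n
        Side of the square neighbourhood, odd, >= 3.  Default 31 px —
        several vessel widths at a 565x584 fundus resolution; scale
        proportionally at other resolutions.
    border_policy
        'reflect' pads by reflection; 'fov-aware' averages over in-FOV
        neighbours only, which avoids the dark-rim artifact at the
        field-of-view edge.
    clip_ceiling
        Raw ratios above this are clipped before rescaling to [0, 1].
    """

    window_n: int = 31
    border_policy: str = "reflect"
    clip_ceiling: float = 4.0

    def __post_init__(self) -> None:
        if self.window_n < 3 or self.window_n % 2 == 0:
            raise ValueError("window_n must be odd and >= 3")
        if self.border_policy not in ("reflect", "fov-aware"):
            raise ValueError(f"unknown border policy {self.border_policy!r}")
        if self.clip_ceiling <= 0:
            raise ValueError("clip_ceiling must be positive")


def _box_mean(arr: np.ndarray, n: int) -> np.ndarray:
    return ndimage.uniform_filter(arr, size=n, mode="reflect")


def local_luminosity_normalize(
    img: FundusImage | np.ndarray,
    cfg: NormalizeConfig | None = None,
    fov: BinaryMask | None = None,
    return_raw: bool = False,
) -> np.ndarray:
    """Divide each pixel by its local window mean.

    Returns the ratio clipped to ``cfg.clip_ceiling`` and rescaled to
    [0, 1]; with ``return_raw=True`` the unbounded ratio is returned
    instead.  Pixels whose window mean is zero map to 0.
    """
    cfg = cfg or NormalizeConfig()
    f = img.pixels if isinstance(img, FundusImage) else np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(f)):
        raise ValueError("image contains non-finite values")
    n = cfg.window_n

    if cfg.border_policy == "fov-aware" and fov is not None:
        m = fov.pixels.astype(np.float64)
        num = _box_mean(f * m, n)
        den = _box_mean(m, n)
        mean = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    else:
        mean = _box_mean(f, n)

    ratio = np.divide(f, mean, out=np.zeros_like(f), where=mean > 1e-300)
    if return_raw:
        return ratio
    return np.clip(ratio, 0.0, cfg.clip_ceiling) / cfg.clip_ceiling
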