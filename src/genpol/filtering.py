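"""Speckle suppression: sliding boxcar averaging and the Lee filter.

The boxcar realizes the ensemble average <.> used by all second-order
matrix estimators.  The Lee filter is the classic local-statistics
minimum-mean-square-error filter for multiplicative speckle: with local
mean m and variance v of the observed intensity x, and an equivalent
number of looks L (speckle variance m^2/L),

    k = max(0, v - m^2/L) / v,        y = m + k (x - m).

Homogeneous regions (v ~ m^2/L) collapse to the local mean; strong
structure (v >> m^2/L) passes through nearly unchanged, preserving edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from genpol.exceptions import DomainError


@dataclass
class FilterConfig:
    """Speckle-filter settings: odd window (default 7, the preprocessing
    scale used throughout), ENL of the input (1 for single look)."""

    window: int = 7
    enl: float = 1.0
    method: str = "lee"

    def __post_init__(self) -> None:
        if self.method not in ("lee", "boxcar"):
            raise DomainError(f"unknown filter method {self.method!r}")
        if self.enl <= 0:
            raise DomainError("enl must be positive")
        if self.window % 2 == 0 or self.window < 1:
            raise DomainError("window must be odd and >= 1")
        if self.method == "lee" and self.window < 3:
            raise DomainError("lee filter needs window >= 3")


def _check_extent(window: int, shape) -> None:
    if window > min(shape):
        raise DomainError(f"window {window} exceeds raster extent {shape}")


def boxcar(raster: np.ndarray, window: int) -> np.ndarray:
    """Sliding mean over an odd window with mirror padding.

    Accepts real or complex rasters; constant input is returned unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise DomainError(f"window must be odd and >= 1, got {window}")
    raster = np.asarray(raster)
    _check_extent(window, raster.shape)
    if window == 1:
        return raster.copy()
    if np.iscomplexobj(raster):
        return (uniform_filter(raster.real, window, mode="reflect")
                + 1j * uniform_filter(raster.imag, window, mode="reflect"))
    return uniform_filter(raster.astype(np.float64), window, mode="reflect")


def lee_filter(intensity: np.ndarray, cfg: FilterConfig | None = None
               ) -> np.ndarray:
    """Local-statistics MMSE (Lee) filter for an intensity-like raster.

    Applied per channel to intensities or covariance diagonals; the same
    gain field can be reused on off-diagonal entries via
    :func:`lee_gain`.
    """
    cfg = cfg or FilterConfig()
    if cfg.enl <= 0:
        raise DomainError("enl must be positive")
    x = np.asarray(intensity, dtype=np.float64)
    if x.min() < 0:
        raise DomainError("lee filter expects a nonnegative intensity raster")
    k, m = lee_gain(x, cfg)
    return m + k * (x - m)


def lee_gain(intensity: np.ndarray, cfg: FilterConfig
             ) -> tuple[np.ndarray, np.ndarray]:
    """Gain field k in [0, 1] and local mean of the Lee filter."""
    x = np.asarray(intensity, dtype=np.float64)
    _check_extent(cfg.window, x.shape)
    m = uniform_filter(x, cfg.window, mode="reflect")
    m2 = uniform_filter(x * x, cfg.window, mode="reflect")
    v = np.maximum(m2 - m * m, 0.0)
    noise = m * m / cfg.enl
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(v > 0, np.maximum(v - noise, 0.0) / np.where(v > 0, v, 1.0),
                     0.0)
    return np.clip(k, 0.0, 1.0), m


def lee_filter_scattering(img, cfg: FilterConfig | None = None):
    """Lee-filter a scattering image in the intensity domain.

    Each channel's intensity |c|^2 is MMSE-filtered and the complex
    amplitude rescaled to match it, preserving the pixel phase.  (The
    complex signal itself is zero-mean speckle — smoothing it directly
    would annihilate it rather than despeckle it.)
    """
    from genpol.io import ScatteringImage  # local import to avoid a cycle

    cfg = cfg or FilterConfig()

    def _smooth(c):
        inten = np.abs(c) ** 2
        filt = lee_filter(inten, cfg)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.sqrt(np.where(inten > 0, filt / np.where(inten > 0,
                                                                inten, 1.0),
                                     0.0))
        return c * scale

    return ScatteringImage(_smooth(img.shh), _smooth(img.shv),
                           _smooth(img.svh), _smooth(img.svv),
                           date_tag=img.date_tag,
                           pixel_spacing=img.pixel_spacing)


def lee_filter_field(field, cfg: FilterConfig | None = None):
    """Lee-filter a Hermitian matrix field with a span-derived gain.

    One gain k per pixel, computed from the trace (span), is applied to
    every matrix entry around its local mean — diagonal and off-diagonal
    entries receive the same smoothing decision, keeping the filtered
    matrices PSD (convex combination of PSD averages and PSD samples).
    """
    from genpol.compact import HermitianField  # local import, avoids a cycle

    cfg = cfg or FilterConfig()
    k, _ = lee_gain(field.trace(), cfg)
    out = np.empty_like(field.entries)
    d = field.dim
    for i in range(d):
        for j in range(d):
            e = field.entries[..., i, j]
            m = boxcar(e, cfg.window)
            out[..., i, j] = m + k * (e - m)
    return HermitianField(out, kind=field.kind, window=cfg.window)


def estimate_enl(intensity: np.ndarray, region_mask: np.ndarray | None = None
                 ) -> float:
    """Equivalent number of looks mean^2/var over a homogeneous region."""
    x = np.asarray(intensity, dtype=np.float64)
    if region_mask is not None:
        x = x[np.asarray(region_mask, dtype=bool)]
    x = x.ravel()
    if x.size < 100:
        raise DomainError(f"need >= 100 pixels for ENL estimation, got {x.size}")
    v = x.var()
    if v <= 0:
        raise DomainError("degenerate (zero-variance) region")
    return float(x.mean() ** 2 / v)
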