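"""Reference post-processing: Gaussian post-smoothing and guided NLM.

The guided non-local-means variant weights each voxel's 5x5x5
neighborhood by similarity of a co-registered guide volume (a T1-like
MR image) rather than of the image being filtered::

    out_j = sum_{i in N_j} w_ij x_i / sum_{i in N_j} w_ij
    w_ij  = exp( -((g_i - g_j) / Omega)^2 / 2 )

There is no patch comparison and no spatial-distance weighting: a single
guide-voxel intensity difference drives each weight. Omega -> infinity
(or a constant guide) reduces the filter to a plain box mean over the
neighborhood; small Omega averages only across voxels the guide deems
similar, which transfers the guide's edges into the filtered image.

Both filters expose an exhaustive NRMSE grid optimizer used to give the
reference methods their best possible (oracle-tuned-on-training-data)
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from .metrics import nrmse
from .petsim import blur_psf

__all__ = ["FilterParamGrid", "gaussian_ps", "nlm_guided", "optimize_filter_param"]


def _default_ps_grid():
    return np.round(np.arange(0.0, 12.0 + 1e-9, 0.1), 10)


def _default_nlm_grid():
    return 10.0 ** np.arange(-5.0, 5.0 + 1e-9, 0.01)


@dataclass
class FilterParamGrid:
    """Search grids: PS FWHM in 0.1 mm steps, Omega in 0.01-decade steps."""

    ps_fwhm_grid: np.ndarray = field(default_factory=_default_ps_grid)
    nlm_omega_grid: np.ndarray = field(default_factory=_default_nlm_grid)

    def __post_init__(self):
        for name in ("ps_fwhm_grid", "nlm_omega_grid"):
            g = np.asarray(getattr(self, name), dtype=np.float64)
            if g.size == 0:
                raise ValueError(f"{name} is empty")
            if g.size > 1 and not np.all(np.diff(g) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, g)


def gaussian_ps(image, fwhm_mm, voxel_size_mm):
    """Gaussian post-smoothing; same contract as the PSF blur."""
    return blur_psf(image, fwhm_mm, voxel_size_mm)


@numba.njit(cache=True)
def _nlm_kernel(images, guide, inv2om2, half, out):  # pragma: no cover - numba
    R = images.shape[0]
    D, H, W = guide.shape
    for z in range(D):
        for y in range(H):
            for x in range(W):
                gj = guide[z, y, x]
                wsum = 0.0
                acc = np.zeros(R)
                for dz in range(-half, half + 1):
                    zz = z + dz
                    if zz < 0 or zz >= D:
                        continue
                    for dy in range(-half, half + 1):
                        yy = y + dy
                        if yy < 0 or yy >= H:
                            continue
                        for dx in range(-half, half + 1):
                            xx = x + dx
                            if xx < 0 or xx >= W:
                                continue
                            d = guide[zz, yy, xx] - gj
                            w = np.exp(-d * d * inv2om2)
                            wsum += w
                            for r in range(R):
                                acc[r] += w * images[r, zz, yy, xx]
                for r in range(R):
                    out[r, z, y, x] = acc[r] / wsum


def _nlm_multi(images: np.ndarray, guide: np.ndarray, omega: float, window: int) -> np.ndarray:
    """Guided NLM of several images sharing one guide (weights computed once)."""
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    images = np.ascontiguousarray(images, dtype=np.float64)
    guide = np.ascontiguousarray(guide, dtype=np.float64)
    if images.shape[1:] != guide.shape:
        raise ValueError(f"image shape {images.shape[1:]} != guide shape {guide.shape}")
    out = np.empty_like(images)
    _nlm_kernel(images, guide, 0.5 / (omega * omega), window // 2, out)
    return out


def nlm_guided(image, guide, omega: float, window: int = 5) -> np.ndarray:
    """Guide-weighted neighborhood mean (see module docstring).

    Neighborhoods are truncated at the volume boundary. The output is a
    convex combination of neighborhood input values, so it is locally
    bounded by the input's neighborhood min/max.
    """
    image = np.asarray(image, dtype=np.float64)
    return _nlm_multi(image[None], guide, omega, window)[0]


def optimize_filter_param(inputs, target, grid, which: str, *,
                          voxel_size_mm=None, guide=None, window: int = 5):
    """Exhaustive NRMSE grid search for a filter parameter.

    Filters every input realization at each grid value, scores the set
    with NRMSE against ``target`` and returns ``(best_param, curve)``
    where ``curve`` has one NRMSE value per grid point. Ties break toward
    the smaller parameter.
    """
    inputs = [np.asarray(v, dtype=np.float64) for v in inputs]
    if len(inputs) == 0:
        raise ValueError("need at least one input realization")
    which = which.lower()
    if which == "ps":
        values = np.asarray(grid.ps_fwhm_grid if isinstance(grid, FilterParamGrid) else grid,
                            dtype=np.float64)
        if voxel_size_mm is None:
            raise ValueError("voxel_size_mm required for PS optimization")
    elif which == "nlm":
        values = np.asarray(grid.nlm_omega_grid if isinstance(grid, FilterParamGrid) else grid,
                            dtype=np.float64)
        if guide is None:
            raise ValueError("guide volume required for NLM optimization")
    else:
        raise ValueError("which must be 'ps' or 'nlm'")
    if values.size == 0:
        raise ValueError("empty parameter grid")

    stack = np.stack(inputs)
    curve = np.empty(values.size)
    for i, p in enumerate(values):
        if which == "ps":
            filtered = [gaussian_ps(v, p, voxel_size_mm) for v in inputs]
        else:
            filtered = _nlm_multi(stack, guide, p, window)
        curve[i] = nrmse(list(filtered), target)
    best = int(np.argmin(curve))  # first minimum = smaller parameter on ties
    return float(values[best]), curve
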