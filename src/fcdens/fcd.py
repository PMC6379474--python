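"""Binarized short-/long-range functional connectivity density maps.

For each gray-matter voxel, the map counts the other mask voxels whose
Pearson correlation with it exceeds a threshold — the voxel's degree in a
binarized correlation graph.  The count is split by center-to-center
distance at a spherical neighborhood radius (6 mm by default):

* ``short``: connections to voxels within the radius (boundary inclusive),
* ``long``: connections beyond it,
* ``global``: their sum, connections to all other mask voxels.

The connection rule is a strict inequality ``r > threshold``.  Maps are then
normalized by division by their mask mean (so the mask mean becomes 1) and
smoothed with a 6 mm FWHM Gaussian restricted to the mask.  Correlations are
computed in row blocks so memory stays bounded; the result is exactly
independent of the block size.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import GrayMatterMask, VolumeGrid

__all__ = [
    "FcdParams",
    "FcdMaps",
    "DegenerateMapError",
    "neighborhood_offsets",
    "compute_fcd",
    "sweep_thresholds",
    "mean_scale",
    "zscore_scale",
    "gaussian_smooth",
    "normalize_and_smooth",
]

#: Default sweep of connection thresholds for the robustness analysis.
DEFAULT_SWEEP = (0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.6, 0.75)


class DegenerateMapError(ValueError):
    """Map cannot be normalized (e.g. zero mean over the mask)."""


@dataclass
class FcdParams:
    """Connectivity-density parameters.

    ``r_threshold`` is the connection definition (0.25 by default); the
    adopted map threshold for reported group comparisons is 0.45.
    ``radius_mm`` is the short/long boundary: short is inclusive (<=),
    long exclusive (>).  ``normalize="mean_scale"`` divides by the mask
    mean; a conventional z-score is available as ``"zscore"``.
    """

    r_threshold: float = 0.25
    radius_mm: float = 6.0
    sweep_thresholds: tuple[float, ...] = DEFAULT_SWEEP
    smooth_fwhm_mm: float = 6.0
    normalize: str = "mean_scale"  # mean_scale | zscore | none
    block_size: int = 512

    def __post_init__(self) -> None:
        thr = (self.r_threshold, *self.sweep_thresholds)
        if any(not 0 < t < 1 for t in thr):
            raise ValueError(f"thresholds must lie strictly in (0, 1): {thr}")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")
        if self.normalize not in ("mean_scale", "zscore", "none"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")


@dataclass
class FcdMaps:
    """Per-subject degree maps at one connection threshold.

    Before normalization the maps are integer-valued with
    ``short + long == global`` at every mask voxel.  After ``mean_scale``
    each map has mean 1 over the mask.
    """

    grid: VolumeGrid
    short_map: np.ndarray
    long_map: np.ndarray
    global_map: np.ndarray
    r_threshold: float
    radius_mm: float = 6.0
    normalized: str = "none"
    smoothed_fwhm_mm: float = 0.0
    subject_id: str = ""

    def map_of(self, kind: str) -> np.ndarray:
        try:
            return {"short": self.short_map, "long": self.long_map,
                    "global": self.global_map}[kind]
        except KeyError:
            raise KeyError(f"map kind must be short|long|global, got {kind!r}")


def neighborhood_offsets(
    radius_mm: float, voxel_size_mm: tuple[float, float, float] | float
) -> np.ndarray:
    """Integer voxel offsets within a spherical neighborhood.

    All offsets ``d`` (excluding the origin) whose center-to-center world
    distance ``||d * voxel_size||`` is <= ``radius_mm`` (boundary included).
    With 3 mm isotropic voxels and a 6 mm radius this yields 32 offsets.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    reach = np.floor(radius_mm / vs + 1e-9).astype(int)
    ax = [np.arange(-r, r + 1) for r in reach]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = np.sum((grid * vs) ** 2, axis=1)
    keep = (d2 <= radius_mm**2 + 1e-6) & ~np.all(grid == 0, axis=1)
    return grid[keep]


def _standardize_columns(series: np.ndarray) -> tuple[np.ndarray, int]:
    """Unit-norm columns for correlation-by-dot-product.

    Constant (zero-variance) columns are zeroed so every correlation
    involving them is 0, never suprathreshold; returns their count.
    """
    y = np.asarray(series, dtype=np.float64)
    y = y - y.mean(axis=0)
    norm = np.linalg.norm(y, axis=0)
    n_const = int(np.sum(norm == 0))
    norm[norm == 0] = 1.0
    return y / norm, n_const


def compute_fcd(
    series: np.ndarray,
    coords_mm: np.ndarray,
    params: FcdParams | None = None,
    thresholds: tuple[float, ...] | None = None,
    grid: VolumeGrid | None = None,
    mask: GrayMatterMask | None = None,
) -> dict[float, FcdMaps] | FcdMaps:
    """Degree maps (unnormalized, unsmoothed) for one subject.

    Parameters
    ----------
    series : (time, n_voxels) array
        Cleaned masked time series, column order matching ``coords_mm``.
    coords_mm : (n_voxels, 3) array
        World-mm centers of the mask voxels.
    thresholds : optional
        When given, maps are produced for each threshold in one pass over
        the correlation blocks and a dict {threshold: FcdMaps} is returned;
        otherwise a single FcdMaps at ``params.r_threshold``.

    When ``grid``/``mask`` are provided the degree vectors are embedded in
    3-D volumes; otherwise maps are returned as 1-D vectors over the mask
    (stored in the FcdMaps fields, grid None-equivalent not allowed then).
    """
    params = params or FcdParams()
    y = np.asarray(series, dtype=np.float64)
    coords = np.asarray(coords_mm, dtype=np.float64)
    n_t, n_vox = y.shape
    if n_vox < 2:
        raise ValueError("need >= 2 mask voxels")
    if coords.shape != (n_vox, 3):
        raise ValueError(f"coords shape {coords.shape} != ({n_vox}, 3)")
    if n_t < 3:
        raise ValueError("need >= 3 time points for correlation")

    single = thresholds is None
    thr = (params.r_threshold,) if single else tuple(thresholds)

    z, n_const = _standardize_columns(y)
    if n_const:
        warnings.warn(
            f"{n_const} constant voxel series treated as correlation 0",
            RuntimeWarning,
            stacklevel=2,
        )

    short_deg = {t: np.zeros(n_vox, dtype=np.int64) for t in thr}
    glob_deg = {t: np.zeros(n_vox, dtype=np.int64) for t in thr}
    r2 = params.radius_mm**2 + 1e-6

    block = max(1, int(params.block_size))
    for start in range(0, n_vox, block):
        stop = min(start + block, n_vox)
        rmat = z[:, start:stop].T @ z  # (block, n_vox) correlations
        diff = coords[start:stop, None, :] - coords[None, :, :]
        near = np.einsum("ijk,ijk->ij", diff, diff) <= r2
        idx = np.arange(start, stop)
        for t in thr:
            conn = rmat > t
            conn[np.arange(stop - start), idx] = False  # exclude self
            glob_deg[t][start:stop] = conn.sum(axis=1)
            short_deg[t][start:stop] = (conn & near).sum(axis=1)

    def _embed(vec: np.ndarray) -> np.ndarray:
        if mask is None:
            return vec.astype(np.float64)
        vol = np.zeros(mask.grid.dims)
        vol[mask.membership] = vec
        return vol

    out: dict[float, FcdMaps] = {}
    use_grid = grid or (mask.grid if mask is not None else None)
    for t in thr:
        s = short_deg[t]
        g = glob_deg[t]
        out[t] = FcdMaps(
            grid=use_grid,
            short_map=_embed(s),
            long_map=_embed(g - s),
            global_map=_embed(g),
            r_threshold=t,
            radius_mm=params.radius_mm,
        )
    return out[thr[0]] if single else out


def sweep_thresholds(
    series: np.ndarray,
    coords_mm: np.ndarray,
    params: FcdParams | None = None,
    grid: VolumeGrid | None = None,
    mask: GrayMatterMask | None = None,
) -> dict[float, FcdMaps]:
    """Degree maps at every threshold of ``params.sweep_thresholds``."""
    params = params or FcdParams()
    return compute_fcd(
        series, coords_mm, params,
        thresholds=params.sweep_thresholds, grid=grid, mask=mask,
    )


def mean_scale(volume: np.ndarray, mask_membership: np.ndarray) -> np.ndarray:
    """Divide by the mean over the mask, so the mask mean becomes 1.

    Idempotent; degenerate (zero-mean) maps raise DegenerateMapError.
    """
    m = np.asarray(mask_membership, dtype=bool)
    mu = float(np.asarray(volume)[m].mean())
    if mu == 0:
        raise DegenerateMapError("map mean over mask is zero; cannot mean-scale")
    out = np.asarray(volume, dtype=np.float64) / mu
    out[~m] = 0.0
    return out


def zscore_scale(volume: np.ndarray, mask_membership: np.ndarray) -> np.ndarray:
    """Conventional (x - mean)/sd z-score over the mask (non-default option)."""
    m = np.asarray(mask_membership, dtype=bool)
    vals = np.asarray(volume, dtype=np.float64)[m]
    sd = vals.std()
    if sd == 0:
        raise DegenerateMapError("map sd over mask is zero; cannot z-score")
    out = np.zeros_like(np.asarray(volume, dtype=np.float64))
    out[m] = (np.asarray(volume)[m] - vals.mean()) / sd
    return out


def gaussian_smooth(
    volume: np.ndarray,
    mask_membership: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float] | float,
) -> np.ndarray:
    """Mask-restricted Gaussian smoothing.

    The kernel sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` in mm, converted
    to voxels.  Smoothing is mask-weighted (kernel renormalized inside the
    mask), so a constant map stays constant inside the mask and no signal
    bleeds in from outside.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    vol = np.asarray(volume, dtype=np.float64)
    m = np.asarray(mask_membership, dtype=bool)
    if fwhm_mm == 0:
        return vol.copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
    num = gaussian_filter(np.where(m, vol, 0.0), sigma=sigma_vox, mode="constant")
    den = gaussian_filter(m.astype(np.float64), sigma=sigma_vox, mode="constant")
    out = np.zeros_like(vol)
    inside = m & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def normalize_and_smooth(
    maps: FcdMaps, mask: GrayMatterMask, params: FcdParams | None = None
) -> FcdMaps:
    """Apply the configured normalization then smoothing to all three maps."""
    params = params or FcdParams()
    norm_fn = {
        "mean_scale": mean_scale,
        "zscore": zscore_scale,
        "none": lambda v, m: np.asarray(v, dtype=np.float64).copy(),
    }[params.normalize]
    m = mask.membership
    vs = mask.grid.voxel_size_mm
    out = {}
    for kind in ("short", "long", "global"):
        try:
            v = norm_fn(maps.map_of(kind), m)
        except DegenerateMapError:
            # a subject with no suprathreshold connections contributes a
            # zero map at this threshold (can occur high in the sweep)
            warnings.warn(
                f"all-zero {kind} degree map at r={maps.r_threshold}; "
                "left unnormalized",
                RuntimeWarning,
                stacklevel=2,
            )
            v = np.zeros_like(np.asarray(maps.map_of(kind), dtype=np.float64))
        v = gaussian_smooth(v, m, params.smooth_fwhm_mm, vs)
        out[kind] = v
    return FcdMaps(
        grid=maps.grid,
        short_map=out["short"],
        long_map=out["long"],
        global_map=out["global"],
        r_threshold=maps.r_threshold,
        radius_mm=maps.radius_mm,
        normalized=params.normalize,
        smoothed_fwhm_mm=params.smooth_fwhm_mm,
        subject_id=maps.subject_id,
    )
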