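"""Marker-defined 3D masking and masked intensity-density quantification.

A volumetric model of a tissue domain (e.g. the presomitic mesoderm,
delimited by *Tbx6* expression) is built by smoothing the marker channel
at a physical detail scale and thresholding at an absolute intensity.
For the reference marker, the threshold is searched automatically so that
the resulting mask volume falls inside a target window (the tissue's
expected volume at stage); expression of other probes is then reported as
intensity sum within the mask divided by the mask volume (a.u. / µm³).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.draw import polygon as draw_polygon

from .grids import Mask3D, VoxelGrid, require_same_geometry

# Gaussian sigma producing a given full width at half maximum
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MaskingConfig:
    """Parameters of surface-mask construction.

    ``smoothing_scale_um`` is the physical detail scale: the marker channel
    is smoothed with a Gaussian whose FWHM equals this value (applied in
    µm, hence anisotropic in voxels).  ``volume_window_um3`` is the target
    [lo, hi] window for the automatic threshold search.
    ``min_component_um3`` drops connected components smaller than this
    (speckle removal) while keeping the bilateral tissue bands.
    """

    smoothing_scale_um: float = 3.0
    volume_window_um3: tuple[float, float] = (9.0e6, 1.1e7)
    min_component_um3: float = 1000.0

    def __post_init__(self) -> None:
        lo, hi = self.volume_window_um3
        if not lo < hi:
            raise ValueError("volume window must satisfy lo < hi")
        if self.smoothing_scale_um <= 0:
            raise ValueError("smoothing scale must be positive")


@dataclass
class ExpressionMeasure:
    """Masked expression measurement for one probe in one sample."""

    sample_id: str
    gene: str
    mask_gene: str
    intensity_sum: float
    volume_um3: float

    @property
    def density(self) -> float:
        """Intensity per µm³ within the mask."""
        return self.intensity_sum / self.volume_um3


def _smooth(channel: VoxelGrid, smoothing_scale_um: float) -> np.ndarray:
    sigma_um = smoothing_scale_um * _FWHM_TO_SIGMA
    sigma_vox = [sigma_um / s for s in channel.spacing]
    return ndi.gaussian_filter(channel.data.astype(np.float32), sigma=sigma_vox)


def _apply_component_policy(
    mask: np.ndarray, voxel_volume: float, min_component_um3: float
) -> np.ndarray:
    if min_component_um3 <= 0 or not mask.any():
        return mask
    labels, n = ndi.label(mask)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts * voxel_volume >= min_component_um3
    keep[0] = False
    return keep[labels]


def build_surface_mask(
    channel: VoxelGrid,
    config: MaskingConfig | None = None,
    threshold: float = 0.0,
    *,
    _smoothed: np.ndarray | None = None,
) -> Mask3D:
    """Threshold the smoothed marker channel at an absolute intensity.

    The mask is ``smoothed(channel) >= threshold`` post-processed by the
    component policy; its volume is non-increasing in the threshold.  An
    empty result is returned (with a warning), not raised.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    config = config or MaskingConfig()
    smoothed = _smoothed if _smoothed is not None else _smooth(channel, config.smoothing_scale_um)
    raw = smoothed >= threshold
    voxvol = channel.voxel_volume_um3
    raw = _apply_component_policy(raw, voxvol, config.min_component_um3)
    if not raw.any():
        warnings.warn(f"threshold {threshold} yields an empty mask", stacklevel=2)
    return Mask3D(
        data=raw,
        spacing=channel.spacing,
        provenance={
            "method": "fixed_threshold",
            "threshold": float(threshold),
            "smoothing_scale_um": config.smoothing_scale_um,
            "min_component_um3": config.min_component_um3,
        },
    )


def auto_threshold_to_volume(
    channel: VoxelGrid, config: MaskingConfig | None = None
) -> tuple[float, Mask3D]:
    """Search the absolute threshold so the mask volume lands in the window.

    Mask volume is monotone non-increasing in the threshold, so the search
    reduces to an exact order statistic of the smoothed intensities: the
    returned threshold is the largest one whose volume still reaches the
    window's lower bound (the most conservative qualifying mask).
    Deterministic.  Raises, naming the nearest achievable volumes, when
    the component-filtered volume jumps over the window.
    """
    config = config or MaskingConfig()
    lo, hi = config.volume_window_um3
    smoothed = _smooth(channel, config.smoothing_scale_um)
    voxvol = channel.voxel_volume_um3
    n_lo = int(np.ceil(lo / voxvol))
    flat = smoothed.ravel()
    if n_lo < 1:
        n_lo = 1
    if n_lo > flat.size:
        raise ValueError(
            f"volume window [{lo:g}, {hi:g}] µm³ exceeds the whole stack "
            f"({flat.size * voxvol:g} µm³)"
        )
    # threshold = n_lo-th largest smoothed value -> >= n_lo voxels retained
    thr = float(np.partition(flat, flat.size - n_lo)[flat.size - n_lo])
    mask = build_surface_mask(channel, config, thr, _smoothed=smoothed)
    vol = mask.volume_um3
    if not (lo <= vol <= hi):
        # ties or component filtering moved the volume out of the window;
        # scan the exact achievable volumes (descending unique thresholds)
        uniq = np.unique(flat)[::-1]
        # exact count of voxels >= each unique value, ties included
        counts = np.cumsum(np.bincount(np.searchsorted(-uniq, -flat), minlength=uniq.size))
        candidate_idx = np.nonzero((counts * voxvol >= lo) & (counts * voxvol <= hi))[0]
        found = False
        for i in candidate_idx:  # largest qualifying threshold first
            m = build_surface_mask(channel, config, float(uniq[i]), _smoothed=smoothed)
            v = m.volume_um3
            if lo <= v <= hi:
                mask, vol, thr = m, v, float(uniq[i])
                found = True
                break
        if not found:
            vols = counts * voxvol
            below = vols[vols < lo]
            above = vols[vols > hi]
            nearest_below = float(below.max()) if below.size else None
            nearest_above = float(above.min()) if above.size else None
            raise ValueError(
                f"no threshold achieves a volume in [{lo:g}, {hi:g}] µm³; "
                f"nearest achievable volumes: {nearest_below!r} (below), "
                f"{nearest_above!r} (above)"
            )
    mask.provenance.update({"method": "auto_threshold", "threshold": thr,
                            "volume_window_um3": list(config.volume_window_um3)})
    return thr, mask


def interpolate_roi_mask(
    annotations: list[tuple[int, np.ndarray]],
    z_extent: int,
    yx_shape: tuple[int, int],
    spacing: tuple[float, float, float],
) -> Mask3D:
    """Build a 3D mask from closed polygons drawn on a subset of z-planes.

    ``annotations`` is a list of ``(z_index, polygon)`` where the polygon
    is an (N, 2) array of (y, x) vertices in µm.  Annotated planes are
    rasterized exactly; intervening planes are filled by linearly
    interpolating the signed-distance transforms of the two bounding
    annotated planes and thresholding at zero; planes outside the
    annotated range copy the nearest annotated plane.
    """
    if len(annotations) < 2:
        raise ValueError("need at least two annotated planes to interpolate")
    dz, dy, dx = spacing
    planes: dict[int, np.ndarray] = {}
    for z_idx, poly in sorted(annotations, key=lambda a: a[0]):
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("each polygon must be an (N>=3, 2) array of (y, x) µm")
        if not (0 <= z_idx < z_extent):
            raise ValueError(f"annotated plane {z_idx} outside z extent {z_extent}")
        shp = ShapelyPolygon(poly)
        if not shp.is_valid:
            raise ValueError(f"polygon on plane {z_idx} is self-intersecting")
        rr, cc = draw_polygon(poly[:, 0] / dy, poly[:, 1] / dx, shape=yx_shape)
        img = np.zeros(yx_shape, dtype=bool)
        img[rr, cc] = True
        planes[z_idx] = img

    def signed_distance(m: np.ndarray) -> np.ndarray:
        # positive inside, negative outside, in µm
        inside = ndi.distance_transform_edt(m, sampling=(dy, dx))
        outside = ndi.distance_transform_edt(~m, sampling=(dy, dx))
        return inside - outside

    zs = sorted(planes)
    sdist = {z: signed_distance(planes[z]) for z in zs}
    out = np.zeros((z_extent,) + yx_shape, dtype=bool)
    for z in range(z_extent):
        if z in planes:
            out[z] = planes[z]
        elif z < zs[0]:
            out[z] = planes[zs[0]]
        elif z > zs[-1]:
            out[z] = planes[zs[-1]]
        else:
            z0 = max(q for q in zs if q < z)
            z1 = min(q for q in zs if q > z)
            w = (z1 - z) / (z1 - z0)
            out[z] = (w * sdist[z0] + (1.0 - w) * sdist[z1]) >= 0.0
    return Mask3D(
        data=out,
        spacing=spacing,
        provenance={"method": "roi_interpolation", "annotated_planes": zs},
    )


def masked_intensity_density(
    grid: VoxelGrid, mask: Mask3D, sample_id: str = "", mask_gene: str = ""
) -> ExpressionMeasure:
    """Intensity sum within the mask divided by the mask volume.

    This is the per-embryo expression measure: integrated probe signal
    over the marker-defined volume, in a.u. per µm³.
    """
    require_same_geometry(grid, mask)
    if mask.is_empty():
        raise ValueError("mask is empty; density undefined")
    total = float(np.sum(grid.data[mask.data], dtype=np.float64))
    return ExpressionMeasure(
        sample_id=sample_id,
        gene=grid.channel,
        mask_gene=mask_gene,
        intensity_sum=total,
        volume_um3=mask.volume_um3,
    )
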