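"""Stack I/O, flat-field shading correction, and per-probe baseline handling.

Shading (flat-field) correction divides each voxel by the normalized gain
of the illumination field measured from uniform dye solutions; the gain is
normalized by its mean so a spatially uniform specimen keeps its mean
intensity.  Baseline subtraction removes per-probe background using a
cutoff calibrated so that a tissue known not to express the gene (or a
probe-null specimen) shows essentially no remaining signal.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile

from .grids import Mask3D, VoxelGrid


# ---------------------------------------------------------------------------
# stack I/O (OME-TIFF)
# ---------------------------------------------------------------------------

def write_stack(grids: VoxelGrid | list[VoxelGrid], path: str | Path) -> Path:
    """Write one or more channels (same geometry) to an OME-TIFF.

    A single :class:`VoxelGrid` is written as a ZYX stack; a list is
    written as one multi-channel CZYX file with channel names preserved.
    """
    path = Path(path)
    single = isinstance(grids, VoxelGrid)
    glist = [grids] if single else list(grids)
    if not glist:
        raise ValueError("nothing to write")
    ref = glist[0]
    for g in glist[1:]:
        if g.data.shape != ref.data.shape or g.spacing != ref.spacing:
            raise ValueError("all channels in one file must share shape and spacing")
    dz, dy, dx = ref.spacing
    metadata = {
        "axes": "ZYX" if single else "CZYX",
        "PhysicalSizeZ": dz,
        "PhysicalSizeY": dy,
        "PhysicalSizeX": dx,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": [g.channel or f"ch{i}" for i, g in enumerate(glist)]},
    }
    data = glist[0].data if single else np.stack([g.data for g in glist])
    tifffile.imwrite(path, data, ome=True, photometric="minisblack", metadata=metadata)
    return path


def _parse_ome_spacing(ome_xml: str) -> tuple[tuple[float, float, float] | None, list[str]]:
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return None, []
    sizes = [pixels.get(f"PhysicalSize{ax}") for ax in ("Z", "Y", "X")]
    spacing = None
    if all(s is not None for s in sizes):
        spacing = tuple(float(s) for s in sizes)
    names = []
    for i, ch in enumerate(pixels.findall("ome:Channel", ns)):
        names.append(ch.get("Name") or f"ch{i}")
    return spacing, names


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float] | None = None,
) -> VoxelGrid | list[VoxelGrid]:
    """Read an (OME-)TIFF stack into one :class:`VoxelGrid` per channel.

    Voxel spacing is taken from the OME pixel-size metadata; a file
    without spacing metadata raises unless ``spacing`` is supplied
    explicitly.  Returns a single grid for a 3D file, a list for a
    multi-channel file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_spacing, channel_names = (None, [])
        if tf.ome_metadata:
            meta_spacing, channel_names = _parse_ome_spacing(tf.ome_metadata)
    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        raise ValueError(
            f"{path} has no voxel-spacing metadata; pass spacing=(dz, dy, dx) explicitly"
        )
    if axes.endswith("ZYX") and data.ndim == 4:
        grids = []
        for i in range(data.shape[0]):
            name = channel_names[i] if i < len(channel_names) else f"ch{i}"
            grids.append(VoxelGrid(data=data[i], spacing=spacing, channel=name))
        return grids
    if data.ndim != 3:
        raise ValueError(f"unsupported stack layout {axes} with shape {data.shape}")
    name = channel_names[0] if channel_names else ""
    return VoxelGrid(data=data, spacing=spacing, channel=name)


# ---------------------------------------------------------------------------
# shading correction
# ---------------------------------------------------------------------------

def shading_correct(grid: VoxelGrid, flatfield: VoxelGrid) -> VoxelGrid:
    """Flat-field (shading) correction: ``out = in × mean(ff) / ff``.

    The flat field must be strictly positive and share the grid's (y, x)
    shape; a 2D-equivalent (constant over z) or full 3D field is accepted
    and broadcast over z.  Normalizing by the flat field's mean preserves
    the mean intensity of a spatially uniform specimen.
    """
    ff = np.asarray(flatfield.data, dtype=np.float64)
    if np.any(ff <= 0):
        raise ValueError("flat field must be strictly positive everywhere")
    if ff.shape[-2:] != grid.data.shape[-2:]:
        raise ValueError(
            f"flat field xy shape {ff.shape[-2:]} does not match grid {grid.data.shape[-2:]}"
        )
    gain = ff / ff.mean()
    out = grid.data.astype(np.float32) / gain.astype(np.float32)
    return grid.with_data(out)


# ---------------------------------------------------------------------------
# baseline calibration and subtraction
# ---------------------------------------------------------------------------

@dataclass
class BaselineCutoff:
    """Per-probe baseline cutoff (a.u.) with its calibration provenance."""

    channel: str
    cutoff: float
    calibration_source: str  # "negative_tissue_region" or "null_embryo"
    tolerance: float

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if not (0 <= self.tolerance < 1):
            raise ValueError("tolerance must lie in [0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BaselineCutoff":
        return cls(**json.loads(Path(path).read_text()))


def calibrate_baseline(
    grids: list[VoxelGrid] | VoxelGrid,
    negative_region: Mask3D | None = None,
    tolerance: float = 1e-4,
    channel: str | None = None,
) -> BaselineCutoff:
    """Find the minimal cutoff leaving no detectable signal in a negative reference.

    The negative reference is either ``negative_region`` (a mask of tissue
    known not to express the probe, applied to each grid) or, when
    ``negative_region`` is None, the entirety of every grid (the
    probe-null-specimen case).  Returns the minimal cutoff ``c`` such that
    the fraction of reference voxels with value ``> c``, pooled over all
    grids, is at most ``tolerance``.  Exact order-statistic computation
    over the pooled values, not a grid search.
    """
    if isinstance(grids, VoxelGrid):
        grids = [grids]
    if not grids:
        raise ValueError("no grids supplied")
    if not (0 <= tolerance < 1):
        raise ValueError("tolerance must lie in [0, 1)")
    values = []
    for g in grids:
        if negative_region is not None:
            if negative_region.data.shape != g.data.shape:
                raise ValueError("negative region shape does not match grid")
            values.append(g.data[negative_region.data].ravel())
        else:
            values.append(g.data.ravel())
    pooled = np.concatenate(values)
    if pooled.size == 0:
        raise ValueError("negative reference region is empty")
    n = pooled.size
    # allow at most k exceedances; minimal qualifying cutoff is the
    # (k+1)-th largest pooled value
    k = int(np.floor(tolerance * n))
    if k >= n:
        cutoff = 0.0
    else:
        cutoff = float(np.partition(pooled, n - k - 1)[n - k - 1])
    cutoff = max(cutoff, 0.0)
    src = "null_embryo" if negative_region is None else "negative_tissue_region"
    return BaselineCutoff(
        channel=channel if channel is not None else grids[0].channel,
        cutoff=cutoff,
        calibration_source=src,
        tolerance=tolerance,
    )


def subtract_baseline(grid: VoxelGrid, cutoff: float | BaselineCutoff) -> VoxelGrid:
    """Baseline subtraction: ``out = max(in − cutoff, 0)`` elementwise."""
    c = cutoff.cutoff if isinstance(cutoff, BaselineCutoff) else float(cutoff)
    if c < 0:
        raise ValueError("cutoff must be >= 0")
    out = np.maximum(grid.data.astype(np.float32) - np.float32(c), np.float32(0))
    return grid.with_data(out)
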