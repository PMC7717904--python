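"""Spot models: detection, intensity measurement, binning and heat colors.

Punctate signal is modelled as ellipsoidal spots of fixed physical size
(lateral diameter × axial extent, the latter elongated by the confocal
PSF).  Detection is scale-matched Laplacian-of-Gaussian filtering with
anisotropic sigmas followed by local-maximum extraction; each spot's
*sum intensity* integrates the channel over the spot ellipsoid, minus
(when local background subtraction is on) the median of a surrounding
shell times the ellipsoid's voxel count.  Spots are then thresholded on
sum intensity, assigned to fixed intensity bins, or mapped to a linear
heat-map color scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .grids import Mask3D, VoxelGrid

UNBINNED = "unbinned"


@dataclass
class SpotDetectParams:
    """Spot-model parameters.

    ``diameter_um`` is the lateral spot diameter; ``psf_axial_um`` the
    axial (z) spot extent, elongated by the point-spread function.
    ``min_sum_intensity`` is the default sum-intensity threshold applied
    after detection.  ``noise_floor_sigma`` scales the robust noise
    estimate of the LoG response below which maxima are ignored.
    """

    diameter_um: float = 4.0
    psf_axial_um: float = 8.0
    local_background: bool = True
    min_sum_intensity: float = 1500.0
    noise_floor_sigma: float = 6.0
    shell_outer_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.psf_axial_um < self.diameter_um:
            raise ValueError("axial extent must be >= lateral diameter")


@dataclass
class SpotBinningScheme:
    """Fixed sum-intensity bins with half-open [lo, hi) intervals.

    The default scheme is: low 1,000–6,000; low-medium 6,000–11,000;
    medium 11,000–16,000; medium-high 16,000–21,000; high ≥ 21,000 (a.u.);
    spots below the first edge are left unbinned and excluded from
    distribution counts.
    """

    edges: tuple[float, ...] = (1000.0, 6000.0, 11000.0, 16000.0, 21000.0)
    labels: tuple[str, ...] = ("low", "low_medium", "medium", "medium_high", "high")

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing")
        if len(self.labels) != len(self.edges):
            raise ValueError("need one label per interval (top interval unbounded)")

    def label_for(self, sum_intensity: float) -> str:
        e = self.edges
        if sum_intensity < e[0]:
            return UNBINNED
        idx = int(np.searchsorted(e, sum_intensity, side="right")) - 1
        return self.labels[idx]


@dataclass
class SpotSet:
    """Detected puncta with positions (µm), sum intensities and labels.

    Backed by a DataFrame with columns ``z_um, y_um, x_um, sum_intensity``
    plus optional ``bin_label`` and ``heat_value``.
    """

    table: pd.DataFrame
    params: SpotDetectParams | None = None
    scheme: SpotBinningScheme | None = None

    _COLUMNS = ("z_um", "y_um", "x_um", "sum_intensity")

    def __post_init__(self) -> None:
        for c in self._COLUMNS:
            if c not in self.table.columns:
                raise ValueError(f"SpotSet table missing column {c!r}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions_um(self) -> np.ndarray:
        return self.table[["z_um", "y_um", "x_um"]].to_numpy()

    @property
    def sum_intensities(self) -> np.ndarray:
        return self.table["sum_intensity"].to_numpy()

    @classmethod
    def empty(cls, params: SpotDetectParams | None = None) -> "SpotSet":
        return cls(table=pd.DataFrame(columns=list(cls._COLUMNS)), params=params)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _ellipsoid_offsets(radii_um: tuple[float, float, float],
                       spacing: tuple[float, float, float],
                       inner_um: tuple[float, float, float] | None = None
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel offsets within an ellipsoid (or shell) centred at the origin."""
    half = [int(np.ceil(r / s)) for r, s in zip(radii_um, spacing)]
    zz, yy, xx = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    d2 = sum(((o * s) / r) ** 2 for o, s, r in zip((zz, yy, xx), spacing, radii_um))
    inside = d2 <= 1.0
    if inner_um is not None:
        d2i = sum(((o * s) / r) ** 2 for o, s, r in zip((zz, yy, xx), spacing, inner_um))
        inside &= d2i > 1.0
    return zz[inside], yy[inside], xx[inside]


def _measure_sum(data: np.ndarray, centers_vox: np.ndarray,
                 params: SpotDetectParams, spacing: tuple[float, float, float]
                 ) -> np.ndarray:
    """Ellipsoid sum intensity with optional shell-median background."""
    radii = (params.psf_axial_um / 2.0, params.diameter_um / 2.0, params.diameter_um / 2.0)
    ell = _ellipsoid_offsets(radii, spacing)
    outer = tuple(r * params.shell_outer_factor for r in radii)
    shell = _ellipsoid_offsets(outer, spacing, inner_um=radii)
    n_ell = len(ell[0])
    shape = data.shape
    sums = np.empty(len(centers_vox), dtype=np.float64)
    for i, c in enumerate(centers_vox):
        idx = [np.clip(c[a] + off, 0, shape[a] - 1) for a, off in enumerate(ell)]
        total = float(data[tuple(idx)].sum(dtype=np.float64))
        if params.local_background:
            sidx = [np.clip(c[a] + off, 0, shape[a] - 1) for a, off in enumerate(shell)]
            bg = float(np.median(data[tuple(sidx)]))
            total -= bg * n_ell
        sums[i] = max(total, 0.0)
    return sums


def detect_spots(
    channel: VoxelGrid,
    params: SpotDetectParams | None = None,
    mask: Mask3D | None = None,
) -> SpotSet:
    """Detect puncta as fixed-size ellipsoidal spots.

    Scale-matched anisotropic LoG filtering (lateral scale diameter/2,
    axial scale psf_axial/2) followed by local-maximum extraction above a
    robust noise floor; maxima closer than one spot radius (anisotropy-
    scaled) are merged keeping the brighter.  If ``mask`` is given, only
    spots whose centres fall inside it are returned.  Sum intensities are
    measured per :func:`_measure_sum`.
    """
    params = params or SpotDetectParams()
    spacing = channel.spacing
    r_lat = params.diameter_um / 2.0
    r_ax = params.psf_axial_um / 2.0
    if any(s > r for s, r in zip(spacing, (r_ax, r_lat, r_lat))):
        warnings.warn("voxel spacing is coarser than the spot radius on some axis; "
                      "detection is sub-resolution", stacklevel=2)
    data = channel.data.astype(np.float32)

    # restrict work to the mask bounding box (padded by one spot extent)
    if mask is not None and not mask.is_empty():
        nz = np.nonzero(mask.data)
        pad = [int(np.ceil(2 * r / s)) for r, s in zip((r_ax, r_lat, r_lat), spacing)]
        lo = [max(0, int(nz[a].min()) - pad[a]) for a in range(3)]
        hi = [min(data.shape[a], int(nz[a].max()) + pad[a] + 1) for a in range(3)]
    else:
        lo = [0, 0, 0]
        hi = list(data.shape)
    sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]

    # LoG blob response (bright blobs -> positive response)
    sigma_um = (r_ax / np.sqrt(3.0), r_lat / np.sqrt(3.0), r_lat / np.sqrt(3.0))
    sigma_vox = [s / sp for s, sp in zip(sigma_um, spacing)]
    response = -ndi.gaussian_laplace(sub, sigma=sigma_vox)

    med = np.median(response)
    mad = np.median(np.abs(response - med))
    noise_sd = 1.4826 * mad if mad > 0 else float(response.std())
    threshold = med + params.noise_floor_sigma * noise_sd
    if noise_sd == 0 and not np.any(response > threshold):
        return SpotSet.empty(params)

    foot_half = [max(1, int(round(r / s))) for r, s in zip((r_ax, r_lat, r_lat), spacing)]
    footprint = np.ones([2 * h + 1 for h in foot_half], dtype=bool)
    local_max = (response == ndi.maximum_filter(response, footprint=footprint))
    cand = np.nonzero(local_max & (response > threshold))
    if cand[0].size == 0:
        return SpotSet.empty(params)
    centers = np.stack(cand, axis=1) + np.array(lo)
    resp_vals = response[cand]

    # merge duplicates closer than one radius (z scaled by the aspect ratio)
    aspect = r_ax / r_lat
    scaled = centers * np.array(spacing) / np.array([aspect, 1.0, 1.0])
    order = np.argsort(resp_vals)[::-1]
    tree = cKDTree(scaled[order])
    pairs = tree.query_pairs(r=r_lat, output_type="ndarray")
    if len(pairs):
        pairs = pairs[np.argsort(pairs[:, 0], kind="stable")]
    drop = np.zeros(len(order), dtype=bool)
    for a, b in pairs:  # a < b in brightness order: keep a, drop b
        if not drop[a]:
            drop[b] = True
    keep = order[~drop]
    centers = centers[keep]

    if mask is not None:
        inside = mask.data[tuple(centers.T)]
        centers = centers[inside]
    if centers.shape[0] == 0:
        return SpotSet.empty(params)

    sums = _measure_sum(data, centers, params, spacing)
    pos_um = centers * np.array(spacing)
    table = pd.DataFrame({
        "z_um": pos_um[:, 0], "y_um": pos_um[:, 1], "x_um": pos_um[:, 2],
        "sum_intensity": sums,
    })
    return SpotSet(table=table.reset_index(drop=True), params=params)


def filter_spots(spots: SpotSet, min_sum_intensity: float) -> SpotSet:
    """Retain spots with ``sum_intensity >= min_sum_intensity`` (inclusive)."""
    table = spots.table[spots.table["sum_intensity"] >= min_sum_intensity]
    return SpotSet(table=table.reset_index(drop=True), params=spots.params,
                   scheme=spots.scheme)


def bin_spots(spots: SpotSet, scheme: SpotBinningScheme | None = None) -> SpotSet:
    """Label each spot by the half-open intensity interval containing it.

    Spots below the first edge are labelled ``unbinned``; the top interval
    is unbounded above; ties at internal edges go to the upper bin.
    """
    scheme = scheme or SpotBinningScheme()
    labels = [scheme.label_for(s) for s in spots.table["sum_intensity"]]
    table = spots.table.copy()
    table["bin_label"] = labels
    return SpotSet(table=table, params=spots.params, scheme=scheme)


def quintile_distribution(spots: SpotSet, as_percent: bool = True) -> pd.Series:
    """Fraction of binned spots per intensity bin (unbinned spots excluded).

    Fractions sum to 1 (or percentages to 100).  Raises if no spot is
    binned.
    """
    if "bin_label" not in spots.table.columns:
        raise ValueError("spots are not binned; call bin_spots first")
    scheme = spots.scheme or SpotBinningScheme()
    binned = spots.table[spots.table["bin_label"] != UNBINNED]
    if len(binned) == 0:
        raise ValueError("no binned spots")
    counts = binned["bin_label"].value_counts()
    frac = pd.Series([counts.get(lb, 0) / len(binned) for lb in scheme.labels],
                     index=list(scheme.labels), name="fraction")
    return 100.0 * frac if as_percent else frac


def assign_heat_colors(spots: SpotSet, scale: tuple[float, float]) -> SpotSet:
    """Linear heat-map value: ``clamp((I − min) / (max − min), 0, 1)``."""
    lo, hi = scale
    if not lo < hi:
        raise ValueError("heat scale must satisfy min < max")
    table = spots.table.copy()
    table["heat_value"] = np.clip(
        (table["sum_intensity"].to_numpy() - lo) / (hi - lo), 0.0, 1.0)
    return SpotSet(table=table, params=spots.params, scheme=spots.scheme)


@dataclass
class SpotMatchResult:
    """Detection-vs-truth matching summary."""

    n_detected: int
    n_truth: int
    n_matched: int
    matches: list[tuple[int, int]] = field(default_factory=list)

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else float("nan")


def match_spots(detected: SpotSet, truth_positions_um: np.ndarray,
                max_dist_um: float = 3.0, axial_scale: float = 2.0) -> SpotMatchResult:
    """Greedy one-to-one matching of detected spots to ground-truth puncta.

    Distances are computed with the z axis compressed by ``axial_scale``
    (the axial/lateral spot aspect).  A truth punctum matches at most one
    detection within ``max_dist_um``.
    """
    truth = np.asarray(truth_positions_um, dtype=float).reshape(-1, 3)
    det = detected.positions_um.astype(float)
    if len(det) == 0 or len(truth) == 0:
        return SpotMatchResult(len(det), len(truth), 0)
    scale = np.array([1.0 / axial_scale, 1.0, 1.0])
    tree = cKDTree(truth * scale)
    dists, idx = tree.query(det * scale, distance_upper_bound=max_dist_um)
    used: set[int] = set()
    matches = []
    for d_i in np.argsort(dists):
        t_i = idx[d_i]
        if not np.isfinite(dists[d_i]) or t_i >= len(truth) or t_i in used:
            continue
        used.add(int(t_i))
        matches.append((int(d_i), int(t_i)))
    return SpotMatchResult(len(det), len(truth), len(matches), matches)
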