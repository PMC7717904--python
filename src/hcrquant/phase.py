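"""Stripe detection and oscillation-phase classification in the PSM.

A snapshot of oscillatory striped expression is classified into one of
three phases by the number and position of its transverse stripes:

* **Phase I** — three stripes, the most posterior limited to the
  posterior midline, the most anterior having reached the anterior
  boundary of the PSM;
* **Phase II** — two stripes, the posterior one expanded laterally and
  the anterior one short of the anterior limit;
* **Phase III** — two distinct stripes plus a third stripe *initiating*
  at the posterior midline (low prominence).

Stripes are found as peaks of the smoothed anteroposterior (AP) mean-
intensity profile within the tissue mask; each stripe's mediolateral (ML)
extent is measured at half-peak height on a maximum-intensity projection
restricted to the stripe's AP window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, peak_widths

from .grids import Mask3D, VoxelGrid, require_same_geometry


@dataclass
class APProfile:
    """Mean masked intensity per AP bin."""

    centers_um: np.ndarray
    mean: np.ndarray
    counts: np.ndarray  # mask voxels per bin
    bin_width_um: float

    @property
    def total_intensity(self) -> float:
        """Σ(profile × bin voxel counts) — equals the masked intensity sum."""
        return float(np.sum(self.mean * self.counts))


@dataclass
class StripeDetectParams:
    """Tunables of stripe detection and the phase criteria.

    The phase criteria are qualitative in origin; these defaults
    operationalize them: a *full* stripe has profile prominence at least
    ``prominence_fraction`` of the profile range, an *initiating* stripe
    has prominence in [``initiating_prominence_fraction``,
    ``prominence_fraction``) and sits in the posterior
    ``posterior_fraction`` of the mask at the midline.  ``f_mid`` is the
    largest ML extent fraction still called "midline-limited";
    ``anterior_tolerance_fraction`` (of the mask AP length) decides
    whether a stripe has reached the anterior boundary.
    """

    bin_width_um: float = 5.0
    profile_smooth_um: float = 10.0
    prominence_fraction: float = 0.2
    initiating_prominence_fraction: float = 0.05
    min_separation_um: float = 40.0
    f_mid: float = 0.4
    anterior_tolerance_fraction: float = 0.05
    posterior_fraction: float = 0.15


@dataclass
class StripeMeasure:
    """One detected transverse stripe."""

    ap_center_um: float
    ap_width_um: float  # FWHM of the profile peak
    ml_extent_fraction: float
    prominence: float
    height: float
    kind: str  # "full" or "initiating"
    midline_limited: bool
    reaches_anterior_boundary: bool


@dataclass
class StripeSet:
    """Detected stripes (ordered anterior → posterior) plus mask context."""

    stripes: list[StripeMeasure]
    ap_min_um: float
    ap_max_um: float
    params: StripeDetectParams

    def __len__(self) -> int:
        return len(self.stripes)

    @property
    def full_stripes(self) -> list[StripeMeasure]:
        return [s for s in self.stripes if s.kind == "full"]

    @property
    def initiating_stripes(self) -> list[StripeMeasure]:
        return [s for s in self.stripes if s.kind == "initiating"]


@dataclass
class PhaseCall:
    """Result of phase classification."""

    phase: str  # "I", "II", "III" or "unclassifiable"
    stripe_count: int
    criteria_trace: dict[str, bool] = field(default_factory=dict)


def ap_profile(grid: VoxelGrid, mask: Mask3D, bin_width_um: float = 5.0) -> APProfile:
    """Mean masked intensity per AP bin.

    The identity Σ(profile × bin counts) = masked intensity sum holds to
    float64 accumulation accuracy.
    """
    require_same_geometry(grid, mask)
    if mask.is_empty():
        raise ValueError("mask is empty")
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    dx = grid.spacing[2]
    nx = grid.data.shape[2]
    col_sums = np.sum(grid.data * mask.data, axis=(0, 1), dtype=np.float64)
    col_counts = np.sum(mask.data, axis=(0, 1), dtype=np.int64)
    bin_idx = np.floor(np.arange(nx) * dx / bin_width_um).astype(int)
    nbins = int(bin_idx[-1]) + 1
    sums = np.bincount(bin_idx, weights=col_sums, minlength=nbins)
    counts = np.bincount(bin_idx, weights=col_counts, minlength=nbins).astype(np.int64)
    occupied = np.nonzero(counts > 0)[0]
    lo, hi = occupied[0], occupied[-1] + 1
    sums, counts = sums[lo:hi], counts[lo:hi]
    mean = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    centers = (np.arange(lo, hi) + 0.5) * bin_width_um
    return APProfile(centers_um=centers, mean=mean, counts=counts,
                     bin_width_um=bin_width_um)


def _mask_ap_limits(mask: Mask3D) -> tuple[float, float]:
    cols = np.any(mask.data, axis=(0, 1))
    idx = np.nonzero(cols)[0]
    dx = mask.spacing[2]
    return float(idx[0] * dx), float(idx[-1] * dx)


def _ml_extent_fraction(
    grid: VoxelGrid, mask: Mask3D, ap_center_um: float, ap_width_um: float
) -> float:
    """Stripe ML span at half-peak height ÷ mask ML span, both measured on
    the z-MIP restricted to the stripe's AP window."""
    dx, dy = grid.spacing[2], grid.spacing[1]
    nx = grid.data.shape[2]
    half = max(ap_width_um / 2.0, dx)
    i0 = max(0, int((ap_center_um - half) / dx))
    i1 = min(nx, int(np.ceil((ap_center_um + half) / dx)) + 1)
    sub = grid.data[:, :, i0:i1]
    msub = mask.data[:, :, i0:i1]
    mip = np.max(np.where(msub, sub, 0.0), axis=(0, 2))
    mask_cols = np.any(msub, axis=(0, 2))
    col_idx = np.nonzero(mask_cols)[0]
    if col_idx.size == 0 or mip.max() <= 0:
        return 0.0
    span_mask = (col_idx[-1] - col_idx[0] + 1) * dy
    above = np.nonzero(mip >= 0.5 * mip.max())[0]
    span_stripe = (above[-1] - above[0] + 1) * dy
    return float(min(1.0, span_stripe / span_mask))


def detect_stripes(
    grid: VoxelGrid,
    mask: Mask3D,
    params: StripeDetectParams | None = None,
) -> StripeSet:
    """Detect transverse expression stripes from the masked AP profile.

    Peaks of the smoothed profile with prominence at least
    ``initiating_prominence_fraction × range`` and mutual separation of at
    least ``min_separation_um`` are candidate stripes; they are labelled
    *full* or *initiating* (posterior midline low-prominence peaks), and
    sub-threshold peaks that qualify as neither are dropped.  An empty
    StripeSet is a valid result.
    """
    params = params or StripeDetectParams()
    prof = ap_profile(grid, mask, params.bin_width_um)
    sigma_bins = params.profile_smooth_um / params.bin_width_um
    smoothed = gaussian_filter1d(prof.mean, sigma=sigma_bins) if sigma_bins > 0 else prof.mean
    rng_ = float(smoothed.max() - smoothed.min())
    ap_min, ap_max = _mask_ap_limits(mask)
    if rng_ <= 0:
        return StripeSet(stripes=[], ap_min_um=ap_min, ap_max_um=ap_max, params=params)
    distance = max(1, int(round(params.min_separation_um / params.bin_width_um)))
    # pad with the profile minimum so stripes truncated at the mask
    # boundary are still peaks with their full prominence
    padded = np.concatenate([[smoothed.min()], smoothed, [smoothed.min()]])
    peaks, props = find_peaks(
        padded,
        prominence=params.initiating_prominence_fraction * rng_,
        distance=distance,
    )
    if peaks.size == 0:
        return StripeSet(stripes=[], ap_min_um=ap_min, ap_max_um=ap_max, params=params)
    widths, _, left_ips, _ = peak_widths(padded, peaks, rel_height=0.5)
    peaks = peaks - 1
    left_ips = left_ips - 1.0
    ap_len = ap_max - ap_min
    delta_ant = params.anterior_tolerance_fraction * ap_len
    posterior_limit = ap_max - params.posterior_fraction * ap_len
    stripes: list[StripeMeasure] = []
    for pk, prom, w_bins, lip in zip(peaks, props["prominences"], widths, left_ips):
        center = float(prof.centers_um[pk])
        width = float(w_bins * params.bin_width_um)
        frac = prom / rng_
        ml_frac = _ml_extent_fraction(grid, mask, center, width)
        left_edge = prof.centers_um[0] + (lip) * params.bin_width_um
        reaches = (left_edge - ap_min) <= delta_ant
        midline_limited = ml_frac <= params.f_mid
        if frac >= params.prominence_fraction:
            kind = "full"
        elif (center >= posterior_limit) and midline_limited:
            kind = "initiating"
        else:
            continue  # sub-threshold, not at the posterior midline: not a stripe
        stripes.append(StripeMeasure(
            ap_center_um=center,
            ap_width_um=width,
            ml_extent_fraction=ml_frac,
            prominence=float(prom),
            height=float(smoothed[pk]),
            kind=kind,
            midline_limited=midline_limited,
            reaches_anterior_boundary=bool(reaches),
        ))
    stripes.sort(key=lambda s: s.ap_center_um)
    return StripeSet(stripes=stripes, ap_min_um=ap_min, ap_max_um=ap_max, params=params)


def classify_phase(stripe_set: StripeSet) -> PhaseCall:
    """Apply the phase criteria to a detected stripe set.

    Rule order: (a) three full stripes with the posterior one midline-
    limited and the anterior one at the anterior boundary → I; (b) two
    full stripes plus an initiating posterior-midline stripe → III;
    (c) two full stripes with the posterior one laterally expanded and the
    anterior one short of the boundary → II; anything else is
    unclassifiable.  The trace records every predicate tested.
    """
    full = stripe_set.full_stripes
    init = stripe_set.initiating_stripes
    trace: dict[str, bool] = {
        "three_full_stripes": len(full) == 3,
        "two_full_stripes": len(full) == 2,
        "initiating_at_posterior_midline": len(init) >= 1,
    }
    n = len(stripe_set)
    if len(full) == 3:
        posterior_limited = full[-1].midline_limited
        anterior_reaches = full[0].reaches_anterior_boundary
        trace["posterior_midline_limited"] = posterior_limited
        trace["anterior_reaches_boundary"] = anterior_reaches
        if posterior_limited and anterior_reaches:
            return PhaseCall(phase="I", stripe_count=n, criteria_trace=trace)
    if len(full) == 2:
        if len(init) >= 1:
            return PhaseCall(phase="III", stripe_count=n, criteria_trace=trace)
        posterior_expanded = not full[-1].midline_limited
        anterior_short = not full[0].reaches_anterior_boundary
        trace["posterior_laterally_expanded"] = posterior_expanded
        trace["anterior_short_of_boundary"] = anterior_short
        if posterior_expanded and anterior_short:
            return PhaseCall(phase="II", stripe_count=n, criteria_trace=trace)
    return PhaseCall(phase="unclassifiable", stripe_count=n, criteria_trace=trace)


def call_phase(
    grid: VoxelGrid, mask: Mask3D, params: StripeDetectParams | None = None
) -> tuple[PhaseCall, StripeSet]:
    """Convenience wrapper: detect stripes then classify."""
    stripes = detect_stripes(grid, mask, params)
    return classify_phase(stripes), stripes


def trough_peak_metric(
    grid: VoxelGrid,
    mask: Mask3D,
    params: StripeDetectParams | None = None,
) -> float:
    """Depth of the expression trough between adjacent oscillatory peaks.

    Returns the minimum of the AP profile between the two most prominent
    *adjacent* detected peaks, divided by the mean of those two peak
    heights; lies in [0, 1] for non-negative profiles (1 = no trough).
    A shallower trough (larger ratio) indicates failed transcriptional
    repression between stripes.
    """
    params = params or StripeDetectParams()
    prof = ap_profile(grid, mask, params.bin_width_um)
    sigma_bins = params.profile_smooth_um / params.bin_width_um
    smoothed = gaussian_filter1d(prof.mean, sigma=sigma_bins) if sigma_bins > 0 else prof.mean
    rng_ = float(smoothed.max() - smoothed.min())
    if rng_ <= 0:
        raise ValueError("flat profile: fewer than 2 stripes detected")
    distance = max(1, int(round(params.min_separation_um / params.bin_width_um)))
    padded = np.concatenate([[smoothed.min()], smoothed, [smoothed.min()]])
    peaks, props = find_peaks(
        padded,
        prominence=params.initiating_prominence_fraction * rng_,
        distance=distance,
    )
    peaks = peaks - 1
    if peaks.size < 2:
        raise ValueError(f"need >= 2 stripes for a trough, found {peaks.size}")
    proms = props["prominences"]
    best = int(np.argmax(proms[:-1] + proms[1:]))
    p0, p1 = peaks[best], peaks[best + 1]
    trough = float(np.min(smoothed[p0:p1 + 1]))
    peak_mean = 0.5 * (float(smoothed[p0]) + float(smoothed[p1]))
    if peak_mean <= 0:
        raise ValueError("non-positive peak heights")
    return trough / peak_mean
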