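"""Synthetic 3D embryo phantoms with known ground truth.

The generator emulates whole-mount HCR confocal stacks of an early-somite
mouse embryo tail:

* a **reference** channel (*Tbx6*-like) filling a bilateral presomitic-
  mesoderm (PSM) shaped domain — two paraxial bands flanking a midline
  gap, merging across the midline in the posterior (tailbud) quarter;
* a **target** channel (*Hes7*-like) with 2–3 transverse oscillatory
  stripes, each a concentric (anisotropic Gaussian) intensity gradient,
  plus a low pan-domain floor and off-target expression in a neural-
  ectoderm-like midline territory outside the reference domain;
* an **intron_puncta** channel of punctate nascent-transcription signal
  whose puncta concentrate in the stripes.

Genotype effects scale the target (and puncta) intensities
multiplicatively; the image is degraded by a multiplicative vignetting
field, Poisson shot noise, Gaussian read noise and a constant baseline
offset.  Every draw is controlled by the spec seed, so identical specs
produce bit-identical stacks.

Axis convention: arrays are (z, y, x) = (DV, ML, AP), anterior at x = 0.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import erf

from .grids import Mask3D, VoxelGrid

CHANNELS = ("reference", "target", "intron_puncta")

PHASES = ("I", "II", "III")

#: full stripes required by each oscillation phase (phase III adds one
#: initiating posterior-midline stripe on top of its two full stripes)
FULL_STRIPES_PER_PHASE = {"I": 3, "II": 2, "III": 2}

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = _FWHM * sigma


class ValidationError(ValueError):
    """A synthetic spec violates its invariants."""


# ---------------------------------------------------------------------------
# spec dataclasses
# ---------------------------------------------------------------------------

@dataclass
class PSMGeometry:
    """Bilateral band domain of the reference marker, in µm.

    The domain is two AP-oriented bands of width ``band_width_um`` flanking
    a midline gap of ``midline_gap_um``, spanning ``dv_thickness_um`` in z;
    in the posterior ``posterior_merge_fraction`` of the AP extent the gap
    is filled (the bands merge across the midline, as in the tailbud).
    """

    ap_start_um: float = 20.0
    ap_length_um: float = 600.0
    ml_center_um: float = 162.0
    band_width_um: float = 90.0
    midline_gap_um: float = 100.0
    dv_start_um: float = 20.0
    dv_thickness_um: float = 80.0
    posterior_merge_fraction: float = 0.25
    edge_smooth_um: float = 2.0

    @property
    def ap_end_um(self) -> float:
        return self.ap_start_um + self.ap_length_um

    @property
    def merge_start_um(self) -> float:
        return self.ap_end_um - self.posterior_merge_fraction * self.ap_length_um

    @property
    def ml_span_um(self) -> float:
        """Outer ML span of the domain (band + gap + band)."""
        return 2.0 * self.band_width_um + self.midline_gap_um

    def true_volume_um3(self) -> float:
        """Analytic volume of the hard (unsmoothed) domain."""
        anterior = (1.0 - self.posterior_merge_fraction) * self.ap_length_um
        posterior = self.posterior_merge_fraction * self.ap_length_um
        area = anterior * 2.0 * self.band_width_um + posterior * self.ml_span_um
        return area * self.dv_thickness_um


@dataclass
class StripeParams:
    """Oscillatory stripe pattern of the target channel.

    ``phase`` selects the stripe layout (None = draw uniformly at
    generation time); ``stripe_count`` may pin the number of full stripes
    and must then match the phase (3 for I, 2 for II and III).  Stripes
    are anisotropic Gaussian bumps: ``peak_intensity`` at the centre
    falling toward ``floor_intensity``, the pan-domain low-level signal.
    Total stripe flux is renormalized to a phase-independent reference so
    cohort-level expression does not depend on the phase at fixation.
    """

    phase: str | None = None
    stripe_count: int | None = None
    peak_intensity: float = 2000.0
    floor_intensity: float = 150.0
    ap_fwhm_um: float = 60.0
    full_ml_fwhm_um: float = 238.0
    midline_ml_fwhm_um: float = 70.0
    initiating_amplitude_fraction: float = 0.3
    trough_fill_fraction: float = 0.0
    center_jitter_um: float = 5.0
    width_jitter_cv: float = 0.03
    amplitude_jitter_cv: float = 0.03


@dataclass
class OfftargetParams:
    """Neural-ectoderm-like expression outside the reference domain."""

    intensity: float = 300.0
    ml_fwhm_um: float = 60.0
    ap_fraction: float = 0.6  # anterior fraction of the AP extent covered


@dataclass
class PunctaParams:
    """Punctate nascent-transcription channel."""

    density_per_um3: float = 3.0e-5
    #: per-bin weights of the piecewise-uniform sum-intensity mixture,
    #: over [1000,6000), [6000,11000), [11000,16000), [16000,21000),
    #: [21000,26000) a.u. — calibrated so a control cohort reproduces the
    #: ~40/30/20/10/<1 % quintile distribution
    intensity_bin_edges: tuple[float, ...] = (1000.0, 6000.0, 11000.0, 16000.0, 21000.0, 26000.0)
    intensity_bin_weights: tuple[float, ...] = (40.0, 30.0, 20.0, 10.0, 0.5)
    sigma_lateral_um: float = 0.7
    sigma_axial_um: float = 1.4
    min_separation_um: float = 8.0
    stripe_bias: float = 0.8  # fraction of puncta placed proportional to the stripe field
    #: the intensity mixture is specified in *measured* (shading-corrected)
    #: units; rendered emission is boosted by this factor to offset the
    #: ~4% of blob flux outside the measurement ellipsoid and the partial
    #: baseline clamping of dim rim voxels (1 / (0.956 × 0.96))
    detection_compensation: float = 1.09


@dataclass
class NoiseParams:
    """Confocal noise model: Poisson shot noise on the vignetted signal
    (``poisson_gain`` photons per a.u.; None or 0 disables it), additive
    Gaussian read noise, and a constant detector baseline offset."""

    poisson_gain: float | None = 0.5
    read_noise_sd: float = 2.0
    baseline_offset: float = 10.0


@dataclass
class VignetteParams:
    """Radial multiplicative shading field in the (y, x) plane:
    ``gain(d) = min_gain + (1 − min_gain) · exp(−(d / falloff_um)²)``
    where d is the distance (µm) from ``center_um`` (default: image
    centre).  ``ff_noise_sd`` is the relative dye-level noise of a
    measured flat field."""

    min_gain: float = 0.7
    falloff_um: float = 400.0
    center_um: tuple[float, float] | None = None  # (y, x) µm
    ff_noise_sd: float = 0.005


#: genotype → multiplicative scaling of target-channel intensity
#: (1.0 = control; 0.0 = probe-null specimen used for baseline calibration)
DEFAULT_GENOTYPE_EFFECTS = {
    "control": 1.0,
    "null": 0.0,
    "fgf4mut": 0.518,
    "hes7het": 0.81,
    "fgf4mut_allelic": 0.67,
    "fgf4mut_hes7het": 0.20,
}


@dataclass
class SyntheticSpec:
    """Full description of one synthetic embryo acquisition."""

    grid_shape: tuple[int, int, int] = (48, 360, 720)
    voxel_spacing: tuple[float, float, float] = (2.5, 0.9, 0.9)
    psm_geometry: PSMGeometry = field(default_factory=PSMGeometry)
    stripe_params: StripeParams = field(default_factory=StripeParams)
    offtarget_params: OfftargetParams = field(default_factory=OfftargetParams)
    puncta_params: PunctaParams = field(default_factory=PunctaParams)
    genotype_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENOTYPE_EFFECTS))
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    vignette_params: VignetteParams = field(default_factory=VignetteParams)
    reference_intensity: float = 1000.0
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, **kwargs) -> "SyntheticSpec":
        """The standard acquisition: ≈1.2e7 voxels at (2.5, 0.9, 0.9) µm."""
        return cls(seed=seed, **kwargs)

    @classmethod
    def small(cls, seed: int = 0, **kwargs) -> "SyntheticSpec":
        """Coarser stack (same physical geometry and noise) for fast
        stripe/phase studies; the punctate channel is left empty because
        sub-voxel puncta are not resolvable at this pitch."""
        spec = cls(
            grid_shape=(24, 180, 360),
            voxel_spacing=(5.0, 1.8, 1.8),
            seed=seed,
            **kwargs,
        )
        spec.puncta_params = replace(spec.puncta_params, density_per_um3=0.0)
        return spec

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError("grid shape and spacing must be positive")
        sp = self.stripe_params
        if sp.phase is not None and sp.phase not in PHASES:
            raise ValidationError(f"unknown phase {sp.phase!r}")
        if sp.stripe_count is not None:
            if sp.stripe_count == 0:
                pass  # explicit stripe-free pattern (null pattern)
            elif sp.phase is None:
                if sp.stripe_count not in (2, 3):
                    raise ValidationError("stripe count must be 0, 2 or 3")
            elif sp.stripe_count != FULL_STRIPES_PER_PHASE[sp.phase]:
                raise ValidationError(
                    f"phase {sp.phase} requires {FULL_STRIPES_PER_PHASE[sp.phase]} "
                    f"full stripes, got {sp.stripe_count}"
                )
        for name, f in self.genotype_effects.items():
            if not (0.0 <= f <= 1.5):
                raise ValidationError(f"genotype factor {name}={f} outside [0, 1.5]")
        for v in (sp.peak_intensity, sp.floor_intensity, self.reference_intensity,
                  self.offtarget_params.intensity):
            if v < 0:
                raise ValidationError("intensities must be >= 0")
        if not (0.0 < self.vignette_params.min_gain <= 1.0):
            raise ValidationError("vignette min_gain must lie in (0, 1]")


# ---------------------------------------------------------------------------
# ground truth and image containers
# ---------------------------------------------------------------------------

@dataclass
class TrueStripe:
    ap_center_um: float
    ap_fwhm_um: float
    ml_fwhm_um: float
    ml_extent_fraction: float
    amplitude: float
    kind: str  # "full" or "initiating"


@dataclass
class GroundTruth:
    """Everything the generator knows about one phantom."""

    reference_mask: Mask3D
    noiseless: dict[str, np.ndarray]
    stripes: list[TrueStripe]
    phase: str | None
    puncta_positions_um: np.ndarray  # (n, 3) in (z, y, x) µm
    puncta_sum_intensities: np.ndarray
    genotype: str
    genotype_factor: float


@dataclass
class EmbryoImage:
    """Multi-channel synthetic acquisition of one embryo."""

    channels: dict[str, VoxelGrid]
    sample_id: str
    genotype: str
    phase: str | None
    seed: int

    @property
    def spacing(self) -> tuple[float, float, float]:
        return next(iter(self.channels.values())).spacing


# ---------------------------------------------------------------------------
# field construction helpers
# ---------------------------------------------------------------------------

def _soft_box(coords: np.ndarray, lo: float, hi: float, edge: float) -> np.ndarray:
    """Smooth indicator of [lo, hi] with erf edges of scale ``edge`` µm."""
    if edge <= 0:
        return ((coords >= lo) & (coords <= hi)).astype(np.float32)
    s = edge * np.sqrt(2.0)
    return (0.5 * (erf((coords - lo) / s) - erf((coords - hi) / s))).astype(np.float32)


def _domain_fields(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Soft indicator (3D float32) and hard boolean mask of the PSM domain."""
    g = spec.psm_geometry
    z, y, x = (np.arange(n, dtype=np.float64) * s
               for n, s in zip(spec.grid_shape, spec.voxel_spacing))
    e = g.edge_smooth_um
    bz = _soft_box(z, g.dv_start_um, g.dv_start_um + g.dv_thickness_um, e)
    bx = _soft_box(x, g.ap_start_um, g.ap_end_um, e)
    half_gap = g.midline_gap_um / 2.0
    band = (_soft_box(y, g.ml_center_um - half_gap - g.band_width_um,
                      g.ml_center_um - half_gap, e)
            + _soft_box(y, g.ml_center_um + half_gap,
                        g.ml_center_um + half_gap + g.band_width_um, e))
    gapfill = _soft_box(y, g.ml_center_um - half_gap, g.ml_center_um + half_gap, e)
    merge = _soft_box(x, g.merge_start_um, g.ap_end_um + 10.0 * e, e)
    byx = np.outer(band, bx) + np.outer(gapfill, bx * merge)
    np.clip(byx, 0.0, 1.0, out=byx)
    soft = (bz[:, None, None] * byx[None, :, :]).astype(np.float32)

    in_z = (z >= g.dv_start_um) & (z <= g.dv_start_um + g.dv_thickness_um)
    in_x = (x >= g.ap_start_um) & (x <= g.ap_end_um)
    in_band = ((np.abs(np.abs(y - g.ml_center_um) - (half_gap + g.band_width_um / 2.0))
                <= g.band_width_um / 2.0))
    in_gap = np.abs(y - g.ml_center_um) < half_gap
    merged_x = x >= g.merge_start_um
    hard_yx = in_band[:, None] & in_x[None, :]
    hard_yx |= in_gap[:, None] & (in_x & merged_x)[None, :]
    hard = in_z[:, None, None] & hard_yx[None, :, :]
    return soft, hard


def _stripe_layout(spec: SyntheticSpec, phase: str | None, rng: np.random.Generator) -> list[TrueStripe]:
    """Nominal stripe set for a phase, with per-embryo jitter and a
    phase-independent total-flux normalization."""
    sp = spec.stripe_params
    g = spec.psm_geometry
    if sp.stripe_count == 0 or phase is None:
        return []
    x0, L = g.ap_start_um, g.ap_length_um
    A, wfull, wmid = sp.peak_intensity, sp.full_ml_fwhm_um, sp.midline_ml_fwhm_um
    layouts = {
        "I": [(x0 + 30.0, wfull, A, "full"),
              (x0 + 280.0, wfull, A, "full"),
              (x0 + 560.0, wmid, A, "full")],
        "II": [(x0 + 120.0, wfull, A, "full"),
               (x0 + 410.0, wfull, A, "full")],
        "III": [(x0 + 70.0, wfull, A, "full"),
                (x0 + 340.0, wfull, A, "full"),
                (x0 + 570.0, wmid, A * sp.initiating_amplitude_fraction, "initiating")],
    }
    stripes = []
    amp_jit = float(np.exp(rng.normal(0.0, sp.amplitude_jitter_cv)))
    for cx, ml_fwhm, amp, kind in layouts[phase]:
        cx = cx + float(rng.normal(0.0, sp.center_jitter_um))
        ap_fwhm = sp.ap_fwhm_um * float(np.exp(rng.normal(0.0, sp.width_jitter_cv)))
        ml_fwhm = ml_fwhm * float(np.exp(rng.normal(0.0, sp.width_jitter_cv)))
        stripes.append(TrueStripe(
            ap_center_um=cx,
            ap_fwhm_um=ap_fwhm,
            ml_fwhm_um=ml_fwhm,
            ml_extent_fraction=min(1.0, ml_fwhm / g.ml_span_um),
            amplitude=amp * amp_jit,
            kind=kind,
        ))
    # renormalize total flux (sum of A·σx·σy) to the two-full-stripe reference
    ref_flux = 2.0 * A * (sp.ap_fwhm_um / _FWHM) * (wfull / _FWHM)
    flux = sum(s.amplitude * (s.ap_fwhm_um / _FWHM) * (s.ml_fwhm_um / _FWHM) for s in stripes)
    if flux > 0:
        scale = ref_flux / flux * amp_jit
        for s in stripes:
            s.amplitude *= scale
    return sorted(stripes, key=lambda s: s.ap_center_um)


def _stripe_field_yx(spec: SyntheticSpec, stripes: list[TrueStripe]) -> np.ndarray:
    """Sum of separable Gaussian stripe bumps, as a 2D (y, x) field."""
    _, ny, nx = spec.grid_shape
    _, dy, dx = spec.voxel_spacing
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    yc = spec.psm_geometry.ml_center_um
    out = np.zeros((ny, nx), dtype=np.float64)
    for s in stripes:
        sx = s.ap_fwhm_um / _FWHM
        sy = s.ml_fwhm_um / _FWHM
        gx = np.exp(-0.5 * ((x - s.ap_center_um) / sx) ** 2)
        gy = np.exp(-0.5 * ((y - yc) / sy) ** 2)
        out += s.amplitude * np.outer(gy, gx)
    sp = spec.stripe_params
    full = [s for s in stripes if s.kind == "full"]
    if sp.trough_fill_fraction > 0 and len(full) >= 2:
        # partial failure of repression between the first two full stripes
        a, b = full[0], full[1]
        mid = 0.5 * (a.ap_center_um + b.ap_center_um)
        sx = (b.ap_center_um - a.ap_center_um) / 4.0
        sy = sp.full_ml_fwhm_um / _FWHM
        gx = np.exp(-0.5 * ((x - mid) / sx) ** 2)
        gy = np.exp(-0.5 * ((y - yc) / sy) ** 2)
        amp = sp.trough_fill_fraction * 0.5 * (a.amplitude + b.amplitude)
        out += amp * np.outer(gy, gx)
    return out.astype(np.float32)


def _offtarget_field(spec: SyntheticSpec, soft_domain: np.ndarray) -> np.ndarray | None:
    """Neural-ectoderm-like midline expression, excluded from the domain."""
    ot = spec.offtarget_params
    if ot.intensity <= 0:
        return None
    g = spec.psm_geometry
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.voxel_spacing
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    sy = ot.ml_fwhm_um / _FWHM
    gy = np.exp(-0.5 * ((y - g.ml_center_um) / sy) ** 2).astype(np.float32)
    bx = _soft_box(x, g.ap_start_um, g.ap_start_um + ot.ap_fraction * g.ap_length_um,
                   g.edge_smooth_um)
    z = np.arange(nz) * dz
    bz = _soft_box(z, g.dv_start_um, g.dv_start_um + g.dv_thickness_um, g.edge_smooth_um)
    yx = (np.float32(ot.intensity) * np.outer(gy, bx)).astype(np.float32)
    field = bz.astype(np.float32)[:, None, None] * yx[None, :, :]
    field *= np.float32(1.0) - soft_domain
    return field


def vignette_field(spec: SyntheticSpec) -> np.ndarray:
    """Analytic multiplicative shading gain as a 2D (y, x) array."""
    vp = spec.vignette_params
    _, ny, nx = spec.grid_shape
    _, dy, dx = spec.voxel_spacing
    if vp.center_um is None:
        cy, cx = (ny - 1) * dy / 2.0, (nx - 1) * dx / 2.0
    else:
        cy, cx = vp.center_um
    y = np.arange(ny) * dy - cy
    x = np.arange(nx) * dx - cx
    d2 = y[:, None] ** 2 + x[None, :] ** 2
    gain = vp.min_gain + (1.0 - vp.min_gain) * np.exp(-d2 / vp.falloff_um**2)
    return gain.astype(np.float32)


def _apply_noise(field: np.ndarray, gain2d: np.ndarray, noise: NoiseParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Vignette, shot noise, read noise and baseline, clipped at zero.

    Shot noise is sampled exactly (Poisson) for dim voxels and by its
    Gaussian limit for photon counts >= 25, where the approximation error
    is negligible; read noise is folded into the same normal draw.
    """
    signal = (field * gain2d[None, :, :]).astype(np.float32, copy=False)
    sd_r = noise.read_noise_sd
    if noise.poisson_gain:
        g = np.float32(noise.poisson_gain)
        lam = signal * g  # expected photon count per voxel
        small = lam < np.float32(25.0)
        # shot variance in a.u.² is lam/g² = signal/g (Gaussian branch only)
        var = np.where(small, np.float32(0.0), signal / g) + np.float32(sd_r**2)
        out = signal + rng.standard_normal(signal.shape, dtype=np.float32) * np.sqrt(var)
        idx = np.flatnonzero(small & (lam > 0))
        if idx.size:
            flat_out, flat_lam, flat_sig = out.ravel(), lam.ravel(), signal.ravel()
            draws = rng.poisson(flat_lam[idx].astype(np.float64)).astype(np.float32) / g
            flat_out[idx] += draws - flat_sig[idx]
        signal = out
    elif sd_r > 0:
        signal = signal + np.float32(sd_r) * rng.standard_normal(signal.shape, dtype=np.float32)
    signal = signal + np.float32(noise.baseline_offset)
    return np.maximum(signal, np.float32(0.0))


def _sample_puncta(spec: SyntheticSpec, hard_mask: np.ndarray,
                   stripe_yx: np.ndarray, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample punctum centres inside the hard domain, biased
    toward the stripe field, with an anisotropy-scaled minimum separation."""
    pp = spec.puncta_params
    g = spec.psm_geometry
    voxvol = float(np.prod(spec.voxel_spacing))
    volume = float(hard_mask.sum()) * voxvol
    n_target = int(rng.poisson(pp.density_per_um3 * volume))
    if n_target == 0:
        return np.zeros((0, 3)), np.zeros(0)
    dz, dy, dx = spec.voxel_spacing
    lo = np.array([g.dv_start_um, g.ml_center_um - g.ml_span_um / 2.0, g.ap_start_um])
    hi = np.array([g.dv_start_um + g.dv_thickness_um,
                   g.ml_center_um + g.ml_span_um / 2.0, g.ap_end_um])
    smax = float(stripe_yx.max()) if stripe_yx.size else 0.0
    # z compressed by the axial/lateral PSF ratio for the separation test
    aniso = np.array([0.5, 1.0, 1.0])
    accepted: list[np.ndarray] = []
    attempts = 0
    max_attempts = 200 * n_target + 1000
    nzyx = np.array(spec.grid_shape)
    while len(accepted) < n_target and attempts < max_attempts:
        attempts += 1
        p = lo + rng.uniform(size=3) * (hi - lo)
        iz, iy, ix = (int(p[0] / dz), int(p[1] / dy), int(p[2] / dx))
        if not (0 <= iz < nzyx[0] and 0 <= iy < nzyx[1] and 0 <= ix < nzyx[2]):
            continue
        if not hard_mask[iz, iy, ix]:
            continue
        if smax > 0:
            w = (1.0 - pp.stripe_bias) + pp.stripe_bias * stripe_yx[iy, ix] / smax
            if rng.uniform() > w:
                continue
        if accepted and pp.min_separation_um > 0:
            d = (np.asarray(accepted) - p) * aniso
            if float(np.min(np.einsum("ij,ij->i", d, d))) < pp.min_separation_um**2:
                continue
        accepted.append(p)
    positions = np.asarray(accepted) if accepted else np.zeros((0, 3))
    edges = np.asarray(pp.intensity_bin_edges)
    weights = np.asarray(pp.intensity_bin_weights, dtype=np.float64)
    weights = weights / weights.sum()
    bins = rng.choice(len(weights), size=len(positions), p=weights)
    sums = edges[bins] + rng.uniform(size=len(positions)) * (edges[bins + 1] - edges[bins])
    return positions, sums


def _render_puncta(spec: SyntheticSpec, positions: np.ndarray, sums: np.ndarray) -> np.ndarray:
    """Render puncta as discrete-normalized Gaussian blobs (per-punctum
    voxel sums equal the drawn intensities exactly, before noise)."""
    field = np.zeros(spec.grid_shape, dtype=np.float32)
    if len(positions) == 0:
        return field
    pp = spec.puncta_params
    dz, dy, dx = spec.voxel_spacing
    sig_vox = np.array([pp.sigma_axial_um / dz, pp.sigma_lateral_um / dy,
                        pp.sigma_lateral_um / dx])
    half = np.maximum(1, np.ceil(4.0 * sig_vox).astype(int))
    nz, ny, nx = spec.grid_shape
    for (pz, py, px), s in zip(positions, sums):
        c = np.array([pz / dz, py / dy, px / dx])
        lo = np.maximum(0, np.floor(c).astype(int) - half)
        hi = np.minimum([nz, ny, nx], np.floor(c).astype(int) + half + 1)
        zz = np.arange(lo[0], hi[0])
        yy = np.arange(lo[1], hi[1])
        xx = np.arange(lo[2], hi[2])
        gz = np.exp(-0.5 * ((zz - c[0]) / sig_vox[0]) ** 2)
        gy = np.exp(-0.5 * ((yy - c[1]) / sig_vox[1]) ** 2)
        gx = np.exp(-0.5 * ((xx - c[2]) / sig_vox[2]) ** 2)
        blob = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        total = blob.sum()
        if total > 0:
            field[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (s / total) * blob
    return field


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_embryo(
    spec: SyntheticSpec,
    genotype: str = "control",
    sample_id: str = "sample",
) -> tuple[EmbryoImage, GroundTruth]:
    """Generate one multi-channel phantom and its ground truth.

    The target channel is ``genotype factor × (stripe field + off-target
    field)``, vignetted and noised; the punctate channel's intensities are
    scaled by the same factor.  Identical spec (including seed) and
    genotype give bit-identical output.
    """
    spec.validate()
    if genotype not in spec.genotype_effects:
        raise KeyError(f"genotype {genotype!r} not in genotype_effects")
    factor = spec.genotype_effects[genotype]
    rng = np.random.default_rng(spec.seed)

    phase = spec.stripe_params.phase
    if phase is None and spec.stripe_params.stripe_count != 0:
        phase = PHASES[rng.integers(len(PHASES))]

    soft, hard = _domain_fields(spec)
    stripes = _stripe_layout(spec, phase, rng)
    stripe_yx = _stripe_field_yx(spec, stripes)

    reference = (spec.reference_intensity * soft).astype(np.float32)
    target = soft * (np.float32(spec.stripe_params.floor_intensity) + stripe_yx[None, :, :])
    off = _offtarget_field(spec, soft)
    if off is not None:
        target = target + off
    target = (np.float32(factor) * target).astype(np.float32)

    positions, sums = _sample_puncta(spec, hard, stripe_yx, rng)
    sums = sums * factor
    # puncta sums are in shading-corrected units: pre-compensate the mean
    # vignette attenuation that survives mean-normalized flat-fielding,
    # plus the finite measurement aperture
    gain2d = vignette_field(spec)
    comp = spec.puncta_params.detection_compensation / float(gain2d.mean())
    puncta = _render_puncta(spec, positions, sums * comp)

    # truncate negligible field tails so shot-noise sampling skips them
    for arr in (reference, target, puncta):
        arr[arr < np.float32(0.05)] = np.float32(0.0)
    noiseless = {"reference": reference, "target": target, "intron_puncta": puncta}
    channels = {
        name: VoxelGrid(
            data=_apply_noise(fieldarr, gain2d, spec.noise_params, rng),
            spacing=spec.voxel_spacing,
            channel=name,
        )
        for name, fieldarr in noiseless.items()
    }
    gt = GroundTruth(
        reference_mask=Mask3D(data=hard, spacing=spec.voxel_spacing,
                              provenance={"method": "synthetic_truth"}),
        noiseless=noiseless,
        stripes=stripes,
        phase=phase,
        puncta_positions_um=positions,
        puncta_sum_intensities=sums,
        genotype=genotype,
        genotype_factor=factor,
    )
    image = EmbryoImage(channels=channels, sample_id=sample_id, genotype=genotype,
                        phase=phase, seed=spec.seed)
    return image, gt


def generate_flatfield(spec: SyntheticSpec, channel: str) -> VoxelGrid:
    """Per-channel flat-field stack: the vignette gain sampled with
    dye-level noise; values lie in (0, 1]."""
    gain = vignette_field(spec)
    seed = (int(spec.seed) * 1000003 + zlib.crc32(channel.encode())) % (2**31)
    rng = np.random.default_rng(seed)
    sd = spec.vignette_params.ff_noise_sd
    field = np.broadcast_to(gain[None, :, :], spec.grid_shape).copy()
    if sd > 0:
        field = field * (1.0 + rng.normal(0.0, sd, size=field.shape).astype(np.float32))
    field = np.clip(field, np.float32(1e-6), np.float32(1.0))
    return VoxelGrid(data=field, spacing=spec.voxel_spacing, channel=channel)


def sample_seed(base_seed: int, index: int) -> int:
    """Deterministic per-sample seed derived from a cohort base seed."""
    return int(np.random.SeedSequence(base_seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def iter_cohort(
    spec: SyntheticSpec,
    genotype_counts: dict[str, int],
    base_seed: int,
) -> Iterator[tuple[EmbryoImage, GroundTruth]]:
    """Lazily generate a cohort, one phantom at a time (memory-friendly)."""
    for gname in genotype_counts:
        if gname not in spec.genotype_effects:
            raise KeyError(f"genotype {gname!r} not in genotype_effects")
    index = 0
    for gname, n in genotype_counts.items():
        for _ in range(n):
            s = replace(spec, seed=sample_seed(base_seed, index))
            yield generate_embryo(s, genotype=gname, sample_id=f"{gname}_{index:03d}")
            index += 1


def simulate_spec_from_toml(path, seed: int = 0) -> SyntheticSpec:
    """Build a SyntheticSpec from a TOML file of overrides.

    Recognized tables mirror the spec dataclasses: ``[grid]`` (shape,
    spacing), ``[psm]``, ``[stripes]``, ``[offtarget]``, ``[puncta]``,
    ``[noise]``, ``[vignette]``, plus ``[genotypes]`` mapping genotype
    names to intensity factors.  Unspecified values keep their defaults.
    """
    import tomllib
    from pathlib import Path as _Path

    raw = tomllib.loads(_Path(path).read_text())
    spec = SyntheticSpec.default(seed=seed)
    grid = raw.get("grid", {})
    if "shape" in grid:
        spec.grid_shape = tuple(int(v) for v in grid["shape"])
    if "spacing" in grid:
        spec.voxel_spacing = tuple(float(v) for v in grid["spacing"])
    mapping = {
        "psm": ("psm_geometry", PSMGeometry),
        "stripes": ("stripe_params", StripeParams),
        "offtarget": ("offtarget_params", OfftargetParams),
        "puncta": ("puncta_params", PunctaParams),
        "noise": ("noise_params", NoiseParams),
        "vignette": ("vignette_params", VignetteParams),
    }
    for table, (attr, cls_) in mapping.items():
        if table in raw:
            setattr(spec, attr, replace(getattr(spec, attr), **raw[table]))
    if "genotypes" in raw:
        spec.genotype_effects.update({k: float(v) for k, v in raw["genotypes"].items()})
    if "reference_intensity" in raw:
        spec.reference_intensity = float(raw["reference_intensity"])
    spec.validate()
    return spec


def generate_cohort(
    spec: SyntheticSpec,
    genotype_counts: dict[str, int],
    base_seed: int,
) -> tuple[list[tuple[EmbryoImage, GroundTruth]], pd.DataFrame]:
    """Generate a cohort plus its sample manifest.

    Per-sample seeds derive deterministically from ``base_seed``; the
    oscillation phase is drawn uniformly per sample unless the spec pins
    it.  Returns the list of ``(EmbryoImage, GroundTruth)`` and a manifest
    DataFrame (sample_id, genotype, phase, seed).
    """
    samples = list(iter_cohort(spec, genotype_counts, base_seed))
    manifest = pd.DataFrame(
        [
            {"sample_id": img.sample_id, "genotype": img.genotype,
             "phase": img.phase, "seed": img.seed}
            for img, _ in samples
        ]
    )
    return samples, manifest
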