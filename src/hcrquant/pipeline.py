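"""End-to-end orchestration: calibrate → mask → quantify → classify → compare.

Two entry points:

* :func:`analyze_cohort` — in-memory, streaming analysis of a synthetic
  cohort (phantoms are generated, measured and discarded one at a time);
* :func:`run_pipeline` — file-based analysis driven by a
  :class:`PipelineConfig` and a sample manifest CSV, writing all
  intermediates and result tables.

Per sample the pipeline applies flat-field shading correction, subtracts
the per-probe calibrated baseline, builds the reference-channel mask by
volume-targeted automatic thresholding, quantifies target intensity
density within the mask, and optionally runs spot models and oscillation-
phase classification.  Group statistics are mean ± s.e.m., pooled
Student's t-tests against the control genotype, and percent-of-control
ratios.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (BaselineCutoff, calibrate_baseline, read_stack,
                          shading_correct, subtract_baseline, write_stack)
from .grids import VoxelGrid
from .masking import MaskingConfig, auto_threshold_to_volume, masked_intensity_density
from .phase import StripeDetectParams, call_phase
from .spots import (SpotBinningScheme, SpotDetectParams, SpotSet, bin_spots,
                    detect_spots, quintile_distribution)
from .stats import CohortResult, compare_cohort
from .synthetic import (EmbryoImage, GroundTruth, SyntheticSpec, generate_embryo,
                        generate_flatfield, iter_cohort, sample_seed)

logger = logging.getLogger("hcrquant")

NULL_GENOTYPE = "null"


@dataclass
class PipelineConfig:
    """All pipeline parameters in one place.

    ``channel_roles`` maps the roles the pipeline needs (reference,
    target, puncta) to channel names in the input files.  Baseline
    cutoffs may be pinned per channel in ``baseline_cutoffs``; channels
    without a pinned cutoff are calibrated from probe-null samples.
    """

    channel_roles: dict[str, str] = field(default_factory=lambda: {
        "reference": "reference", "target": "target", "puncta": "intron_puncta"})
    masking: MaskingConfig = field(default_factory=MaskingConfig)
    spot_params: SpotDetectParams = field(default_factory=SpotDetectParams)
    binning: SpotBinningScheme = field(default_factory=SpotBinningScheme)
    stripe_params: StripeDetectParams = field(default_factory=StripeDetectParams)
    baseline_tolerance: float = 1e-4
    baseline_cutoffs: dict[str, float] = field(default_factory=dict)
    control_genotype: str = "control"
    include_spots: bool = False
    include_phase: bool = False
    manifest_path: str | None = None
    flatfield_paths: dict[str, str] = field(default_factory=dict)
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        cfg = cls()
        if "channels" in raw:
            cfg.channel_roles.update(raw["channels"])
        if "masking" in raw:
            m = raw["masking"]
            cfg.masking = MaskingConfig(
                smoothing_scale_um=m.get("smoothing_scale_um", 3.0),
                volume_window_um3=tuple(m.get("volume_window_um3", (9.0e6, 1.1e7))),
                min_component_um3=m.get("min_component_um3", 1000.0),
            )
        if "spots" in raw:
            s = dict(raw["spots"])
            bins = s.pop("bins", None)
            cfg.spot_params = SpotDetectParams(**s)
            if bins:
                cfg.binning = SpotBinningScheme(edges=tuple(bins["edges"]),
                                                labels=tuple(bins["labels"]))
        if "stripes" in raw:
            cfg.stripe_params = StripeDetectParams(**raw["stripes"])
        if "baseline" in raw:
            cfg.baseline_tolerance = raw["baseline"].get("tolerance", 1e-4)
            cfg.baseline_cutoffs = dict(raw["baseline"].get("cutoffs", {}))
        if "cohort" in raw:
            cfg.control_genotype = raw["cohort"].get("control", "control")
            cfg.manifest_path = raw["cohort"].get("manifest")
            cfg.include_spots = raw["cohort"].get("include_spots", False)
            cfg.include_phase = raw["cohort"].get("include_phase", False)
        if "flatfields" in raw:
            cfg.flatfield_paths = dict(raw["flatfields"])
        if "output" in raw:
            cfg.output_dir = raw["output"].get("dir")
            cfg.seed = raw["output"].get("seed", 0)
        return cfg


# ---------------------------------------------------------------------------
# per-sample processing
# ---------------------------------------------------------------------------

def process_sample(
    channels: dict[str, VoxelGrid],
    flatfields: dict[str, VoxelGrid],
    cutoffs: dict[str, BaselineCutoff | float],
    config: PipelineConfig,
    sample_id: str = "",
) -> dict:
    """Run the per-sample stages; returns a flat record of measurements."""
    roles = config.channel_roles
    ref_name, tgt_name = roles["reference"], roles["target"]
    if ref_name not in channels or tgt_name not in channels:
        raise KeyError(f"sample {sample_id}: channels {ref_name!r}/{tgt_name!r} missing")

    def corrected(name: str) -> VoxelGrid:
        g = channels[name]
        if name in flatfields:
            g = shading_correct(g, flatfields[name])
        if name in cutoffs:
            g = subtract_baseline(g, cutoffs[name])
        return g

    ref = corrected(ref_name)
    target = corrected(tgt_name)
    threshold, mask = auto_threshold_to_volume(ref, config.masking)
    measure = masked_intensity_density(target, mask, sample_id=sample_id,
                                       mask_gene=ref_name)
    record = {
        "sample_id": sample_id,
        "mask_threshold": threshold,
        "mask_volume_um3": mask.volume_um3,
        "intensity_sum": measure.intensity_sum,
        "density": measure.density,
    }
    if config.include_phase:
        phase_call, stripe_set = call_phase(target, mask, config.stripe_params)
        record["phase_called"] = phase_call.phase
        record["n_stripes"] = len(stripe_set)
    if config.include_spots:
        pnc_name = roles.get("puncta")
        if pnc_name and pnc_name in channels:
            puncta = corrected(pnc_name)
            spots = detect_spots(puncta, config.spot_params, mask=mask)
            spots = bin_spots(spots, config.binning)
            record["n_spots"] = len(spots)
            if len(spots):
                try:
                    dist = quintile_distribution(spots)
                    for lb in config.binning.labels:
                        record[f"bin_{lb}_pct"] = float(dist[lb])
                except ValueError:
                    pass
    return record


# ---------------------------------------------------------------------------
# in-memory synthetic-cohort analysis
# ---------------------------------------------------------------------------

def calibrate_from_null(
    spec: SyntheticSpec,
    flatfields: dict[str, VoxelGrid],
    config: PipelineConfig,
    base_seed: int,
) -> dict[str, BaselineCutoff]:
    """Calibrate target/puncta baselines from a probe-null phantom.

    The null specimen (genotype factor 0) carries no probe signal, so the
    entire corrected stack serves as the negative reference; the cutoff is
    the smallest value leaving at most ``baseline_tolerance`` of its
    voxels positive.
    """
    null_spec = replace(spec, seed=sample_seed(base_seed, 999_983))
    image, _ = generate_embryo(null_spec, genotype=NULL_GENOTYPE, sample_id="null_calib")
    cutoffs: dict[str, BaselineCutoff] = {}
    for role in ("target", "puncta"):
        name = config.channel_roles.get(role)
        if not name or name not in image.channels:
            continue
        g = image.channels[name]
        if name in flatfields:
            g = shading_correct(g, flatfields[name])
        cutoffs[name] = calibrate_baseline(g, negative_region=None,
                                           tolerance=config.baseline_tolerance,
                                           channel=name)
    return cutoffs


def analyze_cohort(
    spec: SyntheticSpec,
    genotype_counts: dict[str, int],
    base_seed: int,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, CohortResult]:
    """Generate and quantify a synthetic cohort, streaming one sample at
    a time; returns the per-sample table and the cohort statistics."""
    config = config or PipelineConfig()
    flatfields = {
        name: generate_flatfield(replace(spec, seed=sample_seed(base_seed, 999_979)), name)
        for name in config.channel_roles.values()
    }
    cutoffs = dict(config.baseline_cutoffs)
    if not cutoffs:
        cutoffs = calibrate_from_null(spec, flatfields, config, base_seed)
    records = []
    for image, gt in iter_cohort(spec, genotype_counts, base_seed):
        rec = process_sample(image.channels, flatfields, cutoffs, config,
                             sample_id=image.sample_id)
        rec.update({"genotype": image.genotype, "phase_true": image.phase,
                    "seed": image.seed, "genotype_factor": gt.genotype_factor})
        records.append(rec)
        logger.info("processed %s: density=%.3f volume=%.3g",
                    image.sample_id, rec["density"], rec["mask_volume_um3"])
    table = pd.DataFrame(records)
    densities = {g: sub["density"].tolist() for g, sub in table.groupby("genotype")}
    result = compare_cohort(densities, control=config.control_genotype)
    return table, result


def pooled_spot_distribution(
    spec: SyntheticSpec,
    n_samples: int,
    base_seed: int,
    config: PipelineConfig | None = None,
    genotype: str = "control",
) -> pd.Series:
    """Spot-bin percentages pooled over a cohort of phantoms.

    Runs shading correction, baseline subtraction, reference masking and
    masked spot detection per sample, pools all binned spots, and returns
    the percentage of spots per intensity bin.
    """
    config = config or PipelineConfig()
    roles = config.channel_roles
    flatfields = {
        name: generate_flatfield(replace(spec, seed=sample_seed(base_seed, 999_979)), name)
        for name in roles.values()
    }
    cutoffs = dict(config.baseline_cutoffs)
    if not cutoffs:
        cutoffs = calibrate_from_null(spec, flatfields, config, base_seed)
    tables = []
    for image, _gt in iter_cohort(spec, {genotype: n_samples}, base_seed):
        puncta = image.channels[roles["puncta"]]
        puncta = shading_correct(puncta, flatfields[roles["puncta"]])
        if roles["puncta"] in cutoffs:
            puncta = subtract_baseline(puncta, cutoffs[roles["puncta"]])
        ref = shading_correct(image.channels[roles["reference"]],
                              flatfields[roles["reference"]])
        _, mask = auto_threshold_to_volume(ref, config.masking)
        spots = detect_spots(puncta, config.spot_params, mask=mask)
        spots = bin_spots(spots, config.binning)
        tables.append(spots.table)
    pooled = SpotSet(table=pd.concat(tables, ignore_index=True),
                     params=config.spot_params, scheme=config.binning)
    return quintile_distribution(pooled)


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------

def simulate_cohort_to_dir(
    spec: SyntheticSpec,
    genotype_counts: dict[str, int],
    base_seed: int,
    outdir: str | Path,
) -> Path:
    """Write a synthetic cohort to disk: one multi-channel OME-TIFF and a
    ground-truth JSON sidecar per sample, per-channel flat-field stacks,
    and a CSV manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ff_spec = replace(spec, seed=sample_seed(base_seed, 999_979))
    ff_paths = {}
    for name in ("reference", "target", "intron_puncta"):
        ff = generate_flatfield(ff_spec, name)
        p = outdir / f"flatfield_{name}.ome.tif"
        write_stack(ff, p)
        ff_paths[name] = str(p)
    rows = []
    for image, gt in iter_cohort(spec, genotype_counts, base_seed):
        path = outdir / f"{image.sample_id}.ome.tif"
        write_stack(list(image.channels.values()), path)
        sidecar = {
            "sample_id": image.sample_id,
            "genotype": image.genotype,
            "genotype_factor": gt.genotype_factor,
            "phase": gt.phase,
            "true_volume_um3": gt.reference_mask.volume_um3,
            "stripes": [dataclasses.asdict(s) for s in gt.stripes],
            "n_puncta": int(len(gt.puncta_positions_um)),
        }
        (outdir / f"{image.sample_id}.truth.json").write_text(json.dumps(sidecar, indent=2))
        rows.append({"sample_id": image.sample_id, "genotype": image.genotype,
                     "phase": image.phase, "seed": image.seed, "path": str(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    ffmap = {"flatfields": ff_paths}
    (outdir / "flatfields.json").write_text(json.dumps(ffmap, indent=2))
    return outdir / "manifest.csv"


def run_pipeline(config: PipelineConfig) -> CohortResult:
    """File-based end-to-end run from a manifest of stacks.

    Manifest columns: ``sample_id, genotype, path`` (plus optional
    ``phase, seed``).  Samples with genotype ``"null"`` are used to
    calibrate baseline cutoffs (unless pinned in the config) and excluded
    from group statistics.  Writes a per-sample results CSV, a cohort
    JSON and a structured log to the output directory.  Fully
    deterministic for a fixed config.
    """
    if not config.manifest_path:
        raise ValueError("config.manifest_path is required")
    # keep_default_na: the literal genotype name "null" must survive parsing
    manifest = pd.read_csv(config.manifest_path, keep_default_na=False)
    if manifest.empty:
        raise ValueError("manifest is empty: nothing to analyze")
    for col in ("sample_id", "genotype", "path"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    outdir = Path(config.output_dir or ".")
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("pipeline config: %s", json.dumps(_config_dict(config), default=str))
        flatfields: dict[str, VoxelGrid] = {}
        for name, p in config.flatfield_paths.items():
            ff = read_stack(p)
            flatfields[name] = ff if isinstance(ff, VoxelGrid) else ff[0]

        def load_channels(path: str) -> dict[str, VoxelGrid]:
            grids = read_stack(path)
            if isinstance(grids, VoxelGrid):
                return {grids.channel or "ch0": grids}
            return {g.channel: g for g in grids}

        cutoffs: dict[str, BaselineCutoff | float] = dict(config.baseline_cutoffs)
        null_rows = manifest[manifest["genotype"] == NULL_GENOTYPE]
        if not cutoffs and not null_rows.empty:
            pooled: dict[str, list[VoxelGrid]] = {}
            for _, row in null_rows.iterrows():
                chans = load_channels(row["path"])
                for role in ("target", "puncta"):
                    name = config.channel_roles.get(role)
                    if name and name in chans:
                        g = chans[name]
                        if name in flatfields:
                            g = shading_correct(g, flatfields[name])
                        pooled.setdefault(name, []).append(g)
            for name, grids in pooled.items():
                cutoffs[name] = calibrate_baseline(
                    grids, negative_region=None,
                    tolerance=config.baseline_tolerance, channel=name)
                logger.info("calibrated baseline %s: cutoff=%.3f", name,
                            cutoffs[name].cutoff)
                cutoffs[name].to_json(outdir / f"baseline_{name}.json")

        records = []
        for _, row in manifest.iterrows():
            if row["genotype"] == NULL_GENOTYPE:
                continue
            sid = str(row["sample_id"])
            try:
                chans = load_channels(row["path"])
                rec = process_sample(chans, flatfields, cutoffs, config, sample_id=sid)
            except Exception as exc:
                raise RuntimeError(f"stage failure for sample {sid!r}: {exc}") from exc
            rec["genotype"] = row["genotype"]
            if "phase" in manifest.columns:
                rec["phase_true"] = row["phase"]
            records.append(rec)
            (outdir / f"{sid}.result.json").write_text(json.dumps(rec, indent=2, default=float))
            logger.info("processed %s: density=%.3f", sid, rec["density"])

        table = pd.DataFrame(records)
        table.to_csv(outdir / "results.csv", index=False)
        densities = {g: sub["density"].tolist() for g, sub in table.groupby("genotype")}
        result = compare_cohort(densities, control=config.control_genotype)
        result.to_json(outdir / "cohort_result.json")
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()


def _config_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)
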