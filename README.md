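# hcrquant

Volumetric quantification of whole-mount HCR fluorescence in 3D confocal
stacks, built for the kind of question that comes up in mouse
somitogenesis work: *how much of a gene's mRNA is expressed specifically
inside the presomitic mesoderm (PSM), and how does that change across
genotypes?*  Because HCR signal is proportional to transcript count,
careful image calibration plus a marker-defined tissue volume turns
whole-mount stacks into quantitative, per-embryo expression measures —
without sectioning or dissociation.

The package re-implements the full measurement chain as an open,
scriptable library:

* **Calibration** — flat-field shading correction from dye-solution
  images (`out = in × mean(ff)/ff`) and per-probe baseline subtraction
  with a cutoff calibrated on negative references (non-expressing
  tissue, or probe-null embryos).
* **Volumetric masking** — a tissue model built from a marker channel
  (e.g. *Tbx6* for the PSM): Gaussian smoothing at a 3 µm detail scale,
  absolute-intensity thresholding with an automatic search that lands
  the mask volume in a target window (default 9.0 × 10⁶ – 1.1 × 10⁷ µm³),
  and polygon-ROI interpolation across z-planes for manual annotation.
* **Intensity density** — the expression measure: intensity sum within
  the mask ÷ mask volume, in a.u./µm³.
* **Spot models** — punctate signal as 4 µm (lateral) × 8 µm (axial)
  ellipsoidal spots with local-background-subtracted sum intensities,
  fixed five-bin intensity classes (1000/6000/11000/16000/21000 a.u.)
  and linear heat-map colors.
* **Oscillation phase** — detection of the PSM's 2–3 transverse
  expression stripes from anteroposterior profiles and classification
  into segmentation-clock phases I/II/III by stripe count, mediolateral
  extent and boundary contact.
* **Cohort statistics** — mean ± s.e.m., pooled two-tailed Student
  t-tests, percent-of-control expression ratios, per-bin spot
  comparisons.
* **Synthetic phantoms** — a first-class generator of 3D multi-channel
  embryo images (PSM-shaped reference domain, striped target channel,
  nascent-transcription puncta, genotype scaling, vignetting, confocal
  noise) with exact ground truth, so the entire chain is testable end
  to end.  See `docs/methods.md` for the model.

## Worked example

Generate a small synthetic cohort (3 control embryos, 3 mutants carrying
a 0.518× expression factor) and run the full pipeline — shading
correction, baseline calibration from a probe-null phantom, reference
masking, masked density, group statistics:

```python
from hcrquant import SyntheticSpec, analyze_cohort

spec = SyntheticSpec.small(seed=0)
table, result = analyze_cohort(spec, {"control": 3, "fgf4mut": 3}, base_seed=1)
print(table[["sample_id", "genotype", "phase_true", "mask_volume_um3", "density"]]
      .round(3).to_string(index=False))

ctl, mut = result.groups["control"], result.groups["fgf4mut"]
cmp = result.comparisons["fgf4mut"]
print(f"control: {ctl.mean:.2f} ± {ctl.sem:.2f} a.u./µm³ (n={ctl.n})")
print(f"mutant:  {mut.mean:.2f} ± {mut.sem:.2f} a.u./µm³ (n={mut.n})")
print(f"mutant expression: {cmp['percent_of_control']:.1f}% of control "
      f"(t={cmp['t']:.2f}, p={cmp['p']:.2g})")
```

Output:

```
  sample_id genotype phase_true  mask_volume_um3  density
control_000  control          I        9000007.2   22.834
control_001  control          I        9000007.2   22.209
control_002  control          I        9000007.2   22.942
fgf4mut_003  fgf4mut         II        9000007.2   11.030
fgf4mut_004  fgf4mut        III        9000007.2   10.971
fgf4mut_005  fgf4mut         II        9000007.2   11.059
control: 22.66 ± 0.23 a.u./µm³ (n=3)
mutant:  11.02 ± 0.03 a.u./µm³ (n=3)
mutant expression: 48.6% of control (t=-50.65, p=9.1e-07)
```

Each row is one embryo: the mask volume landed by the automatic
threshold search (just above the window's 9.0 × 10⁶ µm³ lower bound),
the PSM-specific target-gene density, and the oscillation phase the
phantom was generated in.  The mutant cohort recovers roughly half of
control expression, as configured (the small residual deviation from
51.8% is baseline-subtraction bias plus cohort sampling noise —
`docs/methods.md` discusses both).

A command-line interface mirrors the library
(`hcrquant simulate | correct | calibrate-baseline | mask | quantify |
spots | phase | run-all`), driven by TOML configs and CSV manifests.

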