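"""The phantom generator: determinism, ground-truth consistency, scaling."""

from dataclasses import replace

import numpy as np
import pytest

from hcrquant.synthetic import (DEFAULT_GENOTYPE_EFFECTS, SyntheticSpec,
                                ValidationError, generate_cohort,
                                generate_embryo, generate_flatfield,
                                vignette_field)


def noise_free(spec):
    spec.noise_params = replace(spec.noise_params, poisson_gain=None,
                                read_noise_sd=0.0, baseline_offset=0.0)
    spec.vignette_params = replace(spec.vignette_params, min_gain=1.0,
                                   ff_noise_sd=0.0)
    return spec


class TestGenerateEmbryo:
    def test_null_pattern_gives_all_zero_target(self):
        spec = noise_free(SyntheticSpec.small())
        spec.stripe_params = replace(spec.stripe_params, stripe_count=0,
                                     peak_intensity=0.0, floor_intensity=0.0)
        spec.offtarget_params = replace(spec.offtarget_params, intensity=0.0)
        img, _ = generate_embryo(spec)
        assert not img.channels["target"].data.any()

    def test_phase_one_has_three_stripes(self):
        spec = SyntheticSpec.small()
        spec.stripe_params = replace(spec.stripe_params, phase="I")
        _, gt = generate_embryo(spec)
        assert len(gt.stripes) == 3
        assert all(s.kind == "full" for s in gt.stripes)

    def test_bit_identical_for_same_spec_and_seed(self):
        a, _ = generate_embryo(SyntheticSpec.small(seed=7))
        b, _ = generate_embryo(SyntheticSpec.small(seed=7))
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name].data,
                                          b.channels[name].data)

    def test_invalid_phase_stripe_combination_rejected(self):
        spec = SyntheticSpec.small()
        spec.stripe_params = replace(spec.stripe_params, phase="I", stripe_count=2)
        with pytest.raises(ValidationError, match="phase I"):
            generate_embryo(spec)

    def test_unknown_genotype_rejected(self):
        with pytest.raises(KeyError):
            generate_embryo(SyntheticSpec.small(), genotype="nonexistent")

    def test_default_true_volume_in_expected_window(self):
        spec = SyntheticSpec.default()
        assert 9.0e6 <= spec.psm_geometry.true_volume_um3() <= 1.1e7
        # voxelized truth mask agrees (coarse small grid, same geometry)
        _, gt = generate_embryo(SyntheticSpec.small())
        assert 9.0e6 <= gt.reference_mask.volume_um3 <= 1.1e7

    def test_ground_truth_shapes_and_puncta_bounds(self):
        spec = SyntheticSpec.default(seed=3)
        img, gt = generate_embryo(spec)
        for name, arr in gt.noiseless.items():
            assert arr.shape == spec.grid_shape
            assert img.channels[name].data.shape == spec.grid_shape
        extent = np.array(spec.grid_shape) * np.array(spec.voxel_spacing)
        assert np.all(gt.puncta_positions_um >= 0)
        assert np.all(gt.puncta_positions_um <= extent)
        # all puncta lie inside the true reference domain
        idx = (gt.puncta_positions_um / np.array(spec.voxel_spacing)).astype(int)
        assert gt.reference_mask.data[tuple(idx.T)].all()

    def test_noiseless_target_scales_linearly_with_genotype_factor(self):
        spec = noise_free(SyntheticSpec.small(seed=5))
        _, gt_ctl = generate_embryo(spec, genotype="control")
        _, gt_mut = generate_embryo(spec, genotype="fgf4mut")
        m = gt_ctl.reference_mask.data
        ratio = gt_mut.noiseless["target"][m].sum() / gt_ctl.noiseless["target"][m].sum()
        assert ratio == pytest.approx(0.518, rel=1e-5)

    def test_phase_one_ground_truth_geometry(self):
        g = SyntheticSpec.small().psm_geometry
        for seed in range(5):
            spec = SyntheticSpec.small(seed=seed)
            spec.stripe_params = replace(spec.stripe_params, phase="I")
            _, gt = generate_embryo(spec)
            anterior, posterior = gt.stripes[0], gt.stripes[-1]
            # anterior stripe touches the anterior boundary (within 5% of AP length)
            edge = anterior.ap_center_um - anterior.ap_fwhm_um / 2.0
            assert edge <= g.ap_start_um + 0.05 * g.ap_length_um
            # posterior stripe is midline-limited
            assert posterior.ml_extent_fraction <= 0.4


class TestGenerateFlatfield:
    def test_unit_gain_gives_unit_field(self):
        spec = SyntheticSpec.small()
        spec.vignette_params = replace(spec.vignette_params, min_gain=1.0,
                                       ff_noise_sd=0.0)
        ff = generate_flatfield(spec, "target")
        np.testing.assert_array_equal(ff.data, np.ones(spec.grid_shape, np.float32))

    def test_radial_falloff_center_brighter_than_edge(self):
        spec = SyntheticSpec.small()
        spec.vignette_params = replace(spec.vignette_params, min_gain=0.5)
        ff = generate_flatfield(spec, "target")
        nz, ny, nx = spec.grid_shape
        assert ff.data[0, ny // 2, nx // 2] > ff.data[0, 0, 0]
        assert np.all(ff.data > 0) and np.all(ff.data <= 1.0)

    def test_noiseless_field_matches_analytic_falloff_formula(self):
        spec = SyntheticSpec.small()
        spec.vignette_params = replace(spec.vignette_params, min_gain=0.6,
                                       falloff_um=300.0, ff_noise_sd=0.0)
        ff = generate_flatfield(spec, "target")
        vp = spec.vignette_params
        _, dy, dx = spec.voxel_spacing
        _, ny, nx = spec.grid_shape
        cy, cx = (ny - 1) * dy / 2.0, (nx - 1) * dx / 2.0
        for (z, y, x) in [(0, 0, 0), (3, 50, 100), (10, 90, 180), (5, 10, 300), (0, 179, 359)]:
            d2 = (y * dy - cy) ** 2 + (x * dx - cx) ** 2
            expected = vp.min_gain + (1 - vp.min_gain) * np.exp(-d2 / vp.falloff_um**2)
            assert ff.data[z, y, x] == pytest.approx(expected, rel=1e-5)

    def test_channels_get_independent_dye_noise(self):
        spec = SyntheticSpec.small()
        a = generate_flatfield(spec, "target")
        b = generate_flatfield(spec, "reference")
        assert not np.array_equal(a.data, b.data)


class TestGenerateCohort:
    def test_counts_and_factors(self):
        samples, manifest = generate_cohort(SyntheticSpec.small(), {"control": 3},
                                            base_seed=11)
        assert len(samples) == 3
        assert all(gt.genotype_factor == 1.0 for _, gt in samples)
        assert list(manifest["genotype"]) == ["control"] * 3

    def test_unknown_genotype_errors(self):
        with pytest.raises(KeyError):
            generate_cohort(SyntheticSpec.small(), {"mystery": 2}, base_seed=0)

    def test_noiseless_cohort_mean_ratio_matches_factor(self):
        spec = noise_free(SyntheticSpec.small())
        samples, manifest = generate_cohort(
            spec, {"control": 8, "fgf4mut": 8}, base_seed=2)
        means = {"control": [], "fgf4mut": []}
        for img, gt in samples:
            m = gt.reference_mask.data
            means[img.genotype].append(gt.noiseless["target"][m].mean())
        ratio = np.mean(means["fgf4mut"]) / np.mean(means["control"])
        assert ratio == pytest.approx(0.518, rel=0.01)

    def test_reproducible_manifest_and_stacks(self):
        s1, m1 = generate_cohort(SyntheticSpec.small(), {"control": 2}, base_seed=9)
        s2, m2 = generate_cohort(SyntheticSpec.small(), {"control": 2}, base_seed=9)
        assert m1.equals(m2)
        np.testing.assert_array_equal(s1[0][0].channels["target"].data,
                                      s2[0][0].channels["target"].data)

    def test_phases_drawn_from_all_three(self):
        _, manifest = generate_cohort(SyntheticSpec.small(), {"control": 12},
                                      base_seed=4)
        assert set(manifest["phase"]) <= {"I", "II", "III"}
        assert len(set(manifest["phase"])) >= 2


class TestSpecValidation:
    def test_default_genotype_factors_match_reported_reductions(self):
        eff = DEFAULT_GENOTYPE_EFFECTS
        assert eff["fgf4mut"] == 0.518
        assert eff["hes7het"] == pytest.approx(1 - 0.19)
        assert eff["fgf4mut_allelic"] == pytest.approx(1 - 0.33)
        assert eff["fgf4mut_hes7het"] == pytest.approx(1 - 0.80)

    def test_out_of_range_genotype_factor_rejected(self):
        spec = SyntheticSpec.small()
        spec.genotype_effects["huge"] = 2.0
        with pytest.raises(ValidationError):
            spec.validate()

    def test_vignette_field_bounds(self):
        spec = SyntheticSpec.small()
        gain = vignette_field(spec)
        assert gain.min() >= spec.vignette_params.min_gain - 1e-6
        assert gain.max() <= 1.0 + 1e-6
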