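"""Synthetic cohort generator: calibration, determinism, effect structure."""

import dataclasses

import numpy as np
import pytest

from brixflow.cohort import (
    AcquisitionProtocol,
    CohortDesign,
    GroupSpec,
    HypoxiaCoupling,
    ParameterField,
    default_design,
    generate_parameter_maps,
    simulate_dce,
    simulate_growth,
    simulate_hypoxic_fraction,
)
from brixflow.growth import relative_volume
from brixflow.kinetics import fit_roi
from brixflow.model import brix_rsi
from brixflow.stats import pearson


def flat_fields():
    return {
        "A": ParameterField(1.2, 0.0, 0.0),
        "k_ep": ParameterField(3.0, 0.0, 0.0),
        "k_el": ParameterField(0.25, 0.0, 0.0),
    }


class TestParameterMaps:
    def test_identity_effect_zero_variance_identical_maps(self):
        design = CohortDesign(
            groups=(GroupSpec("G", 1, 1.0, 1.0),),
            seed=0,
            parameter_fields=flat_fields(),
        )
        pre = generate_parameter_maps(design, 0, 0, "pre")
        post = generate_parameter_maps(design, 0, 0, "post")
        np.testing.assert_array_equal(pre.A, post.A)
        np.testing.assert_array_equal(pre.k_el, post.k_el)

    def test_mean_ratio_equals_multiplier(self):
        """In-ROI mean post/pre ratio calibrates exactly to the A-multiplier."""
        design = CohortDesign(groups=(GroupSpec("RT", 1, 1.29, 0.73),), seed=4)
        pre = generate_parameter_maps(design, 0, 0, "pre")
        post = generate_parameter_maps(design, 0, 0, "post")
        mask = pre.roi_mask
        assert int(mask.sum()) > 350  # default ROI is ~400 voxels
        ratio_a = post.A[mask].mean() / pre.A[mask].mean()
        ratio_kel = post.k_el[mask].mean() / pre.k_el[mask].mean()
        assert ratio_a == pytest.approx(1.29, rel=0.02)
        assert ratio_kel == pytest.approx(0.73, rel=0.02)
        # k_ep untouched by treatment
        np.testing.assert_array_equal(pre.k_ep, post.k_ep)

    def test_positive_fields_inside_roi(self):
        design = default_design(seed=9)
        truth = generate_parameter_maps(design, 2, 3, "post")
        for fld in (truth.A, truth.k_ep, truth.k_el):
            assert np.all(fld[truth.roi_mask] > 0)

    def test_empty_roi_rejected(self):
        design = CohortDesign(
            groups=(GroupSpec("G", 1),), seed=0, roi_semi_axes=(0.01, 0.01)
        )
        with pytest.raises(ValueError):
            generate_parameter_maps(design, 0, 0, "pre")

    def test_non_positive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("G", 1, a_effect=0.0)
        with pytest.raises(ValueError):
            GroupSpec("G", 1, kel_effect=-1.0)


class TestSimulateDCE:
    def _noiseless_design(self):
        return CohortDesign(
            groups=(GroupSpec("G", 1),),
            seed=0,
            noise_sd=0.0,
            grid_size=12,
            roi_semi_axes=(4.2, 3.4),
            parameter_fields=flat_fields(),
        )

    def test_baseline_frames_carry_no_enhancement(self):
        design = self._noiseless_design()
        truth = generate_parameter_maps(design, 0, 0, "pre")
        series = simulate_dce(truth, design, 1)
        nb = series.n_baseline_frames
        assert np.all(series.frame_times[:nb] <= 0)
        np.testing.assert_array_equal(series.signal[:, :, :nb], design.baseline_signal)

    def test_known_voxel_value(self):
        """Forward signal equals baseline * (1 + Brix RSI) at every frame."""
        design = self._noiseless_design()
        truth = generate_parameter_maps(design, 0, 0, "pre")
        series = simulate_dce(truth, design, 1)
        r, c = map(lambda v: v[0], np.nonzero(truth.roi_mask))
        t = series.frame_times[series.n_baseline_frames :]
        expected = design.baseline_signal * (1 + brix_rsi(t, 1.2, 3.0, 0.25))
        np.testing.assert_allclose(series.signal[r, c, series.n_baseline_frames :], expected)

    def test_same_seed_bit_identical(self):
        design = dataclasses.replace(self._noiseless_design(), noise_sd=0.05)
        truth = generate_parameter_maps(design, 0, 0, "pre")
        s1 = simulate_dce(truth, design, 77)
        s2 = simulate_dce(truth, design, 77)
        np.testing.assert_array_equal(s1.signal, s2.signal)
        s3 = simulate_dce(truth, design, 78)
        assert not np.array_equal(s1.signal, s3.signal)

    def test_noiseless_fit_recovers_ground_truth(self):
        """End-to-end: fitting a zero-noise simulated ROI returns the truth."""
        design = dataclasses.replace(
            self._noiseless_design(),
            parameter_fields={
                "A": ParameterField(1.2, 0.15, 0.12),
                "k_ep": ParameterField(3.0, 0.20, 0.15),
                "k_el": ParameterField(0.25, 0.15, 0.12),
            },
        )
        truth = generate_parameter_maps(design, 0, 0, "pre")
        series = simulate_dce(truth, design, 5, actual_injection_duration_s=7.0)
        pmap = fit_roi(series)
        mask = truth.roi_mask
        for fitted, true in ((pmap.A, truth.A), (pmap.k_ep, truth.k_ep), (pmap.k_el, truth.k_el)):
            rel_err = np.abs(fitted[mask] - true[mask]) / true[mask]
            assert np.max(rel_err) < 1e-4


class TestSimulateGrowth:
    def test_zero_modifier_freezes_volume(self):
        design = CohortDesign(
            groups=(GroupSpec("frozen", 3, growth_modifier=0.0),),
            seed=0,
            caliper_noise_sd_mm=0.0,
            growth_rate_cv=0.0,
        )
        for rec in simulate_growth(design, 1):
            v = rec.volumes()
            np.testing.assert_allclose(v, v[0])

    def test_mean_relative_volume_monotone_in_modifier(self):
        design = CohortDesign(
            groups=(
                GroupSpec("fast", 6, growth_modifier=1.0),
                GroupSpec("slow", 6, growth_modifier=0.4),
            ),
            seed=0,
            caliper_noise_sd_mm=0.0,
        )
        recs = simulate_growth(design, 3)
        by_group = {"fast": [], "slow": []}
        for rec in recs:
            by_group[rec.group].append(relative_volume(rec))
        fast = np.mean(by_group["fast"], axis=0)
        slow = np.mean(by_group["slow"], axis=0)
        assert np.all(fast >= slow)

    def test_default_group_ordering_matches_treatment_strength(self):
        """Day-28 mean relative volume orders the arms by treatment intensity:
        control > PL-DXR > hypoxic RT > PL-DXR+hypoxic RT > RT, across seeds."""
        expected = ["Control", "PL-DXR", "Hypoxic RT", "PL-DXR + hypoxic RT", "RT"]
        design = default_design(seed=0)
        for seed in range(20):
            finals = {}
            for rec in simulate_growth(design, seed):
                finals.setdefault(rec.group, []).append(relative_volume(rec)[-1])
            means = {g: np.mean(v) for g, v in finals.items()}
            ordered = sorted(means, key=means.get, reverse=True)
            assert ordered == expected, f"seed {seed}: {ordered}"


class TestHypoxicFraction:
    def test_direct_evaluation(self):
        design = default_design(
            seed=0, hypoxia_coupling=HypoxiaCoupling(0.17, -0.21, 0.0)
        )
        assert simulate_hypoxic_fraction(0.0, design, 1) == pytest.approx(0.17)
        assert simulate_hypoxic_fraction(0.29, design, 1) == pytest.approx(0.17 - 0.21 * 0.29)

    def test_clipping_to_unit_interval(self):
        design = default_design(
            seed=0, hypoxia_coupling=HypoxiaCoupling(0.1, -0.9, 0.0)
        )
        assert simulate_hypoxic_fraction(5.0, design, 1) == 0.0

    def test_noise_free_coupling_is_perfectly_negative(self):
        design = default_design(
            seed=0, hypoxia_coupling=HypoxiaCoupling(0.17, -0.21, 0.0)
        )
        changes = [-0.18, -0.26, 0.04, 0.20, 0.29]
        hf = [simulate_hypoxic_fraction(c, design, i) for i, c in enumerate(changes)]
        assert pearson(hf, changes).r == pytest.approx(-1.0)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            HypoxiaCoupling(slope=0.1)


class TestDesignValidation:
    def test_invalid_acquisition(self):
        with pytest.raises(ValueError):
            AcquisitionProtocol(frame_interval_s=0)
        with pytest.raises(ValueError):
            AcquisitionProtocol(n_baseline_frames=0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(noise_sd=-0.1)

    def test_default_acquisition_grid(self):
        times, nb = AcquisitionProtocol().frame_times_min()
        assert nb == 5
        assert len(times) == 105  # 5 baseline + 100 post-contrast frames
        assert times[nb - 1] == 0.0
        assert times[-1] == pytest.approx(20.0)
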