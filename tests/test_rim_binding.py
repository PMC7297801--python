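"""Rim profiling and the binding-efficiency contrast statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guvquant import (GuvDetection, compute_binding_efficiency, detect_guvs,
                      estimate_solution_intensity, extract_rim_profile,
                      per_phase_binding, segment_phases, segregation_profile,
                      simulate_guv_image)
from guvquant.errors import QuantificationError
from guvquant.rim import RimProfile

from conftest import half_and_half_arcs, make_scene


def _profile_from_values(values: dict[str, np.ndarray]) -> RimProfile:
    n = len(next(iter(values.values())))
    angles = (np.arange(n) + 0.5) * (2 * np.pi / n)
    return RimProfile(angles=angles,
                      intensities={k: np.asarray(v, dtype=float)
                                   for k, v in values.items()},
                      rim_band=(17.0, 23.0), center_xy=(64.0, 64.0),
                      radius=20.0, stat="max")


class TestExtractRimProfile:
    def test_uniform_rim_gives_constant_profile(self):
        image, _ = simulate_guv_image(make_scene(contrast={"lectin_1": {"ld": 1.0}}))
        det = detect_guvs(image)[0]
        prof = extract_rim_profile(image, det, stat="max")
        # constant up to the angular modulation of bilinear interpolation
        # (up to ~8% where the circle passes between pixel rows)
        values = prof.intensities["lectin_1"]
        assert values.std() / values.mean() < 0.04
        assert np.allclose(values, 200.0, rtol=0.09)
        # the unbiased matched-template statistic has no such modulation
        fit_values = extract_rim_profile(image, det, stat="fit").intensities["lectin_1"]
        assert np.allclose(fit_values, 200.0, rtol=0.01)

    def test_step_profile_follows_phase_arcs(self):
        image, _ = simulate_guv_image(make_scene(
            contrast={"lectin_1": {"ld": 1.0, "lo": -0.5}},
            phase_arcs=half_and_half_arcs()))
        det = detect_guvs(image)[0]
        prof = extract_rim_profile(image, det, stat="max")
        values = prof.intensities["lectin_1"]
        ld_bins = prof.angles < np.pi
        # exempt bins within ~2 px of arc length of the two boundaries
        # (one pixel subtends ~3 degrees at radius 20)
        halfwidth = 2 / 20.0
        boundary = (np.abs(prof.angles - np.pi) < halfwidth) | \
                   (np.minimum(prof.angles, 2 * np.pi - prof.angles) < halfwidth)
        assert np.allclose(values[ld_bins & ~boundary], 200.0, rtol=0.10)
        # on the dim arc the negative rim tail pulls the whole band below
        # the solution; the band-edge value is 100 - 50*exp(-9/8) ~ 83.8
        assert np.allclose(values[~ld_bins & ~boundary], 83.8, rtol=0.10)
        # the two arcs remain cleanly separated bin by bin
        assert values[ld_bins & ~boundary].min() > values[~ld_bins & ~boundary].max()

    def test_radial_max_is_robust_to_one_pixel_center_error(self):
        """Shifting the detected center by 1 px still recovers the rim peak
        in every angular bin (the point of the max-over-band statistic)."""
        image, _ = simulate_guv_image(make_scene(contrast={"lectin_1": {"ld": 1.0}}))
        det = detect_guvs(image)[0]
        shifted = GuvDetection(center_xy=(det.center_xy[0] + 1.0,
                                          det.center_xy[1]),
                               radius=det.radius, score=det.score)
        prof_true = extract_rim_profile(image, det, stat="max")
        prof_shift = extract_rim_profile(image, shifted, stat="max")
        a = prof_shift.intensities["lectin_1"]
        b = prof_true.intensities["lectin_1"]
        # every bin still lands on the rim peak (within the interpolation
        # modulation); the profile mean is essentially unchanged
        assert np.allclose(a, b, rtol=0.10)
        assert abs(a.mean() - b.mean()) / b.mean() < 0.01

    def test_band_outside_image_errors(self):
        image, _ = simulate_guv_image(make_scene())
        det = GuvDetection(center_xy=(5.0, 64.0), radius=20.0, score=1.0)
        with pytest.raises(QuantificationError, match="outside"):
            extract_rim_profile(image, det)

    def test_flagged_detection_refused(self):
        image, _ = simulate_guv_image(make_scene())
        det = GuvDetection(center_xy=(64.0, 64.0), radius=20.0, score=1.0,
                           flags={"border_touching"})
        with pytest.raises(QuantificationError, match="flagged"):
            extract_rim_profile(image, det)


class TestBindingEfficiency:
    def test_zero_when_rim_equals_solution(self):
        prof = _profile_from_values({"lectin_1": np.full(360, 100.0)})
        assert compute_binding_efficiency(prof, 100.0, "lectin_1") == 0.0

    def test_contrast_one(self):
        prof = _profile_from_values({"lectin_1": np.full(360, 200.0)})
        assert compute_binding_efficiency(prof, 100.0, "lectin_1") == 1.0

    def test_solution_must_be_positive(self):
        prof = _profile_from_values({"lectin_1": np.full(360, 200.0)})
        with pytest.raises(QuantificationError):
            compute_binding_efficiency(prof, 0.0, "lectin_1")

    def test_empty_bin_subset_errors(self):
        prof = _profile_from_values({"lectin_1": np.full(360, 200.0)})
        with pytest.raises(QuantificationError):
            compute_binding_efficiency(prof, 100.0, "lectin_1",
                                       bins=np.array([], dtype=int))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=3,
                    max_size=50),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, values, k):
        """Multiplying a channel (and thus its solution reference) by k > 0
        leaves the contrast unchanged: it is a ratio."""
        solution = 50.0
        prof_a = _profile_from_values({"lectin_1": np.asarray(values)})
        prof_b = _profile_from_values({"lectin_1": np.asarray(values) * k})
        be_a = compute_binding_efficiency(prof_a, solution, "lectin_1")
        be_b = compute_binding_efficiency(prof_b, solution * k, "lectin_1")
        assert be_a >= -1 and be_b >= -1
        assert np.isclose(be_a, be_b, rtol=1e-9, atol=1e-9)


class TestPerPhaseAndSegregation:
    def _quantified(self, contrast, seed=1):
        image, _ = simulate_guv_image(make_scene(
            contrast=contrast, phase_arcs=half_and_half_arcs(), seed=seed))
        det = detect_guvs(image)[0]
        sol = {r: estimate_solution_intensity(image, [det], r)
               for r in image.lectin_roles}
        prof = extract_rim_profile(image, det, stat="max")
        labeling = segment_phases(prof)
        return prof, labeling, sol

    def test_phase_specific_contrasts_recovered(self):
        prof, labeling, sol = self._quantified(
            {"lectin_1": {"ld": 0.0, "lo": 7.0}})
        result = per_phase_binding(prof, labeling, sol)
        assert abs(result.per_phase["lectin_1"]["ld"]) < 0.05
        assert result.per_phase["lectin_1"]["lo"] == pytest.approx(7.0, rel=0.1)
        assert result.n_bins_per_phase["ld"] > 100
        assert result.mode == "phase_separated"

    def test_mirrored_preferences_swap(self):
        prof, labeling, sol = self._quantified(
            {"lectin_1": {"ld": 0.0, "lo": 7.0}, "lectin_2": {"ld": 7.0, "lo": 0.0}})
        result = per_phase_binding(prof, labeling, sol)
        a, b = result.per_phase["lectin_1"], result.per_phase["lectin_2"]
        assert a["lo"] == pytest.approx(b["ld"], rel=0.02)
        assert a["ld"] == pytest.approx(b["lo"], abs=0.05)

    def test_uniform_labeling_reports_only_present_phase(self):
        image, _ = simulate_guv_image(make_scene())
        det = detect_guvs(image)[0]
        sol = {"lectin_1": estimate_solution_intensity(image, [det], "lectin_1")}
        prof = extract_rim_profile(image, det, stat="max")
        labeling = segment_phases(prof)
        assert labeling.mode == "uniform"
        result = per_phase_binding(prof, labeling, sol)
        assert set(result.per_phase["lectin_1"]) == {"ld"}

    def test_anticorrelated_lectins_give_negative_correlation(self):
        prof, _, _ = self._quantified(
            {"lectin_1": {"ld": 0.0, "lo": 7.0}, "lectin_2": {"ld": 7.0, "lo": 0.0}})
        seg = segregation_profile(prof, "lectin_1", "lectin_2")
        assert seg.correlation < -0.9
        assert set(seg.table.columns) == {"angle_rad", "lectin_1", "lectin_2"}

    def test_identical_and_complementary_profiles(self):
        step = np.where(np.arange(360) < 180, 200.0, 50.0)
        prof = _profile_from_values({"lectin_1": step, "lectin_2": step.copy()})
        assert segregation_profile(prof, "lectin_1", "lectin_2").correlation \
            == pytest.approx(1.0)
        prof = _profile_from_values({"lectin_1": step, "lectin_2": 250.0 - step})
        assert segregation_profile(prof, "lectin_1", "lectin_2").correlation \
            == pytest.approx(-1.0)

    def test_zero_variance_profile_flagged_nan(self):
        prof = _profile_from_values({"lectin_1": np.full(360, 100.0),
                                     "lectin_2": np.arange(360.0)})
        assert np.isnan(segregation_profile(prof, "lectin_1", "lectin_2").correlation)
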