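"""Sagittal angles: worked examples, generator round trips, invariances."""

import math

import pytest

from posturemetrics import (
    AnnotatedView,
    Landmark,
    SagittalTruth,
    View,
    bilateral_mean,
    compute_profile,
    generate_sagittal_view,
    random_sagittal_truth,
)
from posturemetrics.geometry import Point2D
from posturemetrics.sagittal import (
    SAGITTAL_PARAMETERS,
    chest_inclination,
    head_protraction,
    lumbar_lordosis,
    sacral_slope,
    sagittal_pelvic_tilt,
    thoracic_kyphosis,
    gravity_line_angles,
)


def view_with(landmarks: dict, side="LEFT") -> AnnotatedView:
    pts = {Landmark(k): Point2D(*xy) for k, xy in landmarks.items()}
    return AnnotatedView(view=View(side), subject_id="t", landmarks=pts)


class TestIndividualAngles:
    def test_vertical_sacral_tangent_is_zero(self):
        v = view_with(
            {"sacral_tangent_lower": (0, 0), "sacral_tangent_upper": (0, 1)}
        )
        assert sacral_slope(v) == 0.0

    def test_sacral_slope_arctan_example(self):
        v = view_with(
            {"sacral_tangent_lower": (0, 0), "sacral_tangent_upper": (0.4663, 1)}
        )
        assert sacral_slope(v) == pytest.approx(25.0, abs=0.05)

    def test_parallel_tangents_give_zero_lordosis(self):
        v = view_with(
            {
                "l5s1_tangent_lower": (0, 0),
                "l5s1_tangent_upper": (0.2, 1),
                "t12l1_tangent_lower": (1, 0.5),
                "t12l1_tangent_upper": (1.2, 1.5),
            }
        )
        assert lumbar_lordosis(v) == pytest.approx(0.0, abs=1e-9)

    def test_lordosis_is_sum_of_opposite_tangent_inclinations(self):
        # L5-S1 tangent leaning 20 deg one way, T12-L1 22 deg the other
        v = view_with(
            {
                "l5s1_tangent_lower": (0, 0),
                "l5s1_tangent_upper": (math.sin(math.radians(20)), math.cos(math.radians(20))),
                "t12l1_tangent_lower": (0, 1),
                "t12l1_tangent_upper": (
                    -math.sin(math.radians(22)),
                    1 + math.cos(math.radians(22)),
                ),
            }
        )
        assert lumbar_lordosis(v) == pytest.approx(42.0, abs=1e-9)

    def test_kyphosis_is_sum_of_opposite_tangent_inclinations(self):
        v = view_with(
            {
                "t12l1_tangent_lower": (0, 0),
                "t12l1_tangent_upper": (
                    -math.sin(math.radians(20.5)),
                    math.cos(math.radians(20.5)),
                ),
                "c7t1_tangent_lower": (0, 1),
                "c7t1_tangent_upper": (
                    math.sin(math.radians(24)),
                    1 + math.cos(math.radians(24)),
                ),
            }
        )
        assert thoracic_kyphosis(v) == pytest.approx(44.5, abs=1e-9)

    def test_chest_inclination_examples(self):
        flat = view_with({"c7": (0, 0), "neck_thorax_junction": (1, 0)})
        assert chest_inclination(flat) == 0.0
        sloped = view_with({"c7": (0, 0), "neck_thorax_junction": (1, -0.5095)})
        assert chest_inclination(sloped) == pytest.approx(27.0, abs=0.05)

    def test_head_protraction_examples(self):
        v = view_with({"c7": (0, 0), "external_auditory_meatus": (1, 1)})
        assert head_protraction(v) == pytest.approx(45.0)
        v53 = view_with({"c7": (0, 0), "external_auditory_meatus": (0.7454, 1)})
        assert head_protraction(v53) == pytest.approx(53.3, abs=0.05)

    def test_pelvic_tilt_sign_convention(self):
        level = view_with({"asis_left": (1, 0), "psis_left": (-1, 0)})
        assert sagittal_pelvic_tilt(level) == 0.0
        # ASIS one unit caudal over 5.671 horizontal: arctan(1/5.671) = 10 deg
        anterior = view_with({"asis_left": (5.671, -1), "psis_left": (0, 0)})
        assert sagittal_pelvic_tilt(anterior) == pytest.approx(10.0, abs=0.05)
        swapped = view_with({"asis_left": (5.671, 1), "psis_left": (0, 0)})
        assert sagittal_pelvic_tilt(swapped) == pytest.approx(-10.0, abs=0.05)

    def test_gravity_line_angles(self):
        plumb = view_with(
            {
                "malleolus_left": (0, 0),
                "trochanter_left": (0, 500),
                "acromion_left": (0, 800),
                "external_auditory_meatus": (0, 930),
            }
        )
        assert gravity_line_angles(plumb) == (0.0, 0.0, 0.0)
        h = 500.0
        tilted = view_with(
            {
                "malleolus_left": (0, 0),
                "trochanter_left": (h * math.tan(math.radians(3)), h),
                "acromion_left": (0, 800),
                "external_auditory_meatus": (0, 930),
            }
        )
        ta, aa, ea = gravity_line_angles(tilted)
        assert ta == pytest.approx(3.0, abs=1e-9)
        assert aa == 0.0 and ea == 0.0

    def test_frontal_view_rejected(self, symmetric_front_back):
        front, _ = symmetric_front_back
        with pytest.raises(ValueError, match="LEFT or RIGHT"):
            compute_profile(front)


class TestProfiles:
    def test_full_synthetic_view_has_all_nine(self, left_view):
        profile = compute_profile(left_view)
        assert all(v is not None for v in profile.as_dict().values())
        assert profile.side == "LEFT"

    def test_missing_ear_drops_ea_and_hp_only(self, left_view):
        pts = {k: v for k, v in left_view.landmarks.items() if k != Landmark.EAR}
        v = AnnotatedView(view=View.LEFT, subject_id="t", landmarks=pts)
        profile = compute_profile(v)
        assert profile.EA is None and profile.HP is None
        assert "EA" in profile.reasons and "HP" in profile.reasons
        for name in ("SS", "LL", "TK", "CI", "SPT", "TA", "AA"):
            assert getattr(profile, name) is not None

    def test_empty_view_all_absent(self):
        v = AnnotatedView(view=View.LEFT, subject_id="t", landmarks={})
        profile = compute_profile(v)
        assert all(val is None for val in profile.as_dict().values())
        assert set(profile.reasons) == set(SAGITTAL_PARAMETERS)

    def test_bilateral_mean(self, left_view):
        right = generate_sagittal_view(
            SagittalTruth(SS=26.0), side="RIGHT", subject_id="t"
        )
        left = generate_sagittal_view(SagittalTruth(SS=24.0), side="LEFT", subject_id="t")
        mean = bilateral_mean(compute_profile(left), compute_profile(right))
        assert mean.side == "MEAN"
        assert mean.SS == pytest.approx(25.0, abs=1e-9)
        # identical profiles average to themselves
        p = compute_profile(left_view)
        same = bilateral_mean(p, p)
        for k, val in p.as_dict().items():
            assert same.as_dict()[k] == pytest.approx(val, abs=1e-12)

    def test_bilateral_mean_drops_one_sided_fields(self, left_view):
        p_full = compute_profile(left_view)
        pts = {k: v for k, v in left_view.landmarks.items() if k != Landmark.EAR}
        p_partial = compute_profile(
            AnnotatedView(view=View.LEFT, subject_id="t", landmarks=pts)
        )
        mean = bilateral_mean(p_full, p_partial)
        assert mean.EA is None and mean.HP is None
        assert mean.SS is not None


class TestRoundTripAndInvariance:
    def test_table_mean_truth_recovered(self):
        truth = SagittalTruth(SS=24.7, LL=41.7, TK=44.5, CI=27.1, HP=53.3)
        profile = compute_profile(generate_sagittal_view(truth))
        for name in SAGITTAL_PARAMETERS:
            assert profile.as_dict()[name] == pytest.approx(getattr(truth, name), abs=0.1)

    def test_500_random_truths_recovered(self, rng):
        """Zero-noise generation then measurement recovers truth to <= 0.01 deg."""
        worst = 0.0
        for _ in range(500):
            truth = random_sagittal_truth(rng)
            side = "LEFT" if rng.random() < 0.5 else "RIGHT"
            profile = compute_profile(generate_sagittal_view(truth, side=side))
            for name in SAGITTAL_PARAMETERS:
                worst = max(worst, abs(profile.as_dict()[name] - getattr(truth, name)))
        assert worst <= 0.01

    def test_similarity_transform_invariance(self, rng, left_view):
        """Translation + uniform scaling leave every angle unchanged."""
        base = compute_profile(left_view).as_dict()
        for _ in range(20):
            tx, ty = rng.uniform(-1e3, 1e3, 2)
            s = rng.uniform(0.2, 5.0)
            pts = {
                k: Point2D(s * p.x + tx, s * p.y + ty)
                for k, p in left_view.landmarks.items()
            }
            moved = compute_profile(
                AnnotatedView(view=View.LEFT, subject_id="t", landmarks=pts)
            )
            for name in SAGITTAL_PARAMETERS:
                assert moved.as_dict()[name] == pytest.approx(base[name], abs=1e-8)
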