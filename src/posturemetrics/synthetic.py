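"""Synthetic landmark sets and measurement studies with known truth.

The generators construct annotated views whose noise-free measurement
reproduces a chosen true parameter vector exactly, then optionally
perturb every landmark coordinate with i.i.d. Gaussian placement noise.
This makes every downstream computation testable end-to-end without
photographs, and gives the reliability machinery data with a known
variance-component structure.

Default truth means and SDs are calibrated to the magnitudes a healthy
school-age screening cohort shows (SS ~ 25 deg, LL ~ 42, TK ~ 44,
CI ~ 27, HP ~ 53; trunk asymmetry totals ~ 21 index units), so that
"realistic" fixtures come out of the box. Statures are in pixels of a
nominal full-body photograph (default 1000 px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import FrameConvention, Point2D
from .landmarks import (
    AnnotatedView,
    CohortRecord,
    Landmark,
    MeasurementRecord,
    View,
)

#: Default sagittal truth, degrees (screening-cohort central values).
DEFAULT_SAGITTAL_MEANS = {
    "SS": 24.7,
    "LL": 41.7,
    "TK": 44.5,
    "CI": 27.1,
    "HP": 53.3,
    "SPT": 10.0,
    "TA": 2.0,
    "AA": 1.0,
    "EA": 1.5,
}

#: Matching between-subject SDs, degrees.
DEFAULT_SAGITTAL_SDS = {
    "SS": 7.0,
    "LL": 9.5,
    "TK": 6.7,
    "CI": 7.1,
    "HP": 3.1,
    "SPT": 3.0,
    "TA": 1.0,
    "AA": 1.0,
    "EA": 1.0,
}

#: Physiologic sampling ranges for random truths, degrees.
SAGITTAL_RANGES = {
    "SS": (5.0, 50.0),
    "LL": (10.0, 70.0),
    "TK": (10.0, 70.0),
    "CI": (5.0, 55.0),
    "HP": (35.0, 75.0),
    "SPT": (-20.0, 25.0),
    "TA": (-8.0, 8.0),
    "AA": (-8.0, 8.0),
    "EA": (-8.0, 8.0),
}


class ConstructionError(ValueError):
    """The requested truth cannot be realized as a landmark geometry."""


@dataclass(frozen=True)
class SagittalTruth:
    """True sagittal angles (degrees) a generated view must reproduce."""

    SS: float = DEFAULT_SAGITTAL_MEANS["SS"]
    LL: float = DEFAULT_SAGITTAL_MEANS["LL"]
    TK: float = DEFAULT_SAGITTAL_MEANS["TK"]
    CI: float = DEFAULT_SAGITTAL_MEANS["CI"]
    HP: float = DEFAULT_SAGITTAL_MEANS["HP"]
    SPT: float = DEFAULT_SAGITTAL_MEANS["SPT"]
    TA: float = DEFAULT_SAGITTAL_MEANS["TA"]
    AA: float = DEFAULT_SAGITTAL_MEANS["AA"]
    EA: float = DEFAULT_SAGITTAL_MEANS["EA"]
    stature: float = 1000.0
    ll_split: float | None = None  # L5-S1 tangent's share of LL; default LL/2

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DEFAULT_SAGITTAL_MEANS}


@dataclass(frozen=True)
class FrontalTruth:
    """True frontal/back asymmetry geometry, pixels."""

    trunk_height_e: float = 330.0
    ref_offset: float = 0.0  # lateral sternal-notch/C7 offset from midline
    width_axilla_left: float = 110.0  # c
    width_axilla_right: float = 110.0  # d
    width_waist_left: float = 95.0  # a
    width_waist_right: float = 95.0  # b
    dh_shoulder: float = 0.0
    dh_axilla: float = 0.0
    dh_waist: float = 0.0
    stature: float = 1000.0

    def __post_init__(self):
        if self.trunk_height_e <= 0:
            raise ConstructionError("trunk height e must be positive")
        for w in (
            self.width_axilla_left,
            self.width_axilla_right,
            self.width_waist_left,
            self.width_waist_right,
        ):
            if w <= 0:
                raise ConstructionError("trunk widths must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian error structure for landmark placement and rating studies."""

    landmark_sd: float = 0.0  # px, i.i.d. per coordinate
    rater_bias_sd: float = 0.0  # units of the rated parameter
    session_drift_sd: float = 0.0
    residual_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        for sd in (self.landmark_sd, self.rater_bias_sd, self.session_drift_sd, self.residual_sd):
            if sd < 0:
                raise ValueError("noise SDs must be non-negative")

    def rng(self, rng: np.random.Generator | None = None) -> np.random.Generator:
        if rng is not None:
            return rng
        return np.random.default_rng(self.seed)


def _tan(deg: float) -> float:
    return math.tan(math.radians(deg))


def _dir_from_vertical(deg: float) -> tuple[float, float]:
    """Unit vector at ``deg`` degrees from +y, positive toward +x (anterior)."""
    return math.sin(math.radians(deg)), math.cos(math.radians(deg))


def generate_sagittal_view(
    truth: SagittalTruth = SagittalTruth(),
    noise: NoiseModel = NoiseModel(),
    side: str = "LEFT",
    subject_id: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> AnnotatedView:
    """Construct a profile view that measures back to ``truth`` exactly
    (before noise).

    Geometry: the lateral malleolus sits at the origin with the vertical
    through it; trochanter, acromion and ear lie on rays at TA/AA/EA.
    Contour tangent pairs are placed at inclinations that reproduce SS,
    LL and TK, with LL split between its two tangents (symmetrically by
    default) and the T12-L1 tangent shared between LL and TK — the same
    differencing an inclinometer performs. C7, the neck-thorax junction
    and the pelvis landmarks are placed to reproduce HP, CI and SPT.
    """
    s = truth.stature
    side_l = side.lower()
    if side_l not in ("left", "right"):
        raise ValueError("side must be LEFT or RIGHT")

    for name in ("SS", "CI", "HP"):
        val = getattr(truth, name)
        if not 0.0 <= val < 90.0:
            raise ConstructionError(f"{name}={val} outside [0, 90)")
    for name in ("LL", "TK"):
        val = getattr(truth, name)
        if not 0.0 <= val < 180.0:
            raise ConstructionError(f"{name}={val} outside [0, 180)")
    for name in ("SPT", "TA", "AA", "EA"):
        val = getattr(truth, name)
        if not -90.0 < val < 90.0:
            raise ConstructionError(f"{name}={val} outside (-90, 90)")

    pts: dict[Landmark, Point2D] = {}
    malleolus = Point2D(0.0, 0.0)
    pts[Landmark(f"malleolus_{side_l}")] = malleolus

    # gravity-line landmarks on rays from the malleolus (heights are
    # anthropometric fractions of stature)
    for name, angle, h in (
        (f"trochanter_{side_l}", truth.TA, 0.50 * s),
        (f"acromion_{side_l}", truth.AA, 0.80 * s),
        ("external_auditory_meatus", truth.EA, 0.93 * s),
    ):
        pts[Landmark(name)] = Point2D(h * _tan(angle), h)

    ear = pts[Landmark.EAR]
    # C7 posterior to and below the ear so that the C7->ear segment makes HP
    # with the horizontal
    r = 0.08 * s
    c7 = Point2D(
        ear.x - r * math.cos(math.radians(truth.HP)),
        ear.y - r * math.sin(math.radians(truth.HP)),
    )
    pts[Landmark.C7] = c7
    # junction anterior to and below C7 at CI to the horizontal
    m = 0.10 * s
    pts[Landmark.NECK_THORAX_JUNCTION] = Point2D(
        c7.x + m * math.cos(math.radians(truth.CI)),
        c7.y - m * math.sin(math.radians(truth.CI)),
    )

    # pelvis: PSIS posterior, ASIS anterior and caudal by SPT
    w = 0.12 * s
    psis = Point2D(-0.06 * s, 0.55 * s)
    pts[Landmark(f"psis_{side_l}")] = psis
    pts[Landmark(f"asis_{side_l}")] = Point2D(
        psis.x + w * math.cos(math.radians(truth.SPT)),
        psis.y - w * math.sin(math.radians(truth.SPT)),
    )

    # contour tangents: angles measured from the vertical, anterior lean > 0
    ll_lower = truth.ll_split if truth.ll_split is not None else truth.LL / 2.0
    theta_l5s1 = ll_lower  # leans anterior going up
    theta_t12l1 = ll_lower - truth.LL  # leans posterior
    theta_c7t1 = theta_t12l1 + truth.TK
    for name, theta in (("l5s1", theta_l5s1), ("t12l1", theta_t12l1), ("c7t1", theta_c7t1)):
        if not -90.0 < theta < 90.0:
            raise ConstructionError(
                f"{name} tangent inclination {theta:.1f} deg unreachable "
                f"(LL={truth.LL}, TK={truth.TK}, split={ll_lower})"
            )
    seg = 0.06 * s
    tangent_anchor = {
        "sacral": (-0.07 * s, 0.48 * s),
        "l5s1": (-0.07 * s, 0.56 * s),
        "t12l1": (-0.06 * s, 0.66 * s),
        "c7t1": (-0.04 * s, 0.82 * s),
    }
    # the sacral contour leans posterior going up by SS
    for stem, theta in (
        ("sacral", -truth.SS),
        ("l5s1", theta_l5s1),
        ("t12l1", theta_t12l1),
        ("c7t1", theta_c7t1),
    ):
        ax, ay = tangent_anchor[stem]
        dx, dy = _dir_from_vertical(theta)
        pts[Landmark(f"{stem}_tangent_lower")] = Point2D(ax, ay)
        pts[Landmark(f"{stem}_tangent_upper")] = Point2D(ax + seg * dx, ay + seg * dy)

    gen = noise.rng(rng)
    if noise.landmark_sd > 0:
        pts = {
            k: Point2D(
                p.x + gen.normal(0.0, noise.landmark_sd),
                p.y + gen.normal(0.0, noise.landmark_sd),
            )
            for k, p in pts.items()
        }
    return AnnotatedView(
        view=View(side.upper()),
        subject_id=subject_id,
        landmarks=pts,
        frame=FrameConvention(anterior_sign=1),
    )


def generate_frontal_views(
    truth: FrontalTruth = FrontalTruth(),
    noise: NoiseModel = NoiseModel(),
    subject_id: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> tuple[AnnotatedView, AnnotatedView]:
    """(front, back) views whose noise-free ATSI and POTSI equal
    :func:`expected_index` of ``truth``.

    The same trunk geometry drives both views; the front anchors the
    midline at the navel with the sternal notch offset laterally, the
    back anchors it at the gluteal cleft with C7 offset. Height
    differences are applied symmetrically (left up, right down).
    """
    gen = noise.rng(rng)
    views = []
    for view, ref_lm, anchor_lm in (
        (View.FRONT, Landmark.STERNAL_NOTCH, Landmark.NAVEL),
        (View.BACK, Landmark.C7, Landmark.GLUTEAL_CLEFT_TOP),
    ):
        y0 = 0.55 * truth.stature  # anchor height
        h_ax = y0 + 0.80 * truth.trunk_height_e
        h_waist = y0 + 0.25 * truth.trunk_height_e
        h_sh = y0 + 1.05 * truth.trunk_height_e
        pts: dict[Landmark, Point2D] = {
            anchor_lm: Point2D(0.0, y0),
            ref_lm: Point2D(truth.ref_offset, y0 + truth.trunk_height_e),
            Landmark.TRUNK_EDGE_AXILLA_LEFT: Point2D(truth.width_axilla_left, h_ax),
            Landmark.TRUNK_EDGE_AXILLA_RIGHT: Point2D(-truth.width_axilla_right, h_ax),
            Landmark.TRUNK_EDGE_WAIST_LEFT: Point2D(
                truth.width_waist_left, h_waist + truth.dh_waist / 2.0
            ),
            Landmark.TRUNK_EDGE_WAIST_RIGHT: Point2D(
                -truth.width_waist_right, h_waist - truth.dh_waist / 2.0
            ),
            Landmark.SHOULDER_LEFT: Point2D(
                0.85 * truth.width_axilla_left, h_sh + truth.dh_shoulder / 2.0
            ),
            Landmark.SHOULDER_RIGHT: Point2D(
                -0.85 * truth.width_axilla_right, h_sh - truth.dh_shoulder / 2.0
            ),
            Landmark.AXILLA_LEFT: Point2D(
                0.85 * truth.width_axilla_left, h_ax + truth.dh_axilla / 2.0
            ),
            Landmark.AXILLA_RIGHT: Point2D(
                -0.85 * truth.width_axilla_right, h_ax - truth.dh_axilla / 2.0
            ),
            Landmark.MALLEOLUS_LEFT: Point2D(0.07 * truth.stature, 0.0),
            Landmark.MALLEOLUS_RIGHT: Point2D(-0.07 * truth.stature, 0.0),
        }
        if noise.landmark_sd > 0:
            pts = {
                k: Point2D(
                    p.x + gen.normal(0.0, noise.landmark_sd),
                    p.y + gen.normal(0.0, noise.landmark_sd),
                )
                for k, p in pts.items()
            }
        views.append(
            AnnotatedView(view=view, subject_id=subject_id, landmarks=pts)
        )
    return views[0], views[1]


def expected_index(truth: FrontalTruth) -> float:
    """Closed-form ATSI/POTSI total implied by a frontal truth."""
    e = truth.trunk_height_e
    c, d = truth.width_axilla_left, truth.width_axilla_right
    a, b = truth.width_waist_left, truth.width_waist_right
    return 100.0 * (
        abs(truth.ref_offset) / e
        + abs(c - d) / (c + d)
        + abs(a - b) / (a + b)
        + abs(truth.dh_shoulder) / e
        + abs(truth.dh_axilla) / e
        + abs(truth.dh_waist) / e
    )


def random_sagittal_truth(
    rng: np.random.Generator, ranges: dict[str, tuple[float, float]] | None = None
) -> SagittalTruth:
    """Uniform draw of a realizable truth from physiologic ranges.

    The LL/TK tangent construction is kept feasible by re-drawing until
    all three tangent inclinations stay inside (-90, 90) degrees (the
    default ranges virtually always satisfy this on the first draw).
    """
    ranges = dict(SAGITTAL_RANGES if ranges is None else ranges)
    for _ in range(100):
        draw = {k: float(rng.uniform(*ranges[k])) for k in ranges}
        ll_lower = draw["LL"] / 2.0
        if abs(ll_lower - draw["LL"] + draw["TK"]) < 89.0 and abs(ll_lower) < 89.0:
            return SagittalTruth(**draw)
    raise ConstructionError("could not draw a realizable sagittal truth")


def generate_rater_study(
    n_subjects: int = 30,
    k_raters: int = 3,
    s_sessions: int = 1,
    subject_mean: float = DEFAULT_SAGITTAL_MEANS["SS"],
    subject_sd: float = DEFAULT_SAGITTAL_SDS["SS"],
    rater_bias_sd: float = 0.0,
    session_drift_sd: float = 0.0,
    residual_sd: float = 1.0,
    parameter: str = "SS",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[MeasurementRecord]:
    """Long-format ratings from the additive variance-component model

    value[i, j, t] = mu + subject[i] + rater[j] + session[t] + eps[i, j, t]

    with independent Gaussian components. Defaults mirror a reliability
    study of 30 subjects rated by 3 observers with ~1 degree residual
    error against ~7 degrees of between-subject spread.
    """
    if n_subjects < 2 or k_raters < 1 or s_sessions < 1:
        raise ValueError("need n_subjects >= 2, k_raters >= 1, s_sessions >= 1")
    gen = rng if rng is not None else np.random.default_rng(seed)
    subj = gen.normal(0.0, subject_sd, n_subjects)
    raters = gen.normal(0.0, rater_bias_sd, k_raters) if rater_bias_sd > 0 else np.zeros(k_raters)
    sessions = (
        gen.normal(0.0, session_drift_sd, s_sessions)
        if session_drift_sd > 0
        else np.zeros(s_sessions)
    )
    records = []
    for i in range(n_subjects):
        for j in range(k_raters):
            for t in range(s_sessions):
                eps = gen.normal(0.0, residual_sd) if residual_sd > 0 else 0.0
                records.append(
                    MeasurementRecord(
                        subject_id=f"s{i + 1:03d}",
                        rater_id=f"r{j + 1}",
                        session_id=f"t{t}",
                        parameter=parameter,
                        value=float(subject_mean + subj[i] + raters[j] + sessions[t] + eps),
                    )
                )
    return records


def generate_cohort(
    strata: dict[tuple[str, int], dict[str, tuple[float, float]]],
    n_per_stratum: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[CohortRecord]:
    """Cohort observations for normative-table construction.

    ``strata`` maps (sex, age) to {parameter: (mean, sd)}; each stratum
    gets ``n_per_stratum`` subjects with one Gaussian draw per parameter.
    """
    gen = rng if rng is not None else np.random.default_rng(seed)
    records = []
    for (sex, age), params in sorted(strata.items()):
        for i in range(n_per_stratum):
            sid = f"{sex}{age}_{i + 1:05d}"
            for param, (mean, sd) in sorted(params.items()):
                records.append(
                    CohortRecord(
                        subject_id=sid,
                        sex=sex,
                        age_years=age,
                        parameter=param,
                        value=float(gen.normal(mean, sd)),
                    )
                )
    return records


def default_cohort_spec() -> dict[tuple[str, int], dict[str, tuple[float, float]]]:
    """A single-stratum spec (girls, age 7) with chart-consistent spreads.

    Means are the chart medians; SDs are set so the Gaussian quantiles
    track the chart envelope (e.g. SS ~ Normal(27, 7.3)).
    """
    return {
        ("F", 7): {
            "SS": (27.0, 7.3),
            "LL": (29.0, 9.0),
            "TK": (42.0, 9.0),
            "CI": (27.0, 6.2),
            "HP": (58.0, 6.0),
        }
    }
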