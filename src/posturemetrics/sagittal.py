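"""Sagittal-plane postural parameters from a profile photograph.

Nine angles are computed from a LEFT or RIGHT annotated view:

========  ==================================================================
SS        sacral slope — sacral contour tangent vs. the vertical
LL        lumbar lordosis — angle between the L5-S1 and T12-L1 contour
          tangents (directions taken caudal -> cranial)
TK        thoracic kyphosis — angle between the T12-L1 and C7-T1 tangents
CI        chest inclination — C7 to anterior neck-thorax junction vs.
          the horizontal
HP        head protraction — C7 to external auditory meatus vs. the
          horizontal (smaller = more forward head)
SPT       sagittal pelvic tilt — ASIS-PSIS line vs. the horizontal,
          signed, positive for anterior tilt (ASIS below PSIS)
TA/AA/EA  gravity-line angles — malleolus to trochanter / acromion / ear
          vs. the vertical through the malleolus, signed, positive
          anterior
========  ==================================================================

For a lordotic (or kyphotic) contour whose two tangents lean to opposite
sides of the vertical, LL (TK) equals the sum of the tangents' unsigned
inclinations to the vertical — the same differencing an inclinometer
performs between its two application sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import (
    InvalidGeometryError,
    Line2D,
    angle_between,
    angle_to_horizontal,
    angle_to_vertical,
)
from .landmarks import AnnotatedView, Landmark, MissingLandmarkError, View, sided

SAGITTAL_PARAMETERS = ("SS", "LL", "TK", "CI", "HP", "SPT", "TA", "AA", "EA")


@dataclass(frozen=True)
class SagittalProfile:
    """The nine sagittal angles for one side (or the bilateral mean).

    Absent fields are ``None``; :attr:`reasons` records why each absent
    field could not be computed.
    """

    side: str  # LEFT, RIGHT or MEAN
    SS: float | None = None
    LL: float | None = None
    TK: float | None = None
    CI: float | None = None
    HP: float | None = None
    SPT: float | None = None
    TA: float | None = None
    AA: float | None = None
    EA: float | None = None
    reasons: dict = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.reasons is None:
            object.__setattr__(self, "reasons", {})

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in SAGITTAL_PARAMETERS}


def _tangent(v: AnnotatedView, lower: Landmark, upper: Landmark) -> Line2D:
    line = Line2D(v[lower], v[upper], label=f"{lower.value}-{upper.value}")
    if line.direction[1] < 0:
        # normalize caudal -> cranial so oriented tangent angles are stable
        line = Line2D(line.q, line.p, label=line.label)
    return line


def _check_sagittal(v: AnnotatedView) -> str:
    if v.view not in (View.LEFT, View.RIGHT):
        raise ValueError(f"sagittal parameters need a LEFT or RIGHT view, got {v.view.value}")
    return v.view.value


def sacral_slope(v: AnnotatedView) -> float:
    """SS: unsigned angle of the sacral contour tangent to the vertical."""
    _check_sagittal(v)
    t = _tangent(v, Landmark.SACRAL_TANGENT_LOWER, Landmark.SACRAL_TANGENT_UPPER)
    return angle_to_vertical(t.p, t.q)


def lumbar_lordosis(v: AnnotatedView) -> float:
    """LL: oriented angle between the L5-S1 and T12-L1 tangent directions."""
    _check_sagittal(v)
    lo = _tangent(v, Landmark.L5S1_TANGENT_LOWER, Landmark.L5S1_TANGENT_UPPER)
    hi = _tangent(v, Landmark.T12L1_TANGENT_LOWER, Landmark.T12L1_TANGENT_UPPER)
    return angle_between(lo, hi, oriented=True)


def thoracic_kyphosis(v: AnnotatedView) -> float:
    """TK: oriented angle between the T12-L1 and C7-T1 tangent directions."""
    _check_sagittal(v)
    lo = _tangent(v, Landmark.T12L1_TANGENT_LOWER, Landmark.T12L1_TANGENT_UPPER)
    hi = _tangent(v, Landmark.C7T1_TANGENT_LOWER, Landmark.C7T1_TANGENT_UPPER)
    return angle_between(lo, hi, oriented=True)


def chest_inclination(v: AnnotatedView) -> float:
    """CI: C7 -> neck-thorax junction segment vs. the horizontal."""
    _check_sagittal(v)
    return angle_to_horizontal(v[Landmark.C7], v[Landmark.NECK_THORAX_JUNCTION])


def head_protraction(v: AnnotatedView) -> float:
    """HP: C7 -> external auditory meatus segment vs. the horizontal."""
    _check_sagittal(v)
    return angle_to_horizontal(v[Landmark.C7], v[Landmark.EAR])


def sagittal_pelvic_tilt(v: AnnotatedView) -> float:
    """SPT: signed ASIS-PSIS angle to the horizontal; positive = anterior tilt."""
    side = _check_sagittal(v)
    asis, psis = v[sided("asis", side)], v[sided("psis", side)]
    if asis.x == psis.x and asis.y == psis.y:
        raise InvalidGeometryError(f"ASIS and PSIS coincide on {side} view")
    # positive when the ASIS sits caudal to the PSIS
    unsigned = angle_to_horizontal(asis, psis)
    if asis.y == psis.y:
        return 0.0
    return unsigned if asis.y < psis.y else -unsigned


def gravity_line_angles(v: AnnotatedView) -> tuple[float, float, float]:
    """(TA, AA, EA): signed malleolus->landmark angles to the vertical."""
    side = _check_sagittal(v)
    base = v[sided("malleolus", side)]
    ta = angle_to_vertical(base, v[sided("trochanter", side)], signed=True, frame=v.frame)
    aa = angle_to_vertical(base, v[sided("acromion", side)], signed=True, frame=v.frame)
    ea = angle_to_vertical(base, v[Landmark.EAR], signed=True, frame=v.frame)
    return ta, aa, ea


_COMPUTATIONS = {
    "SS": sacral_slope,
    "LL": lumbar_lordosis,
    "TK": thoracic_kyphosis,
    "CI": chest_inclination,
    "HP": head_protraction,
    "SPT": sagittal_pelvic_tilt,
}


def compute_profile(v: AnnotatedView) -> SagittalProfile:
    """Compute every available sagittal parameter of one profile view.

    Parameters whose landmarks are absent (or degenerate) are left ``None``
    with the failure reason recorded — never silently fabricated.
    """
    side = _check_sagittal(v)
    values: dict[str, float | None] = {}
    reasons: dict[str, str] = {}
    for name, fn in _COMPUTATIONS.items():
        try:
            values[name] = fn(v)
        except (MissingLandmarkError, InvalidGeometryError) as e:
            values[name] = None
            reasons[name] = str(e)
    tips = {
        "TA": lambda: v[sided("trochanter", side)],
        "AA": lambda: v[sided("acromion", side)],
        "EA": lambda: v[Landmark.EAR],
    }
    for name, tip in tips.items():
        try:
            values[name] = angle_to_vertical(
                v[sided("malleolus", side)], tip(), signed=True, frame=v.frame
            )
        except (MissingLandmarkError, InvalidGeometryError) as e:
            values[name] = None
            reasons[name] = str(e)
    return SagittalProfile(side=side, reasons=reasons, **values)


def bilateral_mean(left: SagittalProfile, right: SagittalProfile) -> SagittalProfile:
    """Field-wise mean of the two sides; fields absent on either side stay absent."""
    values: dict[str, float | None] = {}
    reasons: dict[str, str] = {}
    for name in SAGITTAL_PARAMETERS:
        lv, rv = getattr(left, name), getattr(right, name)
        if lv is None or rv is None:
            values[name] = None
            reasons[name] = "absent on one side"
        else:
            values[name] = 0.5 * (lv + rv)
    return SagittalProfile(side="MEAN", reasons=reasons, **values)
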