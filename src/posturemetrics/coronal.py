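"""Coronal-plane trunk asymmetry indices and lower-limb angles.

ATSI (front view) and POTSI (back view) are each the sum of six
dimensionless sub-indices, every one scaled by 100 so that a typical
screening cohort scores in the tens (the convention of the surface-
topography literature these indices come from):

* one reference-point frontal asymmetry index — lateral offset of the
  sternal notch (ATSI) or C7 (POTSI) from the vertical midline, divided
  by the trunk height ``e``;
* two width asymmetry indices ``FAI-A`` and ``FAI-T`` — |c-d|/(c+d) and
  |a-b|/(a+b), where c,d (a,b) are the horizontal distances from the
  trunk edges at axilla (waist) level to the midline;
* three height difference indices ``HDI-S/A/T`` — left-right level
  differences at the shoulders, axillas and waist, divided by ``e``.

The midline is the vertical through the navel (front) or the top of the
gluteal cleft (back); ``e`` is the vertical distance from that anchor to
the reference point. Both anchors are configurable; these defaults match
the diagrams' apparent construction. Height differences are measured
along the vertical axis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import InvalidGeometryError, Line2D, angle_between
from .landmarks import AnnotatedView, Landmark, View, sided


@dataclass(frozen=True)
class AsymmetryIndexResult:
    """ATSI or POTSI with its six sub-indices (index units, 100x ratios)."""

    kind: str  # "ATSI" | "POTSI"
    fai_ref: float  # FAI-SN (front) or FAI-C7 (back)
    fai_a: float
    fai_t: float
    hdi_s: float
    hdi_a: float
    hdi_t: float
    trunk_height_e: float  # pixels

    @property
    def total(self) -> float:
        return self.fai_ref + self.fai_a + self.fai_t + self.hdi_s + self.hdi_a + self.hdi_t


def _trunk_index(
    v: AnnotatedView,
    kind: str,
    reference: Landmark,
    midline_anchor: Landmark,
) -> AsymmetryIndexResult:
    ref = v[reference]
    anchor = v[midline_anchor]
    x_mid = anchor.x
    e = abs(ref.y - anchor.y)
    if e <= 0:
        raise InvalidGeometryError(
            f"trunk height e is zero: '{reference.value}' and "
            f"'{midline_anchor.value}' at the same height"
        )
    # horizontal distances of trunk edges to the midline
    c = abs(v[Landmark.TRUNK_EDGE_AXILLA_LEFT].x - x_mid)
    d = abs(v[Landmark.TRUNK_EDGE_AXILLA_RIGHT].x - x_mid)
    a = abs(v[Landmark.TRUNK_EDGE_WAIST_LEFT].x - x_mid)
    b = abs(v[Landmark.TRUNK_EDGE_WAIST_RIGHT].x - x_mid)
    if c + d <= 0 or a + b <= 0:
        raise InvalidGeometryError("trunk width (c+d or a+b) is zero")
    fai_ref = 100.0 * abs(ref.x - x_mid) / e
    fai_a = 100.0 * abs(c - d) / (c + d)
    fai_t = 100.0 * abs(a - b) / (a + b)
    hdi_s = 100.0 * abs(v[Landmark.SHOULDER_LEFT].y - v[Landmark.SHOULDER_RIGHT].y) / e
    hdi_a = 100.0 * abs(v[Landmark.AXILLA_LEFT].y - v[Landmark.AXILLA_RIGHT].y) / e
    hdi_t = (
        100.0
        * abs(v[Landmark.TRUNK_EDGE_WAIST_LEFT].y - v[Landmark.TRUNK_EDGE_WAIST_RIGHT].y)
        / e
    )
    return AsymmetryIndexResult(kind, fai_ref, fai_a, fai_t, hdi_s, hdi_a, hdi_t, e)


def atsi(v: AnnotatedView) -> AsymmetryIndexResult:
    """Anterior Trunk Symmetry Index from a FRONT view.

    Reference point: sternal notch; midline: vertical through the navel;
    e: vertical navel -> sternal-notch distance.
    """
    if v.view is not View.FRONT:
        raise ValueError(f"ATSI needs a FRONT view, got {v.view.value}")
    return _trunk_index(v, "ATSI", Landmark.STERNAL_NOTCH, Landmark.NAVEL)


def potsi(v: AnnotatedView) -> AsymmetryIndexResult:
    """Posterior Trunk Symmetry Index from a BACK view.

    Reference point: C7; midline: vertical through the top of the gluteal
    cleft; e: vertical C7 -> gluteal-cleft distance.
    """
    if v.view is not View.BACK:
        raise ValueError(f"POTSI needs a BACK view, got {v.view.value}")
    return _trunk_index(v, "POTSI", Landmark.C7, Landmark.GLUTEAL_CLEFT_TOP)


def tibiofemoral_angle(v: AnnotatedView, side: str) -> float:
    """TFA: included angle at the knee between knee->ankle and knee->ASIS.

    180 deg = straight limb; see :func:`limb_deviation` for the signed
    departure from collinearity.
    """
    if v.view is not View.FRONT:
        raise ValueError(f"TFA needs a FRONT view, got {v.view.value}")
    knee = v[sided("knee", side)]
    ankle = v[sided("ankle", side)]
    asis = v[sided("asis", side)]
    return angle_between(
        Line2D(knee, ankle, label=f"knee-ankle {side}"),
        Line2D(knee, asis, label=f"knee-ASIS {side}"),
        oriented=True,
    )


def tibiocalcaneal_angle(v: AnnotatedView, side: str) -> float:
    """TCA: included angle at the Achilles point between the calcaneus and
    mid-calf segments; 180 deg = straight hindfoot axis."""
    if v.view is not View.BACK:
        raise ValueError(f"TCA needs a BACK view, got {v.view.value}")
    ach = v[sided("achilles", side)]
    calc = v[sided("calcaneus", side)]
    calf = v[sided("mid_calf", side)]
    return angle_between(
        Line2D(ach, calc, label=f"achilles-calcaneus {side}"),
        Line2D(ach, calf, label=f"achilles-mid-calf {side}"),
        oriented=True,
    )


def limb_deviation(
    v: AnnotatedView, side: str, kind: str = "tibiofemoral"
) -> float:
    """Signed deviation from collinearity, in degrees.

    0 = perfectly straight. Positive = valgus: the distal point deviates
    laterally (away from the body midline) relative to the proximal
    segment's line. The canonical frontal frame has +x = anatomical left,
    so "lateral" is +x for the left limb and -x for the right.
    """
    if kind == "tibiofemoral":
        vertex = v[sided("knee", side)]
        proximal = v[sided("asis", side)]
        distal = v[sided("ankle", side)]
        included = tibiofemoral_angle(v, side)
    elif kind == "tibiocalcaneal":
        vertex = v[sided("achilles", side)]
        proximal = v[sided("mid_calf", side)]
        distal = v[sided("calcaneus", side)]
        included = tibiocalcaneal_angle(v, side)
    else:
        raise ValueError("kind must be 'tibiofemoral' or 'tibiocalcaneal'")
    deviation = 180.0 - included
    # cross product of proximal->vertex with vertex->distal: sign of the bend
    ux, uy = vertex.x - proximal.x, vertex.y - proximal.y
    wx, wy = distal.x - vertex.x, distal.y - vertex.y
    cross = ux * wy - uy * wx
    # the proximal->distal sweep runs caudally; a bend whose distal end
    # moves toward +x has cross > 0 in the y-up frame
    lateral = 1.0 if side.upper() == "LEFT" else -1.0
    if cross == 0:
        return 0.0
    return deviation if (cross > 0) == (lateral > 0) else -deviation
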