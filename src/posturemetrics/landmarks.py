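"""Landmark vocabulary, annotated-view JSON I/O, and QC validation.

The annotation file format is a small JSON document (schema id
``posturemetrics-view/1``) holding one photograph's operator-placed
landmarks::

    {
      "schema": "posturemetrics-view/1",
      "view": "LEFT",
      "subject_id": "s001",
      "sex": "F",
      "age_years": 7,
      "image_size": [1200, 1600],
      "anterior": "+x",
      "vertical_calibration": [[610, 1500], [612, 100]],
      "landmarks": {"c7": [601.5, 402.0], ...}
    }

Coordinates are image pixels. When ``image_size`` ([width, height]) is
present the y axis is assumed to point down (image convention) and is
flipped into the canonical y-up frame on read (y' = H - y); without it,
coordinates are taken to be canonical already. ``vertical_calibration``
is an optional pair of points on the plumbline (given in the same pixel
convention); the whole landmark set is rotated so that this pair becomes
exactly vertical, compensating a tilted camera. ``anterior`` ("+x" or
"-x", sagittal views only) states which way the subject faces in the
image; landmarks are mirrored on read so the canonical frame always has
anterior = +x. For BACK views the image shows the subject's left on the
image left, so x is mirrored to keep canonical +x = anatomical left.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .geometry import FrameConvention, Point2D

SCHEMA_ID = "posturemetrics-view/1"


class View(str, enum.Enum):
    FRONT = "FRONT"
    BACK = "BACK"
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Landmark(str, enum.Enum):
    """Closed vocabulary of anatomical and measurement points.

    Sided points carry an explicit ``_left``/``_right`` suffix (anatomical
    side). Tangent lines to the body contour are encoded as operator-placed
    lower/upper point pairs, mirroring semi-automatic on-screen placement.
    """

    # midline / trunk points
    STERNAL_NOTCH = "sternal_notch"
    C7 = "c7"
    T12_L1 = "t12_l1"
    L5_S1 = "l5_s1"
    NAVEL = "navel"
    GLUTEAL_CLEFT_TOP = "gluteal_cleft_top"
    NECK_THORAX_JUNCTION = "neck_thorax_junction"
    EAR = "external_auditory_meatus"
    # pelvis
    ASIS_LEFT = "asis_left"
    ASIS_RIGHT = "asis_right"
    PSIS_LEFT = "psis_left"
    PSIS_RIGHT = "psis_right"
    # girdle / limbs
    ACROMION_LEFT = "acromion_left"
    ACROMION_RIGHT = "acromion_right"
    TROCHANTER_LEFT = "trochanter_left"
    TROCHANTER_RIGHT = "trochanter_right"
    MALLEOLUS_LEFT = "malleolus_left"
    MALLEOLUS_RIGHT = "malleolus_right"
    KNEE_LEFT = "knee_left"
    KNEE_RIGHT = "knee_right"
    ANKLE_LEFT = "ankle_left"
    ANKLE_RIGHT = "ankle_right"
    CALCANEUS_LEFT = "calcaneus_left"
    CALCANEUS_RIGHT = "calcaneus_right"
    ACHILLES_LEFT = "achilles_left"
    ACHILLES_RIGHT = "achilles_right"
    MID_CALF_LEFT = "mid_calf_left"
    MID_CALF_RIGHT = "mid_calf_right"
    # trunk contour points (frontal / back views)
    AXILLA_LEFT = "axilla_left"
    AXILLA_RIGHT = "axilla_right"
    SHOULDER_LEFT = "shoulder_left"
    SHOULDER_RIGHT = "shoulder_right"
    TRUNK_EDGE_AXILLA_LEFT = "trunk_edge_axilla_left"
    TRUNK_EDGE_AXILLA_RIGHT = "trunk_edge_axilla_right"
    TRUNK_EDGE_WAIST_LEFT = "trunk_edge_waist_left"
    TRUNK_EDGE_WAIST_RIGHT = "trunk_edge_waist_right"
    # contour tangent pairs (sagittal views)
    SACRAL_TANGENT_LOWER = "sacral_tangent_lower"
    SACRAL_TANGENT_UPPER = "sacral_tangent_upper"
    L5S1_TANGENT_LOWER = "l5s1_tangent_lower"
    L5S1_TANGENT_UPPER = "l5s1_tangent_upper"
    T12L1_TANGENT_LOWER = "t12l1_tangent_lower"
    T12L1_TANGENT_UPPER = "t12l1_tangent_upper"
    C7T1_TANGENT_LOWER = "c7t1_tangent_lower"
    C7T1_TANGENT_UPPER = "c7t1_tangent_upper"


def sided(stem: str, side: str) -> Landmark:
    """Resolve a sided landmark, e.g. sided('asis', 'LEFT') -> ASIS_LEFT."""
    return Landmark(f"{stem}_{side.lower()}")


#: Landmarks a sagittal view needs for the full nine-parameter profile.
#: Side-specific points use the viewed side.
def sagittal_required(view_side: str) -> frozenset[Landmark]:
    s = view_side.lower()
    return frozenset(
        {
            Landmark.SACRAL_TANGENT_LOWER,
            Landmark.SACRAL_TANGENT_UPPER,
            Landmark.L5S1_TANGENT_LOWER,
            Landmark.L5S1_TANGENT_UPPER,
            Landmark.T12L1_TANGENT_LOWER,
            Landmark.T12L1_TANGENT_UPPER,
            Landmark.C7T1_TANGENT_LOWER,
            Landmark.C7T1_TANGENT_UPPER,
            Landmark.C7,
            Landmark.NECK_THORAX_JUNCTION,
            Landmark.EAR,
            Landmark(f"asis_{s}"),
            Landmark(f"psis_{s}"),
            Landmark(f"malleolus_{s}"),
            Landmark(f"trochanter_{s}"),
            Landmark(f"acromion_{s}"),
        }
    )


FRONT_REQUIRED = frozenset(
    {
        Landmark.STERNAL_NOTCH,
        Landmark.NAVEL,
        Landmark.TRUNK_EDGE_AXILLA_LEFT,
        Landmark.TRUNK_EDGE_AXILLA_RIGHT,
        Landmark.TRUNK_EDGE_WAIST_LEFT,
        Landmark.TRUNK_EDGE_WAIST_RIGHT,
        Landmark.SHOULDER_LEFT,
        Landmark.SHOULDER_RIGHT,
        Landmark.AXILLA_LEFT,
        Landmark.AXILLA_RIGHT,
    }
)

BACK_REQUIRED = frozenset(
    {
        Landmark.C7,
        Landmark.GLUTEAL_CLEFT_TOP,
        Landmark.TRUNK_EDGE_AXILLA_LEFT,
        Landmark.TRUNK_EDGE_AXILLA_RIGHT,
        Landmark.TRUNK_EDGE_WAIST_LEFT,
        Landmark.TRUNK_EDGE_WAIST_RIGHT,
        Landmark.SHOULDER_LEFT,
        Landmark.SHOULDER_RIGHT,
        Landmark.AXILLA_LEFT,
        Landmark.AXILLA_RIGHT,
    }
)


def required_landmarks(view: View) -> frozenset[Landmark]:
    if view in (View.LEFT, View.RIGHT):
        return sagittal_required(view.value)
    return FRONT_REQUIRED if view is View.FRONT else BACK_REQUIRED


class ViewFormatError(ValueError):
    """The annotation file violates the view schema."""


@dataclass(frozen=True)
class AnnotatedView:
    """One photograph's landmarks, already in the canonical y-up frame."""

    view: View
    subject_id: str
    landmarks: Mapping[Landmark, Point2D]
    sex: str | None = None
    age_years: int | None = None
    frame: FrameConvention = FrameConvention()
    image_size: tuple[int, int] | None = None
    calibrated: bool = False

    def __getitem__(self, name: Landmark) -> Point2D:
        try:
            return self.landmarks[name]
        except KeyError:
            raise MissingLandmarkError(name, self.view) from None

    def __contains__(self, name: Landmark) -> bool:
        return name in self.landmarks

    def has(self, *names: Landmark) -> bool:
        return all(n in self.landmarks for n in names)


class MissingLandmarkError(KeyError):
    def __init__(self, name: Landmark, view: View):
        self.landmark = name
        super().__init__(f"landmark '{name.value}' absent from {view.value} view")

    def __str__(self) -> str:  # KeyError quotes its arg otherwise
        return self.args[0]


# ---------------------------------------------------------------------------
# view JSON I/O


def _transform_points(
    raw: dict[str, tuple[float, float]],
    image_size: tuple[int, int] | None,
    mirror_x: bool,
    vertical_pair: list[tuple[float, float]] | None,
) -> dict[str, Point2D]:
    pts = {}
    for name, (x, y) in raw.items():
        if image_size is not None:
            y = image_size[1] - y
        if mirror_x:
            x = -x
        pts[name] = (x, y)

    if vertical_pair is not None:
        (x1, y1), (x2, y2) = vertical_pair
        if image_size is not None:
            y1, y2 = image_size[1] - y1, image_size[1] - y2
        if mirror_x:
            x1, x2 = -x1, -x2
        dx, dy = x2 - x1, y2 - y1
        if dx == 0 and dy == 0:
            raise ViewFormatError("vertical_calibration points coincide")
        if dy < 0:  # orient the plumbline upward
            dx, dy = -dx, -dy
        tilt = math.atan2(dx, dy)  # rotation taking the pair onto +y
        c, s = math.cos(tilt), math.sin(tilt)
        pts = {n: (c * x - s * y, s * x + c * y) for n, (x, y) in pts.items()}
    return {n: Point2D(x, y) for n, (x, y) in pts.items()}


def read_view(path: str | Path, strict: bool = True) -> AnnotatedView:
    """Read an annotation file into the canonical frame.

    With ``strict`` (default), missing required landmarks raise
    :class:`ViewFormatError`; pass ``strict=False`` to load partial
    annotations (downstream computations then yield absent fields).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ViewFormatError(f"{path}: not valid JSON ({e})") from e
    return parse_view(doc, source=str(path), strict=strict)


def parse_view(doc: dict, source: str = "<dict>", strict: bool = True) -> AnnotatedView:
    if not isinstance(doc, dict):
        raise ViewFormatError(f"{source}: top level must be an object")
    schema = doc.get("schema")
    if schema != SCHEMA_ID:
        raise ViewFormatError(f"{source}: schema must be '{SCHEMA_ID}', got {schema!r}")
    try:
        view = View(doc["view"])
    except (KeyError, ValueError):
        raise ViewFormatError(
            f"{source}: 'view' must be one of FRONT/BACK/LEFT/RIGHT"
        ) from None
    subject_id = doc.get("subject_id")
    if not isinstance(subject_id, str) or not subject_id:
        raise ViewFormatError(f"{source}: 'subject_id' must be a non-empty string")
    sex = doc.get("sex")
    if sex is not None and sex not in ("F", "M"):
        raise ViewFormatError(f"{source}: 'sex' must be 'F' or 'M'")
    age = doc.get("age_years")
    if age is not None and (not isinstance(age, int) or age < 0):
        raise ViewFormatError(f"{source}: 'age_years' must be a non-negative integer")

    image_size = doc.get("image_size")
    if image_size is not None:
        if (
            not isinstance(image_size, (list, tuple))
            or len(image_size) != 2
            or not all(isinstance(v, (int, float)) and v > 0 for v in image_size)
        ):
            raise ViewFormatError(f"{source}: 'image_size' must be [width, height] > 0")
        image_size = (int(image_size[0]), int(image_size[1]))

    raw_landmarks = doc.get("landmarks")
    if not isinstance(raw_landmarks, dict):
        raise ViewFormatError(f"{source}: 'landmarks' must be an object")
    known = {lm.value for lm in Landmark}
    unknown = sorted(set(raw_landmarks) - known)
    if unknown:
        raise ViewFormatError(f"{source}: unknown landmark names: {', '.join(unknown)}")
    raw_pts: dict[str, tuple[float, float]] = {}
    bad = []
    for name, xy in raw_landmarks.items():
        if (
            not isinstance(xy, (list, tuple))
            or len(xy) != 2
            or not all(isinstance(v, (int, float)) and math.isfinite(v) for v in xy)
        ):
            bad.append(name)
            continue
        x, y = float(xy[0]), float(xy[1])
        if image_size is not None and not (0 <= x <= image_size[0] and 0 <= y <= image_size[1]):
            raise ViewFormatError(
                f"{source}: landmark '{name}' at ({x}, {y}) outside image bounds {image_size}"
            )
        raw_pts[name] = (x, y)
    if bad:
        raise ViewFormatError(
            f"{source}: landmarks must be finite [x, y] pairs: {', '.join(sorted(bad))}"
        )

    anterior = doc.get("anterior", "+x")
    if anterior not in ("+x", "-x"):
        raise ViewFormatError(f"{source}: 'anterior' must be '+x' or '-x'")
    # mirror so canonical +x = anterior (sagittal) or anatomical left (frontal).
    # A BACK photograph shows the subject's left on the image left, hence the flip.
    mirror_x = (anterior == "-x") if view in (View.LEFT, View.RIGHT) else (view is View.BACK)

    calib = doc.get("vertical_calibration")
    if calib is not None:
        if (
            not isinstance(calib, (list, tuple))
            or len(calib) != 2
            or not all(isinstance(p, (list, tuple)) and len(p) == 2 for p in calib)
        ):
            raise ViewFormatError(f"{source}: 'vertical_calibration' must be two [x, y] points")
        calib = [(float(p[0]), float(p[1])) for p in calib]

    points = _transform_points(raw_pts, image_size, mirror_x, calib)
    landmarks = {Landmark(n): p for n, p in points.items()}

    if strict:
        missing = sorted(lm.value for lm in required_landmarks(view) - set(landmarks))
        if missing:
            raise ViewFormatError(
                f"{source}: {view.value} view missing required landmarks: {', '.join(missing)}"
            )

    return AnnotatedView(
        view=view,
        subject_id=subject_id,
        landmarks=landmarks,
        sex=sex,
        age_years=age,
        image_size=image_size,
        calibrated=calib is not None,
    )


def write_view(v: AnnotatedView, path: str | Path) -> None:
    """Serialize a canonical-frame view (no pixel-convention round trip)."""
    doc = {
        "schema": SCHEMA_ID,
        "view": v.view.value,
        "subject_id": v.subject_id,
        "landmarks": {lm.value: [p.x, p.y] for lm, p in sorted(v.landmarks.items())},
    }
    if v.sex is not None:
        doc["sex"] = v.sex
    if v.age_years is not None:
        doc["age_years"] = v.age_years
    if v.view is View.BACK:
        # undo the canonical mirror so parse_view(write_view(v)) round-trips
        doc["landmarks"] = {n: [-x, y] for n, (x, y) in doc["landmarks"].items()}
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# QC validation (the pitfall catalogue as data, not exceptions)


@dataclass(frozen=True)
class QCFinding:
    code: str
    severity: str  # "error" blocks a computation, "warning" does not
    message: str
    blocks: tuple[str, ...] = ()  # parameter names made uncomputable


def validate_view(v: AnnotatedView) -> list[QCFinding]:
    """Screen a view for the common acquisition errors that corrupt measures.

    Findings are returned as data; nothing raises. An ``error``-severity
    finding means the listed parameters cannot be computed from this view.
    """
    findings: list[QCFinding] = []
    missing = sorted(lm.value for lm in required_landmarks(v.view) - set(v.landmarks))
    if missing:
        blocked: tuple[str, ...]
        if v.view is View.FRONT:
            blocked = ("ATSI",)
        elif v.view is View.BACK:
            blocked = ("POTSI",)
        else:
            blocked = ("sagittal profile",)
        findings.append(
            QCFinding(
                code="missing-landmarks",
                severity="error",
                message=f"missing landmarks: {', '.join(missing)}",
                blocks=blocked,
            )
        )
    if v.view is View.BACK and Landmark.GLUTEAL_CLEFT_TOP not in v:
        findings.append(
            QCFinding(
                code="gluteal-cleft-absent",
                severity="error",
                message=(
                    "gluteal cleft top not annotated (typically covered by "
                    "underpants): POTSI not computable"
                ),
                blocks=("POTSI",),
            )
        )
    if v.view in (View.FRONT, View.BACK) and v.has(
        Landmark.MALLEOLUS_LEFT, Landmark.MALLEOLUS_RIGHT
    ):
        ml, mr = v[Landmark.MALLEOLUS_LEFT], v[Landmark.MALLEOLUS_RIGHT]
        stature_scale = max(
            (abs(p.y - ml.y) for p in v.landmarks.values()), default=0.0
        )
        if abs(ml.x - mr.x) < 0.02 * max(stature_scale, 1.0):
            findings.append(
                QCFinding(
                    code="one-leg-stance",
                    severity="warning",
                    message=(
                        "malleoli nearly coincide horizontally: possible one-leg "
                        "stance, coronal symmetry unreliable"
                    ),
                )
            )
    if not v.calibrated:
        findings.append(
            QCFinding(
                code="no-vertical-calibration",
                severity="warning",
                message=(
                    "no vertical calibration pair: image columns assumed plumb "
                    "(camera must be level)"
                ),
            )
        )
    return findings


# ---------------------------------------------------------------------------
# measurement / cohort CSV I/O


@dataclass(frozen=True)
class MeasurementRecord:
    """One rating: a parameter value for (subject, rater, session)."""

    subject_id: str
    rater_id: str
    session_id: str
    parameter: str
    value: float


MEASUREMENT_HEADER = ["subject", "rater", "session", "parameter", "value"]


def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read the long-format repeated-measurements CSV."""
    records: list[MeasurementRecord] = []
    seen: set[tuple[str, str, str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != MEASUREMENT_HEADER:
            raise ValueError(
                f"{path}: header must be {','.join(MEASUREMENT_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            key = (row["subject"], row["rater"], row["session"], row["parameter"])
            if key in seen:
                raise ValueError(f"{path}:{i}: duplicate record key {key}")
            seen.add(key)
            try:
                value = float(row["value"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}:{i}: non-numeric value {row['value']!r}"
                ) from None
            if not math.isfinite(value):
                raise ValueError(f"{path}:{i}: non-finite value {row['value']!r}")
            records.append(MeasurementRecord(*key, value))
    return records


def write_measurements(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_HEADER)
        for r in records:
            writer.writerow(
                [r.subject_id, r.rater_id, r.session_id, r.parameter, repr(r.value)]
            )


@dataclass(frozen=True)
class CohortRecord:
    """One cohort observation for normative-table construction."""

    subject_id: str
    sex: str
    age_years: int
    parameter: str
    value: float


COHORT_HEADER = ["subject", "sex", "age", "parameter", "value"]


def read_cohort(path: str | Path) -> list[CohortRecord]:
    records: list[CohortRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != COHORT_HEADER:
            raise ValueError(
                f"{path}: header must be {','.join(COHORT_HEADER)}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            if row["sex"] not in ("F", "M"):
                raise ValueError(f"{path}:{i}: sex must be F or M")
            try:
                age = int(row["age"])
                value = float(row["value"])
            except (TypeError, ValueError):
                raise ValueError(f"{path}:{i}: malformed age/value") from None
            records.append(
                CohortRecord(row["subject"], row["sex"], age, row["parameter"], value)
            )
    return records


def write_cohort(records: Iterable[CohortRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_HEADER)
        for r in records:
            writer.writerow([r.subject_id, r.sex, r.age_years, r.parameter, repr(r.value)])
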