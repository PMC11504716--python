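"""Frankfurt-plane construction and the 36 cranial angles.

Two angle types are computed from 3D landmark coordinates:

* **line-plane** — the acute angle between a landmark-defined line and the
  Frankfurt horizontal (FH) plane, the standard reference plane through the
  left orbitale and both porions.  With line direction ``d`` and unit plane
  normal ``n`` the reported angle is ``90° − arccos(|d·n| / ‖d‖)``, i.e. the
  complement of the line-normal angle, in [0, 90].  The absolute value makes
  the result independent of normal orientation and landmark ordering.
* **three-point** — the vertex angle of the triangle spanned by three
  landmarks, from the Law of Cosines on the side lengths, in [0, 180].

Both are invariant under rotation, translation and uniform scaling of the
specimen.  Cosine arguments are clamped to [-1, 1]; clamping beyond 1e-12
indicates a degenerate configuration and is counted by the caller-visible
``ClampCounter``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landmarks import LandmarkSet

DEGREES = 180.0 / np.pi


class GeometryError(ValueError):
    """Degenerate landmark configuration (missing/collinear/coincident)."""


@dataclass(frozen=True)
class Plane:
    """Plane through ``point`` with unit ``normal``."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise GeometryError("plane normal must be a unit vector")

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal, float)


class ClampCounter:
    """Counts arccos-argument clamps; any clamp beyond tol is an error."""

    def __init__(self, tol: float = 1e-12):
        self.tol = tol
        self.count = 0

    def clamp(self, value: float) -> float:
        if abs(value) > 1.0:
            if abs(value) - 1.0 > self.tol:
                raise GeometryError(f"cosine argument {value!r} out of range beyond tolerance")
            self.count += 1
            return float(np.sign(value))
        return float(value)


_DEFAULT_COUNTER = ClampCounter()


def frankfurt_plane(s: LandmarkSet) -> Plane:
    """FH plane through left orbitale, left porion and right porion.

    The normal is canonicalized to have a non-negative z component (ties
    broken toward +y then +x); the canonical sign never affects angle values
    because line-plane angles use ``|d·n|``.
    """
    pts = {}
    for code, side in (("or", "left"), ("po", "left"), ("po", "right")):
        p = s.get(code, side)
        if p is None:
            raise GeometryError(f"FH plane needs landmark {code!r} ({side}); absent "
                                f"in specimen {s.specimen_id!r}")
        pts[(code, side)] = p
    a, b, c = pts[("or", "left")], pts[("po", "left")], pts[("po", "right")]
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n)
    if norm < 1e-9 * max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1.0):
        raise GeometryError("FH landmarks are collinear; plane undefined")
    n = n / norm
    for axis in (2, 1, 0):
        if abs(n[axis]) > 1e-12:
            if n[axis] < 0:
                n = -n
            break
    return Plane(tuple(a), tuple(n))


def line_plane_angle(a, b, plane: Plane, counter: ClampCounter | None = None) -> float:
    """Acute angle (degrees, [0, 90]) between line a→b and a plane."""
    counter = counter or _DEFAULT_COUNTER
    d = np.asarray(b, float) - np.asarray(a, float)
    nd = np.linalg.norm(d)
    if nd == 0.0:
        raise GeometryError("zero-length line direction")
    cos_to_normal = counter.clamp(abs(float(d @ plane.n)) / nd)
    return 90.0 - float(np.arccos(cos_to_normal)) * DEGREES


def three_point_angle(a, v, c, counter: ClampCounter | None = None) -> float:
    """Angle at vertex ``v`` (degrees, [0, 180]) via the Law of Cosines."""
    counter = counter or _DEFAULT_COUNTER
    a = np.asarray(a, float)
    v = np.asarray(v, float)
    c = np.asarray(c, float)
    va = np.linalg.norm(a - v)
    vc = np.linalg.norm(c - v)
    if va == 0.0 or vc == 0.0:
        raise GeometryError("triangle vertex coincides with an endpoint")
    ac = np.linalg.norm(c - a)
    cos_v = counter.clamp((va * va + vc * vc - ac * ac) / (2.0 * va * vc))
    return float(np.arccos(cos_v)) * DEGREES


# ---------------------------------------------------------------------------
# Angle registry
# ---------------------------------------------------------------------------

LINE_PLANE = "line_plane"
THREE_POINT = "three_point"


@dataclass(frozen=True)
class AngleDefinition:
    """One registered cranial angle before bilateral expansion.

    ``landmarks`` are (code, side) pairs; for three-point definitions the
    vertex is the middle entry.  ``laterality`` is one of midsagittal
    (single measurement from midline landmarks), transversal (single
    measurement spanning both sides), or bilateral (expands to an (R) and an
    (L) measurement with the side placeholder bound per side).
    """

    code: str
    kind: str
    landmarks: tuple[tuple[str, str], ...]
    laterality: str
    description: str = ""

    def expanded(self) -> list[tuple[str, tuple[tuple[str, str], ...]]]:
        """[(measurement name, bound (code, side) pairs)]; bilateral → R then L."""
        if self.laterality != "bilateral":
            return [(self.code, self.landmarks)]
        out = []
        for side, tag in (("right", "R"), ("left", "L")):
            bound = tuple((c, side if s == "*" else s) for c, s in self.landmarks)
            out.append((f"{self.code} ({tag})", bound))
        return out


def _mid(*codes: str) -> tuple[tuple[str, str], ...]:
    return tuple((c, "mid") for c in codes)


def _tv(right: str, vertex: str, left: str) -> tuple[tuple[str, str], ...]:
    # transversal: (right, midline vertex, left) ordering, fixed for reproducibility
    return ((right, "right"), (vertex, "mid"), (left, "left"))


_ANGLE_ROWS: list[AngleDefinition] = [
    # --- line-plane, midsagittal (14) ---
    AngleDefinition("n-b-FH", LINE_PLANE, _mid("n", "b"), "midsagittal", "frontal slope"),
    AngleDefinition("n-m-FH", LINE_PLANE, _mid("n", "m"), "midsagittal", "frontal profile"),
    AngleDefinition("ob-l-FH", LINE_PLANE, _mid("ob", "l"), "midsagittal", "parietal slope"),
    AngleDefinition("l-op-FH", LINE_PLANE, _mid("l", "op"), "midsagittal", "lambda-opisthocranion"),
    AngleDefinition("l-i-FH", LINE_PLANE, _mid("l", "i"), "midsagittal", "lambda-inion"),
    AngleDefinition("op-i-FH", LINE_PLANE, _mid("op", "i"), "midsagittal", "opisthocranion-inion"),
    AngleDefinition("ba-o-FH", LINE_PLANE, _mid("ba", "o"), "midsagittal", "foramen magnum tilt"),
    AngleDefinition("n-i-FH", LINE_PLANE, _mid("n", "i"), "midsagittal", "calotte-basis"),
    AngleDefinition("g-l-FH", LINE_PLANE, _mid("g", "l"), "midsagittal", "glabella-lambda"),
    AngleDefinition("g-i-FH", LINE_PLANE, _mid("g", "i"), "midsagittal", "glabella-inion"),
    AngleDefinition("n-pr-FH", LINE_PLANE, _mid("n", "pr"), "midsagittal", "facial profile"),
    AngleDefinition("n-ss-FH", LINE_PLANE, _mid("n", "ss"), "midsagittal", "nasal profile"),
    AngleDefinition("ss-pr-FH", LINE_PLANE, _mid("ss", "pr"), "midsagittal", "alveolar profile"),
    AngleDefinition("n-rhi-FH", LINE_PLANE, _mid("n", "rhi"), "midsagittal", "nasal bones slope"),
    # --- line-plane, bilateral (3 -> 6 measurements) ---
    AngleDefinition("zm-zo-FH", LINE_PLANE, (("zm", "*"), ("zo", "*")), "bilateral",
                    "zygomaticomaxillary suture tilt"),
    AngleDefinition("so-zo-FH", LINE_PLANE, (("so", "*"), ("zo", "*")), "bilateral",
                    "sagittal tilt of the orbit entrance"),
    AngleDefinition("ek-mf-FH", LINE_PLANE, (("ek", "*"), ("mf", "*")), "bilateral",
                    "horizontal tilt of the orbit entrance"),
    # --- three-point, midsagittal (9) ---
    AngleDefinition("n-m-b", THREE_POINT, _mid("n", "m", "b"), "midsagittal", "frontal curvature"),
    AngleDefinition("n-g-m", THREE_POINT, _mid("n", "g", "m"), "midsagittal", "glabellar"),
    AngleDefinition("l-op-i", THREE_POINT, _mid("l", "op", "i"), "midsagittal", "upper occipital"),
    AngleDefinition("pr-g-l", THREE_POINT, _mid("pr", "g", "l"), "midsagittal",
                    "prosthion-glabella-lambda"),
    AngleDefinition("n-pr-ba", THREE_POINT, _mid("n", "pr", "ba"), "midsagittal",
                    "facial triangle, vertex at prosthion"),
    AngleDefinition("g-n-rhi", THREE_POINT, _mid("g", "n", "rhi"), "midsagittal", "nasofrontal"),
    AngleDefinition("rhi-n-pr", THREE_POINT, _mid("rhi", "n", "pr"), "midsagittal",
                    "nasal bone projection vs upper facial height"),
    AngleDefinition("rhi-n-ss", THREE_POINT, _mid("rhi", "n", "ss"), "midsagittal",
                    "nasal bone projection vs nasal height"),
    AngleDefinition("n-mn-rhi", THREE_POINT, _mid("n", "mn", "rhi"), "midsagittal",
                    "nasal bone curvature"),
    # --- three-point, transversal (5) ---
    AngleDefinition("fmo-n-fmo", THREE_POINT, _tv("fmo", "n", "fmo"), "transversal", "nasomalar"),
    AngleDefinition("zm-ss-zm", THREE_POINT, _tv("zm", "ss", "zm"), "transversal", "zygomaxillary"),
    AngleDefinition("nm-rhi-nm", THREE_POINT, _tv("nm", "rhi", "nm"), "transversal",
                    "nasomaxillare-rhinion"),
    AngleDefinition("mf-n-mf", THREE_POINT, _tv("mf", "n", "mf"), "transversal", "maxillofrontal"),
    AngleDefinition("nl-ss-nl", THREE_POINT, _tv("nl", "ss", "nl"), "transversal", "nasolateral"),
    # --- three-point, bilateral (1 -> 2 measurements) ---
    AngleDefinition("po-ms-ast", THREE_POINT, (("po", "*"), ("ms", "*"), ("ast", "*")),
                    "bilateral", "mastoid, vertex at mastoidale"),
]


def build_angle_registry() -> tuple[AngleDefinition, ...]:
    """The fixed 32-definition registry expanding to 36 angle measurements."""
    return tuple(_ANGLE_ROWS)


def angle_measurement_names(registry: Sequence[AngleDefinition] | None = None) -> list[str]:
    regs = build_angle_registry() if registry is None else registry
    return [name for d in regs for name, _ in d.expanded()]


def export_angle_registry_json(path: str | Path) -> None:
    payload = [
        {"code": d.code, "kind": d.kind, "laterality": d.laterality,
         "landmarks": [list(lm) for lm in d.landmarks], "description": d.description}
        for d in build_angle_registry()
    ]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# Angle table assembly
# ---------------------------------------------------------------------------

@dataclass
class AngleTable:
    """Specimens × 36 angle measurements (degrees; NaN marks absent)."""

    frame: pd.DataFrame  # index specimen_id, float columns per measurement
    sex: pd.Series       # aligned with frame.index; values male/female/None

    @property
    def angle_columns(self) -> list[str]:
        return list(self.frame.columns)

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "sex", self.sex)
        out.to_csv(path, index_label="specimen_id", float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AngleTable":
        raw = pd.read_csv(path, index_col="specimen_id", float_precision="round_trip")
        sex = raw.pop("sex") if "sex" in raw.columns else pd.Series(index=raw.index, dtype=object)
        sex = sex.where(sex.isin(["male", "female"]), None)
        return cls(raw.astype(float), sex)


def compute_specimen_angles(
    s: LandmarkSet, counter: ClampCounter | None = None
) -> tuple[dict[str, float], dict[str, str]]:
    """All 36 measurements for one specimen; absent angles are omitted.

    Returns (values, absence reasons).  An angle is absent iff a required
    landmark is missing, or — for line-plane angles — the FH plane cannot be
    constructed.
    """
    values: dict[str, float] = {}
    reasons: dict[str, str] = {}
    fh: Plane | None = None
    fh_error: str | None = None
    try:
        fh = frankfurt_plane(s)
    except GeometryError as exc:
        fh_error = str(exc)

    for definition in build_angle_registry():
        for name, bound in definition.expanded():
            pts = []
            missing = None
            for code, side in bound:
                p = s.get(code, side)
                if p is None:
                    missing = f"missing landmark {code} ({side})"
                    break
                pts.append(p)
            if missing:
                reasons[name] = missing
                continue
            if definition.kind == LINE_PLANE:
                if fh is None:
                    reasons[name] = f"FH plane unavailable: {fh_error}"
                    continue
                values[name] = line_plane_angle(pts[0], pts[1], fh, counter)
            else:
                values[name] = three_point_angle(pts[0], pts[1], pts[2], counter)
    return values, reasons


def compute_angle_table(
    specimens: Iterable[LandmarkSet], counter: ClampCounter | None = None
) -> AngleTable:
    """Assemble the specimens × 36 angle feature matrix (degrees)."""
    names = angle_measurement_names()
    rows, sexes, ids = [], [], []
    for s in specimens:
        vals, _ = compute_specimen_angles(s, counter)
        rows.append([vals.get(n, np.nan) for n in names])
        sexes.append(s.sex)
        ids.append(s.specimen_id)
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="specimen_id"), columns=names, dtype=float)
    return AngleTable(frame, pd.Series(sexes, index=frame.index, name="sex"))


#: Angle measurements that require the prosthion landmark.
PROSTHION_ANGLES = ("n-pr-FH", "ss-pr-FH", "pr-g-l", "n-pr-ba", "rhi-n-pr")
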