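"""Cranial landmark registry, coordinate I/O, and acquisition-error assessment.

The registry covers the 26 named cranial landmarks used throughout the
package: 14 midsagittal points, 11 bilateral pairs, and the orbitale, which
by convention is acquired on the left side only.  Expanding bilateral
landmarks to their two sides yields 37 point slots per specimen.

Coordinates are Cartesian, in millimetres.  Missing landmarks are
first-class: a specimen simply lacks the (code, side) entry — they are never
encoded as zeros or NaN coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree

import numpy as np
import pandas as pd

MIDSAGITTAL = "midsagittal"
BILATERAL = "bilateral"
LEFT_ONLY = "left_only"

SIDES = ("mid", "left", "right")


@dataclass(frozen=True)
class LandmarkSpec:
    """One named cranial landmark and its laterality."""

    code: str
    full_name: str
    definition: str
    laterality: str  # midsagittal | bilateral | left_only

    @property
    def sides(self) -> tuple[str, ...]:
        if self.laterality == MIDSAGITTAL:
            return ("mid",)
        if self.laterality == LEFT_ONLY:
            return ("left",)
        return ("left", "right")


_REGISTRY_ROWS = [
    # midsagittal
    ("n", "nasion", "intersection of the frontonasal suture and the median plane", MIDSAGITTAL),
    ("b", "bregma", "intersection of the coronal and sagittal sutures", MIDSAGITTAL),
    ("g", "glabella", "most anterior midline point at the supraorbital ridge level", MIDSAGITTAL),
    ("m", "metopion", "midline point on the line joining the frontal eminences", MIDSAGITTAL),
    ("ob", "obelion", "sagittal-suture point on the line joining the parietal foramina", MIDSAGITTAL),
    ("l", "lambda", "intersection of the sagittal and lambdoid sutures", MIDSAGITTAL),
    ("op", "opisthocranion", "most posterior midline point of the occipital, farthest from glabella", MIDSAGITTAL),
    ("i", "inion", "midline intersection of the superior nuchal lines", MIDSAGITTAL),
    ("ba", "basion", "midpoint of the anterior margin of the foramen magnum", MIDSAGITTAL),
    ("o", "opisthion", "midpoint of the posterior margin of the foramen magnum", MIDSAGITTAL),
    ("rhi", "rhinion", "internasal suture at the margin of the piriform aperture", MIDSAGITTAL),
    ("ss", "subspinale", "deepest point on the intermaxillary suture below the anterior nasal spine", MIDSAGITTAL),
    ("pr", "prosthion", "most anterior midline point of the upper alveolar process", MIDSAGITTAL),
    ("mn", "midnasale", "deepest midline point on the nasal bones", MIDSAGITTAL),
    # bilateral
    ("fmo", "frontomalare orbitale", "zygomaticofrontal suture at the lateral orbital margin", BILATERAL),
    ("ast", "asterion", "meeting point of lambdoid, parietomastoid and occipitomastoid sutures", BILATERAL),
    ("ms", "mastoidale", "most inferior point of the mastoid process", BILATERAL),
    ("mf", "maxillofrontale", "frontomaxillary suture at the medial orbital margin", BILATERAL),
    ("ek", "ektokonchion", "lateral orbital margin opposite maxillofrontale, parallel to the superior margin", BILATERAL),
    ("so", "supraorbitale", "most superior point of the superior orbital margin", BILATERAL),
    ("zo", "zygoorbitale", "zygomaxillary suture at the inferior orbital margin", BILATERAL),
    ("nl", "nasolaterale", "most lateral point on the margin of the piriform aperture", BILATERAL),
    ("zm", "zygomaxillare", "most inferior point of the zygomaticomaxillary suture", BILATERAL),
    ("nm", "nasomaxillare", "nasomaxillary suture at the margin of the piriform aperture", BILATERAL),
    ("po", "porion", "most superior point on the margin of the external auditory meatus", BILATERAL),
    # left only (digitized on the left side by convention)
    ("or", "orbitale", "most inferior point of the inferior orbital margin", LEFT_ONLY),
]


def build_landmark_registry() -> tuple[LandmarkSpec, ...]:
    """Return the fixed cranial landmark registry (26 specs, 37 point slots)."""
    return tuple(LandmarkSpec(*row) for row in _REGISTRY_ROWS)


_REGISTRY = build_landmark_registry()
_SPEC_BY_CODE: dict[str, LandmarkSpec] = {s.code: s for s in _REGISTRY}


def registry_slots(registry: Sequence[LandmarkSpec] | None = None) -> list[tuple[str, str]]:
    """All (code, side) slots obtained by expanding the registry; length 37."""
    regs = _REGISTRY if registry is None else registry
    return [(s.code, side) for s in regs for side in s.sides]


class LandmarkError(ValueError):
    """Raised on invalid landmark codes, sides, or malformed input files."""


@dataclass(frozen=True)
class LandmarkPoint:
    code: str
    side: str  # mid | left | right
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        spec = _SPEC_BY_CODE.get(self.code)
        if spec is None:
            raise LandmarkError(f"unknown landmark code {self.code!r}")
        if self.side not in spec.sides:
            raise LandmarkError(
                f"side {self.side!r} invalid for landmark {self.code!r} "
                f"(laterality {spec.laterality}; allowed: {spec.sides})"
            )
        if len(self.xyz) != 3 or not all(math.isfinite(v) for v in self.xyz):
            raise LandmarkError(f"non-finite coordinates for {self.code!r}: {self.xyz}")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class LandmarkSet:
    """All digitized points of one specimen, keyed by (code, side)."""

    specimen_id: str
    sex: str | None = None  # "male" | "female" | None
    points: dict[tuple[str, str], LandmarkPoint] = field(default_factory=dict)
    source: str = ""

    def add(self, point: LandmarkPoint) -> None:
        key = (point.code, point.side)
        if key in self.points:
            raise LandmarkError(
                f"duplicate landmark {point.code!r} side {point.side!r} "
                f"for specimen {self.specimen_id!r}"
            )
        self.points[key] = point

    def get(self, code: str, side: str = "mid") -> np.ndarray | None:
        pt = self.points.get((code, side))
        return None if pt is None else pt.array

    def has(self, code: str, side: str = "mid") -> bool:
        return (code, side) in self.points

    @property
    def completeness(self) -> tuple[int, int]:
        """(present, expected) over the 37 registry slots."""
        slots = registry_slots()
        return sum(1 for k in slots if k in self.points), len(slots)

    def missing_slots(self) -> list[tuple[str, str]]:
        return [k for k in registry_slots() if k not in self.points]

    def transformed(self, fn) -> "LandmarkSet":
        """New set with every coordinate mapped through ``fn(xyz-array) -> xyz``."""
        out = LandmarkSet(self.specimen_id, self.sex, {}, self.source)
        for pt in self.points.values():
            new = np.asarray(fn(pt.array), dtype=float)
            out.add(LandmarkPoint(pt.code, pt.side, tuple(new)))
        return out


@dataclass
class AcquisitionTrialSet:
    """Repeated digitizations of the same specimen, for intraobserver error."""

    specimen_id: str
    trials: list[LandmarkSet]

    def __post_init__(self) -> None:
        if len(self.trials) < 2:
            raise LandmarkError("need at least 2 acquisition trials")
        for t in self.trials:
            if t.specimen_id != self.specimen_id:
                raise LandmarkError(
                    f"trial specimen {t.specimen_id!r} != {self.specimen_id!r}"
                )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["specimen_id", "sex", "landmark", "side", "x", "y", "z"]


def read_landmarks_csv(path: str | Path) -> list[LandmarkSet]:
    """Read specimen landmark coordinates from the documented CSV format.

    Columns: specimen_id, sex, landmark, side, x, y, z (header required,
    coordinates in mm).  Unknown codes and duplicate (specimen, code, side)
    rows are rejected with the offending line number; landmarks simply not
    listed for a specimen are recorded as absent.
    """
    frame = pd.read_csv(path, dtype={"specimen_id": str, "sex": str, "landmark": str, "side": str},
                        float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise LandmarkError(f"{path}: missing required columns {missing}")
    sets: dict[str, LandmarkSet] = {}
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        sid = row["specimen_id"]
        sex = row["sex"] if isinstance(row["sex"], str) and row["sex"] else None
        if sex is not None and sex not in ("male", "female"):
            raise LandmarkError(f"{path}:{line}: sex must be male/female, got {sex!r}")
        if sid not in sets:
            sets[sid] = LandmarkSet(sid, sex, {}, source=str(path))
        elif sex is not None and sets[sid].sex is None:
            sets[sid].sex = sex
        try:
            pt = LandmarkPoint(row["landmark"], row["side"],
                               (float(row["x"]), float(row["y"]), float(row["z"])))
            sets[sid].add(pt)
        except (LandmarkError, ValueError, TypeError) as exc:
            raise LandmarkError(f"{path}:{line}: {exc}") from exc
    return list(sets.values())


def write_landmarks_csv(sets: Iterable[LandmarkSet], path: str | Path) -> None:
    """Write LandmarkSets in the format :func:`read_landmarks_csv` reads.

    Coordinates are written with 17 significant digits (shortest exact
    double representation or better) so a round trip is bit-exact.
    """
    rows = []
    for s in sets:
        for (code, side), pt in sorted(s.points.items()):
            x, y, z = pt.xyz
            rows.append({"specimen_id": s.specimen_id, "sex": s.sex or "",
                         "landmark": code, "side": side, "x": x, "y": y, "z": z})
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# MeshLab picked-points (.pp) I/O
# ---------------------------------------------------------------------------

def default_pp_aliases() -> dict[str, tuple[str, str]]:
    """Default mapping from picked-point names to (code, side).

    Covers ``code`` for midsagittal, ``code_L`` / ``code_R`` for bilateral
    landmarks, and both ``or`` and ``or_L`` for the left-only orbitale.
    """
    aliases: dict[str, tuple[str, str]] = {}
    for spec in _REGISTRY:
        if spec.laterality == MIDSAGITTAL:
            aliases[spec.code] = (spec.code, "mid")
        elif spec.laterality == LEFT_ONLY:
            aliases[spec.code] = (spec.code, "left")
            aliases[f"{spec.code}_L"] = (spec.code, "left")
        else:
            aliases[f"{spec.code}_L"] = (spec.code, "left")
            aliases[f"{spec.code}_R"] = (spec.code, "right")
    return aliases


def load_pp_aliases(path: str | Path) -> dict[str, tuple[str, str]]:
    """Load a user alias table from JSON: {"name": ["code", "side"], ...}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {name: (code, side) for name, (code, side) in raw.items()}


def read_picked_points(
    path: str | Path,
    aliases: Mapping[str, tuple[str, str]] | None = None,
    specimen_id: str | None = None,
    sex: str | None = None,
) -> LandmarkSet:
    """Parse a MeshLab picked-points XML file into a LandmarkSet."""
    aliases = default_pp_aliases() if aliases is None else dict(aliases)
    tree = ElementTree.parse(path)
    out = LandmarkSet(specimen_id or Path(path).stem, sex, {}, source=str(path))
    for node in tree.getroot().iter("point"):
        name = node.get("name")
        if name is None:
            raise LandmarkError(f"{path}: <point> without name attribute")
        if name not in aliases:
            valid = ", ".join(sorted(aliases))
            raise LandmarkError(f"{path}: unmappable point name {name!r}; valid names: {valid}")
        code, side = aliases[name]
        xyz = tuple(float(node.get(axis)) for axis in ("x", "y", "z"))
        out.add(LandmarkPoint(code, side, xyz))
    return out


def write_picked_points(s: LandmarkSet, path: str | Path) -> None:
    root = ElementTree.Element("PickedPoints")
    rev = {v: k for k, v in default_pp_aliases().items()}
    for (code, side), pt in sorted(s.points.items()):
        name = rev.get((code, side), code if side == "mid" else f"{code}_{side[0].upper()}")
        x, y, z = pt.xyz
        ElementTree.SubElement(root, "point", name=name,
                               x=f"{x:.17g}", y=f"{y:.17g}", z=f"{z:.17g}")
    ElementTree.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# Geometry helpers on LandmarkSets
# ---------------------------------------------------------------------------

_PLANES = {"x=0": 0, "y=0": 1, "z=0": 2}
_SWAP = {"left": "right", "right": "left", "mid": "mid"}


def mirror_landmark_set(s: LandmarkSet, plane: str = "y=0") -> LandmarkSet:
    """Reflect all coordinates across a coordinate plane and swap L/R labels.

    Mirroring twice restores the original set.  Note the orbitale, a
    left-only landmark, maps onto a right-side slot under mirroring and is
    dropped with all other slots that do not exist in the registry expansion.
    """
    if plane not in _PLANES:
        raise LandmarkError(f"plane must be one of {sorted(_PLANES)}, got {plane!r}")
    axis = _PLANES[plane]
    out = LandmarkSet(s.specimen_id, s.sex, {}, source=s.source)
    for pt in s.points.values():
        xyz = list(pt.xyz)
        xyz[axis] = -xyz[axis]
        new_side = _SWAP[pt.side]
        if new_side not in _SPEC_BY_CODE[pt.code].sides:
            continue  # e.g. mirrored orbitale has no right-side slot
        out.add(LandmarkPoint(pt.code, new_side, tuple(xyz)))
    return out


def intraobserver_error(
    trial_set: AcquisitionTrialSet, per_axis: bool = False
) -> pd.DataFrame:
    """Per-landmark digitization error (mm) across repeated acquisition trials.

    The error of a landmark is the standard deviation of its trial
    positions: the square root of the sum over the three axes of the
    sample variance (divisor n-1) of the trial coordinates.  Equivalently,
    the root mean squared Euclidean deviation from the trial centroid under
    the sample-variance convention.  Landmarks present in fewer than two
    trials are reported with NaN error and ``assessable = False``.

    With ``per_axis=True``, additional sd_x/sd_y/sd_z columns report the
    per-axis standard deviations whose squares sum to ``error_mm ** 2``.
    """
    rows = []
    all_keys = sorted({k for t in trial_set.trials for k in t.points})
    for code, side in all_keys:
        coords = np.array([t.points[(code, side)].xyz
                           for t in trial_set.trials if (code, side) in t.points])
        row: dict[str, object] = {"landmark": code, "side": side, "n_trials": len(coords)}
        if len(coords) < 2:
            row.update(error_mm=np.nan, assessable=False)
            if per_axis:
                row.update(sd_x=np.nan, sd_y=np.nan, sd_z=np.nan)
        else:
            var = coords.var(axis=0, ddof=1)
            row.update(error_mm=float(np.sqrt(var.sum())), assessable=True)
            if per_axis:
                sd = np.sqrt(var)
                row.update(sd_x=sd[0], sd_y=sd[1], sd_z=sd[2])
        rows.append(row)
    return pd.DataFrame(rows)
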