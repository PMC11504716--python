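"""Synthetic data generation for the cranial-angle sex-estimation pipeline.

The study's CT-derived coordinates are not publicly deposited, so this
module provides two generators with the statistical structure the analysis
assumes:

* :func:`generate_angle_table` draws specimens × 36 angle tables directly
  from per-sex normal distributions whose moments come from the packaged
  reference statistics (per-sex mean/SD/min/max/n for every angle).
* :func:`generate_landmark_sets` emits full 37-landmark specimens from
  calibrated per-sex mean landmark templates plus digitization noise and a
  random rigid transform, so the geometry stage can be exercised end to end.

The templates are synthetic: per-sex mean configurations fitted by least
squares so that each sex's template reproduces the reference per-sex mean
angles.  They make no claim of anatomical accuracy beyond producing angles
in plausible ranges with the observed direction of sexual dimorphism
(e.g. the male glabellar angle n-g-m is smaller, the male occipital
protrusion angle op-i-FH larger, than the female ones).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import PROSTHION_ANGLES, AngleTable, angle_measurement_names
from .landmarks import LandmarkPoint, LandmarkSet

MALE, FEMALE = "male", "female"

#: Sample sizes of the reference study (males / females).
DEFAULT_N_MALE, DEFAULT_N_FEMALE = 154, 180
#: Prosthion missingness observed in the reference statistics.
DEFAULT_MISSING_PR = {MALE: (154 - 136) / 154, FEMALE: (180 - 166) / 180}


class FixtureError(RuntimeError):
    """Packaged fixture missing or failing its checksum."""


@dataclass(frozen=True)
class AngleMoments:
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class AngleSexStats:
    code: str
    male: AngleMoments
    female: AngleMoments
    p_text: str
    test: str  # "t" | "U"

    @property
    def p_below(self) -> float:
        """Numeric upper bound of the printed p-value."""
        t = self.p_text
        return float(t[1:]) if t.startswith("<") else float(t)

    def significant(self, alpha: float = 0.05) -> bool:
        t = self.p_text
        if t.startswith("<"):
            return float(t[1:]) <= alpha
        return float(t) < alpha


@dataclass(frozen=True)
class AngleDistributionSpec:
    """Reference per-sex angle distributions (the packaged transcription)."""

    angles: Mapping[str, AngleSexStats]

    def __getitem__(self, code: str) -> AngleSexStats:
        return self.angles[code]

    def codes(self) -> list[str]:
        return list(self.angles)

    def significant_codes(self, alpha: float = 0.05) -> list[str]:
        return [c for c, a in self.angles.items() if a.significant(alpha)]


def _read_data(name: str) -> dict:
    ref = resources.files("cranangles.data").joinpath(name)
    if not ref.is_file():
        raise FixtureError(f"packaged fixture {name!r} not found")
    return json.loads(ref.read_text(encoding="utf-8"))


def load_reference_stats() -> AngleDistributionSpec:
    """Load the packaged per-sex angle reference statistics, verifying checksum."""
    payload = _read_data("angle_reference_stats.json")
    canon = json.dumps(payload["angles"], sort_keys=True, separators=(",", ":"))
    digest = hashlib.sha256(canon.encode()).hexdigest()
    if digest != payload["sha256"]:
        raise FixtureError("angle reference fixture failed checksum verification")
    angles = {}
    for row in payload["angles"]:
        angles[row["code"]] = AngleSexStats(
            code=row["code"],
            male=AngleMoments(**row["male"]),
            female=AngleMoments(**row["female"]),
            p_text=row["p_text"],
            test=row["test"],
        )
    if sorted(angles) != sorted(angle_measurement_names()):
        raise FixtureError("angle reference fixture does not cover the 36-angle registry")
    return AngleDistributionSpec(angles)


def load_reference_ai_subsets() -> dict[str, list[str]]:
    """Reference attribute-importance subsets (for comparison, never selection)."""
    return dict(_read_data("reference_ai_subsets.json")["subsets"])


def load_landmark_templates() -> dict[str, dict[tuple[str, str], np.ndarray]]:
    """Calibrated per-sex mean landmark templates, keyed (code, side) -> xyz."""
    payload = _read_data("synthetic_landmark_templates.json")
    out: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for sex in (MALE, FEMALE):
        pts = {}
        for key, xyz in payload[sex].items():
            code, side = key.split("|")
            pts[(code, side)] = np.asarray(xyz, dtype=float)
        out[sex] = pts
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the reference study: 154 males / 180 females, prosthion
    missing in 18/154 males and 14/180 females, independent
    angles (inter-angle correlations are not published), full-strength sex
    differences.  ``effect_scale`` interpolates the per-sex means toward the
    pooled mean; 0 gives the null (identical sex distributions).
    """

    n_male: int = DEFAULT_N_MALE
    n_female: int = DEFAULT_N_FEMALE
    correlation: str | float | np.ndarray = "independent"
    effect_scale: float = 1.0
    missing_pr_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_PR))
    truncate: bool = False
    seed: int = 0
    # landmark-level generation only:
    noise_sd: float = 0.3      # isotropic digitization noise per axis, mm
    rigid_transform: bool = True

    def __post_init__(self) -> None:
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        for sex, rate in self.missing_pr_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing_pr_rate[{sex}] outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _covariance(sds: np.ndarray, correlation) -> np.ndarray:
    k = len(sds)
    if isinstance(correlation, str):
        if correlation != "independent":
            raise ValueError(f"unknown correlation mode {correlation!r}")
        corr = np.eye(k)
    elif np.isscalar(correlation):
        rho = float(correlation)
        corr = np.full((k, k), rho) + (1 - rho) * np.eye(k)
    else:
        corr = np.asarray(correlation, float)
        if corr.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
    cov = corr * np.outer(sds, sds)
    # feasibility check: Cholesky fails on non-PSD input
    try:
        np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive semi-definite") from exc
    return cov


# ---------------------------------------------------------------------------
# Angle-table generator
# ---------------------------------------------------------------------------

def generate_angle_table(
    spec: AngleDistributionSpec | None = None,
    config: SyntheticConfig | None = None,
) -> AngleTable:
    """Draw a synthetic specimens × 36 angle table from the reference moments.

    Per sex, angle vectors are multivariate normal with the reference
    per-sex means and SDs and the configured correlation structure.  With
    ``truncate=True`` draws are redrawn per cell (independent case) or
    clipped (correlated case) to the printed min/max.  Sex differences are
    scaled by ``effect_scale``; prosthion-dependent angles are set absent at
    the configured per-sex rates.
    """
    spec = spec or load_reference_stats()
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    codes = spec.codes()
    mean = {s: np.array([getattr(spec[c], s).mean for c in codes]) for s in (MALE, FEMALE)}
    sd = {s: np.array([getattr(spec[c], s).sd for c in codes]) for s in (MALE, FEMALE)}
    lo = {s: np.array([getattr(spec[c], s).min for c in codes]) for s in (MALE, FEMALE)}
    hi = {s: np.array([getattr(spec[c], s).max for c in codes]) for s in (MALE, FEMALE)}
    n_total = {MALE: config.n_male, FEMALE: config.n_female}
    w = (config.n_male * mean[MALE] + config.n_female * mean[FEMALE]) / (
        config.n_male + config.n_female)

    blocks, sexes, ids = [], [], []
    for sex, prefix in ((MALE, "M"), (FEMALE, "F")):
        n = n_total[sex]
        mu = w + config.effect_scale * (mean[sex] - w)
        cov = _covariance(sd[sex], config.correlation)
        draws = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
        if config.truncate:
            independent = isinstance(config.correlation, str)
            shift = mu - mean[sex]  # keep truncation window centred on the scaled mean
            lo_s, hi_s = lo[sex] + shift, hi[sex] + shift
            if independent:
                for _ in range(200):
                    bad = (draws < lo_s) | (draws > hi_s)
                    if not bad.any():
                        break
                    redraw = rng.normal(mu, sd[sex], size=draws.shape)
                    draws[bad] = redraw[bad]
            draws = np.clip(draws, lo_s, hi_s)
        # prosthion missingness
        n_missing = int(round(config.missing_pr_rate.get(sex, 0.0) * n))
        missing_rows = rng.choice(n, size=n_missing, replace=False)
        for col in PROSTHION_ANGLES:
            draws[missing_rows, codes.index(col)] = np.nan
        blocks.append(draws)
        sexes += [sex] * n
        ids += [f"{prefix}{i + 1:04d}" for i in range(n)]

    frame = pd.DataFrame(np.vstack(blocks), index=pd.Index(ids, name="specimen_id"),
                         columns=codes, dtype=float)
    return AngleTable(frame, pd.Series(sexes, index=frame.index, name="sex"))


# ---------------------------------------------------------------------------
# Landmark-level generator
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # uniform over SO(3) via QR of a Gaussian matrix with sign fix
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_landmark_sets(config: SyntheticConfig | None = None) -> list[LandmarkSet]:
    """Generate full 37-landmark specimens from the calibrated sex templates.

    Each specimen is ``neutral ± effect_scale · displacement`` (plus for
    males, minus for females) where ``neutral`` is the midpoint of the two
    calibrated templates and ``displacement`` half their difference, with
    isotropic Gaussian digitization noise of ``noise_sd`` mm per coordinate
    and, optionally, a random rigid transform.  Prosthion is dropped at the
    configured per-sex rates, so downstream prosthion angles come out absent
    exactly as in incomplete real material.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    templates = load_landmark_templates()
    slots = sorted(templates[MALE])
    male_arr = np.array([templates[MALE][k] for k in slots])
    female_arr = np.array([templates[FEMALE][k] for k in slots])
    neutral = (male_arr + female_arr) / 2.0
    disp = (male_arr - female_arr) / 2.0

    out: list[LandmarkSet] = []
    for sex, prefix, n, sign in ((MALE, "M", config.n_male, +1.0),
                                 (FEMALE, "F", config.n_female, -1.0)):
        n_missing = int(round(config.missing_pr_rate.get(sex, 0.0) * n))
        missing_rows = set(rng.choice(n, size=n_missing, replace=False).tolist())
        for i in range(n):
            coords = neutral + sign * config.effect_scale * disp
            coords = coords + rng.normal(0.0, config.noise_sd, size=coords.shape)
            if config.rigid_transform:
                rot = _random_rotation(rng)
                shift = rng.uniform(-100.0, 100.0, size=3)
                coords = coords @ rot.T + shift
            s = LandmarkSet(f"{prefix}{i + 1:04d}", sex, {}, source="synthetic")
            for (code, side), xyz in zip(slots, coords):
                if code == "pr" and i in missing_rows:
                    continue
                s.add(LandmarkPoint(code, side, tuple(xyz)))
            out.append(s)
    return out
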