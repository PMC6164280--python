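"""Body-dimension measurement, distance-dependent correction, and deviations.

Heights (withers, back, waist, chest top/bottom) are perpendicular distances
from picked landmark points to the RANSAC ground plane; body length is the
distance between the ground-plane projections of the shoulder point and the
pin bone; chest depth is the height difference between the chest top and the
brisket bottom.

Time-of-flight range measurements understate true dimensions by a factor that
depends on the photographic distance d (the scene's mean sensor range to the
subject).  The correction model is a multiplicative scale s(d) — a polynomial
of degree ≤ 2 in d fitted by least squares to (d, true/raw) ratio
observations gathered from calibration objects (spheres, cuboids) of known
size scanned at several distances.  Corrected dimension = raw × s(d).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import PlaneModel

logger = logging.getLogger("bovimetry")

__all__ = [
    "DIMENSION_NAMES",
    "PICK_NAMES",
    "BodyPicks",
    "CorrectionModel",
    "BodyDimensions",
    "DeviationReport",
    "measure_height",
    "measure_length",
    "fit_correction",
    "apply_correction",
    "compute_body_dimensions",
    "deviation_report",
]

DIMENSION_NAMES = (
    "withers_height", "chest_depth", "back_height", "body_length", "waist_height",
)
PICK_NAMES = (
    "withers_top", "chest_top", "chest_bottom", "back_top", "waist_top",
    "shoulder_point", "pin_bone",
)


@dataclass
class BodyPicks:
    """Named landmark coordinates (metres) plus the scene's photographic distance."""

    picks: dict[str, np.ndarray]
    photographic_distance: float

    def __post_init__(self) -> None:
        missing = [n for n in PICK_NAMES if n not in self.picks]
        if missing:
            raise ValueError(f"missing picks: {', '.join(missing)}")
        self.picks = {k: np.asarray(v, dtype=np.float64).reshape(3) for k, v in self.picks.items()}
        for name, p in self.picks.items():
            if not np.isfinite(p).all():
                raise ValueError(f"pick {name!r} is not finite")
        if self.photographic_distance <= 0:
            raise ValueError("photographic_distance must be positive")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.picks[name]

    @classmethod
    def from_json(cls, path, photographic_distance: float) -> "BodyPicks":
        return cls(json.loads(Path(path).read_text()), photographic_distance)


@dataclass
class CorrectionModel:
    """Multiplicative range correction s(d) = Σ coeffs[k]·d^(deg−k).

    ``coeffs`` are highest-degree-first polynomial coefficients (degree ≤ 2);
    ``calibrated_range`` is the span of distances seen during fitting, and
    ``residual_rms`` the root-mean-square of the ratio-fit residuals.
    """

    coeffs: np.ndarray
    calibrated_range: tuple[float, float] = (1.5, 3.0)
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64).reshape(-1)
        if len(self.coeffs) > 3:
            raise ValueError("correction polynomial degree must be <= 2")
        lo, hi = self.calibrated_range
        grid = np.linspace(lo, hi, 64)
        if (np.polyval(self.coeffs, grid) <= 0).any():
            raise ValueError("s(d) must stay positive over the calibrated range")

    @classmethod
    def identity(cls) -> "CorrectionModel":
        return cls(np.array([1.0]))

    def scale(self, d: float) -> float:
        return float(np.polyval(self.coeffs, d))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "format": "bovimetry-correction-model",
            "coeffs": self.coeffs.tolist(),
            "calibrated_range": list(self.calibrated_range),
            "residual_rms": self.residual_rms,
        }))

    @classmethod
    def load(cls, path) -> "CorrectionModel":
        p = json.loads(Path(path).read_text())
        if p.get("format") != "bovimetry-correction-model":
            raise ValueError(f"{path} is not a correction model file")
        return cls(np.array(p["coeffs"]), tuple(p["calibrated_range"]), p["residual_rms"])


@dataclass
class BodyDimensions:
    """The five body dimensions, raw and after range correction (metres)."""

    raw: dict[str, float]
    corrected: dict[str, float]
    photographic_distance: float

    def __post_init__(self) -> None:
        for d in (self.raw, self.corrected):
            missing = [n for n in DIMENSION_NAMES if n not in d]
            if missing:
                raise ValueError(f"missing dimensions: {missing}")
            bad = [n for n in DIMENSION_NAMES if d[n] <= 0]
            if bad:
                raise ValueError(f"non-positive dimensions: {bad}")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dimension": list(DIMENSION_NAMES),
            "raw_m": [self.raw[n] for n in DIMENSION_NAMES],
            "corrected_m": [self.corrected[n] for n in DIMENSION_NAMES],
        })


@dataclass
class DeviationReport:
    """Per-dimension relative deviations (%) of raw and corrected values."""

    table: pd.DataFrame = field(repr=False)

    @property
    def max_final_deviation(self) -> float:
        return float(self.table["final_dev_pct"].max())

    @property
    def min_final_deviation(self) -> float:
        return float(self.table["final_dev_pct"].min())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def measure_height(point, ground: PlaneModel) -> float:
    """Perpendicular distance from a pick to the ground plane, metres."""
    return float(ground.distance(np.asarray(point, dtype=np.float64))[0])


def measure_length(p1, p2, ground: PlaneModel) -> float:
    """Horizontal extent: distance between the picks' ground-plane projections."""
    q1 = ground.project(np.asarray(p1, dtype=np.float64))[0]
    q2 = ground.project(np.asarray(p2, dtype=np.float64))[0]
    length = float(np.linalg.norm(q1 - q2))
    if length < 1e-12:
        warnings.warn("picks project to the same ground point; length is zero")
    return length


def fit_correction(observations) -> CorrectionModel:
    """Fit the multiplicative scale s(d) to (distance, raw, true) observations.

    The response is the per-observation ratio true/raw.  The polynomial degree
    is min(2, number of distinct distances − 1), so three distances determine
    a quadratic exactly and two a straight line.
    """
    obs = [(float(d), float(raw), float(true)) for d, raw, true in observations]
    if len(obs) < 3:
        raise ValueError("need at least 3 observations")
    d = np.array([o[0] for o in obs])
    ratio = np.array([o[2] / o[1] for o in obs])
    n_dist = len(np.unique(np.round(d, 9)))
    if n_dist < 2:
        raise ValueError(
            "calibration needs observations at >= 2 distinct distances; "
            "scan the objects at more ranges"
        )
    degree = min(2, n_dist - 1)
    coeffs = np.polyfit(d, ratio, degree)
    resid = ratio - np.polyval(coeffs, d)
    model = CorrectionModel(
        coeffs,
        calibrated_range=(float(d.min()), float(d.max())),
        residual_rms=float(np.sqrt((resid ** 2).mean())),
    )
    logger.info("fit_correction: degree %d, residual rms %.2e", degree, model.residual_rms)
    return model


def apply_correction(model: CorrectionModel, raw: float, d: float) -> float:
    """Corrected dimension = raw × s(d); warns when d leaves the fitted range."""
    if raw <= 0:
        raise ValueError("raw dimension must be positive")
    lo, hi = model.calibrated_range
    if not (lo <= d <= hi):
        warnings.warn(
            f"photographic distance {d:.3f} m outside calibrated range [{lo:.3f}, {hi:.3f}]"
        )
    return raw * model.scale(d)


def compute_body_dimensions(
    picks: BodyPicks, ground: PlaneModel, model: CorrectionModel | None = None
) -> BodyDimensions:
    """The five body dimensions from landmark picks against the ground datum."""
    model = model or CorrectionModel.identity()
    raw = {
        "withers_height": measure_height(picks["withers_top"], ground),
        "chest_depth": abs(
            measure_height(picks["chest_top"], ground)
            - measure_height(picks["chest_bottom"], ground)
        ),
        "back_height": measure_height(picks["back_top"], ground),
        "body_length": measure_length(picks["shoulder_point"], picks["pin_bone"], ground),
        "waist_height": measure_height(picks["waist_top"], ground),
    }
    d = picks.photographic_distance
    corrected = {k: apply_correction(model, v, d) for k, v in raw.items()}
    return BodyDimensions(raw, corrected, d)


def deviation_report(measured: BodyDimensions, manual: dict[str, float]) -> DeviationReport:
    """Relative deviations (%) of raw and corrected values vs manual references.

    deviation% = 100 · |measured − manual| / manual, per dimension and stage.
    """
    rows = []
    for name in DIMENSION_NAMES:
        ref = manual[name]
        if ref <= 0:
            raise ValueError(f"manual reference for {name} must be positive")
        rows.append({
            "dimension": name,
            "manual_m": ref,
            "initial_m": measured.raw[name],
            "corrected_m": measured.corrected[name],
            "initial_dev_pct": 100.0 * abs(measured.raw[name] - ref) / ref,
            "final_dev_pct": 100.0 * abs(measured.corrected[name] - ref) / ref,
        })
    return DeviationReport(pd.DataFrame(rows))
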