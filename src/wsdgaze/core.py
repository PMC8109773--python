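"""Core domain types and trial-level preprocessing for fixation-report data.

Coordinate conventions
----------------------
All coordinates are continuous reals in pixel space with the origin at the
top-left corner, x increasing rightward and y increasing downward.  Raw
tracker exports are in *screen* pixels; analysis happens in *image* pixels
after offset correction (the stimulus is displayed centered, at native
resolution, on a larger screen).  No integer snapping is ever applied.

Visual angle is converted at a fixed rate (default 60 px per degree,
appropriate for a 24-inch 1920x1080 monitor viewed from 95 cm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeometryConfig",
    "Fixation",
    "Trial",
    "Dataset",
    "QCReport",
    "screen_to_image",
    "image_to_screen",
    "deg_to_px",
    "px_to_deg",
    "drift_correct",
    "drift_correct_dataset",
    "filter_trials",
    "zscore_ratings",
]

#: discard reason codes used by :func:`filter_trials`
REASON_SHORT = "short_fixation_time"
REASON_DRIFT = "drift_outlier"


@dataclass(frozen=True)
class GeometryConfig:
    """Display geometry: screen size, stimulus size and the px/degree rate.

    The stimulus image is assumed to be displayed centered on the screen at
    native resolution, so the screen->image offset is derived, not stored.
    """

    pixels_per_degree: float = 60.0
    screen_size: tuple[float, float] = (1920.0, 1080.0)
    image_size: tuple[float, float] = (1600.0, 900.0)

    def __post_init__(self) -> None:
        if not self.pixels_per_degree > 0:
            raise ValueError("pixels_per_degree must be positive")
        sw, sh = self.screen_size
        iw, ih = self.image_size
        if iw <= 0 or ih <= 0 or sw <= 0 or sh <= 0:
            raise ValueError("screen and image sizes must be positive")
        if iw > sw or ih > sh:
            raise ValueError("image must fit inside the screen")

    @property
    def image_offset(self) -> tuple[float, float]:
        """Top-left corner of the centered image, in screen pixels."""
        sw, sh = self.screen_size
        iw, ih = self.image_size
        return ((sw - iw) / 2.0, (sh - ih) / 2.0)

    @property
    def image_center(self) -> tuple[float, float]:
        iw, ih = self.image_size
        return (iw / 2.0, ih / 2.0)

    def deg_to_px(self, degrees: float | np.ndarray) -> float | np.ndarray:
        return np.multiply(degrees, self.pixels_per_degree)

    def px_to_deg(self, pixels: float | np.ndarray) -> float | np.ndarray:
        return np.divide(pixels, self.pixels_per_degree)


def deg_to_px(degrees, geom: GeometryConfig):
    """Convert visual degrees to pixels (default 1 degree = 60 px)."""
    return geom.deg_to_px(degrees)


def px_to_deg(pixels, geom: GeometryConfig):
    """Convert pixels to visual degrees; exact inverse of :func:`deg_to_px`."""
    return geom.px_to_deg(pixels)


@dataclass(frozen=True)
class Fixation:
    """A single fixation event within a trial (image-pixel coordinates)."""

    index: int
    x: float
    y: float
    duration_ms: float

    def __post_init__(self) -> None:
        if not self.duration_ms > 0:
            raise ValueError("fixation duration must be positive")


class Trial:
    """Ordered fixations of one participant viewing one image.

    Fixations are stored internally as flat numpy arrays (``indices``,
    ``xy``, ``durations``) for speed; the :attr:`fixations` property exposes
    them as :class:`Fixation` objects.  The first fixation of each trial (the
    one with the lowest index) is carried over from clicking the central dot
    before stimulus onset and is excluded from every metric, but it is kept
    in storage so drift correction stays re-derivable.
    """

    __slots__ = (
        "participant_id",
        "image_id",
        "condition",
        "rating",
        "rating_z",
        "indices",
        "xy",
        "durations",
        "drift_vector",
        "drift_magnitude_deg",
        "discarded",
        "discard_reasons",
    )

    def __init__(
        self,
        participant_id: str,
        image_id: str,
        *,
        condition: str | None = None,
        rating: float | None = None,
        indices: Sequence[int] | np.ndarray = (),
        xy: np.ndarray | Sequence = (),
        durations: Sequence[float] | np.ndarray = (),
        drift_vector: tuple[float, float] | None = None,
        drift_magnitude_deg: float | None = None,
        discarded: bool = False,
        discard_reasons: tuple[str, ...] = (),
        rating_z: float = float("nan"),
    ) -> None:
        self.participant_id = participant_id
        self.image_id = image_id
        self.condition = condition
        self.rating = rating
        self.rating_z = rating_z
        self.indices = np.asarray(indices, dtype=int).reshape(-1)
        self.xy = np.asarray(xy, dtype=float).reshape(-1, 2) if len(self.indices) else np.empty((0, 2))
        self.durations = np.asarray(durations, dtype=float).reshape(-1)
        if not (len(self.indices) == len(self.xy) == len(self.durations)):
            raise ValueError("indices, xy and durations must have equal length")
        if len(self.indices) != len(set(self.indices.tolist())):
            raise ValueError("fixation indices must be unique within a trial")
        if np.any(self.durations <= 0):
            raise ValueError("fixation durations must be positive")
        self.drift_vector = drift_vector
        self.drift_magnitude_deg = drift_magnitude_deg
        self.discarded = discarded
        self.discard_reasons = tuple(discard_reasons)

    @classmethod
    def from_fixations(cls, participant_id: str, image_id: str, fixations: Iterable[Fixation], **kw) -> "Trial":
        fx = list(fixations)
        return cls(
            participant_id,
            image_id,
            indices=[f.index for f in fx],
            xy=[(f.x, f.y) for f in fx],
            durations=[f.duration_ms for f in fx],
            **kw,
        )

    @property
    def n_fixations(self) -> int:
        return len(self.indices)

    @property
    def fixations(self) -> list[Fixation]:
        return [
            Fixation(int(i), float(x), float(y), float(d))
            for i, (x, y), d in zip(self.indices, self.xy, self.durations)
        ]

    def _analyzable_mask(self) -> np.ndarray:
        """All fixations except the first (lowest index)."""
        if self.n_fixations == 0:
            return np.zeros(0, dtype=bool)
        return self.indices != self.indices.min()

    @property
    def analyzable_xy(self) -> np.ndarray:
        return self.xy[self._analyzable_mask()]

    @property
    def analyzable_durations(self) -> np.ndarray:
        return self.durations[self._analyzable_mask()]

    @property
    def total_analyzable_ms(self) -> float:
        return float(self.analyzable_durations.sum())

    def copy(self, **overrides) -> "Trial":
        kw = dict(
            condition=self.condition,
            rating=self.rating,
            rating_z=self.rating_z,
            indices=self.indices,
            xy=self.xy,
            durations=self.durations,
            drift_vector=self.drift_vector,
            drift_magnitude_deg=self.drift_magnitude_deg,
            discarded=self.discarded,
            discard_reasons=self.discard_reasons,
        )
        kw.update(overrides)
        return Trial(self.participant_id, self.image_id, **kw)

    def shifted(self, vector: Sequence[float]) -> "Trial":
        """Return a copy with every fixation translated by ``vector``."""
        v = np.asarray(vector, dtype=float).reshape(2)
        return self.copy(xy=self.xy + v)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Trial({self.participant_id!r}, {self.image_id!r}, "
            f"n_fix={self.n_fixations}, discarded={self.discarded})"
        )


@dataclass
class Dataset:
    """A collection of trials sharing one display geometry."""

    trials: list[Trial]
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def __post_init__(self) -> None:
        keys = [(t.participant_id, t.image_id) for t in self.trials]
        if len(keys) != len(set(keys)):
            raise ValueError("(participant_id, image_id) pairs must be unique")

    @property
    def retained_trials(self) -> list[Trial]:
        return [t for t in self.trials if not t.discarded]

    @property
    def condition_map(self) -> dict[str, str | None]:
        out: dict[str, str | None] = {}
        for t in self.trials:
            out.setdefault(t.image_id, t.condition)
        return out

    def map_trials(self, fn) -> "Dataset":
        return Dataset([fn(t) for t in self.trials], self.geometry)

    def to_fixation_frame(self, retained_only: bool = False) -> pd.DataFrame:
        """Long table with one row per fixation (all fixations, incl. first)."""
        trials = self.retained_trials if retained_only else self.trials
        parts = []
        for t in trials:
            n = t.n_fixations
            parts.append(
                pd.DataFrame(
                    {
                        "participant_id": [t.participant_id] * n,
                        "image_id": [t.image_id] * n,
                        "fixation_index": t.indices,
                        "x": t.xy[:, 0],
                        "y": t.xy[:, 1],
                        "duration_ms": t.durations,
                        "condition": [t.condition] * n,
                        "rating": [t.rating] * n,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(
                columns=[
                    "participant_id", "image_id", "fixation_index",
                    "x", "y", "duration_ms", "condition", "rating",
                ]
            )
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# coordinate transforms


def _as_points(points) -> tuple[np.ndarray, bool]:
    arr = np.asarray(points, dtype=float)
    single = arr.ndim == 1
    return arr.reshape(-1, 2), single


def screen_to_image(points, geom: GeometryConfig):
    """Translate screen-pixel points into image-pixel coordinates.

    Points outside the image are allowed and preserved (never clipped):
    drift correction can legitimately move gaze past the stimulus edge.
    """
    arr, single = _as_points(points)
    out = arr - np.asarray(geom.image_offset)
    return out[0] if single else out


def image_to_screen(points, geom: GeometryConfig):
    """Inverse of :func:`screen_to_image`; exact round trip."""
    arr, single = _as_points(points)
    out = arr + np.asarray(geom.image_offset)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# drift correction


def drift_correct(trial: Trial, dot_location, geom: GeometryConfig) -> Trial:
    """Anchor a trial on the pre-stimulus required fixation point.

    The first fixation of the trial (lowest index) is taken to sit on the
    central dot, so every fixation is translated by
    ``dot_location - first_fixation``; the applied vector and its magnitude
    in visual degrees are recorded on the returned trial.
    """
    if trial.n_fixations == 0:
        raise ValueError("cannot drift-correct a trial with no fixations")
    dot = np.asarray(dot_location, dtype=float).reshape(2)
    first = trial.xy[np.argmin(trial.indices)]
    vec = dot - first
    mag_deg = float(geom.px_to_deg(np.hypot(*vec)))
    out = trial.shifted(vec)
    out.drift_vector = (float(vec[0]), float(vec[1]))
    out.drift_magnitude_deg = mag_deg
    return out


def drift_correct_dataset(dataset: Dataset, dot_location=None) -> Dataset:
    """Drift-correct every trial; the dot defaults to the image center."""
    if dot_location is None:
        dot_location = dataset.geometry.image_center
    return dataset.map_trials(lambda t: drift_correct(t, dot_location, dataset.geometry))


# ---------------------------------------------------------------------------
# trial-level quality filtering


@dataclass
class QCReport:
    """Per-trial discard status plus dataset-level summary counts."""

    table: pd.DataFrame
    n_total: int
    n_discarded: int
    n_short: int
    n_drift: int
    drift_mean_deg: float
    drift_sd_deg: float
    per_participant: pd.Series

    @property
    def discard_fraction(self) -> float:
        return self.n_discarded / self.n_total if self.n_total else 0.0


def filter_trials(
    dataset: Dataset,
    min_fixation_ms: float = 3000.0,
    drift_sd_cutoff: float = 3.0,
) -> tuple[Dataset, QCReport]:
    """Flag low-quality trials after drift correction.

    A trial is discarded when its total fixation time excluding the first
    fixation is strictly less than ``min_fixation_ms`` (half of a 6-second
    display by default), or when its drift-correction magnitude exceeds
    ``mean + drift_sd_cutoff * SD`` of the magnitudes pooled across all
    trials (sample SD, n-1 denominator).  A trial can carry both reason
    codes.  Trials are flagged, not dropped, so the QC decision stays
    auditable; downstream stages use :attr:`Dataset.retained_trials`.
    """
    mags = np.array(
        [t.drift_magnitude_deg for t in dataset.trials if t.drift_magnitude_deg is not None],
        dtype=float,
    )
    use_drift = np.isfinite(drift_sd_cutoff)
    if len(mags) < 2 and use_drift:
        warnings.warn(
            "fewer than 2 drift-corrected trials: drift-outlier criterion skipped",
            stacklevel=2,
        )
        use_drift = False
    if len(mags) >= 2:
        drift_mean = float(mags.mean())
        drift_sd = float(mags.std(ddof=1))
    else:
        drift_mean = float(mags.mean()) if len(mags) else float("nan")
        drift_sd = float("nan")
    threshold = drift_mean + drift_sd_cutoff * drift_sd if use_drift else np.inf

    new_trials: list[Trial] = []
    rows = []
    for t in dataset.trials:
        reasons: list[str] = []
        total = t.total_analyzable_ms
        if total < min_fixation_ms:
            reasons.append(REASON_SHORT)
        if (
            use_drift
            and t.drift_magnitude_deg is not None
            and t.drift_magnitude_deg > threshold
        ):
            reasons.append(REASON_DRIFT)
        new_trials.append(t.copy(discarded=bool(reasons), discard_reasons=tuple(reasons)))
        rows.append(
            {
                "participant_id": t.participant_id,
                "image_id": t.image_id,
                "total_analyzable_ms": total,
                "drift_magnitude_deg": t.drift_magnitude_deg,
                "discarded": bool(reasons),
                "reasons": ";".join(reasons),
            }
        )
    table = pd.DataFrame(rows)
    n_total = len(table)
    n_disc = int(table["discarded"].sum()) if n_total else 0
    per_part = (
        table.groupby("participant_id")["discarded"].sum().astype(int)
        if n_total
        else pd.Series(dtype=int)
    )
    report = QCReport(
        table=table,
        n_total=n_total,
        n_discarded=n_disc,
        n_short=int(table["reasons"].str.contains(REASON_SHORT).sum()) if n_total else 0,
        n_drift=int(table["reasons"].str.contains(REASON_DRIFT).sum()) if n_total else 0,
        drift_mean_deg=drift_mean,
        drift_sd_deg=drift_sd,
        per_participant=per_part,
    )
    return Dataset(new_trials, dataset.geometry), report


# ---------------------------------------------------------------------------
# rating standardization


def zscore_ratings(dataset: Dataset) -> Dataset:
    """Standardize ratings within each participant (sample SD, n-1).

    Participants with fewer than two distinct non-missing ratings get
    missing standardized values (with a warning): a constant rating carries
    no within-participant information.  Only retained trials enter the
    mean/SD; discarded trials inherit missing values.
    """
    by_part: dict[str, list[float]] = {}
    for t in dataset.retained_trials:
        if t.rating is not None and np.isfinite(t.rating):
            by_part.setdefault(t.participant_id, []).append(float(t.rating))

    stats: dict[str, tuple[float, float]] = {}
    for pid, vals in by_part.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 2 or arr.std(ddof=1) == 0.0:
            warnings.warn(
                f"participant {pid!r}: rating SD undefined or zero; "
                "z-scored ratings set to missing",
                stacklevel=2,
            )
            stats[pid] = (float("nan"), float("nan"))
        else:
            stats[pid] = (float(arr.mean()), float(arr.std(ddof=1)))

    def _z(t: Trial) -> Trial:
        if (
            t.discarded
            or t.rating is None
            or not np.isfinite(t.rating)
            or t.participant_id not in stats
        ):
            return t.copy(rating_z=float("nan"))
        m, s = stats[t.participant_id]
        z = (float(t.rating) - m) / s if np.isfinite(s) else float("nan")
        return t.copy(rating_z=z)

    return dataset.map_trials(_z)
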