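"""CSV readers/writers for every pipeline artifact, plus run configuration.

All artifacts are plain CSV (UTF-8, '.' decimal, no locale dependence) —
POI definitions in particular need only three columns (image name and the
two coordinates), which makes them trivial to share and version.  Pixel
coordinates are 0-based with the origin at the top-left corner.  Every
writer can stamp a ``# key=value`` comment header (used by the CLI to embed
the resolved-config hash); readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Dataset, GeometryConfig, Trial
from .metrics import EllipseAOI, KernelConfig, POI
from .noise import NoiseConfig
from .poi import GmmSettings
from .saliency import SaliencyMap
from .simulate import GeneratorConfig

__all__ = [
    "read_fixations",
    "write_fixations",
    "read_aois",
    "write_aois",
    "read_pois",
    "write_pois",
    "read_saliency_map",
    "write_saliency_map",
    "read_manual_overrides",
    "write_table",
    "read_table",
    "write_processed",
    "read_processed",
    "RunConfig",
]

FIXATION_COLUMNS = ["participant_id", "image_id", "fixation_index", "x", "y", "duration_ms"]
AOI_COLUMNS = ["image_id", "label", "cx", "cy", "a", "b", "theta_rad"]
POI_COLUMNS = ["image_name", "x_coordinate", "y_coordinate"]


class FormatError(ValueError):
    """A file does not match its declared CSV dialect."""


def _read_csv(path, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{name} file {path} is missing required column(s): "
            + ", ".join(repr(c) for c in missing)
        )
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str], path, name: str) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.values)[0]) + 2  # header is line 1
            raise FormatError(
                f"{name} file {path}: non-numeric value in column {c!r} at line {line}"
            )
        df[c] = coerced
    return df


def _write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write any tabular artifact (metric table, model results, robustness)."""
    _write_csv(df, path, header_comment)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# fixation reports


def read_fixations(path, geometry: GeometryConfig | None = None) -> Dataset:
    """Read a fixation report CSV into a Dataset (one row per fixation).

    Required columns: participant_id, image_id, fixation_index, x, y,
    duration_ms.  Optional: condition, rating.  Coordinates may be screen or
    image pixels depending on pipeline stage; the file does not distinguish.
    """
    df = _read_csv(path, FIXATION_COLUMNS, "fixation")
    df = _require_numeric(df, ["fixation_index", "x", "y", "duration_ms"], path, "fixation")
    geometry = geometry or GeometryConfig()
    trials: list[Trial] = []
    for (pid, img), grp in df.groupby(["participant_id", "image_id"], sort=True):
        cond = grp["condition"].iloc[0] if "condition" in grp else None
        cond = None if pd.isna(cond) else str(cond)
        rating = grp["rating"].iloc[0] if "rating" in grp else None
        rating = None if rating is None or pd.isna(rating) else float(rating)
        trials.append(
            Trial(
                str(pid),
                str(img),
                condition=cond,
                rating=rating,
                indices=grp["fixation_index"].to_numpy(int),
                xy=grp[["x", "y"]].to_numpy(float),
                durations=grp["duration_ms"].to_numpy(float),
            )
        )
    return Dataset(trials, geometry)


def write_fixations(dataset: Dataset, path, header_comment: str | None = None) -> None:
    df = dataset.to_fixation_frame()
    _write_csv(df, path, header_comment)


# ---------------------------------------------------------------------------
# AOI / POI definitions


def read_aois(path) -> list[EllipseAOI]:
    df = _read_csv(path, AOI_COLUMNS, "AOI")
    df = _require_numeric(df, ["cx", "cy", "a", "b", "theta_rad"], path, "AOI")
    return [
        EllipseAOI(
            str(r.image_id), str(r.label), (float(r.cx), float(r.cy)),
            (float(r.a), float(r.b)), float(r.theta_rad),
        )
        for r in df.itertuples()
    ]


def write_aois(aois: list[EllipseAOI], path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "image_id": a.image_id, "label": a.label,
                "cx": a.center[0], "cy": a.center[1],
                "a": a.semi_axes[0], "b": a.semi_axes[1], "theta_rad": a.rotation,
            }
            for a in aois
        ],
        columns=AOI_COLUMNS,
    )
    _write_csv(df, path, header_comment)


def read_pois(path) -> list[POI]:
    """Read a POI CSV: three mandatory columns (image name, x, y).

    Optional ``label`` and ``provenance`` columns are honored; absent labels
    default to the row number so each POI stays uniquely addressable.
    """
    df = _read_csv(path, POI_COLUMNS, "POI")
    df = _require_numeric(df, ["x_coordinate", "y_coordinate"], path, "POI")
    out = []
    for i, r in enumerate(df.itertuples()):
        label = str(getattr(r, "label")) if "label" in df.columns and pd.notna(getattr(r, "label")) else f"poi{i}"
        prov = str(getattr(r, "provenance")) if "provenance" in df.columns and pd.notna(getattr(r, "provenance")) else "manual"
        out.append(POI(str(r.image_name), label, float(r.x_coordinate), float(r.y_coordinate), prov))
    return out


def write_pois(pois: list[POI], path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "image_name": p.image_id,
                "x_coordinate": p.x,
                "y_coordinate": p.y,
                "label": p.label,
                "provenance": p.provenance,
            }
            for p in pois
        ],
        columns=POI_COLUMNS + ["label", "provenance"],
    )
    _write_csv(df, path, header_comment)


def read_manual_overrides(path) -> dict[tuple[str, str], int | None]:
    """Read a manual component-match override table.

    Columns: image_id, label, component_index (empty = force the AOI-center
    fallback).  Used to reproduce by-hand component-to-AOI matching.
    """
    df = _read_csv(path, ["image_id", "label", "component_index"], "override")
    out: dict[tuple[str, str], int | None] = {}
    for r in df.itertuples():
        comp = None if pd.isna(r.component_index) else int(r.component_index)
        out[(str(r.image_id), str(r.label))] = comp
    return out


# ---------------------------------------------------------------------------
# saliency maps


def read_saliency_map(path, image_id: str | None = None) -> SaliencyMap:
    """Read a dense saliency grid (CSV matrix, or .npy for bulk storage)."""
    path = Path(path)
    if path.suffix == ".npy":
        grid = np.load(path)
    else:
        grid = np.loadtxt(path, delimiter=",")
    return SaliencyMap(image_id=image_id or path.stem, grid=grid)


def write_saliency_map(smap: SaliencyMap, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npy":
        np.save(path, smap.grid)
    else:
        np.savetxt(path, smap.grid, delimiter=",")


# ---------------------------------------------------------------------------
# processed datasets (corrected + QC-flagged) persisted across CLI stages


def write_processed(dataset: Dataset, directory, header_comment: str | None = None) -> None:
    """Persist a corrected dataset as two CSVs (fixations + trial metadata)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fixations(dataset, directory / "fixations_corrected.csv", header_comment)
    rows = []
    for t in dataset.trials:
        dv = t.drift_vector or (np.nan, np.nan)
        rows.append(
            {
                "participant_id": t.participant_id,
                "image_id": t.image_id,
                "condition": t.condition,
                "rating": t.rating,
                "rating_z": t.rating_z,
                "drift_dx": dv[0],
                "drift_dy": dv[1],
                "drift_magnitude_deg": t.drift_magnitude_deg,
                "discarded": t.discarded,
                "reasons": ";".join(t.discard_reasons),
            }
        )
    _write_csv(pd.DataFrame(rows), directory / "trials.csv", header_comment)


def read_processed(directory, geometry: GeometryConfig | None = None) -> Dataset:
    directory = Path(directory)
    ds = read_fixations(directory / "fixations_corrected.csv", geometry)
    meta = pd.read_csv(directory / "trials.csv", comment="#", float_precision="round_trip")
    meta_by_key = {
        (str(r.participant_id), str(r.image_id)): r for r in meta.itertuples()
    }
    trials = []
    for t in ds.trials:
        r = meta_by_key.get((t.participant_id, t.image_id))
        if r is None:
            trials.append(t)
            continue
        reasons = tuple(str(r.reasons).split(";")) if isinstance(r.reasons, str) and r.reasons else ()
        trials.append(
            t.copy(
                rating_z=float(r.rating_z) if pd.notna(r.rating_z) else float("nan"),
                drift_vector=(float(r.drift_dx), float(r.drift_dy))
                if pd.notna(r.drift_dx)
                else None,
                drift_magnitude_deg=float(r.drift_magnitude_deg)
                if pd.notna(r.drift_magnitude_deg)
                else None,
                discarded=bool(r.discarded),
                discard_reasons=reasons,
            )
        )
    return Dataset(trials, ds.geometry)


# ---------------------------------------------------------------------------
# run configuration


def _dataclass_from_mapping(cls, mapping: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise FormatError(
            f"unknown key(s) in config section {section!r}: {sorted(unknown)}"
        )
    return cls(**mapping)


@dataclass
class RunConfig:
    """Resolved configuration for a CLI run; unknown keys are rejected."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    gmm: GmmSettings = field(default_factory=GmmSettings)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    master_seed: int = 0
    log_level: str = "INFO"

    _SECTIONS = {
        "geometry": GeometryConfig,
        "kernel": KernelConfig,
        "gmm": GmmSettings,
        "noise": NoiseConfig,
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        known = set(cls._SECTIONS) | {"generator", "master_seed", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown top-level config key(s): {sorted(unknown)}")
        kw: dict = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in raw:
                sect = dict(raw[name])
                for key in ("screen_size", "image_size", "sd_deg", "alphas"):
                    if key in sect and isinstance(sect[key], list):
                        sect[key] = tuple(sect[key])
                kw[name] = _dataclass_from_mapping(section_cls, sect, name)
        if "generator" in raw:
            sect = dict(raw["generator"])
            if "geometry" in sect:
                sect["geometry"] = _dataclass_from_mapping(
                    GeometryConfig,
                    {k: tuple(v) if isinstance(v, list) else v for k, v in sect["geometry"].items()},
                    "generator.geometry",
                )
            if "conditions" in sect and isinstance(sect["conditions"], list):
                sect["conditions"] = tuple(sect["conditions"])
            if "condition_violence" in sect:
                sect["condition_violence"] = tuple(
                    (str(k), float(v)) for k, v in sect["condition_violence"]
                )
            kw["generator"] = _dataclass_from_mapping(GeneratorConfig, sect, "generator")
        if "master_seed" in raw:
            kw["master_seed"] = int(raw["master_seed"])
        if "log_level" in raw:
            kw["log_level"] = str(raw["log_level"])
        cfg = cls(**kw)
        # geometry is shared: the generator inherits the top-level geometry
        if "geometry" in kw and "generator" not in raw:
            cfg.generator = replace(cfg.generator, geometry=cfg.geometry)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return clean(
            {
                "geometry": asdict(self.geometry),
                "kernel": asdict(self.kernel),
                "gmm": asdict(self.gmm),
                "noise": asdict(self.noise),
                "generator": asdict(self.generator),
                "master_seed": self.master_seed,
                "log_level": self.log_level,
            }
        )

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
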