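"""Kernel-weighted physical-saliency covariates for AOIs and POIs.

Saliency maps are *inputs*: dense per-pixel grids produced by any published
saliency algorithm (the study behind this package used Graph-Based Visual
Saliency).  This module only aggregates them: the same kernel weights used
for the fixation metrics — the ellipse indicator for an AOI, the rounded
peak-normalized Gaussian for a POI — are applied to each pixel's saliency
and summed, then normalized by the total saliency of the image, yielding a
scalar covariate in [0, 1] that enters the statistical models.

Pixel centers sit at integer coordinates: ``grid[y, x]`` is the saliency of
the pixel centered at (x, y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import GeometryConfig
from .metrics import EllipseAOI, KernelConfig, POI

__all__ = ["SaliencyMap", "weighted_saliency", "make_toy_saliency", "saliency_table"]


@dataclass
class SaliencyMap:
    """Dense nonnegative per-pixel saliency grid for one image (H x W)."""

    image_id: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("saliency grid must be 2-D (H x W)")
        if np.any(self.grid < 0):
            raise ValueError("saliency must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]


def _poi_window(
    poi: POI, sigma_px: float, decimals: int, shape: tuple[int, int]
) -> tuple[slice, slice]:
    """Pixel window outside which the rounded kernel weight is exactly 0.

    The weight rounds to zero once exp(-d^2/(2 sigma^2)) < 0.5 * 10^-decimals,
    i.e. beyond d = sigma * sqrt(2 * ln(2 * 10^decimals)).
    """
    h, w = shape
    r = sigma_px * math.sqrt(2.0 * math.log(2.0 * 10.0**decimals)) + 1.0
    x0 = max(int(math.floor(poi.x - r)), 0)
    x1 = min(int(math.ceil(poi.x + r)) + 1, w)
    y0 = max(int(math.floor(poi.y - r)), 0)
    y1 = min(int(math.ceil(poi.y + r)) + 1, h)
    return slice(y0, y1), slice(x0, x1)


def weighted_saliency(
    smap: SaliencyMap,
    target: EllipseAOI | POI,
    kcfg: KernelConfig | None = None,
    geom: GeometryConfig | None = None,
    *,
    round_weights: bool = True,
) -> float:
    """Normalized kernel-weighted saliency of a target on its image.

    ``sum_pixels weight(pixel) * saliency(pixel) / total`` with the ellipse
    indicator for an AOI and the (by default rounded, mirroring the WSD
    computation) Gaussian kernel for a POI.  Raises on a zero-total map.
    """
    total = smap.total
    if not total > 0:
        raise ValueError("saliency map has zero total; cannot normalize")
    h, w = smap.shape

    if isinstance(target, EllipseAOI):
        a, b = target.semi_axes
        r = max(a, b) + 1.0
        x0 = max(int(math.floor(target.center[0] - r)), 0)
        x1 = min(int(math.ceil(target.center[0] + r)) + 1, w)
        y0 = max(int(math.floor(target.center[1] - r)), 0)
        y1 = min(int(math.ceil(target.center[1] + r)) + 1, h)
        if x0 >= x1 or y0 >= y1:
            return 0.0
        xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        inside = target.contains(np.column_stack([xs.ravel(), ys.ravel()]))
        sal = smap.grid[y0:y1, x0:x1].ravel()
        return float(sal[inside].sum() / total)

    if isinstance(target, POI):
        kcfg = kcfg or KernelConfig()
        geom = geom or GeometryConfig()
        sigma_px = kcfg.sigma_px(geom)
        if round_weights:
            ysl, xsl = _poi_window(target, sigma_px, kcfg.weight_decimals, (h, w))
        else:
            ysl, xsl = slice(0, h), slice(0, w)
        if ysl.start >= ysl.stop or xsl.start >= xsl.stop:
            return 0.0
        xs = np.arange(xsl.start, xsl.stop, dtype=float)
        ys = np.arange(ysl.start, ysl.stop, dtype=float)
        d2 = (xs[None, :] - target.x) ** 2 + (ys[:, None] - target.y) ** 2
        wgt = np.exp(-d2 / (2.0 * sigma_px**2))
        if round_weights:
            wgt = np.round(wgt, kcfg.weight_decimals)
        return float((wgt * smap.grid[ysl, xsl]).sum() / total)

    raise TypeError(f"unsupported target type: {type(target).__name__}")


def saliency_table(
    maps,
    aois: list[EllipseAOI],
    pois: list[POI],
    kcfg: KernelConfig | None = None,
    geom: GeometryConfig | None = None,
    *,
    round_weights: bool = True,
):
    """Per-target normalized saliency covariates as a long table.

    ``maps`` is a mapping ``image_id -> SaliencyMap`` or an iterable of
    ``SaliencyMap`` (maps are consumed one at a time, so large grids can be
    produced lazily).  Returns a DataFrame with one row per (image, label)
    target carrying ``aoi_saliency`` and/or ``poi_saliency``.
    """
    import pandas as pd  # local: keep module import-light for array users

    if isinstance(maps, dict):
        maps = maps.values()
    aoi_by_img: dict[str, dict[str, EllipseAOI]] = {}
    for a in aois:
        aoi_by_img.setdefault(a.image_id, {})[a.label] = a
    poi_by_img: dict[str, dict[str, POI]] = {}
    for p in pois:
        poi_by_img.setdefault(p.image_id, {})[p.label] = p
    rows = []
    for smap in maps:
        img = smap.image_id
        labels = sorted(set(aoi_by_img.get(img, {})) | set(poi_by_img.get(img, {})))
        for label in labels:
            aoi = aoi_by_img.get(img, {}).get(label)
            poi = poi_by_img.get(img, {}).get(label)
            rows.append(
                {
                    "image_id": img,
                    "label": label,
                    "aoi_saliency": (
                        weighted_saliency(smap, aoi, kcfg, geom, round_weights=round_weights)
                        if aoi is not None
                        else float("nan")
                    ),
                    "poi_saliency": (
                        weighted_saliency(smap, poi, kcfg, geom, round_weights=round_weights)
                        if poi is not None
                        else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["image_id", "label", "aoi_saliency", "poi_saliency"])


def make_toy_saliency(
    image_size: tuple[float, float],
    mode: str = "uniform",
    *,
    image_id: str = "toy",
    seed: int | None = None,
    blobs: list[tuple[float, float, float, float]] | None = None,
    value: float = 1.0,
    base: float = 0.0,
) -> SaliencyMap:
    """Deterministic synthetic saliency maps for tests and the synthetic pipeline.

    Modes: ``uniform`` (constant ``value``), ``blobs`` (sum of Gaussian bumps
    ``(x, y, sigma, amplitude)`` plus a constant ``base`` floor), ``noise``
    (seeded uniform noise).  Same seed -> identical grid.
    """
    w, h = int(image_size[0]), int(image_size[1])
    if mode == "uniform":
        grid = np.full((h, w), float(value))
    elif mode == "blobs":
        if not blobs:
            raise ValueError("mode='blobs' requires a blobs list")
        xs = np.arange(w, dtype=float)
        ys = np.arange(h, dtype=float)
        grid = np.full((h, w), float(base))
        for bx, by, bs, amp in blobs:
            grid += amp * np.exp(
                -((xs[None, :] - bx) ** 2 + (ys[:, None] - by) ** 2) / (2.0 * bs**2)
            )
    elif mode == "noise":
        rng = np.random.default_rng(seed)
        grid = rng.uniform(0.0, 1.0, size=(h, w))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SaliencyMap(image_id=image_id, grid=grid)
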