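"""Data-driven POI definition via spherical Gaussian mixture models.

For each stimulus image, the offset- and drift-corrected fixation locations
of all participants are pooled and modeled as a mixture of isotropic
(spherical) bivariate Gaussians fitted by EM.  The number of components k is
chosen by a grid search minimizing the *average* BIC over repeated fits with
different initializations; the single lowest-BIC fit at the chosen k is then
matched against the study's ellipse AOIs: a component whose mean falls
inside an AOI defines that AOI's POI (greedy by mixing weight when several
components qualify).  AOIs with no matching component fall back to the AOI
center.  Finally the isotropic SDs of all matched components, pooled across
images, are averaged to give the kernel sigma for the WSD analysis.

The EM fit itself is delegated to scikit-learn's ``GaussianMixture`` with
``covariance_type="spherical"``; the BIC convention (free parameter count
p = 4k - 1: two mean coordinates and one variance per component plus k - 1
mixing weights) matches that implementation and is pinned here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .core import Dataset, GeometryConfig
from .metrics import EllipseAOI, POI

__all__ = [
    "GMMResult",
    "KSelection",
    "GmmSettings",
    "SigmaEstimate",
    "fit_spherical_gmm",
    "select_k",
    "SphericalMixtureSelector",
    "match_components_to_aois",
    "define_pois",
]


@dataclass(frozen=True)
class GMMResult:
    """A fitted spherical mixture: k isotropic components over 2-D points."""

    k: int
    means: np.ndarray  # (k, 2)
    sigmas: np.ndarray  # (k,) isotropic SDs (covariance sigma^2 * I)
    weights: np.ndarray  # (k,), sums to 1
    log_likelihood: float
    bic: float
    converged: bool
    seed: int
    n_samples: int
    sigma_floored: bool = False

    @property
    def n_parameters(self) -> int:
        """Free parameters of a spherical k-mixture: 4k - 1."""
        return 4 * self.k - 1

    def score_points(self, points: np.ndarray) -> np.ndarray:
        """Per-point log density under the mixture (used for checks/predict)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        log_comp = np.empty((len(pts), self.k))
        for c in range(self.k):
            d2 = np.sum((pts - self.means[c]) ** 2, axis=1)
            var = self.sigmas[c] ** 2
            log_comp[:, c] = (
                math.log(self.weights[c])
                - math.log(2.0 * math.pi * var)
                - d2 / (2.0 * var)
            )
        m = log_comp.max(axis=1, keepdims=True)
        return (m + np.log(np.exp(log_comp - m).sum(axis=1, keepdims=True))).ravel()

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Hard component assignment by maximum posterior responsibility."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        log_comp = np.empty((len(pts), self.k))
        for c in range(self.k):
            d2 = np.sum((pts - self.means[c]) ** 2, axis=1)
            var = self.sigmas[c] ** 2
            log_comp[:, c] = math.log(self.weights[c]) - math.log(var) - d2 / (2.0 * var)
        return np.argmax(log_comp, axis=1)


def fit_spherical_gmm(
    points,
    k: int,
    seed: int = 0,
    *,
    reg_covar: float = 1e-6,
    max_iter: int = 200,
) -> GMMResult:
    """Fit one spherical GMM by EM (k-means initialization, fixed seed).

    ``reg_covar`` acts as a variance floor; a component whose variance
    collapses onto it is flagged via ``sigma_floored``.
    """
    X = np.asarray(points, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(X)):
        raise ValueError("points must be finite")
    n = len(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} points, got n={n}")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="spherical",
        reg_covar=reg_covar,
        max_iter=max_iter,
        init_params="kmeans",
        n_init=1,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(X)
    variances = np.asarray(gm.covariances_, dtype=float)
    floored = bool(np.any(variances <= reg_covar * (1.0 + 1e-9)))
    loglik = float(gm.score(X) * n)
    return GMMResult(
        k=k,
        means=np.asarray(gm.means_, dtype=float),
        sigmas=np.sqrt(variances),
        weights=np.asarray(gm.weights_, dtype=float),
        log_likelihood=loglik,
        bic=float(gm.bic(X)),
        converged=bool(gm.converged_),
        seed=seed,
        n_samples=n,
        sigma_floored=floored,
    )


@dataclass
class KSelection:
    """Result of the BIC grid search over component counts."""

    table: pd.DataFrame  # columns: k, mean_bic, sd_bic, n_converged
    chosen_k: int
    best_fit: GMMResult

    def __post_init__(self) -> None:
        if self.best_fit.k != self.chosen_k:
            raise ValueError("best_fit must have chosen_k components")


def select_k(
    points,
    k_range: Iterable[int] = range(1, 51),
    repeats: int = 50,
    seed: int = 0,
    *,
    reg_covar: float = 1e-6,
) -> KSelection:
    """Grid search over k: repeated spherical-GMM fits scored by average BIC.

    For each k, ``repeats`` fits are run with seeds ``seed + repeat_index``;
    the mean and sample SD of the BIC over converged fits are recorded, the
    k minimizing the mean BIC is chosen (ties to the smaller k), and the
    single lowest-BIC converged fit at that k is returned.
    """
    X = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(X)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain positive integers")
    feasible = [k for k in ks if k <= n]
    if len(feasible) < len(ks):
        warnings.warn(
            f"k_range truncated to k <= n = {n} (was max {max(ks)})", stacklevel=2
        )
    if not feasible:
        raise ValueError("no feasible k: fewer points than the smallest k")

    rows = []
    best_per_k: dict[int, GMMResult] = {}
    for k in feasible:
        fits = [
            fit_spherical_gmm(X, k, seed + r, reg_covar=reg_covar)
            for r in range(repeats)
        ]
        conv = [f for f in fits if f.converged]
        if not conv:
            warnings.warn(f"all {repeats} fits diverged at k={k}; k dropped", stacklevel=2)
            continue
        bics = np.array([f.bic for f in conv])
        rows.append(
            {
                "k": k,
                "mean_bic": float(bics.mean()),
                "sd_bic": float(bics.std(ddof=1)) if len(bics) > 1 else 0.0,
                "n_converged": len(conv),
            }
        )
        best_per_k[k] = min(conv, key=lambda f: f.bic)
    if not rows:
        raise RuntimeError("no k produced a converged fit")
    table = pd.DataFrame(rows)
    chosen_k = int(table.loc[table["mean_bic"].idxmin(), "k"])
    return KSelection(table=table, chosen_k=chosen_k, best_fit=best_per_k[chosen_k])


class SphericalMixtureSelector(BaseEstimator):
    """Spherical-GMM clusterer with BIC-based selection of the component count.

    scikit-learn-style estimator wrapping :func:`select_k`: ``fit(X)`` runs
    the repeated-fit BIC grid search on an ``(n, 2)`` array of fixation
    locations and exposes the selected mixture through fitted attributes.

    Parameters
    ----------
    k_min, k_max : smallest / largest component count searched.
    repeats : fits per k with distinct seeds (``random_state + repeat``).
    random_state : master seed; the whole search is deterministic given it.

    Attributes
    ----------
    k_ : selected component count (minimum average BIC).
    means_, sigmas_, weights_ : parameters of the lowest-BIC fit at ``k_``.
    bic_table_ : per-k mean/SD of BIC over converged repeats.
    best_result_ : the underlying :class:`GMMResult`.
    """

    def __init__(
        self,
        k_min: int = 1,
        k_max: int = 50,
        repeats: int = 50,
        random_state: int = 0,
        reg_covar: float = 1e-6,
    ) -> None:
        self.k_min = k_min
        self.k_max = k_max
        self.repeats = repeats
        self.random_state = random_state
        self.reg_covar = reg_covar

    def fit(self, X, y=None) -> "SphericalMixtureSelector":
        sel = select_k(
            X,
            k_range=range(self.k_min, self.k_max + 1),
            repeats=self.repeats,
            seed=self.random_state,
            reg_covar=self.reg_covar,
        )
        self.selection_ = sel
        self.k_ = sel.chosen_k
        self.best_result_ = sel.best_fit
        self.means_ = sel.best_fit.means
        self.sigmas_ = sel.best_fit.sigmas
        self.weights_ = sel.best_fit.weights
        self.bic_table_ = sel.table
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "best_result_"):
            raise RuntimeError("SphericalMixtureSelector is not fitted")
        return self.best_result_.predict(np.asarray(X, dtype=float))

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def match_components_to_aois(
    fit: GMMResult,
    aois: Sequence[EllipseAOI],
) -> dict[str, int | None]:
    """Geometric component-to-AOI matching (mean inside ellipse, weight-greedy).

    A component is a candidate for an AOI iff its mean lies inside the AOI
    ellipse.  Candidates are assigned greedily by descending mixing weight
    (ties broken by distance to the AOI center); each component serves at
    most one AOI.  Unmatched AOIs map to ``None`` (fallback flagged).
    """
    candidates = []
    for aoi in aois:
        inside = aoi.contains(fit.means)
        for c in range(fit.k):
            if inside[c]:
                dist = math.hypot(
                    fit.means[c, 0] - aoi.center[0], fit.means[c, 1] - aoi.center[1]
                )
                candidates.append((-fit.weights[c], dist, c, aoi.label))
    candidates.sort()
    mapping: dict[str, int | None] = {a.label: None for a in aois}
    used: set[int] = set()
    for _negw, _dist, c, label in candidates:
        if mapping[label] is None and c not in used:
            mapping[label] = c
            used.add(c)
    return mapping


@dataclass(frozen=True)
class GmmSettings:
    """Grid-search settings for data-driven POI definition."""

    k_min: int = 1
    k_max: int = 50
    repeats: int = 50
    reg_covar: float = 1e-6

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class SigmaEstimate:
    """Pooled average isotropic SD of the AOI-matched mixture components."""

    mean_px: float
    sd_px: float
    mean_deg: float
    n_components: int


@dataclass
class PoiDefinition:
    """Output of :func:`define_pois`."""

    pois: list[POI]
    sigma: SigmaEstimate
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    fits: dict[str, GMMResult] = field(default_factory=dict)


def define_pois(
    dataset: Dataset,
    aois: Sequence[EllipseAOI],
    settings: GmmSettings | None = None,
    seed: int = 0,
    manual_overrides: Mapping[tuple[str, str], int | None] | None = None,
) -> PoiDefinition:
    """Define one POI per (image, AOI label) from pooled corrected fixations.

    Per image: pooled analyzable fixations of all retained trials ->
    :func:`select_k` -> best fit -> :func:`match_components_to_aois`.
    Matched AOIs get the component mean as POI (provenance
    ``gmm_component``); unmatched AOIs (including every AOI of an image with
    no retained fixations) fall back to the AOI center (provenance
    ``aoi_center_fallback``).  An optional manual-override mapping
    ``(image_id, label) -> component index or None`` reproduces hand
    matching.  The returned sigma estimate averages the isotropic SDs of all
    matched components pooled across images (reported unrounded).
    """
    settings = settings or GmmSettings()
    geom: GeometryConfig = dataset.geometry
    aois_by_img: dict[str, list[EllipseAOI]] = {}
    for a in aois:
        aois_by_img.setdefault(a.image_id, []).append(a)

    pooled: dict[str, list[np.ndarray]] = {img: [] for img in aois_by_img}
    for t in dataset.retained_trials:
        if t.image_id in pooled and len(t.analyzable_xy):
            pooled[t.image_id].append(t.analyzable_xy)

    pois: list[POI] = []
    matched_sigmas: list[float] = []
    diag_rows = []
    fits: dict[str, GMMResult] = {}
    for i_img, img in enumerate(sorted(aois_by_img)):
        img_aois = aois_by_img[img]
        pts_list = pooled.get(img, [])
        pts = np.concatenate(pts_list) if pts_list else np.empty((0, 2))
        if len(pts) == 0:
            warnings.warn(
                f"image {img!r} has no retained fixations; all its POIs fall back "
                "to AOI centers",
                stacklevel=2,
            )
            for a in img_aois:
                pois.append(POI(img, a.label, *a.center, provenance="aoi_center_fallback"))
            continue
        # distinct master seed per image, all derived from the caller's seed
        img_seed = int(seed + 7919 * i_img) % (2**31 - 1)
        sel = select_k(
            pts,
            k_range=range(settings.k_min, settings.k_max + 1),
            repeats=settings.repeats,
            seed=img_seed,
            reg_covar=settings.reg_covar,
        )
        fits[img] = sel.best_fit
        dt = sel.table.copy()
        dt.insert(0, "image_id", img)
        dt["chosen"] = dt["k"] == sel.chosen_k
        diag_rows.append(dt)
        mapping = match_components_to_aois(sel.best_fit, img_aois)
        if manual_overrides:
            for a in img_aois:
                key = (img, a.label)
                if key in manual_overrides:
                    mapping[a.label] = manual_overrides[key]
        for a in img_aois:
            comp = mapping.get(a.label)
            if comp is None:
                pois.append(POI(img, a.label, *a.center, provenance="aoi_center_fallback"))
            else:
                mx, my = sel.best_fit.means[comp]
                pois.append(POI(img, a.label, float(mx), float(my), provenance="gmm_component"))
                matched_sigmas.append(float(sel.best_fit.sigmas[comp]))

    if matched_sigmas:
        arr = np.asarray(matched_sigmas)
        sigma = SigmaEstimate(
            mean_px=float(arr.mean()),
            sd_px=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            mean_deg=float(geom.px_to_deg(arr.mean())),
            n_components=len(arr),
        )
    else:
        warnings.warn("no component matched any AOI; sigma estimate undefined", stacklevel=2)
        sigma = SigmaEstimate(float("nan"), float("nan"), float("nan"), 0)
    diagnostics = (
        pd.concat(diag_rows, ignore_index=True) if diag_rows else pd.DataFrame()
    )
    return PoiDefinition(pois=pois, sigma=sigma, diagnostics=diagnostics, fits=fits)
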