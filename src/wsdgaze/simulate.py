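"""Synthetic fixation-report generator emulating a social-scene viewing study.

The generator emulates the structure of the study this package was built
around: 90 participants freely view 72 images (1600 x 900 px, centered on a
1920 x 1080 screen) for 6 seconds each and then rate the depicted
interaction's violence on a 1-7 Likert scale.  A third of the images show
violent, a third friendly and a third ambiguous interactions; every image
contains two faces, and roughly half (37 of 72, as in the study) contain a
point of physical contact.

Per trial, a latent perceived-violence value (condition mean plus noise)
drives both the rating and the attention mixture: higher perceived violence
shifts attention weight away from the faces and toward the contact point.
Fixation locations are drawn from an isotropic Gaussian mixture over the
latent targets plus a broad background component; durations are lognormal
(right-skewed, median ~250 ms) and fixations are emitted until the trial's
duration budget is exhausted.  The first fixation of every trial sits on the
central dot displaced by a per-trial drift vector, exactly as a video-based
tracker's calibration drift would displace it — so the generated reports are
in *screen* coordinates and need the same offset/drift correction as real
exports.  A small fraction of trials is "inattentive" (short recording) so
the quality filter has something realistic to catch.

A ground-truth sidecar (true target locations, true cluster sigma, planted
effect sizes) is returned separately so the fixation CSVs remain
format-identical to real tracker exports.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import Dataset, GeometryConfig, Trial
from .metrics import EllipseAOI, KernelConfig, POI
from .saliency import make_toy_saliency, saliency_table

__all__ = [
    "SceneTemplate",
    "GeneratorConfig",
    "generate_dataset",
    "generate_aois",
    "pois_from_aoi_centers",
    "toy_saliency_table",
    "make_scene_templates",
]


@dataclass(frozen=True)
class SceneTemplate:
    """Latent layout of one synthetic stimulus image."""

    image_id: str
    condition: str
    targets: dict[str, tuple[float, float]]  # label -> true location (image px)
    has_contact: bool


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults for the synthetic dataset.

    The defaults mirror the emulated study: 90 participants, 72 images split
    evenly over violent / friendly / ambiguous interactions, 37 images with
    a contact point, 6-second trials, fixation-cluster sigma 0.75 degrees and
    a mean drift-correction magnitude of 1.32 degrees.  Effect sizes are
    multiplicative attention-weight modifiers per unit of centered perceived
    violence (range roughly -3..+3): at the defaults a maximally violent
    trial moves ~18% of face weight away and adds ~36% contact weight.
    """

    n_participants: int = 90
    n_images: int = 72
    n_contact_images: int | None = None  # default: round(n_images * 37/72)
    conditions: tuple[str, ...] = ("violent", "friendly", "ambiguous")
    trial_duration_ms: float = 6000.0
    fixation_median_ms: float = 250.0
    fixation_log_sd: float = 0.55
    min_fixation_ms: float = 60.0
    cluster_sigma_deg: float = 0.75
    background_sigma_deg: float = 6.0
    drift_mean_deg: float = 1.32  # mean magnitude; components are iid normal
    face_weight: float = 0.28  # per face, before modifiers
    contact_weight: float = 0.16
    face_effect: float = 0.06  # fractional face-weight loss per violence unit
    contact_effect: float = 0.12  # fractional contact-weight gain per violence unit
    participant_sd: float = 0.10  # between-participant SD of face preference (fraction)
    condition_violence: tuple[tuple[str, float], ...] = (
        ("violent", 5.5),
        ("ambiguous", 3.5),
        ("friendly", 2.0),
    )
    rating_sd: float = 1.0
    inattentive_rate: float = 0.02
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_images < 1:
            raise ValueError("need at least one participant and one image")
        if self.trial_duration_ms <= self.min_fixation_ms:
            raise ValueError("trial duration budget is infeasible")
        if not 0.0 <= self.inattentive_rate < 1.0:
            raise ValueError("inattentive_rate must be in [0, 1)")
        if self.face_weight < 0 or self.contact_weight < 0:
            raise ValueError("attention weights must be nonnegative")

    @property
    def contact_count(self) -> int:
        if self.n_contact_images is not None:
            return self.n_contact_images
        return int(round(self.n_images * 37.0 / 72.0))

    @property
    def condition_means(self) -> dict[str, float]:
        return dict(self.condition_violence)


def _condition_assignment(cfg: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    """Near-equal condition split, shuffled deterministically."""
    n, k = cfg.n_images, len(cfg.conditions)
    conds = [cfg.conditions[i % k] for i in range(n)]
    rng.shuffle(conds)
    return conds


def make_scene_templates(cfg: GeneratorConfig, rng: np.random.Generator) -> list[SceneTemplate]:
    """Lay out latent targets: two faces in the upper image, contact between them."""
    iw, ih = cfg.geometry.image_size
    conds = _condition_assignment(cfg, rng)
    contact_flags = np.zeros(cfg.n_images, dtype=bool)
    contact_flags[: cfg.contact_count] = True
    rng.shuffle(contact_flags)
    templates = []
    for i in range(cfg.n_images):
        img = f"img{i:03d}"
        f1 = (
            rng.uniform(0.12 * iw, 0.38 * iw),
            rng.uniform(0.18 * ih, 0.45 * ih),
        )
        f2 = (
            rng.uniform(0.62 * iw, 0.88 * iw),
            rng.uniform(0.18 * ih, 0.45 * ih),
        )
        targets = {"face1": f1, "face2": f2}
        if contact_flags[i]:
            targets["contact"] = (
                (f1[0] + f2[0]) / 2.0 + rng.uniform(-0.05 * iw, 0.05 * iw),
                rng.uniform(0.55 * ih, 0.78 * ih),
            )
        templates.append(
            SceneTemplate(image_id=img, condition=conds[i], targets=targets,
                          has_contact=bool(contact_flags[i]))
        )
    return templates


def _attention_weights(
    cfg: GeneratorConfig,
    template: SceneTemplate,
    violence_centered: float,
    face_bias: float = 0.0,
) -> tuple[list[str], np.ndarray]:
    """Mixture weights over [face1, face2, (contact), background] for one trial."""
    labels = ["face1", "face2"]
    wf = max(
        cfg.face_weight * (1.0 + face_bias) * (1.0 - cfg.face_effect * violence_centered),
        0.01,
    )
    w = [wf, wf]
    if template.has_contact:
        labels.append("contact")
        w.append(max(cfg.contact_weight * (1.0 + cfg.contact_effect * violence_centered), 0.01))
    labels.append("background")
    w.append(max(1.0 - sum(w), 0.05))
    arr = np.asarray(w, dtype=float)
    return labels, arr / arr.sum()


def generate_dataset(
    cfg: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[Dataset, dict]:
    """Generate a pre-correction dataset (screen coordinates) plus ground truth.

    Returns ``(dataset, sidecar)`` where the sidecar records the true target
    locations, the scene templates, the true cluster sigma and the planted
    effect sizes.  Fully deterministic given the seed (default:
    ``cfg.master_seed``).
    """
    cfg = cfg or GeneratorConfig()
    seed = cfg.master_seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    geom = cfg.geometry
    templates = make_scene_templates(cfg, rng)

    sigma_px = float(geom.deg_to_px(cfg.cluster_sigma_deg))
    bg_sigma_px = float(geom.deg_to_px(cfg.background_sigma_deg))
    drift_sd_px = float(geom.deg_to_px(cfg.drift_mean_deg)) * math.sqrt(2.0 / math.pi)
    mu_log = math.log(cfg.fixation_median_ms)
    dot_screen = np.array([geom.screen_size[0] / 2.0, geom.screen_size[1] / 2.0])
    offset = np.asarray(geom.image_offset)
    img_center = np.asarray(geom.image_center)
    cond_means = cfg.condition_means

    trials: list[Trial] = []
    for p in range(cfg.n_participants):
        pid = f"P{p:03d}"
        face_bias = float(rng.normal(0.0, cfg.participant_sd))
        for tpl in templates:
            v_latent = cond_means[tpl.condition] + rng.normal(0.0, cfg.rating_sd)
            rating = int(np.clip(round(v_latent), 1, 7))
            v_centered = float(np.clip(v_latent, 1.0, 7.0) - 4.0)
            labels, weights = _attention_weights(cfg, tpl, v_centered, face_bias)
            drift = rng.normal(0.0, drift_sd_px, size=2)

            budget = cfg.trial_duration_ms
            if rng.random() < cfg.inattentive_rate:
                budget = rng.uniform(800.0, 2800.0)

            xs: list[np.ndarray] = []
            durs: list[float] = []
            # first fixation: on the dot, displaced only by drift
            first_dur = float(
                min(np.exp(rng.normal(mu_log, cfg.fixation_log_sd)), budget)
            )
            xs.append(dot_screen + drift)
            durs.append(max(first_dur, cfg.min_fixation_ms))
            remaining = budget - durs[0]
            while remaining >= cfg.min_fixation_ms:
                dur = float(np.exp(rng.normal(mu_log, cfg.fixation_log_sd)))
                dur = min(dur, remaining)
                comp = labels[rng.choice(len(labels), p=weights)]
                if comp == "background":
                    loc = img_center + rng.normal(0.0, bg_sigma_px, size=2)
                else:
                    loc = np.asarray(tpl.targets[comp]) + rng.normal(0.0, sigma_px, size=2)
                if dur >= cfg.min_fixation_ms:
                    xs.append(loc + offset + drift)  # true image pos -> screen + drift
                    durs.append(dur)
                remaining -= dur
            trials.append(
                Trial(
                    pid,
                    tpl.image_id,
                    condition=tpl.condition,
                    rating=rating,
                    indices=np.arange(1, len(durs) + 1),
                    xy=np.vstack(xs),
                    durations=np.asarray(durs),
                )
            )

    sidecar = {
        "seed": seed,
        "cluster_sigma_deg": cfg.cluster_sigma_deg,
        "effects": {"face_effect": cfg.face_effect, "contact_effect": cfg.contact_effect},
        "conditions": {t.image_id: t.condition for t in templates},
        "targets": {
            t.image_id: {lab: list(loc) for lab, loc in t.targets.items()}
            for t in templates
        },
        "has_contact": {t.image_id: t.has_contact for t in templates},
        "config": _config_dict(cfg),
    }
    return Dataset(trials, geom), sidecar


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["geometry"] = {
        "pixels_per_degree": cfg.geometry.pixels_per_degree,
        "screen_size": list(cfg.geometry.screen_size),
        "image_size": list(cfg.geometry.image_size),
    }
    d["conditions"] = list(cfg.conditions)
    d["condition_violence"] = [list(x) for x in cfg.condition_violence]
    return d


def generate_aois(
    sidecar: dict,
    *,
    face_axes_deg: tuple[float, float] = (65.0 / 60.0, 80.0 / 60.0),
    contact_axes_deg: tuple[float, float] = (0.75, 0.75),
    axis_jitter: float = 0.18,
    rotation_jitter: float = 0.3,
) -> list[EllipseAOI]:
    """Ellipse AOIs centered exactly on the sidecar's true target locations.

    Contact AOIs exist only for images flagged as containing a contact point.
    Semi-axes are given in visual degrees (converted through the sidecar's
    geometry) so the same definitions scale across rigs.  Hand-drawn AOIs
    vary in size and tilt between images, so semi-axes are jittered by a
    uniform +-``axis_jitter`` fraction and rotations drawn from
    +-``rotation_jitter`` radians (deterministic given the sidecar's seed).
    The default semi-axes (65 x 80 px for faces, 45 px for contact points at
    60 px/degree) are calibrated against the emulated study's reported
    zero-dwell proportions (roughly 30% of contact trials and very few face
    trials have zero dwell when fixation clusters have a 0.75 degree SD), so
    the hard AOI boundary sees realistic traffic.
    """
    ppd = float(sidecar.get("config", {}).get("geometry", {}).get("pixels_per_degree", 60.0))
    face_axes = (face_axes_deg[0] * ppd, face_axes_deg[1] * ppd)
    contact_axes = (contact_axes_deg[0] * ppd, contact_axes_deg[1] * ppd)
    rng = np.random.default_rng(int(sidecar.get("seed", 0)) + 104729)
    aois = []
    for img, targets in sorted(sidecar["targets"].items()):
        for label, loc in sorted(targets.items()):
            base = contact_axes if label == "contact" else face_axes
            axes = tuple(float(ax * rng.uniform(1 - axis_jitter, 1 + axis_jitter)) for ax in base)
            rot = float(rng.uniform(-rotation_jitter, rotation_jitter))
            aois.append(EllipseAOI(img, label, (float(loc[0]), float(loc[1])), axes, rot))
    return aois


def pois_from_aoi_centers(aois: list[EllipseAOI]) -> list[POI]:
    """The AOI-center POI variant: one POI at each ellipse center."""
    return [POI(a.image_id, a.label, a.center[0], a.center[1], provenance="aoi_center_fallback")
            for a in aois]


def toy_saliency_table(
    sidecar: dict,
    aois: list[EllipseAOI],
    pois: list[POI],
    kcfg: KernelConfig | None = None,
    geom: GeometryConfig | None = None,
    *,
    blob_sigma_px: float = 80.0,
    base: float = 0.05,
):
    """Saliency covariates from toy blob maps (bumps at the true targets).

    Maps are generated lazily, one image at a time, so full-resolution grids
    never coexist in memory.
    """
    geom = geom or GeometryConfig()
    size = geom.image_size

    def _maps():
        for img, targets in sorted(sidecar["targets"].items()):
            blobs = [(x, y, blob_sigma_px, 1.0) for x, y in targets.values()]
            yield make_toy_saliency(size, "blobs", image_id=img, blobs=blobs, base=base)

    return saliency_table(_maps(), aois, pois, kcfg, geom)
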