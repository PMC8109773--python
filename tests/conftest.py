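"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import wsdgaze as wg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from wsdgaze.core import drift_correct_dataset, filter_trials, zscore_ratings


@pytest.fixture(scope="session")
def geom() -> wg.GeometryConfig:
    return wg.GeometryConfig()


def preprocess(dataset: wg.Dataset) -> tuple[wg.Dataset, object]:
    """Offset-correct, drift-correct, QC-filter and z-score a raw dataset."""
    g = dataset.geometry
    ds = dataset.map_trials(lambda t: t.shifted([-g.image_offset[0], -g.image_offset[1]]))
    ds = drift_correct_dataset(ds)
    ds, qc = filter_trials(ds)
    return zscore_ratings(ds), qc


@pytest.fixture(scope="session")
def small_pipeline():
    """A 20-participant x 24-image synthetic study, fully preprocessed.

    Returns a dict with the corrected dataset, ground truth, AOIs, AOI-center
    POIs, saliency covariates and the metric table.
    """
    cfg = wg.GeneratorConfig(n_participants=20, n_images=24, master_seed=7)
    raw, sidecar = wg.generate_dataset(cfg)
    ds, qc = preprocess(raw)
    aois = wg.generate_aois(sidecar)
    pois = wg.pois_from_aoi_centers(aois)
    sal = wg.toy_saliency_table(sidecar, aois, pois)
    mt = wg.metric_table(ds, aois, pois)
    return {
        "cfg": cfg,
        "dataset": ds,
        "qc": qc,
        "sidecar": sidecar,
        "aois": aois,
        "pois": pois,
        "saliency": sal,
        "metrics": mt,
    }


def make_trial(
    pid="P0",
    img="img0",
    fixations=((1, 800.0, 450.0, 400.0), (2, 820.0, 470.0, 3500.0)),
    **kw,
):
    """Build a Trial from (index, x, y, duration_ms) tuples."""
    fx = np.asarray(fixations, dtype=float)
    return wg.Trial(
        pid,
        img,
        indices=fx[:, 0].astype(int),
        xy=fx[:, 1:3],
        durations=fx[:, 3],
        **kw,
    )
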