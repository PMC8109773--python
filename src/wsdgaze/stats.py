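"""Trial-level mixed-effects analysis of the fixation-duration metrics.

Each analysis fits a linear mixed-effects model at the trial level with
crossed random intercepts for participant and stimulus:

    outcome ~ predictor + saliency [+ aoi_area] + (1 | participant) + (1 | stimulus)

where the outcome is either the AOI dwell time or the WSD (summed over the
target labels of the analysis, e.g. both faces), the predictor is the image
condition (treatment-coded against the ``friendly`` reference) or the
within-participant z-scored violence rating, and the covariates follow a
fixed rule: the normalized kernel-weighted saliency of the target always
enters; the AOI area enters only for the dwell-time outcome (POIs and their
kernels all share one size, so there is no size to control for).

Fitting is by restricted maximum likelihood through statsmodels' ``MixedLM``
with the two crossed intercepts expressed as variance components on a single
all-ones group.  Wald t/p values use the normal approximation; an lme4-style
fit with Satterthwaite degrees of freedom (via R's lmerTest) is available as
an alternative backend for cross-checking.  Marginal and conditional R^2 are
the usual variance-partition quantities (fixed / fixed+random over total).
"""

from __future__ import annotations

import os
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["ModelSpec", "FitResult", "build_model_table", "fit_lmm"]

FACE_PREFIX = "face"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one trial-level analysis.

    ``target`` selects which metric-table labels form the outcome: ``face``
    sums every label starting with ``face``; any other value matches one
    label exactly.  ``subset`` restricts the images analyzed: ``all``, or
    ``require:<label1>,<label2>,...`` keeping only images on which all the
    listed target labels are defined (the contact analysis of the emulated
    study used only images containing every target type).
    """

    outcome: str = "wsd"  # "aoi_dwell" | "wsd"
    predictor: str = "condition"  # "condition" | "zscored_rating"
    target: str = "face"
    subset: str = "all"
    reference_condition: str = "friendly"
    center_saliency: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in ("aoi_dwell", "wsd"):
            raise ValueError("outcome must be 'aoi_dwell' or 'wsd'")
        if self.predictor not in ("condition", "zscored_rating"):
            raise ValueError("predictor must be 'condition' or 'zscored_rating'")

    @property
    def uses_area(self) -> bool:
        return self.outcome == "aoi_dwell"

    @property
    def outcome_column(self) -> str:
        return "aoi_dwell_ms" if self.outcome == "aoi_dwell" else "wsd_ms"

    @property
    def saliency_column(self) -> str:
        return "aoi_saliency" if self.outcome == "aoi_dwell" else "poi_saliency"


@dataclass
class FitResult:
    """Fixed-effect estimates and fit diagnostics of one mixed model."""

    terms: pd.DataFrame  # term, b, ci_low, ci_high, t, p
    converged: bool
    n_obs: int
    r2_marginal: float = float("nan")
    r2_conditional: float = float("nan")
    backend: str = "statsmodels"
    message: str = ""

    def coef(self, term: str) -> pd.Series:
        hit = self.terms[self.terms["term"] == term]
        if hit.empty:
            raise KeyError(f"no term {term!r}; have {list(self.terms['term'])}")
        return hit.iloc[0]


def _target_labels(metric_table: pd.DataFrame, target: str) -> list[str]:
    labels = sorted(metric_table["label"].unique())
    if target == FACE_PREFIX:
        chosen = [l for l in labels if str(l).startswith(FACE_PREFIX)]
    else:
        chosen = [l for l in labels if l == target]
    if not chosen:
        raise ValueError(f"no labels match target {target!r} (have {labels})")
    return chosen


def build_model_table(
    metric_table: pd.DataFrame,
    spec: ModelSpec,
    saliency: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per retained trial: outcome, predictor, covariates, IDs.

    Metrics, saliencies and AOI areas are summed over the labels selected by
    ``spec.target`` (e.g. the two faces of each image).  ``saliency`` is a
    per-(image, label) table with ``aoi_saliency``/``poi_saliency`` columns;
    if omitted, the saliency covariate is skipped with a warning (the
    reference analysis always includes it).
    """
    labels = _target_labels(metric_table, spec.target)
    mt = metric_table

    if spec.subset == "all":
        images = set(mt["image_id"].unique())
    elif spec.subset.startswith("require:"):
        required = [s.strip() for s in spec.subset[len("require:"):].split(",") if s.strip()]
        per_img = mt.groupby("image_id")["label"].agg(lambda s: set(s))
        images = {img for img, labs in per_img.items() if all(r in labs for r in required)}
    else:
        raise ValueError(f"unknown subset rule {spec.subset!r}")

    sub = mt[mt["label"].isin(labels) & mt["image_id"].isin(images)]
    if sub.empty:
        raise ValueError("model-table subset is empty")

    agg = {"outcome": (spec.outcome_column, "sum")}
    if spec.uses_area:
        agg["aoi_area"] = ("aoi_area_px2", "sum")
    table = (
        sub.groupby(["participant_id", "image_id"], as_index=False)
        .agg(
            condition=("condition", "first"),
            rating_z=("rating_z", "first"),
            **agg,
        )
    )

    if saliency is not None:
        sal = saliency[saliency["label"].isin(labels)]
        sal_sum = (
            sal.groupby("image_id", as_index=False)[spec.saliency_column]
            .sum()
            .rename(columns={spec.saliency_column: "saliency"})
        )
        table = table.merge(sal_sum, on="image_id", how="left")
        if spec.center_saliency:
            table["saliency"] = table["saliency"] - table["saliency"].mean()
    else:
        warnings.warn("no saliency table given; saliency covariate omitted", stacklevel=2)

    if spec.predictor == "zscored_rating":
        n_missing = int(table["rating_z"].isna().sum())
        if n_missing:
            warnings.warn(f"dropping {n_missing} trials with missing z-scored rating",
                          stacklevel=2)
            table = table[table["rating_z"].notna()]
    if table.empty:
        raise ValueError("model table is empty after predictor filtering")
    if table["outcome"].isna().any():
        raise ValueError("outcome column contains missing values "
                         f"({spec.outcome_column}: is the matching target defined?)")
    return table.reset_index(drop=True)


def _formula(spec: ModelSpec, table: pd.DataFrame) -> str:
    if spec.predictor == "condition":
        pred = f"C(condition, Treatment({spec.reference_condition!r}))"
    else:
        pred = "rating_z"
    rhs = [pred]
    if "saliency" in table.columns:
        rhs.append("saliency")
    if spec.uses_area and "aoi_area" in table.columns:
        rhs.append("aoi_area")
    return "outcome ~ " + " + ".join(rhs)


def condition_term(spec: ModelSpec, level: str) -> str:
    """statsmodels term name for a condition contrast vs. the reference."""
    return f"C(condition, Treatment({spec.reference_condition!r}))[T.{level}]"


def _check_rank(md) -> None:
    exog = md.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name one offending column (last-to-first so covariates are blamed
        # before the intercept)
        for j in reversed(range(exog.shape[1])):
            reduced = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(
                    f"rank-deficient design: column {md.exog_names[j]!r} is redundant"
                )
        raise ValueError("rank-deficient design")


def fit_lmm(table: pd.DataFrame, spec: ModelSpec, backend: str = "statsmodels") -> FitResult:
    """Fit the trial-level LMM by REML; convergence failure is reported, not raised.

    Requires at least two participants and two stimuli (otherwise the random
    intercepts are meaningless).  A rank-deficient fixed-effect design raises
    with the offending column named.
    """
    if table["participant_id"].nunique() < 2:
        raise ValueError("need >= 2 participants for a participant random intercept")
    if table["image_id"].nunique() < 2:
        raise ValueError("need >= 2 stimuli for a stimulus random intercept")
    if backend == "lmer":
        return _fit_lmer(table, spec)
    if backend != "statsmodels":
        raise ValueError(f"unknown backend {backend!r}")

    formula = _formula(spec, table)
    data = table.copy()

    # REML is equivariant under linear rescaling, so fit on unit-variance
    # variables (ms-scale outcomes make the likelihood surface badly
    # conditioned) and map coefficients back afterwards.
    y = np.asarray(data["outcome"], dtype=float)
    if np.allclose(np.var(y), 0.0):
        return FitResult(
            terms=pd.DataFrame(columns=["term", "b", "ci_low", "ci_high", "t", "p"]),
            converged=False,
            n_obs=len(data),
            message="zero-variance outcome",
        )
    sy = float(np.std(y, ddof=1))
    data["outcome"] = y / sy
    col_scale: dict[str, float] = {}
    for col in ("saliency", "aoi_area"):
        if col in data.columns:
            sx = float(np.std(np.asarray(data[col], dtype=float), ddof=1))
            if sx > 0:
                col_scale[col] = sx
                data[col] = data[col] / sx

    md = smf.mixedlm(
        formula,
        data,
        groups=np.ones(len(data)),
        vc_formula={
            "participant": "0 + C(participant_id)",
            "stimulus": "0 + C(image_id)",
        },
    )
    _check_rank(md)

    # lbfgs sometimes claims convergence on a spurious stationary point of
    # these flat/boundary REML surfaces, and sometimes fails where powell
    # succeeds: always run both and keep the best converged solution by
    # restricted log-likelihood (a powell->lbfgs refinement is the fallback
    # when neither converges alone).
    res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell"):
                cand = md.fit(reml=True, method=method, maxiter=400)
                ok = bool(cand.converged) and np.all(np.isfinite(cand.fe_params))
                if ok and (res is None or cand.llf > res.llf):
                    res = cand
            if res is None:
                cand = md.fit(reml=True, method=["powell", "lbfgs"], maxiter=400)
                ok = bool(cand.converged) and np.all(np.isfinite(cand.fe_params))
                res = cand  # converged or not, this is the reported attempt
    except (np.linalg.LinAlgError, ValueError, RuntimeError) as exc:
        return FitResult(
            terms=pd.DataFrame(columns=["term", "b", "ci_low", "ci_high", "t", "p"]),
            converged=False,
            n_obs=len(data),
            message=f"fit failed: {exc}",
        )
    converged = bool(res.converged) and np.all(np.isfinite(res.fe_params))

    fe = res.fe_params
    ci = res.conf_int().loc[fe.index]
    # undo the internal scaling: every coefficient carries sy; a coefficient
    # of a scaled covariate additionally carries 1/sx
    back = np.array([sy / col_scale.get(name, 1.0) for name in fe.index])
    terms = pd.DataFrame(
        {
            "term": fe.index,
            "b": fe.values * back,
            "ci_low": ci[0].values * back,
            "ci_high": ci[1].values * back,
            "t": res.tvalues.loc[fe.index].values,
            "p": res.pvalues.loc[fe.index].values,
        }
    )
    # variance ratios are scale-invariant: compute them on the scaled fit
    var_fixed = float(np.var(md.exog @ fe.values))
    var_random = float(np.sum(res.vcomp)) if res.vcomp is not None else 0.0
    var_resid = float(res.scale)
    total = var_fixed + var_random + var_resid
    return FitResult(
        terms=terms.reset_index(drop=True),
        converged=converged,
        n_obs=len(data),
        r2_marginal=var_fixed / total if total > 0 else float("nan"),
        r2_conditional=(var_fixed + var_random) / total if total > 0 else float("nan"),
        backend="statsmodels",
    )


_LMER_SCRIPT = """
suppressMessages(library(lmerTest))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
if ("condition" %in% names(d)) {{
  d$condition <- relevel(factor(d$condition), ref = "{ref}")
}}
m <- lmer({formula}, data = d, REML = TRUE)
s <- as.data.frame(summary(m)$coefficients)
s$term <- rownames(s)
write.csv(s, args[2], row.names = FALSE)
"""


def _fit_lmer(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Reference-behavior backend: lme4/lmerTest via Rscript (Satterthwaite df)."""
    rhs = ["condition" if spec.predictor == "condition" else "rating_z"]
    if "saliency" in table.columns:
        rhs.append("saliency")
    if spec.uses_area and "aoi_area" in table.columns:
        rhs.append("aoi_area")
    formula = (
        "outcome ~ " + " + ".join(rhs) + " + (1 | participant_id) + (1 | image_id)"
    )
    with tempfile.TemporaryDirectory() as tmp:
        data_csv = os.path.join(tmp, "data.csv")
        out_csv = os.path.join(tmp, "coef.csv")
        script = os.path.join(tmp, "fit.R")
        table.to_csv(data_csv, index=False)
        with open(script, "w") as fh:
            fh.write(_LMER_SCRIPT.format(formula=formula, ref=spec.reference_condition))
        proc = subprocess.run(
            ["Rscript", "--vanilla", script, data_csv, out_csv],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            return FitResult(
                terms=pd.DataFrame(columns=["term", "b", "ci_low", "ci_high", "t", "p"]),
                converged=False,
                n_obs=len(table),
                backend="lmer",
                message=proc.stderr[-2000:],
            )
        coefs = pd.read_csv(out_csv)
    se = coefs["Std. Error"]
    terms = pd.DataFrame(
        {
            "term": coefs["term"],
            "b": coefs["Estimate"],
            "ci_low": coefs["Estimate"] - 1.96 * se,
            "ci_high": coefs["Estimate"] + 1.96 * se,
            "t": coefs["t value"],
            "p": coefs["Pr(>|t|)"],
        }
    )
    return FitResult(terms=terms, converged=True, n_obs=len(table), backend="lmer")
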