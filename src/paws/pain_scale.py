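"""The univariate pain scale: proportional-odds ordinal regression.

A trial's standardized feature vector z is mapped to a scalar score
s = beta . z by a cumulative-logit (proportional-odds) model over the
ordered stimulus classes cs < db < lp < hp:

    P(class <= j | z) = logistic(c_j - beta . z),   c_1 < c_2 < c_3.

The linear predictor s is the univariate pain score.  For reporting, s is
rescaled affinely so that the no-pain/pain boundary (the db|lp cutpoint c_2)
maps to 0 and the low/high-pain boundary (the lp|hp cutpoint c_3) maps to 1:

    s' = (s - c_2) / (c_3 - c_2).

Binary classification uses s > c_2 (equivalently s' > 0) as "pain".
Feature importances are the loadings beta on the standardized features.

Fitting is maximum likelihood (quasi-Newton, gradient tolerance 1e-8, at
most 500 iterations).  If the optimizer fails to converge or the classes are
(quasi-)separable, the fit is retried once with a small ridge penalty
(1e-6 on beta) and a warning is recorded on the model.
"""

from __future__ import annotations

import hashlib
import json
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .config import Config
from .errors import ModelError, PawsError
from .features import StandardizationParams, feature_set, zscore_table
from .io import PAIN_STIMULI, STIMULI

_RIDGE_ALPHA = 1e-6
_SEPARATION_BETA = 10.0  # |beta| beyond this on standardized features ~ separation
_MAXITER = 500
_GTOL = 1e-8


@dataclass
class PainScaleModel:
    """A fitted univariate pain scale.

    ``beta`` are loadings on standardized features; ``cutpoints`` are the
    ordered boundaries between consecutive *realized* classes
    (``class_labels``).  ``pain_cutpoint``/``unit_cutpoint`` are the
    rescaling anchors (db|lp -> 0, lp|hp -> 1) when those boundaries exist.
    """

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    beta: np.ndarray
    cutpoints: np.ndarray
    class_labels: tuple[str, ...]
    n_obs: int
    loglike: float
    loglike_null: float
    converged: bool
    warnings: tuple[str, ...] = ()
    cutpoint_se: np.ndarray | None = None
    beta_se: np.ndarray | None = None
    config: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ModelError("cutpoints must be strictly increasing")

    def _boundary(self, left: str, right: str) -> float | None:
        labels = self.class_labels
        for i in range(len(labels) - 1):
            if labels[i] == left and labels[i + 1] == right:
                return float(self.cutpoints[i])
        return None

    @property
    def pain_cutpoint(self) -> float | None:
        """The db|lp boundary: zero point of the rescaled scale."""
        return self._boundary("db", "lp")

    @property
    def unit_cutpoint(self) -> float | None:
        """The lp|hp boundary: unit point of the rescaled scale."""
        return self._boundary("lp", "hp")

    @property
    def config_hash(self) -> str | None:
        if self.config is None:
            return None
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()
        ).hexdigest()[:16]

    def standardize(self, features: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        """Standardize raw features with the stored fit-time parameters."""
        if isinstance(features, pd.DataFrame):
            missing = [n for n in self.feature_names if n not in features.columns]
            if missing:
                raise PawsError(f"feature(s) {missing} not found in input")
            x = features.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        else:
            try:
                x = np.array([[float(features[n]) for n in self.feature_names]])
            except KeyError as exc:
                raise PawsError(f"feature {exc} not found in input") from exc
        return (x - self.means) / self.sds

    def to_dict(self) -> dict[str, Any]:
        return {
            "format": "paws-pain-scale",
            "version": 1,
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "beta": self.beta.tolist(),
            "cutpoints": self.cutpoints.tolist(),
            "class_labels": list(self.class_labels),
            "n_obs": self.n_obs,
            "loglike": self.loglike,
            "loglike_null": self.loglike_null,
            "converged": self.converged,
            "warnings": list(self.warnings),
            "cutpoint_se": None if self.cutpoint_se is None else self.cutpoint_se.tolist(),
            "beta_se": None if self.beta_se is None else self.beta_se.tolist(),
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PainScaleModel":
        if d.get("format") != "paws-pain-scale":
            raise ModelError("not a pain-scale model file")
        return cls(
            feature_names=tuple(d["feature_names"]),
            means=np.array(d["means"], dtype=float),
            sds=np.array(d["sds"], dtype=float),
            beta=np.array(d["beta"], dtype=float),
            cutpoints=np.array(d["cutpoints"], dtype=float),
            class_labels=tuple(d["class_labels"]),
            n_obs=int(d["n_obs"]),
            loglike=float(d["loglike"]),
            loglike_null=float(d["loglike_null"]),
            converged=bool(d["converged"]),
            warnings=tuple(d["warnings"]),
            cutpoint_se=None if d["cutpoint_se"] is None else np.array(d["cutpoint_se"]),
            beta_se=None if d["beta_se"] is None else np.array(d["beta_se"]),
            config=d.get("config"),
        )


@dataclass(frozen=True)
class ScoredTrial:
    """Scores and predictions for a single trial."""

    score: float            # raw linear predictor s = beta . z
    pain_score: float | None  # rescaled s' = (s - c2) / (c3 - c2)
    predicted_class: str
    predicted_pain: bool


def _delta_method_cutpoint_se(
    model: OrderedModel, params: np.ndarray, cov: np.ndarray, k: int
) -> np.ndarray | None:
    """SEs of the cutpoints c_j = t_1 + sum_{i<=j} exp(t_i) via the delta method."""
    q = len(params) - k
    if cov is None or not np.all(np.isfinite(cov)):
        return None
    J = np.zeros((q, len(params)))
    for j in range(q):
        J[j, k] = 1.0
        for i in range(1, j + 1):
            J[j, k + i] = np.exp(params[k + i])
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    if np.any(var < 0):
        return None
    return np.sqrt(var)


def fit_ordinal_scale(
    table: pd.DataFrame,
    features: str | Sequence[str] = "post",
    config: Config | None = None,
) -> PainScaleModel:
    """Fit the proportional-odds pain scale on a feature table.

    Parameters
    ----------
    table
        Feature table with a ``stimulus`` column (ordered cs < db < lp < hp)
        and the named feature columns.
    features
        'pre', 'post', 'all', or an explicit sequence of column names.
    """
    cols = list(feature_set(features)) if isinstance(features, str) else list(features)
    if len(table) < 8:
        raise ModelError(f"need at least 8 rows to fit, got {len(table)}")
    stim = table["stimulus"].astype(str)
    present = [s for s in STIMULI if (stim == s).any()]
    if len(present) < 2:
        raise ModelError("need at least 2 stimulus classes present")

    ztab, std = zscore_table(table, cols)
    z = ztab.loc[:, cols].reset_index(drop=True)
    endog = pd.Series(
        pd.Categorical(stim.to_numpy(), categories=present, ordered=True)
    )

    flags: list[str] = []
    if np.linalg.cond(z.to_numpy()) > 1e8:
        flags.append("collinear")

    model = OrderedModel(endog, z, distr="logit")
    k = len(cols)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            res = model.fit(method="bfgs", maxiter=_MAXITER, gtol=_GTOL, disp=False)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
            cov = np.asarray(res.cov_params())
            beta_se = np.asarray(res.bse)[:k]
        except Exception:
            params, converged, cov, beta_se = None, False, None, None

    separated = params is not None and np.max(np.abs(params[:k])) > _SEPARATION_BETA
    if params is None or not converged or separated:
        # ridge fallback: penalized ML keeps the fit finite under separation
        start = params if params is not None else np.asarray(model.start_params)
        obj = lambda p: -model.loglike(p) + _RIDGE_ALPHA * np.sum(p[:k] ** 2)
        opt = minimize(obj, start, method="BFGS",
                       options={"gtol": _GTOL, "maxiter": _MAXITER})
        params = np.asarray(opt.x, dtype=float)
        converged = True  # penalized refit always returns a usable model
        cov, beta_se = None, None
        flags.append("separation")
        if not opt.success:
            flags.append("penalized-fit-not-converged")

    beta = params[:k]
    cutpoints = np.asarray(model.transform_threshold_params(params))[1:-1]
    loglike = float(model.loglike(params))
    counts = endog.value_counts()
    n = len(endog)
    loglike_null = float(sum(c * np.log(c / n) for c in counts if c > 0))
    cut_se = (
        _delta_method_cutpoint_se(model, params, cov, k) if cov is not None else None
    )

    return PainScaleModel(
        feature_names=tuple(cols),
        means=std.means,
        sds=std.sds,
        beta=beta,
        cutpoints=cutpoints,
        class_labels=tuple(present),
        n_obs=n,
        loglike=loglike,
        loglike_null=loglike_null,
        converged=converged,
        warnings=tuple(flags),
        cutpoint_se=cut_se,
        beta_se=beta_se,
        config=config.to_dict() if config is not None else None,
    )


def _class_probs(model: PainScaleModel, s: np.ndarray) -> np.ndarray:
    """Cumulative-logit class probabilities for raw scores s."""
    cum = expit(model.cutpoints[None, :] - s[:, None])  # (n, n_cuts)
    ones = np.ones((len(s), 1))
    cum_full = np.hstack([np.zeros((len(s), 1)), cum, ones])
    return np.diff(cum_full, axis=1)


def score_table(model: PainScaleModel, table: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a feature table.

    Returns a copy of the metadata columns with ``score`` (raw linear
    predictor), ``pain_score`` (rescaled), ``predicted_class`` and
    ``predicted_pain`` columns appended.
    """
    z = model.standardize(table)
    s = z @ model.beta
    probs = _class_probs(model, s)
    classes = np.array(model.class_labels)[np.argmax(probs, axis=1)]
    c2, c3 = model.pain_cutpoint, model.unit_cutpoint
    out = table.loc[:, [c for c in table.columns if c in
                        ("trial_id", "strain", "mouse_id", "stimulus", "condition")]].copy()
    out["score"] = s
    out["pain_score"] = (s - c2) / (c3 - c2) if c2 is not None and c3 is not None else np.nan
    out["predicted_class"] = classes
    out["predicted_pain"] = s > c2 if c2 is not None else np.nan
    return out


def score(model: PainScaleModel, features: Mapping[str, float]) -> ScoredTrial:
    """Score a single trial's feature vector."""
    z = model.standardize(features)
    s = float(np.asarray(z @ model.beta).ravel()[0])
    probs = _class_probs(model, np.array([s]))[0]
    predicted_class = model.class_labels[int(np.argmax(probs))]
    c2, c3 = model.pain_cutpoint, model.unit_cutpoint
    pain_score = (s - c2) / (c3 - c2) if c2 is not None and c3 is not None else None
    predicted_pain = bool(s > c2) if c2 is not None else predicted_class in PAIN_STIMULI
    return ScoredTrial(
        score=s,
        pain_score=pain_score,
        predicted_class=predicted_class,
        predicted_pain=predicted_pain,
    )


def feature_importance(model: PainScaleModel) -> list[tuple[str, float]]:
    """Loadings on standardized features, sorted by |loading| descending."""
    order = np.argsort(-np.abs(model.beta))
    return [(model.feature_names[i], float(model.beta[i])) for i in order]
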