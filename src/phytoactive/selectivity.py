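"""Selectivity ratio (SR) via PLS target projection.

A PLS1 regression of (log) bioactivity on the (log, autoscaled) feature
matrix is rotated onto the single direction of its regression vector
("target projection").  For each feature the variance explained along the
target-projected score, v_expl, is compared with the residual variance,
v_resid; the selectivity ratio is SR = v_expl / v_resid.  SR > 1 therefore
means the target-projected component explains more than half of that
feature's variance — the conventional screening threshold for calling a
variable selective for the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .preprocess import BioactivityVector, FeatureMatrix, parse_feature_id

__all__ = [
    "PlsModel",
    "SRResult",
    "fit_pls",
    "select_n_components",
    "target_projection",
    "selectivity_ratio",
    "sr_analysis",
]


@dataclass
class PlsModel:
    """Fitted PLS1 model plus the preprocessing applied to reach it."""

    n_components: int
    scores: np.ndarray      # (n, a)
    weights: np.ndarray     # (p, a)
    loadings: np.ndarray    # (p, a)
    b: np.ndarray           # regression vector in preprocessed coordinates, (p,)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float

    def preprocess(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.preprocess(X) @ self.b + self.y_mean


@dataclass
class SRResult:
    feature_ids: list[str]
    sr: np.ndarray
    explained_fraction: np.ndarray
    rank: np.ndarray  # 1 = highest SR
    ion_mode: str = "NEG"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "ion_mode": self.ion_mode,
                "sr": self.sr,
                "explained_fraction": self.explained_fraction,
                "rank": self.rank,
            }
        )
        return df.sort_values("rank").reset_index(drop=True)


def _center_scale(X: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        sd = np.ones(X.shape[1])
    return (X - mean) / sd, mean, sd


def fit_pls(
    X: np.ndarray, y: np.ndarray, n_components: int, scale: bool = True
) -> PlsModel:
    """Fit a PLS1 model of y on X (column-centred, unit-variance by default).

    Deterministic: PLS1 weights are closed-form (w = X'y / ||X'y|| per
    deflation step), no iteration-order ambiguity.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on the number of fractions")
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components={n_components} invalid; must be in [1, {max_comp}]"
        )
    Xs, x_mean, x_scale = _center_scale(X, scale)
    y_mean = float(y.mean())
    yc = y - y_mean
    if np.linalg.norm(Xs.T @ yc) == 0:
        raise ValueError("no covariance between X and y; PLS weight vector is zero")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when y residual vanishes
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(Xs, yc)
    b = np.asarray(pls.coef_).reshape(-1)
    return PlsModel(
        n_components=n_components,
        scores=np.asarray(pls.x_scores_),
        weights=np.asarray(pls.x_weights_),
        loadings=np.asarray(pls.x_loadings_),
        b=b,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
    )


def select_n_components(
    X: np.ndarray, y: np.ndarray, max_components: int = 10, scale: bool = True
) -> int:
    """Pick the component count by leave-one-out CV (minimum RMSECV).

    Ties go to the smaller model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 fractions for LOO component selection")
    amax = min(max_components, n - 2, X.shape[1])
    press = np.zeros(amax)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        for a in range(1, amax + 1):
            try:
                m = fit_pls(X[mask], y[mask], a, scale=scale)
                pred = m.predict(X[i : i + 1])[0]
            except ValueError:
                press[a - 1] = np.inf
                continue
            press[a - 1] += (pred - y[i]) ** 2
    return int(np.argmin(press)) + 1


def target_projection(model: PlsModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the model onto its regression vector.

    Returns the target-projected scores ``t_tp = Xs b / ||b||`` and loadings
    ``p_tp = Xs' t_tp / (t_tp' t_tp)`` computed on the model's preprocessed
    coordinates.
    """
    bnorm = np.linalg.norm(model.b)
    if bnorm == 0:
        raise ValueError("regression vector is zero; target projection undefined")
    Xs = model.preprocess(X)
    t_tp = Xs @ (model.b / bnorm)
    denom = float(t_tp @ t_tp)
    if denom == 0:
        raise ValueError("target-projected scores are identically zero")
    p_tp = Xs.T @ t_tp / denom
    return t_tp, p_tp


def selectivity_ratio(
    X: np.ndarray,
    t_tp: np.ndarray,
    p_tp: np.ndarray,
    feature_ids: list[str] | None = None,
    ion_mode: str = "NEG",
    model: PlsModel | None = None,
) -> SRResult:
    """Per-feature explained/residual variance decomposition along ``t_tp``.

    ``X`` is preprocessed with ``model`` when given (otherwise assumed to be
    already in the coordinates ``t_tp``/``p_tp`` were computed in).  Features
    with zero residual get SR = +inf and rank above all finite values; ties
    break by ascending m/z when feature ids are supplied, else by position.
    """
    Xs = model.preprocess(X) if model is not None else np.asarray(X, dtype=float)
    t_tp = np.asarray(t_tp, dtype=float)
    p_tp = np.asarray(p_tp, dtype=float)
    n, p = Xs.shape
    if t_tp.shape[0] != n or p_tp.shape[0] != p:
        raise ValueError("dimension mismatch between X, t_tp and p_tp")
    tt = float(t_tp @ t_tp)
    v_expl = p_tp**2 * tt
    resid = Xs - np.outer(t_tp, p_tp)
    v_resid = np.einsum("ij,ij->j", resid, resid)
    # guard tiny negative round-off and the all-zero column (0/0 -> SR 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(v_resid > 0, v_expl / v_resid, np.inf)
        frac = np.where(v_expl + v_resid > 0, v_expl / (v_expl + v_resid), 0.0)
    sr = np.where((v_expl == 0) & (v_resid == 0), 0.0, sr)

    if feature_ids is not None:
        if len(feature_ids) != p:
            raise ValueError("feature_ids length does not match X")
        mz = np.array([parse_feature_id(f)[1] for f in feature_ids])
    else:
        feature_ids = [f"0.00_{100.0 + i:.4f}" for i in range(p)]
        mz = np.arange(p, dtype=float)
    order = np.lexsort((mz, -frac))  # frac is monotone in SR and finite
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return SRResult(
        feature_ids=list(feature_ids),
        sr=sr,
        explained_fraction=frac,
        rank=rank,
        ion_mode=ion_mode,
    )


def sr_analysis(
    matrix: FeatureMatrix,
    viability: BioactivityVector,
    n_components: int | str = "auto",
    scale: bool = True,
    log_response: bool = False,
) -> SRResult:
    """End-to-end SR on a (log-transformed) feature matrix and viability vector."""
    from .preprocess import log_transform_response

    if matrix.n_fractions < 3:
        raise ValueError("SR needs at least 3 fractions")
    v = viability.aligned_to(matrix)
    y = log_transform_response(v) if log_response else v.viability_pct
    X = matrix.values()
    if n_components == "auto":
        n_components = select_n_components(X, y, scale=scale)
    model = fit_pls(X, y, int(n_components), scale=scale)
    t_tp, p_tp = target_projection(model, X)
    return selectivity_ratio(
        X, t_tp, p_tp, feature_ids=matrix.feature_ids,
        ion_mode=matrix.ion_mode, model=model,
    )
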