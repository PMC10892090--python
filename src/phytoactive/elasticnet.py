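"""Bootstrap Elastic Net ensemble feature ranking.

With ~21 fractions and >1500 features a single penalized regression is an
unstable variable selector, so the ranking statistic here is the selection
frequency over an ensemble (default 1000) of Elastic Net models, each fit
on a bootstrap resample of the fractions with its penalty weight chosen by
internal cross-validation on that resample.  Features are ranked by how
often they carry a nonzero coefficient, with mean |coefficient| and then
ascending m/z as tie-breaks.  POS- and NEG-mode matrices are modelled
separately and never mixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .preprocess import BioactivityVector, FeatureMatrix, parse_feature_id

__all__ = ["EnsembleConfig", "ENRankResult", "fit_ensemble", "rank_features", "en_analysis"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble settings.

    n_models : ensemble size (1000 by default).
    alpha : L1/L2 mixing weight in (0, 1]; the ridge-leaning default (0.2)
        keeps families of near-collinear bioactives selected together
        (grouping effect); 0.5 gives an even lasso/ridge blend.
    lambda_selection : number of internal CV folds used to pick the penalty
        strength within each bootstrap member.
    n_alphas : length of the penalty-strength grid searched per member.
    seed : RNG seed; the whole ensemble is reproducible from it.
    """

    n_models: int = 1000
    alpha: float = 0.2
    lambda_selection: int = 5
    n_alphas: int = 15
    eps: float = 0.02    # alpha_min/alpha_max of the penalty path
    tol: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class ENRankResult:
    feature_ids: list[str]
    selection_frequency: np.ndarray
    mean_abs_coefficient: np.ndarray
    rank: np.ndarray          # float; NaN for never-selected features
    n_selected: int           # the "of N" denominator
    ion_mode: str = "NEG"

    def rank_label(self, fid: str) -> str:
        """Table-style label, e.g. ``"1 (of 85)"``; ``"-"`` if never selected."""
        i = self.feature_ids.index(fid)
        if np.isnan(self.rank[i]):
            return "-"
        return f"{int(self.rank[i])} (of {self.n_selected})"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "ion_mode": self.ion_mode,
                "selection_frequency": self.selection_frequency,
                "mean_abs_coefficient": self.mean_abs_coefficient,
                "rank": self.rank,
                "n_selected": self.n_selected,
            }
        )
        return df.sort_values(
            ["rank"], na_position="last", kind="stable"
        ).reset_index(drop=True)


def fit_ensemble(
    X: np.ndarray, y: np.ndarray, config: EnsembleConfig = EnsembleConfig()
) -> np.ndarray:
    """Fit the bootstrap ensemble; returns coefficients, shape (n_models, p).

    Each member draws a same-size bootstrap resample of fractions,
    standardizes X within the resample, centres y, fits Elastic Net at the
    configured L1/L2 mix with the penalty weight chosen by internal K-fold
    CV on the resample, and maps coefficients back to the original scale
    (divide by the within-resample standard deviation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on the number of fractions")
    if n < 6:
        raise ValueError("ensemble resampling needs at least 6 fractions")

    rng = np.random.default_rng(config.seed)
    member_seeds = rng.integers(0, 2**31 - 1, size=config.n_models)
    coefs = np.zeros((config.n_models, p))
    if np.std(y) == 0:
        return coefs  # no signal: every member is the null model

    for m, mseed in enumerate(member_seeds):
        mrng = np.random.default_rng(int(mseed))
        idx = mrng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        if np.std(yb) == 0:
            continue
        mu, sd = Xb.mean(axis=0), Xb.std(axis=0)
        sd_safe = np.where(sd == 0, 1.0, sd)
        Xs = (Xb - mu) / sd_safe
        yc = yb - yb.mean()
        cv = KFold(
            n_splits=min(config.lambda_selection, n - 1),
            shuffle=True,
            random_state=int(mseed) % (2**31 - 1),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            enet = ElasticNetCV(
                l1_ratio=config.alpha,
                alphas=config.n_alphas,  # grid size; sklearn builds the path
                eps=config.eps,
                tol=config.tol,
                cv=cv,
                fit_intercept=False,
                max_iter=2000,
                # seeded random coordinate selection: faster on correlated
                # columns and decorrelates which member of a collinear family
                # enters first across ensemble members
                selection="random",
                random_state=int(mseed) % (2**31 - 1),
            )
            enet.fit(Xs, yc)
        coefs[m] = enet.coef_ / sd_safe
        coefs[m, sd == 0] = 0.0
    return coefs


def rank_features(
    ensemble: np.ndarray, feature_ids: list[str], ion_mode: str = "NEG"
) -> ENRankResult:
    """Rank by selection frequency, then mean |coefficient|, then ascending m/z."""
    ensemble = np.asarray(ensemble, dtype=float)
    if ensemble.ndim != 2 or ensemble.shape[0] == 0:
        raise ValueError("empty or malformed ensemble")
    if ensemble.shape[1] != len(feature_ids):
        raise ValueError("ensemble width does not match feature_ids")
    selected = ensemble != 0
    freq = selected.mean(axis=0)
    n_sel_members = selected.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_abs = np.where(
            n_sel_members > 0,
            np.abs(ensemble).sum(axis=0) / np.maximum(n_sel_members, 1),
            0.0,
        )
    mz = np.array([parse_feature_id(f)[1] for f in feature_ids])
    order = np.lexsort((mz, -mean_abs, -freq))
    p = len(feature_ids)
    n_selected = int((freq > 0).sum())
    rank = np.full(p, np.nan)
    r = 1
    for j in order:
        if freq[j] > 0:
            rank[j] = r
            r += 1
    return ENRankResult(
        feature_ids=list(feature_ids),
        selection_frequency=freq,
        mean_abs_coefficient=mean_abs,
        rank=rank,
        n_selected=n_selected,
        ion_mode=ion_mode,
    )


def en_analysis(
    matrix: FeatureMatrix,
    viability: BioactivityVector,
    config: EnsembleConfig = EnsembleConfig(),
    log_response: bool = False,
) -> ENRankResult:
    """End-to-end ensemble ranking on a (log-transformed) matrix.

    The response is modelled on the % viability scale by default (the scale
    on which a dose-response readout is linear in log concentration); pass
    ``log_response=True`` for the ln-response variant.
    """
    from .preprocess import log_transform_response

    v = viability.aligned_to(matrix)
    y = log_transform_response(v) if log_response else v.viability_pct
    ens = fit_ensemble(matrix.values(), y, config)
    return rank_features(ens, matrix.feature_ids, ion_mode=matrix.ion_mode)
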