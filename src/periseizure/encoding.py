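"""Encoding model: GLM of seizure power with bootstrap drop-one contributions.

A Gaussian identity-link GLM (ordinary least squares with intercept)
predicts the 4-14 Hz seizure EEG power of each recording from the
pre-seizure and during-seizure neural-activity means.  The *relative
contribution* of each predictor is estimated by repeated random 70/30
train/validation splitting: on each of ``n_boot`` iterations the training
rows are resampled with replacement, the full model and each drop-one
model are fit on that bootstrap sample, and held-out R^2 is computed on
the untouched validation rows.  A predictor's contribution is the decline
in mean validation R^2 when it is dropped, clipped at zero; relative
contributions are the clipped declines normalized to sum to one.

Validation R^2 may legitimately be negative (worse than predicting the
validation mean); clipping applies only to the contributions, never to
the reported full-model R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import PeriSeizureError, SingularDesignError, SplitError

__all__ = [
    "GLMFit",
    "ContributionResult",
    "BootstrapContributionGLM",
    "fit_glm",
    "contribution_analysis",
    "correlate",
]


@dataclass
class GLMFit:
    """Least-squares GLM fit: ``coefficients[0]`` is the intercept."""

    coefficients: np.ndarray
    r_squared: float

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]


@dataclass
class ContributionResult:
    """Bootstrap drop-one contribution analysis summary.

    ``contributions`` are the clipped mean validation-R^2 declines per
    predictor (>= 0); ``relative_contributions`` normalize them to sum to 1
    (all zero when no predictor helps).
    """

    r_squared_full: float
    contributions: dict[str, float]
    relative_contributions: dict[str, float]
    n_boot: int
    train_fraction: float
    seed: int | None
    drop_r_squared: dict[str, float] = field(default_factory=dict)


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """1 - SSE/SST; defined as 0 when y is constant (SST = 0)."""
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0
    sse = float(np.sum((y - y_hat) ** 2))
    return 1.0 - sse / sst


def fit_glm(X: np.ndarray, y: np.ndarray) -> GLMFit:
    """Gaussian identity-link GLM: least squares with intercept.

    Raises :class:`SingularDesignError` on rank-deficient designs (e.g. a
    constant or duplicated predictor column).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise PeriSeizureError("X and y row counts differ")
    if X.shape[0] < X.shape[1] + 2:
        raise PeriSeizureError(
            f"need at least {X.shape[1] + 2} rows to fit {X.shape[1]} predictors"
        )
    A = _design(X)
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    return GLMFit(coefficients=coef, r_squared=_r_squared(y, A @ coef))


class BootstrapContributionGLM(BaseEstimator):
    """Bootstrap drop-one relative-contribution analysis as an estimator.

    Parameters
    ----------
    n_boot : int
        Number of bootstrap iterations (the study design uses 5000; smaller
        values trade precision for speed).
    train_fraction : float
        Fraction of rows used for training in each split (0.7).
    resplit_each_iteration : bool
        Draw a fresh train/validation split every iteration (default).  When
        False a single split is drawn once and reused, with the bootstrap
        resampling still applied to the training rows.
    random_state : int or None
        Seed for the split and resampling stream; fixing it makes the
        result bit-reproducible.

    Attributes (after ``fit``)
    --------------------------
    r_squared_full_ : float
        Mean validation R^2 of the full model.
    contributions_ : ndarray
        Clipped mean validation-R^2 decline per predictor.
    relative_contributions_ : ndarray
        Contributions normalized to sum to 1 (all zero if none positive).
    drop_r_squared_ : ndarray
        Mean validation R^2 of each drop-one model.
    """

    def __init__(
        self,
        n_boot: int = 5000,
        train_fraction: float = 0.7,
        resplit_each_iteration: bool = True,
        random_state: int | None = None,
    ):
        self.n_boot = n_boot
        self.train_fraction = train_fraction
        self.resplit_each_iteration = resplit_each_iteration
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BootstrapContributionGLM":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise PeriSeizureError("X must be 2-dimensional (rows x predictors)")
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise PeriSeizureError("X and y row counts differ")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise PeriSeizureError("design matrix contains non-finite values")
        if np.any(np.ptp(X, axis=0) == 0):
            raise SingularDesignError("a predictor column is constant")
        if not 0.0 < self.train_fraction < 1.0:
            raise PeriSeizureError("train_fraction must lie in (0, 1)")
        if self.n_boot < 1:
            raise PeriSeizureError("n_boot must be at least 1")
        n_train = int(round(self.train_fraction * n))
        n_val = n - n_train
        if n_val < 2 or n_train < p + 2:
            raise SplitError(
                f"{n} rows cannot give >= 2 validation rows and "
                f">= {p + 2} training rows at train_fraction={self.train_fraction}"
            )

        rng = np.random.default_rng(self.random_state)
        full = np.empty(self.n_boot)
        drops = np.empty((self.n_boot, p))
        keep = [np.delete(np.arange(p), j) for j in range(p)]
        perm = rng.permutation(n)
        for b in range(self.n_boot):
            if self.resplit_each_iteration or b == 0:
                perm = rng.permutation(n)
            train, val = perm[:n_train], perm[n_train:]
            boot = train[rng.integers(0, n_train, n_train)]
            Xb, yb = X[boot], y[boot]
            Xv, yv = X[val], y[val]
            Ab = _design(Xb)
            coef = np.linalg.lstsq(Ab, yb, rcond=None)[0]
            full[b] = _r_squared(yv, _design(Xv) @ coef)
            for j in range(p):
                cols = keep[j]
                coef_j = np.linalg.lstsq(
                    np.column_stack([np.ones(n_train), Xb[:, cols]]), yb, rcond=None
                )[0]
                drops[b, j] = _r_squared(
                    yv, np.column_stack([np.ones(n_val), Xv[:, cols]]) @ coef_j
                )

        self.n_features_in_ = p
        self.r_squared_full_ = float(full.mean())
        self.drop_r_squared_ = drops.mean(axis=0)
        raw = self.r_squared_full_ - self.drop_r_squared_
        self.raw_declines_ = raw
        self.contributions_ = np.clip(raw, 0.0, None)
        total = self.contributions_.sum()
        self.relative_contributions_ = (
            self.contributions_ / total if total > 0 else np.zeros(p)
        )
        return self

    def result(self, feature_names: list[str] | None = None) -> ContributionResult:
        """Package fitted attributes as a :class:`ContributionResult`."""
        check_is_fitted(self, "contributions_")
        p = self.n_features_in_
        names = feature_names or [f"x{j}" for j in range(p)]
        if len(names) != p:
            raise PeriSeizureError("feature_names length mismatch")
        return ContributionResult(
            r_squared_full=self.r_squared_full_,
            contributions=dict(zip(names, map(float, self.contributions_))),
            relative_contributions=dict(
                zip(names, map(float, self.relative_contributions_))
            ),
            n_boot=self.n_boot,
            train_fraction=self.train_fraction,
            seed=self.random_state,
            drop_r_squared=dict(zip(names, map(float, self.drop_r_squared_))),
        )


def contribution_analysis(
    X: np.ndarray,
    y: np.ndarray,
    n_boot: int = 5000,
    train_fraction: float = 0.7,
    seed: int | None = None,
    feature_names: list[str] | None = None,
    resplit_each_iteration: bool = True,
) -> ContributionResult:
    """Functional wrapper over :class:`BootstrapContributionGLM`."""
    est = BootstrapContributionGLM(
        n_boot=n_boot,
        train_fraction=train_fraction,
        resplit_each_iteration=resplit_each_iteration,
        random_state=seed,
    ).fit(X, y)
    return est.result(feature_names)


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise PeriSeizureError("series lengths differ")
    if len(x) < 3:
        raise PeriSeizureError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PeriSeizureError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
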