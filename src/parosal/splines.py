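"""Cubic-spline DVH summarization and the spline-expanded logistic model.

Each DVH is compressed to six numbers by least-squares fitting a cubic spline
with 5 equally spaced knots to the cumulative curve on a dense dose grid; the
resulting coefficients (intercept + 5 basis weights) become the predictors of
a ridge-stabilized logistic regression, optionally with a natural-spline
expansion of each coefficient to add flexibility.

Basis construction.  A cubic spline on knots t1 < ... < tK that is "natural"
(linear) beyond both extreme knots spans only a K-dimensional space, which
cannot deliver K+1 full-rank coefficients.  We therefore use the
truncated-power cubic basis {1, u, (u-t1)^3+, ..., (u-t_{K-1})^3+} on dose
scaled by the top knot: a genuine cubic spline with the K stated knots, with
a zero second derivative at the left boundary, whose last-knot basis function
vanishes identically on the fitting range and is dropped.  This yields
exactly K+1 coefficients (6 at the default K=5), contains every straight
line, and is full rank on any dense grid.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .cohort import Cohort
from .dvh import DoseVolumeHistogram

__all__ = [
    "SplineFeatureVector",
    "spline_featurize",
    "dvh_spline_design",
    "natural_spline_columns",
    "SplineLogisticModel",
    "SplineLogisticResults",
    "fit_spline_logistic",
    "tune_expansion",
]

DEFAULT_RIDGE = 1e-4  # per-observation L2 penalty on the logistic weights


class SplineFitError(ValueError):
    """Raised when the DVH spline basis is rank deficient (degenerate support)."""


@dataclasses.dataclass(frozen=True)
class SplineFeatureVector:
    """Six coefficients summarizing one DVH, with the knots that defined them."""

    coefficients: np.ndarray  # intercept + n_knots basis weights
    knots: np.ndarray  # dose knots in Gy, equally spaced
    fit_rmse: float  # RMS approximation error in fractional volume units

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, float))
        object.__setattr__(self, "knots", np.asarray(self.knots, float))
        if self.coefficients.size != self.knots.size + 1:
            raise ValueError("expected intercept + one weight per knot")


def dvh_spline_design(dose: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix [1, u, (u-k_1)^3+, ..., (u-k_{K-1})^3+], u = dose/knots[-1]."""
    dose = np.asarray(dose, float)
    knots = np.asarray(knots, float)
    top = knots[-1]
    if top <= knots[0]:
        raise SplineFitError("knot range is degenerate")
    u = dose / top
    k = knots / top
    cols = [np.ones_like(u), u]
    for kj in k[:-1]:
        cols.append(np.clip(u - kj, 0.0, None) ** 3)
    return np.column_stack(cols)


def spline_featurize(
    dvh: DoseVolumeHistogram,
    n_knots: int = 5,
    dose_range: tuple[float, float] | None = None,
    grid_step: float = 0.5,
    check_support: bool = True,
) -> SplineFeatureVector:
    """Least-squares cubic-spline summary of a DVH.

    Knots are placed equally spaced across ``dose_range`` (default: 0 to the
    DVH's maximum observed dose); the spline is fitted by ordinary least
    squares to the step-interpolated cumulative curve on a dense
    ``grid_step``-Gy grid.  Returns intercept + ``n_knots`` basis weights.
    """
    if n_knots < 2:
        raise ValueError("n_knots must be at least 2")
    lo, hi = dose_range if dose_range is not None else (0.0, dvh.max_dose)
    if hi <= lo:
        raise SplineFitError(
            f"degenerate dose range [{lo}, {hi}] for {dvh.gland_label} DVH"
        )
    if check_support and dvh.max_dose > hi + 1e-9:
        raise ValueError("dose_range must cover the DVH support")
    knots = np.linspace(lo, hi, n_knots)
    n_grid = int(np.floor((hi - lo) / grid_step)) + 1
    grid = lo + np.arange(n_grid) * grid_step
    y = dvh.evaluate(grid)
    X = dvh_spline_design(grid, knots)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SplineFitError(
            f"rank-deficient spline basis (rank {rank} < {X.shape[1]}) "
            f"for {dvh.gland_label} DVH with max dose {dvh.max_dose:.2f} Gy"
        )
    rmse = float(np.sqrt(np.mean((X @ coef - y) ** 2)))
    return SplineFeatureVector(coefficients=coef, knots=knots, fit_rmse=rmse)


# ----------------------------------------------------------------------
# predictor-side natural-spline expansion
# ----------------------------------------------------------------------
def natural_spline_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Non-constant natural cubic spline basis for a scalar predictor.

    Standard truncated-power natural basis with K knots: the linear term plus
    K-2 curvature terms d_k(x) - d_{K-1}(x), where
    d_k(x) = [(x - t_k)^3+ - (x - t_K)^3+] / (t_K - t_k).  Fewer than three
    distinct knots reduce to the plain linear term.
    """
    x = np.asarray(x, float)
    knots = np.unique(np.asarray(knots, float))
    cols = [x]
    K = knots.size
    if K >= 3:
        def d(k: float) -> np.ndarray:
            return (
                np.clip(x - k, 0.0, None) ** 3 - np.clip(x - knots[-1], 0.0, None) ** 3
            ) / (knots[-1] - k)

        d_last = d(knots[-2])
        for t in knots[:-2]:
            cols.append(d(t) - d_last)
    return np.column_stack(cols)


def _expand_features(X: np.ndarray, knot_sets: list[np.ndarray] | None) -> np.ndarray:
    if knot_sets is None:
        return X
    return np.column_stack(
        [natural_spline_columns(X[:, j], knot_sets[j]) for j in range(X.shape[1])]
    )


def _quantile_knots(X: np.ndarray, n_knots: int) -> list[np.ndarray] | None:
    if n_knots < 2:
        return None
    qs = np.linspace(0.0, 1.0, n_knots)
    return [np.quantile(X[:, j], qs) for j in range(X.shape[1])]


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------
class SplineLogisticModel:
    """Spline-featurized DVHs feeding a ridge-stabilized logistic regression.

    Parameters
    ----------
    cohort
        Training cohort; each ipsilateral DVH is summarized by
        :func:`spline_featurize`.
    cutoff
        Flow-ratio cutoff defining the binary outcome (default 0.5, the
        tuning cutoff for the machine-learning models).
    expansion_knots
        Knot count of the additive natural-spline expansion applied to each
        of the six coefficients (0 = plain logistic on the coefficients).
    ridge
        Per-observation L2 penalty; keeps the fit finite under separation and
        makes predictions invariant to dataset replication.
    """

    def __init__(
        self,
        cohort: Cohort,
        cutoff: float = 0.5,
        n_knots: int = 5,
        dose_range: tuple[float, float] = (0.0, 70.0),
        expansion_knots: int = 0,
        ridge: float = DEFAULT_RIDGE,
        grid_step: float = 0.5,
    ):
        self.cohort = cohort
        self.cutoff = cutoff
        self.n_knots = n_knots
        self.dose_range = dose_range
        self.expansion_knots = expansion_knots
        self.ridge = ridge
        self.grid_step = grid_step
        self.features = np.vstack(
            [
                spline_featurize(
                    r.dvh, n_knots=n_knots, dose_range=dose_range, grid_step=grid_step
                ).coefficients
                for r in cohort
            ]
        )
        self.labels = cohort.labels(cutoff)

    def fit(self) -> "SplineLogisticResults":
        return fit_spline_logistic(
            self.features,
            self.labels,
            expansion_knots=self.expansion_knots,
            ridge=self.ridge,
            _parent=self,
        )


@dataclasses.dataclass
class SplineLogisticResults:
    """Fitted spline-logistic predictor."""

    weights: np.ndarray  # logistic coefficients on standardized expanded features
    intercept: float
    expansion_knot_sets: list[np.ndarray] | None
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    ridge: float
    expansion_knots: int
    fitted_probabilities: np.ndarray
    model: SplineLogisticModel | None = None
    tuning: dict | None = None

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        """Complication probabilities from raw 6-coefficient feature rows."""
        X = np.atleast_2d(np.asarray(X, float))
        Z = _expand_features(X, self.expansion_knot_sets)
        Z = (Z - self.feature_mean) / self.feature_scale
        return 1.0 / (1.0 + np.exp(-(Z @ self.weights + self.intercept)))

    def predict(self, data: Cohort | DoseVolumeHistogram) -> np.ndarray | float:
        """Probabilities for a cohort (array) or a single DVH (scalar)."""
        if self.model is None:
            raise ValueError("results were fitted from bare features; use predict_features")
        single = isinstance(data, DoseVolumeHistogram)
        dvhs = [data] if single else [r.dvh for r in data]
        for dvh in dvhs:
            if dvh.max_dose > self.model.dose_range[1] + 1e-9:
                warnings.warn(
                    f"DVH support ({dvh.max_dose:.1f} Gy) exceeds the training dose "
                    f"range {self.model.dose_range}; prediction is an extrapolation",
                    stacklevel=2,
                )
        X = np.vstack(
            [
                spline_featurize(
                    dvh,
                    n_knots=self.model.n_knots,
                    dose_range=self.model.dose_range,
                    grid_step=self.model.grid_step,
                    check_support=False,
                ).coefficients
                for dvh in dvhs
            ]
        )
        p = self.predict_features(X)
        return float(p[0]) if single else p

    def summary(self) -> str:
        n_cols = self.weights.size
        lines = [
            "Spline-logistic DVH model",
            "=========================",
            f"observations            {self.fitted_probabilities.size}",
            f"expanded predictors     {n_cols}",
            f"expansion knots/coef    {self.expansion_knots}",
            f"ridge (per obs.)        {self.ridge:g}",
            f"intercept               {self.intercept:+.4f}",
        ]
        lines += [f"w[{j:02d}]                   {w:+.4f}" for j, w in enumerate(self.weights)]
        return "\n".join(lines)


def _penalized_logistic(Z: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    """Minimize mean Bernoulli NLL + 0.5*ridge*||w||^2 (intercept unpenalized).

    The per-observation scaling of both terms makes the optimum exactly
    invariant to replicating the dataset.
    """
    n, p = Z.shape

    def obj(beta: np.ndarray):
        w, b = beta[:-1], beta[-1]
        eta = Z @ w + b
        # log(1 + exp(eta)) - y*eta, numerically stable
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        mu = expit(eta)
        g_w = Z.T @ (mu - y) / n + ridge * w
        g_b = np.mean(mu - y)
        return nll + 0.5 * ridge * np.dot(w, w), np.concatenate([g_w, [g_b]])

    res = minimize(
        obj,
        np.zeros(p + 1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 10000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.x


def fit_spline_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    expansion_knots: int = 0,
    ridge: float = DEFAULT_RIDGE,
    _parent: SplineLogisticModel | None = None,
) -> SplineLogisticResults:
    """Penalized-ML logistic regression on (optionally spline-expanded) features.

    The L2 penalty is scaled per observation, so replicating every row leaves
    the optimum unchanged.  Raises on single-class labels.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels, int)
    if y.min() == y.max():
        raise ValueError("labels contain a single class; cannot fit a classifier")
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least 2 patients per class")
    knot_sets = _quantile_knots(X, expansion_knots)
    Z = _expand_features(X, knot_sets)
    mean = Z.mean(axis=0)
    scale = Z.std(axis=0)
    scale[scale == 0] = 1.0
    Zs = (Z - mean) / scale
    beta = _penalized_logistic(Zs, y, ridge)
    fitted = expit(Zs @ beta[:-1] + beta[-1])
    return SplineLogisticResults(
        weights=beta[:-1],
        intercept=float(beta[-1]),
        expansion_knot_sets=knot_sets,
        feature_mean=mean,
        feature_scale=scale,
        ridge=ridge,
        expansion_knots=expansion_knots,
        fitted_probabilities=fitted,
        model=_parent,
    )


def tune_expansion(
    cohort: Cohort,
    cutoff: float = 0.5,
    knot_grid: tuple[int, ...] = (0, 2, 3, 4),
    n_folds: int = 10,
    seed: int = 0,
    **model_kwargs,
) -> tuple[int, list[dict]]:
    """Choose the predictor-side expansion knot count by stratified K-fold CV AUC.

    Returns the winning knot count and the full (knots, cv_auc) trace.
    """
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import auc

    base = SplineLogisticModel(cohort, cutoff=cutoff, **model_kwargs)
    X, y = base.features, base.labels
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    trace = []
    for q in knot_grid:
        aucs = []
        for tr, te in folds:
            res = fit_spline_logistic(X[tr], y[tr], expansion_knots=q, ridge=base.ridge)
            aucs.append(auc(res.predict_features(X[te]), y[te]))
        trace.append({"expansion_knots": q, "cv_auc": float(np.mean(aucs))})
    best = max(trace, key=lambda row: row["cv_auc"])
    return int(best["expansion_knots"]), trace
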