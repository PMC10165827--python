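"""Single-hidden-layer neural network on the 1-Gy DVH grid.

The network reads the cumulative DVH sampled at 1-Gy intervals from 0 to
70 Gy (71 inputs), passes it through one logistic hidden layer (12 units by
default) and a logistic output, and is trained by full-batch quasi-Newton
minimization of the penalized criterion

    L(w) = -sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)] + decay * sum w^2,

the classical weight-decay formulation for this architecture (biases are
excluded from the penalty by default).  ``decay = 0.8`` is the default,
selected in the source analysis by ten-fold cross-validation; it both
regularizes and smooths the otherwise flat cost surface produced by the
strongly correlated DVH inputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .cohort import Cohort
from .dvh import DoseVolumeHistogram

__all__ = [
    "NeuralNetConfig",
    "NeuralNetWeights",
    "DVHNeuralNet",
    "NeuralNetResults",
    "fit_nn",
    "predict_nn",
    "tune_nn",
]

PROB_CLIP = 1e-12


@dataclasses.dataclass(frozen=True)
class NeuralNetConfig:
    """Architecture and training settings for the DVH network."""

    hidden_units: int = 12
    decay: float = 0.8
    max_iter: int = 500
    seed: int = 0
    n_restarts: int = 5
    grid_step: float = 1.0
    max_dose: float = 70.0
    penalize_biases: bool = False

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.decay < 0:
            raise ValueError("decay must be nonnegative")

    @property
    def n_inputs(self) -> int:
        return int(np.floor(self.max_dose / self.grid_step + 1e-12)) + 1

    @property
    def n_weights(self) -> int:
        """(inputs+1)*hidden + (hidden+1) free parameters."""
        return (self.n_inputs + 1) * self.hidden_units + self.hidden_units + 1


@dataclasses.dataclass(frozen=True)
class NeuralNetWeights:
    """Input->hidden and hidden->output weight sets including biases."""

    w1: np.ndarray  # (hidden, inputs)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2, [self.b2]])

    @classmethod
    def from_flat(cls, theta: np.ndarray, hidden: int, inputs: int) -> "NeuralNetWeights":
        k = hidden * inputs
        return cls(
            w1=theta[:k].reshape(hidden, inputs),
            b1=theta[k : k + hidden],
            w2=theta[k + hidden : k + 2 * hidden],
            b2=float(theta[-1]),
        )

    @property
    def count(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + 1


def _forward(theta: np.ndarray, X: np.ndarray, hidden: int):
    inputs = X.shape[1]
    w = NeuralNetWeights.from_flat(theta, hidden, inputs)
    h = expit(X @ w.w1.T + w.b1)
    p = expit(h @ w.w2 + w.b2)
    return p, h, w


def _loss_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, hidden: int,
               decay: float, penalize_biases: bool):
    p, h, w = _forward(theta, X, hidden)
    pc = np.clip(p, PROB_CLIP, 1 - PROB_CLIP)
    nll = -np.sum(y * np.log(pc) + (1 - y) * np.log1p(-pc))
    penalty_vec = theta if penalize_biases else np.concatenate(
        [w.w1.ravel(), np.zeros(hidden), w.w2, [0.0]]
    )
    loss = nll + decay * np.dot(penalty_vec, penalty_vec)
    # backprop
    dz2 = p - y  # (n,)
    g_w2 = h.T @ dz2
    g_b2 = dz2.sum()
    dz1 = np.outer(dz2, w.w2) * h * (1 - h)  # (n, hidden)
    g_w1 = dz1.T @ X
    g_b1 = dz1.sum(axis=0)
    grad = np.concatenate([g_w1.ravel(), g_b1, g_w2, [g_b2]])
    grad = grad + 2.0 * decay * penalty_vec
    return loss, grad


def _cohort_inputs(cohort: Cohort, config: NeuralNetConfig) -> np.ndarray:
    return np.vstack(
        [r.dvh.resample(config.grid_step, config.max_dose) for r in cohort]
    )


class DVHNeuralNet:
    """Neural-network complication model built from a cohort.

    ``fit()`` runs ``n_restarts`` seeded random initializations (uniform on
    [-0.5, 0.5]) through L-BFGS and keeps the lowest penalized loss.
    """

    def __init__(self, cohort: Cohort, cutoff: float = 0.5,
                 config: NeuralNetConfig | None = None):
        self.config = config or NeuralNetConfig()
        self.cohort = cohort
        self.cutoff = cutoff
        self.X = _cohort_inputs(cohort, self.config)
        self.y = cohort.labels(cutoff)
        if self.y.min() == self.y.max():
            raise ValueError("outcome has no variation at this cutoff")

    def fit(self) -> "NeuralNetResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        best = None
        best_trace: list[float] = []
        converged = False
        for _ in range(cfg.n_restarts):
            theta0 = rng.uniform(-0.5, 0.5, size=cfg.n_weights)
            trace: list[float] = []
            res = minimize(
                _loss_grad,
                theta0,
                args=(self.X, self.y, cfg.hidden_units, cfg.decay, cfg.penalize_biases),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": cfg.max_iter, "ftol": 1e-12, "gtol": 1e-8},
                callback=lambda xk: trace.append(
                    _loss_grad(xk, self.X, self.y, cfg.hidden_units, cfg.decay,
                               cfg.penalize_biases)[0]
                ),
            )
            init_loss = _loss_grad(theta0, self.X, self.y, cfg.hidden_units,
                                   cfg.decay, cfg.penalize_biases)[0]
            if best is None or res.fun < best.fun:
                best = res
                best_trace = [init_loss] + trace
                converged = bool(res.success)
        weights = NeuralNetWeights.from_flat(best.x, cfg.hidden_units, self.X.shape[1])
        return NeuralNetResults(
            model=self,
            weights=weights,
            config=cfg,
            training_loss=float(best.fun),
            loss_trace=np.asarray(best_trace),
            converged=converged,
        )


@dataclasses.dataclass(frozen=True)
class NeuralNetResults:
    """Trained network: weights, config and the training loss trajectory."""

    weights: NeuralNetWeights
    config: NeuralNetConfig
    training_loss: float
    loss_trace: np.ndarray
    converged: bool
    model: DVHNeuralNet | None = None

    def predict(self, data: Cohort | DoseVolumeHistogram) -> np.ndarray | float:
        """Complication probability; DVHs are resampled to the model's grid."""
        single = isinstance(data, DoseVolumeHistogram)
        dvhs = [data] if single else [r.dvh for r in data]
        X = np.vstack(
            [d.resample(self.config.grid_step, self.config.max_dose) for d in dvhs]
        )
        p, _, _ = _forward(self.weights.flatten(), X, self.config.hidden_units)
        return float(p[0]) if single else p

    def summary(self) -> str:
        cfg = self.config
        return "\n".join(
            [
                "DVH neural network (single hidden layer)",
                "=========================================",
                f"inputs                 {cfg.n_inputs} (0..{cfg.max_dose:g} Gy, "
                f"{cfg.grid_step:g}-Gy grid)",
                f"hidden units           {cfg.hidden_units}",
                f"weight decay           {cfg.decay:g}",
                f"free parameters        {self.weights.count}",
                f"restarts / seed        {cfg.n_restarts} / {cfg.seed}",
                f"penalized loss         {self.training_loss:.4f}",
                f"converged              {self.converged}",
            ]
        )


def fit_nn(cohort: Cohort, cutoff: float = 0.5,
           config: NeuralNetConfig | None = None) -> NeuralNetResults:
    """Convenience wrapper: ``DVHNeuralNet(cohort, cutoff, config).fit()``."""
    return DVHNeuralNet(cohort, cutoff=cutoff, config=config).fit()


def predict_nn(results: NeuralNetResults,
               data: Cohort | DoseVolumeHistogram) -> np.ndarray | float:
    return results.predict(data)


def tune_nn(
    cohort: Cohort,
    cutoff: float = 0.5,
    decay_grid: tuple[float, ...] = (0.0, 0.1, 0.4, 0.8, 1.6),
    hidden_grid: tuple[int, ...] = (12,),
    n_folds: int = 10,
    seed: int = 0,
    base_config: NeuralNetConfig | None = None,
) -> tuple[NeuralNetConfig, list[dict]]:
    """Grid-search (hidden_units, decay) by stratified K-fold CV AUC.

    Returns the best config and the full (config, cv_auc) trace, one entry
    per grid point.  Folds whose training part loses a class trigger an
    error after a reseeded retry.
    """
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import auc

    base = base_config or NeuralNetConfig()
    X_all = _cohort_inputs(cohort, base)
    y = cohort.labels(cutoff)
    if y.min() == y.max():
        raise ValueError("outcome has no variation at this cutoff")

    folds = None
    for attempt in range(2):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        candidate = list(skf.split(X_all, y))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
               for tr, te in candidate):
            folds = candidate
            break
    if folds is None:
        raise ValueError("could not stratify folds with both classes present")

    trace = []
    for hidden in hidden_grid:
        for decay in decay_grid:
            cfg = dataclasses.replace(base, hidden_units=hidden, decay=decay)
            aucs = []
            for tr, te in folds:
                res = DVHNeuralNet(cohort.subset(tr), cutoff=cutoff, config=cfg).fit()
                scores = res.predict(cohort.subset(te))
                aucs.append(auc(scores, y[te]))
            trace.append(
                {"hidden_units": hidden, "decay": decay, "cv_auc": float(np.mean(aucs))}
            )
    best_row = max(trace, key=lambda r: r["cv_auc"])
    best = dataclasses.replace(
        base, hidden_units=best_row["hidden_units"], decay=best_row["decay"]
    )
    return best, trace
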