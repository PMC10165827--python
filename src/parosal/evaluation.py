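"""Train/test protocol and cutoff-dependent AUC comparison of the predictors.

The evaluation mirrors a standard outcome-prediction protocol: a stratified
70/30 train/test split, training of each candidate model on the training set
(LKB by maximum likelihood at the 0.25 cutoff; spline-logistic and neural
network at the 0.5 cutoff), a single scoring pass over the test set, and
then, for every complication cutoff on a grid, the test-set ROC AUC of each
model plus pairwise significance tests of AUC differences.  A literature
LKB parameterization (31 Gy, 0.54, 1) is scored without any fitting as a
reference.  Scores are cutoff-independent; only the binary labels change
along the grid.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .cohort import Cohort
from .lkb import LKBModel, LKBParameters, _CohortArrays
from .neural import DVHNeuralNet, NeuralNetConfig
from .splines import SplineLogisticModel

__all__ = [
    "SplitSpec",
    "split_cohort",
    "auc",
    "compare_auc",
    "CutoffAUCResult",
    "EvaluationConfig",
    "cutoff_auc_analysis",
    "DEFAULT_CUTOFF_GRID",
    "LITERATURE_PARAMS",
    "MODEL_NAMES",
]

#: parotid LKB parameters reported in the reference literature fit
LITERATURE_PARAMS = LKBParameters(td50_1=31.0, m=0.54, n=1.0)

DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(0.25, 0.751, 0.05), 2))

MODEL_NAMES = ("lkb_fitted", "lkb_literature", "spline", "neural_net")


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """70/30 train/test split, stratified on the label at ``stratify_cutoff``."""

    train_fraction: float = 0.7
    seed: int = 0
    stratify_cutoff: float = 0.5
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_cohort(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    """Disjoint, exhaustive, seeded train/test partition of a cohort.

    The training set receives ``round(train_fraction * N)`` records
    (510 -> 357/153 at 70/30); stratification keeps the event rate at
    ``stratify_cutoff`` balanced across the two parts.
    """
    n = len(cohort)
    if n < 10:
        raise ValueError("cohort too small to split (need >= 10 records)")
    n_train = int(round(spec.train_fraction * n))
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    else:
        y = cohort.labels(spec.stratify_cutoff)
        class_indices = [np.flatnonzero(y == c) for c in (0, 1)]
        # largest-remainder allocation so the class counts sum to n_train
        exact = [spec.train_fraction * idx.size for idx in class_indices]
        takes = [int(np.floor(e)) for e in exact]
        remainders = np.array(exact) - np.array(takes)
        for c in np.argsort(-remainders):
            if sum(takes) >= n_train:
                break
            takes[c] += 1
        train_parts = []
        for idx, take in zip(class_indices, takes):
            perm = rng.permutation(idx.size)
            train_parts.append(idx[perm[:take]])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.setdiff1d(np.arange(n), train_idx)
    prov = cohort.provenance
    return (
        cohort.subset(train_idx, provenance=f"{prov} [train seed={spec.seed}]"),
        cohort.subset(test_idx, provenance=f"{prov} [test seed={spec.seed}]"),
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form with ties counted 0.5."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placement_values(scores: np.ndarray, labels: np.ndarray):
    """Per-subject placement (structural) components of the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def compare_auc(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    method: str = "delong",
    n_permutations: int = 10000,
    seed: int = 0,
) -> float:
    """Two-sided p-value for equality of two correlated (paired) AUCs.

    ``method="delong"`` uses the asymptotic variance of the paired AUC
    difference built from per-subject placement values (the correlated-ROC
    construction); ``method="permutation"`` randomly swaps the two models'
    scores within subjects.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")

    if method == "permutation":
        return _permutation_p(scores_a, scores_b, labels, n_permutations, seed)
    if method != "delong":
        raise ValueError(f"unknown method {method!r}")

    v10_a, v01_a, auc_a = _placement_values(scores_a, labels)
    v10_b, v01_b, auc_b = _placement_values(scores_b, labels)
    n1, n0 = v10_a.size, v01_a.size
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least two subjects per class")
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n0
    if var <= 0:
        warnings.warn("zero variance of the AUC difference; returning p = 1",
                      stacklevel=2)
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * ndtr(-abs(z)))


def _permutation_p(scores_a, scores_b, labels, n_permutations, seed) -> float:
    observed = abs(auc(scores_a, labels) - auc(scores_b, labels))
    if observed == 0 and np.array_equal(scores_a, scores_b):
        return 1.0
    rng = np.random.default_rng(seed)
    n = labels.size
    hits = 0
    for _ in range(n_permutations):
        swap = rng.random(n) < 0.5
        sa = np.where(swap, scores_b, scores_a)
        sb = np.where(swap, scores_a, scores_b)
        if abs(auc(sa, labels) - auc(sb, labels)) >= observed - 1e-15:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ----------------------------------------------------------------------
# cutoff-dependent analysis
# ----------------------------------------------------------------------
@dataclasses.dataclass(frozen=True)
class EvaluationConfig:
    """Training settings for the four candidate models."""

    lkb_cutoff: float = 0.25
    ml_cutoff: float = 0.5
    literature_params: LKBParameters = LITERATURE_PARAMS
    nn_config: NeuralNetConfig = dataclasses.field(default_factory=NeuralNetConfig)
    spline_expansion_knots: int = 3
    refit_lkb_per_cutoff: bool = False


@dataclasses.dataclass(frozen=True)
class CutoffAUCResult:
    """Per-cutoff test-set AUCs and pairwise p-values for the four models."""

    cutoffs: np.ndarray
    auc_by_model: dict[str, np.ndarray]
    pairwise_p: dict[tuple[str, str], np.ndarray]
    n_test: int
    n_events_by_cutoff: np.ndarray
    scores: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cutoff, model, auc, n_events."""
        rows = []
        for i, c in enumerate(self.cutoffs):
            for name in MODEL_NAMES:
                rows.append(
                    {
                        "cutoff": float(c),
                        "model": name,
                        "auc": self.auc_by_model[name][i],
                        "n_events": int(self.n_events_by_cutoff[i]),
                    }
                )
        return pd.DataFrame(rows)

    def pairwise_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.cutoffs):
            for (a, b), p in self.pairwise_p.items():
                rows.append(
                    {"cutoff": float(c), "model_a": a, "model_b": b, "p_value": p[i]}
                )
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """AUC versus complication cutoff, one line per candidate model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for name in MODEL_NAMES:
            ax.plot(self.cutoffs, self.auc_by_model[name], marker="o", label=name)
        ax.set_xlabel("complication cutoff (flow ratio)")
        ax.set_ylabel("test-set AUC")
        ax.set_ylim(0.4, 1.0)
        ax.legend()
        return ax


def cutoff_auc_analysis(
    train: Cohort,
    test: Cohort,
    cutoff_grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID,
    config: EvaluationConfig | None = None,
) -> CutoffAUCResult:
    """Fit the candidate models on ``train``, sweep cutoffs on ``test``.

    Each model is trained once (LKB at ``config.lkb_cutoff``, the two
    machine-learning models at ``config.ml_cutoff``) and its test scores are
    evaluated against relabeled outcomes for every cutoff in the grid;
    ``refit_lkb_per_cutoff=True`` refits the LKB likelihood at each cutoff
    instead.  Cutoffs where the test set has a single class yield NaN rows
    rather than being dropped.
    """
    if len(cutoff_grid) == 0:
        raise ValueError("cutoff grid is empty")
    config = config or EvaluationConfig()

    lkb_res = LKBModel(train, cutoff=config.lkb_cutoff).fit()
    spline_res = SplineLogisticModel(
        train,
        cutoff=config.ml_cutoff,
        expansion_knots=config.spline_expansion_knots,
    ).fit()
    nn_res = DVHNeuralNet(train, cutoff=config.ml_cutoff, config=config.nn_config).fit()

    test_arrays = _CohortArrays(test)
    scores = {
        "lkb_fitted": lkb_res.predict(test),
        "lkb_literature": test_arrays.ntcp(config.literature_params),
        "spline": spline_res.predict(test),
        "neural_net": nn_res.predict(test),
    }

    cutoffs = np.asarray(cutoff_grid, float)
    pairs = [
        (MODEL_NAMES[i], MODEL_NAMES[j])
        for i in range(len(MODEL_NAMES))
        for j in range(i + 1, len(MODEL_NAMES))
    ]
    aucs = {name: np.full(cutoffs.size, np.nan) for name in MODEL_NAMES}
    pvals = {pair: np.full(cutoffs.size, np.nan) for pair in pairs}
    n_events = np.zeros(cutoffs.size, dtype=int)

    for i, c in enumerate(cutoffs):
        y = test.labels(float(c))
        n_events[i] = int(y.sum())
        if y.min() == y.max():
            continue  # reported as missing (NaN), not silently dropped
        cutoff_scores = dict(scores)
        if config.refit_lkb_per_cutoff:
            try:
                cutoff_scores["lkb_fitted"] = (
                    LKBModel(train, cutoff=float(c)).fit().predict(test)
                )
            except ValueError:
                cutoff_scores["lkb_fitted"] = np.full(len(test), np.nan)
        for name in MODEL_NAMES:
            if not np.any(np.isnan(cutoff_scores[name])):
                aucs[name][i] = auc(cutoff_scores[name], y)
        for a, b in pairs:
            sa, sb = cutoff_scores[a], cutoff_scores[b]
            if np.any(np.isnan(sa)) or np.any(np.isnan(sb)):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvals[(a, b)][i] = compare_auc(sa, sb, y)

    return CutoffAUCResult(
        cutoffs=cutoffs,
        auc_by_model=aucs,
        pairwise_p=pvals,
        n_test=len(test),
        n_events_by_cutoff=n_events,
        scores=scores,
    )
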