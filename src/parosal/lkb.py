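"""Lyman-Kutcher-Burman (LKB) normal tissue complication probability model.

The LKB model reduces a heterogeneous cumulative DVH to an equivalent
single-step irradiation via the effective-volume power law

    v_eff = sum_i dV_i (D_i / D_max)^(1/n),        d_eff = D_max,

then applies a probit dose-response in the reduced dose:

    TD50(v) = TD50(1) / v_eff^n,
    t       = (d_eff - TD50(v)) / (m * TD50(v)),
    NTCP    = Phi(t),

with Phi the standard normal CDF.  The three organ-specific parameters are
``TD50(1)`` (dose giving 50% complication probability under uniform
whole-organ irradiation), the slope ``m`` (``m * TD50(v)`` acts as the
standard deviation of the dose-response) and the volume-effect exponent ``n``
(``n = 1`` collapses the model onto mean organ dose; small ``n`` weights the
maximum dose).

Parameters are estimated by maximum likelihood on binary complication labels
(salivary flow ratio strictly below a cutoff, 0.25 by default).  The
:class:`LKBModel` / :class:`LKBResults` pair follows the fit/results idiom of
statistical modelling packages.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr

from .cohort import Cohort
from .dvh import DoseVolumeHistogram

__all__ = [
    "LKBParameters",
    "ReducedDVH",
    "reduce_dvh",
    "ntcp",
    "LKBModel",
    "LKBResults",
    "fit_lkb",
    "negative_log_likelihood",
]

#: probabilities are clipped to this interval inside the likelihood
PROB_CLIP = 1e-12

DEFAULT_BOUNDS = {"td50_1": (5.0, 150.0), "m": (0.05, 5.0), "n": (0.01, 1.0)}
DEFAULT_INIT = (40.0, 0.5, 0.7)
# deterministic multi-start grid; the likelihood can be flat in n
MULTISTART = [
    (40.0, 0.5, 0.7),
    (30.0, 1.0, 0.95),
    (60.0, 0.5, 0.5),
    (35.0, 1.5, 0.99),
    (45.0, 0.25, 0.3),
]


@dataclasses.dataclass(frozen=True)
class LKBParameters:
    """The organ-specific triple (TD50(1) [Gy], m, n) of the LKB model."""

    td50_1: float
    m: float
    n: float
    n_upper: float = 1.0

    def __post_init__(self) -> None:
        if not self.td50_1 > 0:
            raise ValueError("td50_1 must be positive")
        if not self.m > 0:
            raise ValueError("m must be positive")
        if not 0 < self.n <= self.n_upper:
            raise ValueError(f"n must lie in (0, {self.n_upper}]")

    def astuple(self) -> tuple[float, float, float]:
        return (self.td50_1, self.m, self.n)


@dataclasses.dataclass(frozen=True)
class ReducedDVH:
    """Effective single-step irradiation equivalent to a heterogeneous DVH."""

    d_eff: float
    v_eff: float
    t: float | None = None


def reduce_dvh(dvh: DoseVolumeHistogram, n: float, bin_dose: str = "edge") -> ReducedDVH:
    """Effective-volume reduction of a DVH at volume-effect exponent ``n``.

    Returns ``d_eff = D_max`` and ``v_eff = sum_i dV_i (D_i/D_max)^(1/n)``
    over the differential bins (fractional volumes, so the total-volume
    normalization is implicit).  Raises on an all-zero-dose DVH.
    """
    if not 0 < n <= 1 + 1e-12:
        raise ValueError("n must lie in (0, 1]")
    doses, masses = dvh.differential(bin_dose=bin_dose)
    d_max = dvh.max_dose
    if d_max <= 0:
        raise ValueError("degenerate DVH: no volume receives a positive dose")
    v_eff = float(np.dot(masses, (doses / d_max) ** (1.0 / n)))
    return ReducedDVH(d_eff=d_max, v_eff=v_eff)


def ntcp(
    dvh: DoseVolumeHistogram, params: LKBParameters, bin_dose: str = "edge"
) -> float:
    """Normal tissue complication probability of one DVH under ``params``."""
    red = reduce_dvh(dvh, params.n, bin_dose=bin_dose)
    td50_v = params.td50_1 / red.v_eff**params.n
    t = (red.d_eff - td50_v) / (params.m * td50_v)
    return float(ndtr(t))


# ----------------------------------------------------------------------
# vectorized cohort arrays
# ----------------------------------------------------------------------
class _CohortArrays:
    """Padded (masses, doses, d_max) matrices for fast cohort-wide NTCP."""

    def __init__(self, cohort: Cohort, bin_dose: str = "edge"):
        pairs = [r.dvh.differential(bin_dose=bin_dose) for r in cohort]
        d_max = np.array([r.dvh.max_dose for r in cohort])
        if np.any(d_max <= 0):
            bad = [cohort[i].patient_id for i in np.flatnonzero(d_max <= 0)]
            raise ValueError(f"degenerate DVH (zero dose) for patients {bad}")
        width = max(d.size for d, _ in pairs)
        self.doses = np.zeros((len(cohort), width))
        self.masses = np.zeros_like(self.doses)
        for i, (d, m) in enumerate(pairs):
            self.doses[i, : d.size] = d
            self.masses[i, : m.size] = m
        self.d_max = d_max
        self.ratio = self.doses / d_max[:, None]  # in [0, 1]

    def ntcp(self, params: LKBParameters) -> np.ndarray:
        v_eff = np.einsum("ij,ij->i", self.masses, self.ratio ** (1.0 / params.n))
        td50_v = params.td50_1 / v_eff**params.n
        t = (self.d_max - td50_v) / (params.m * td50_v)
        return ndtr(t)


def negative_log_likelihood(
    cohort: Cohort, params: LKBParameters, cutoff: float = 0.25
) -> float:
    """Bernoulli negative log-likelihood of the cohort labels under the LKB model."""
    arrays = _CohortArrays(cohort)
    y = cohort.labels(cutoff)
    return _nll(arrays, y, params)


def _nll(arrays: _CohortArrays, y: np.ndarray, params: LKBParameters) -> float:
    p = np.clip(arrays.ntcp(params), PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------
class LKBModel:
    """Maximum-likelihood LKB model for a cohort at a complication cutoff.

    Optimization runs on transformed parameters (log TD50(1), log m, and a
    logit rescaling of n onto its bound interval) so positivity and the bound
    on n are enforced by construction; a small deterministic multi-start grid
    guards against the flat-in-n likelihood.
    """

    def __init__(
        self,
        cohort: Cohort,
        cutoff: float = 0.25,
        bounds: dict[str, tuple[float, float]] | None = None,
        bin_dose: str = "edge",
    ):
        if len(cohort) == 0:
            raise ValueError("cohort is empty")
        if not 0 < cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        self.cohort = cohort
        self.cutoff = cutoff
        self.bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
        self.bin_dose = bin_dose
        self._arrays = _CohortArrays(cohort, bin_dose=bin_dose)
        self._y = cohort.labels(cutoff)
        if self._y.min() == self._y.max():
            raise ValueError("outcome has no variation at this cutoff")

    # parameter transform -------------------------------------------------
    def _to_theta(self, params: tuple[float, float, float]) -> np.ndarray:
        td50, m, n = params
        n_lo, n_hi = self.bounds["n"]
        frac = np.clip((n - n_lo) / (n_hi - n_lo), 1e-7, 1 - 1e-7)
        return np.array([np.log(td50), np.log(m), logit(frac)])

    def _from_theta(self, theta: np.ndarray) -> LKBParameters:
        n_lo, n_hi = self.bounds["n"]
        return LKBParameters(
            td50_1=float(np.exp(theta[0])),
            m=float(np.exp(theta[1])),
            n=float(n_lo + (n_hi - n_lo) * expit(theta[2])),
            n_upper=n_hi,
        )

    def loglike(self, params: LKBParameters) -> float:
        return -_nll(self._arrays, self._y, params)

    def nll(self, params: LKBParameters) -> float:
        return _nll(self._arrays, self._y, params)

    def fit(
        self,
        init: LKBParameters | tuple[float, float, float] | None = None,
        multistart: bool = True,
        maxiter: int = 500,
    ) -> "LKBResults":
        """Minimize the negative log-likelihood; returns :class:`LKBResults`."""
        if isinstance(init, LKBParameters):
            init = init.astuple()
        starts = [init or DEFAULT_INIT]
        if multistart:
            starts += [s for s in MULTISTART if s != starts[0]]
        td50_b, m_b = self.bounds["td50_1"], self.bounds["m"]
        theta_bounds = [
            (np.log(td50_b[0]), np.log(td50_b[1])),
            (np.log(m_b[0]), np.log(m_b[1])),
            (-16.0, 16.0),
        ]

        def objective(theta: np.ndarray) -> float:
            return _nll(self._arrays, self._y, self._from_theta(theta))

        best = None
        any_converged = False
        for start in starts:
            res = minimize(
                objective,
                self._to_theta(start),
                method="L-BFGS-B",
                bounds=theta_bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
            )
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        params = self._from_theta(best.x)
        return LKBResults(
            model=self,
            params=params,
            nll=float(best.fun),
            converged=any_converged,
            n_starts=len(starts),
            init=LKBParameters(*(init or DEFAULT_INIT)),
        )


@dataclasses.dataclass(frozen=True)
class LKBResults:
    """Fitted LKB parameters with likelihood diagnostics."""

    model: LKBModel
    params: LKBParameters
    nll: float
    converged: bool
    n_starts: int
    init: LKBParameters

    @property
    def n_patients(self) -> int:
        return len(self.model.cohort)

    @property
    def cutoff(self) -> float:
        return self.model.cutoff

    def predict(self, data: Cohort | DoseVolumeHistogram) -> np.ndarray | float:
        """NTCP for a cohort (array) or a single DVH (scalar)."""
        if isinstance(data, DoseVolumeHistogram):
            return ntcp(data, self.params, bin_dose=self.model.bin_dose)
        return _CohortArrays(data, bin_dose=self.model.bin_dose).ntcp(self.params)

    def to_dict(self) -> dict:
        return {
            "td50_1_gy": self.params.td50_1,
            "m": self.params.m,
            "n": self.params.n,
            "nll": self.nll,
            "converged": self.converged,
            "n_patients": self.n_patients,
            "cutoff": self.cutoff,
        }

    def summary(self) -> str:
        lines = [
            "LKB maximum-likelihood fit",
            "==========================",
            f"patients              {self.n_patients}",
            f"complication cutoff   {self.cutoff:.2f} x baseline flow",
            f"events                {int(self.model._y.sum())}",
            f"TD50(1)  [Gy]         {self.params.td50_1:.3f}",
            f"m                     {self.params.m:.4f}",
            f"n                     {self.params.n:.4f}",
            f"neg. log-likelihood   {self.nll:.4f}",
            f"converged             {self.converged} ({self.n_starts} starts)",
        ]
        return "\n".join(lines)


def fit_lkb(
    cohort: Cohort,
    cutoff: float = 0.25,
    init: LKBParameters | tuple[float, float, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> LKBResults:
    """Convenience wrapper: ``LKBModel(cohort, cutoff, bounds).fit(init)``."""
    return LKBModel(cohort, cutoff=cutoff, bounds=bounds).fit(init=init)
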