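"""Cumulative dose-volume histograms (DVHs).

A cumulative DVH is a non-increasing step function ``V(d)`` giving, for each
dose level ``d`` (Gy), the fraction of the organ volume receiving at least
``d``.  It is the universal input to every predictor in this package: the
Lyman-Kutcher-Burman reduction consumes its differential bins, the spline
featurizer fits a smooth curve to it, and the neural network reads it on a
fixed 1-Gy grid.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

__all__ = ["DoseVolumeHistogram", "DVHValidationError", "uniform_dvh"]

#: absolute tolerance used when validating volume fractions
VOLUME_TOL = 1e-9

BinDose = Literal["edge", "midpoint"]


class DVHValidationError(ValueError):
    """Raised when a dose-volume histogram violates its invariants."""


@dataclasses.dataclass(frozen=True)
class DoseVolumeHistogram:
    """A cumulative, fractional-volume DVH for one gland.

    Parameters
    ----------
    dose_edges
        Strictly increasing dose values in Gy; the first edge must be 0.
    cum_volume
        Fraction of the organ volume receiving at least the corresponding
        dose.  ``cum_volume[0]`` must be 1 (the whole organ receives >= 0 Gy)
        and the sequence must be non-increasing with values in [0, 1].
    total_volume
        Absolute organ volume in arbitrary units; kept for provenance only,
        all computations use fractional volumes.
    gland_label
        ``"ipsilateral"`` or ``"contralateral"``.
    """

    dose_edges: np.ndarray
    cum_volume: np.ndarray
    total_volume: float = 1.0
    gland_label: str = "ipsilateral"

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=float)
        vol = np.asarray(self.cum_volume, dtype=float)
        if edges.ndim != 1 or vol.ndim != 1:
            raise DVHValidationError("dose_edges and cum_volume must be 1-D")
        if edges.size == 0:
            raise DVHValidationError("empty DVH")
        if edges.shape != vol.shape:
            raise DVHValidationError(
                f"dose_edges has {edges.size} entries but cum_volume has {vol.size}"
            )
        if not (np.all(np.isfinite(edges)) and np.all(np.isfinite(vol))):
            raise DVHValidationError("non-finite values in DVH")
        if edges[0] != 0.0:
            raise DVHValidationError(f"first dose edge must be 0 Gy, got {edges[0]}")
        if edges.size > 1 and np.any(np.diff(edges) <= 0):
            raise DVHValidationError("dose_edges must be strictly increasing")
        if abs(vol[0] - 1.0) > VOLUME_TOL:
            raise DVHValidationError(
                f"cum_volume[0] must be 1 (whole organ receives >= 0 Gy), got {vol[0]}"
            )
        if np.any(vol < -VOLUME_TOL) or np.any(vol > 1.0 + VOLUME_TOL):
            raise DVHValidationError("cum_volume values must lie in [0, 1]")
        if vol.size > 1 and np.any(np.diff(vol) > VOLUME_TOL):
            raise DVHValidationError("cum_volume must be non-increasing")
        if not self.total_volume > 0:
            raise DVHValidationError("total_volume must be positive")
        edges.setflags(write=False)
        vol.setflags(write=False)
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "cum_volume", vol)

    # ------------------------------------------------------------------
    # differential view
    # ------------------------------------------------------------------
    def differential(self, bin_dose: BinDose = "edge") -> tuple[np.ndarray, np.ndarray]:
        """Differential bins ``(doses, masses)`` of the cumulative DVH.

        The volume drop ``dV_i = cum_volume[i] - cum_volume[i+1]`` is assigned
        to the dose edge at which the cumulative curve drops (default) or to
        the midpoint of the bracketing edges (``bin_dose="midpoint"``).  The
        residual volume at the last edge is appended at the maximum dose, so
        the masses always sum to 1.
        """
        edges, vol = self.dose_edges, self.cum_volume
        drops = vol[:-1] - vol[1:]
        if bin_dose == "edge":
            doses = edges[1:]
        elif bin_dose == "midpoint":
            doses = 0.5 * (edges[:-1] + edges[1:])
        else:  # pragma: no cover - guarded by Literal type
            raise ValueError(f"unknown bin_dose convention {bin_dose!r}")
        doses = np.append(doses, edges[-1])
        masses = np.append(drops, vol[-1])
        return doses, masses

    @property
    def max_dose(self) -> float:
        """Largest dose (Gy) received by a nonzero fraction of the organ."""
        doses, masses = self.differential()
        nz = masses > 0
        return float(doses[nz].max()) if nz.any() else 0.0

    # ------------------------------------------------------------------
    # evaluation / resampling
    # ------------------------------------------------------------------
    def evaluate(self, dose: np.ndarray, kind: str = "step") -> np.ndarray:
        """Cumulative volume fraction at arbitrary doses.

        ``kind="step"`` (default) treats the DVH as a right-continuous step
        function: the value at dose ``d`` is ``cum_volume`` at the largest
        edge <= ``d``.  ``kind="linear"`` interpolates linearly between edges.
        Doses strictly beyond the last edge map to 0.
        """
        dose = np.asarray(dose, dtype=float)
        if kind == "step":
            idx = np.searchsorted(self.dose_edges, dose, side="right") - 1
            idx = np.clip(idx, 0, self.dose_edges.size - 1)
            out = self.cum_volume[idx]
        elif kind == "linear":
            out = np.interp(dose, self.dose_edges, self.cum_volume)
        else:
            raise ValueError(f"unknown interpolation kind {kind!r}")
        out = np.where(dose > self.dose_edges[-1], 0.0, out)
        return np.where(dose < 0, 1.0, out)

    def resample(
        self, grid_step: float = 1.0, max_dose: float = 70.0, kind: str = "step"
    ) -> np.ndarray:
        """Volume fractions on the regular grid ``0, grid_step, ..., max_dose``.

        The 1-Gy grid on [0, 70] Gy (71 values) is the neural-network input
        convention; any positive step is accepted.
        """
        if grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if max_dose < grid_step:
            raise ValueError("max_dose must be at least one grid_step")
        n = int(np.floor(max_dose / grid_step + 1e-12))
        grid = np.arange(n + 1) * grid_step
        return self.evaluate(grid, kind=kind)

    def mean_dose(self, bin_dose: BinDose = "edge") -> float:
        """Mean organ dose in Gy, ``sum_i dV_i * D_i`` over differential bins."""
        doses, masses = self.differential(bin_dose=bin_dose)
        return float(np.dot(doses, masses))


def uniform_dvh(dose: float, gland_label: str = "ipsilateral") -> DoseVolumeHistogram:
    """DVH of uniform whole-organ irradiation: 100% of the volume at ``dose`` Gy."""
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    if dose == 0:
        return DoseVolumeHistogram(np.array([0.0]), np.array([1.0]), gland_label=gland_label)
    return DoseVolumeHistogram(
        np.array([0.0, float(dose)]), np.array([1.0, 1.0]), gland_label=gland_label
    )
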