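"""Patient records, cohorts and their on-disk formats.

A :class:`PatientRecord` couples the ipsilateral parotid DVH with the pre- and
one-year post-radiotherapy stimulated whole-mouth salivary flow rates (g/min).
The flow ratio ``post/pre`` defines the binary complication outcome at any
chosen cutoff: a patient has a complication when the ratio falls strictly
below the cutoff (e.g. below 25% of baseline for a severe reduction).

Two plain-text formats are supported.  CSV splits the cohort into a scalar
table (``patient_id, pre_flow, post_flow``) plus a companion long-format DVH
table (``patient_id, gland, dose_gy, cum_volume_fraction``); JSON nests the
DVH arrays per patient in a single file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .dvh import DoseVolumeHistogram, DVHValidationError

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "CohortParseError",
    "complication_label",
    "read_cohort",
    "write_cohort",
]

PATIENT_COLUMNS = ["patient_id", "pre_flow", "post_flow"]
DVH_COLUMNS = ["patient_id", "gland", "dose_gy", "cum_volume_fraction"]


class CohortValidationError(ValueError):
    """A record violates a cohort invariant; the message names the patient."""


class CohortParseError(ValueError):
    """A cohort file could not be parsed; the message names file and record."""


def complication_label(record: "PatientRecord", cutoff: float) -> int:
    """1 if the salivary flow ratio is strictly below ``cutoff``, else 0.

    Ties at the cutoff are non-complications ("reduced to less than" the
    stated fraction of baseline).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    return int(record.flow_ratio < cutoff)


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """One subject: id, ipsilateral DVH and pre/post salivary flow rates."""

    patient_id: str
    dvh: DoseVolumeHistogram
    pre_flow: float
    post_flow: float
    dvh_contra: DoseVolumeHistogram | None = None

    def __post_init__(self) -> None:
        if not self.pre_flow > 0:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: pre_flow must be > 0 "
                f"(got {self.pre_flow}); the flow ratio is undefined otherwise"
            )
        if self.post_flow < 0:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: post_flow must be >= 0 (got {self.post_flow})"
            )

    @property
    def flow_ratio(self) -> float:
        """Post- over pre-therapy stimulated salivary flow (unitless, >= 0)."""
        return self.post_flow / self.pre_flow


@dataclasses.dataclass(frozen=True)
class Cohort:
    """An ordered collection of patient records with unique ids."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id(s) in cohort: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    @property
    def flow_ratios(self) -> np.ndarray:
        return np.array([r.flow_ratio for r in self.records])

    def labels(self, cutoff: float) -> np.ndarray:
        """Binary complication labels at ``cutoff`` for every record."""
        return np.array([complication_label(r, cutoff) for r in self.records], dtype=int)

    def subset(self, indices: Sequence[int], provenance: str | None = None) -> "Cohort":
        prov = self.provenance if provenance is None else provenance
        return Cohort(tuple(self.records[i] for i in indices), provenance=prov)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _default_dvh_path(path: Path) -> Path:
    return path.with_name(path.stem + ".dvh.csv")


def _record_from_parts(
    pid: str, pre: float, post: float, dvhs: dict[str, DoseVolumeHistogram]
) -> PatientRecord:
    if "ipsilateral" not in dvhs:
        raise CohortValidationError(f"patient {pid!r}: missing ipsilateral DVH")
    return PatientRecord(
        patient_id=pid,
        dvh=dvhs["ipsilateral"],
        dvh_contra=dvhs.get("contralateral"),
        pre_flow=pre,
        post_flow=post,
    )


def _build_dvh(pid: str, gland: str, dose: np.ndarray, vol: np.ndarray) -> DoseVolumeHistogram:
    order = np.argsort(dose, kind="stable")
    try:
        return DoseVolumeHistogram(dose[order], vol[order], gland_label=gland)
    except DVHValidationError as exc:
        raise CohortValidationError(f"patient {pid!r}, {gland} DVH: {exc}") from exc


def read_cohort(path: str | Path, format: str = "csv", dvh_path: str | Path | None = None) -> Cohort:
    """Read and validate a cohort from disk.

    For ``format="csv"``, ``path`` is the scalar patient table and the DVH
    table defaults to ``<stem>.dvh.csv`` next to it.  Every DVH is validated
    on construction; violations raise :class:`CohortValidationError` naming
    the patient and the broken rule.
    """
    path = Path(path)
    if format == "json":
        return _read_json(path)
    if format != "csv":
        raise ValueError(f"unknown cohort format {format!r}")
    dvh_path = _default_dvh_path(path) if dvh_path is None else Path(dvh_path)
    try:
        patients = pd.read_csv(path, dtype={"patient_id": str})
        dvh_table = pd.read_csv(dvh_path, dtype={"patient_id": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise CohortParseError(f"failed to parse cohort file: {exc}") from exc
    for col in PATIENT_COLUMNS:
        if col not in patients.columns:
            raise CohortParseError(f"{path}: missing required column {col!r}")
    for col in DVH_COLUMNS:
        if col not in dvh_table.columns:
            raise CohortParseError(f"{dvh_path}: missing required column {col!r}")
    dvh_groups = {
        key: grp for key, grp in dvh_table.groupby(["patient_id", "gland"], sort=False)
    }
    records = []
    for row in patients.itertuples(index=False):
        pid = str(row.patient_id)
        dvhs = {}
        for gland in ("ipsilateral", "contralateral"):
            grp = dvh_groups.get((pid, gland))
            if grp is not None:
                dvhs[gland] = _build_dvh(
                    pid,
                    gland,
                    grp["dose_gy"].to_numpy(float),
                    grp["cum_volume_fraction"].to_numpy(float),
                )
        records.append(_record_from_parts(pid, float(row.pre_flow), float(row.post_flow), dvhs))
    return Cohort(tuple(records), provenance=f"read from {path}")


def _read_json(path: Path) -> Cohort:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CohortParseError(f"{path}: invalid JSON ({exc})") from exc
    records = []
    for idx, entry in enumerate(payload.get("patients", [])):
        try:
            pid = str(entry["patient_id"])
        except KeyError as exc:
            raise CohortParseError(f"{path}: patient #{idx} missing patient_id") from exc
        dvhs = {}
        for key, gland in (("dvh", "ipsilateral"), ("dvh_contra", "contralateral")):
            blob = entry.get(key)
            if blob is not None:
                dvhs[gland] = _build_dvh(
                    pid,
                    gland,
                    np.asarray(blob["dose_gy"], dtype=float),
                    np.asarray(blob["cum_volume_fraction"], dtype=float),
                )
        records.append(
            _record_from_parts(pid, float(entry["pre_flow"]), float(entry["post_flow"]), dvhs)
        )
    return Cohort(tuple(records), provenance=payload.get("provenance", f"read from {path}"))


def write_cohort(
    cohort: Cohort, path: str | Path, format: str = "csv", dvh_path: str | Path | None = None
) -> None:
    """Write a cohort in the CSV-pair or nested-JSON layout of :func:`read_cohort`."""
    path = Path(path)
    if format == "json":
        payload = {"provenance": cohort.provenance, "patients": []}
        for r in cohort:
            entry = {
                "patient_id": r.patient_id,
                "pre_flow": r.pre_flow,
                "post_flow": r.post_flow,
                "dvh": {
                    "dose_gy": r.dvh.dose_edges.tolist(),
                    "cum_volume_fraction": r.dvh.cum_volume.tolist(),
                },
            }
            if r.dvh_contra is not None:
                entry["dvh_contra"] = {
                    "dose_gy": r.dvh_contra.dose_edges.tolist(),
                    "cum_volume_fraction": r.dvh_contra.cum_volume.tolist(),
                }
            payload["patients"].append(entry)
        path.write_text(json.dumps(payload, indent=1))
        return
    if format != "csv":
        raise ValueError(f"unknown cohort format {format!r}")
    dvh_path = _default_dvh_path(path) if dvh_path is None else Path(dvh_path)
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in cohort],
            "pre_flow": [r.pre_flow for r in cohort],
            "post_flow": [r.post_flow for r in cohort],
        }
    ).to_csv(path, index=False)
    rows = []
    for r in cohort:
        glands = [("ipsilateral", r.dvh)]
        if r.dvh_contra is not None:
            glands.append(("contralateral", r.dvh_contra))
        for gland, dvh in glands:
            for d, v in zip(dvh.dose_edges, dvh.cum_volume):
                rows.append((r.patient_id, gland, repr(float(d)), repr(float(v))))
    pd.DataFrame(rows, columns=DVH_COLUMNS).to_csv(dvh_path, index=False)
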