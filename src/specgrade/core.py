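"""Core domain types and plain-text I/O for spectral tables.

A :class:`SpectralDataset` holds one intensity row per acquired spectrum on a
shared wavenumber axis (cm^-1), with per-spectrum identifiers, patient IDs and
a class label.  Class labels are the fixed codes ``G1`` (grade I), ``G2``
(grade II) and ``G1R`` (grade I that recurred).

On-disk layout (documented bit-exactly in the README):

* spectra: wide CSV, first column ``spectrum_id``, remaining column headers are
  the wavenumbers in 17-significant-digit decimal text, one row per spectrum;
* metadata: TSV with columns ``spectrum_id``, ``patient_id``, ``label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

CLASS_CODES = ("G1", "G2", "G1R")

STAGE_TAGS = ("raw", "truncated", "derivative", "normalized")


class SpectraFormatError(ValueError):
    """Malformed spectra table (ragged rows, duplicate or non-numeric axis)."""


class ConsistencyError(ValueError):
    """Spectra and metadata disagree (missing/extra IDs, label conflicts)."""


@dataclass
class SpectralDataset:
    """Spectra matrix plus per-row identity and class annotation.

    Parameters
    ----------
    wavenumbers
        Strictly monotonic axis in cm^-1 (stored high-to-low by convention,
        matching spectrometer output; every operation is direction-agnostic).
    intensities
        ``(n_spectra, n_wavenumbers)`` matrix, absorbance or derivative units.
    spectrum_ids, patient_ids, labels
        Per-row strings; all rows of one patient must share a label.
    stage_tag
        Provenance of the values: ``raw``, ``truncated``, ``derivative`` or
        ``normalized``.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    spectrum_ids: np.ndarray
    patient_ids: np.ndarray
    labels: np.ndarray
    stage_tag: str = "raw"

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.spectrum_ids = np.asarray(self.spectrum_ids, dtype=object)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        wn = self.wavenumbers
        if wn.ndim != 1 or wn.size == 0:
            raise SpectraFormatError("wavenumber axis must be a non-empty 1-D array")
        d = np.diff(wn)
        if wn.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraFormatError(
                "wavenumber axis must be strictly monotonic (no duplicates)"
            )
        n = self.intensities.shape[0]
        if self.intensities.shape[1] != wn.size and not (n == 0):
            raise SpectraFormatError(
                f"intensity columns ({self.intensities.shape[1]}) do not match "
                f"axis length ({wn.size})"
            )
        for name, arr in (
            ("spectrum_ids", self.spectrum_ids),
            ("patient_ids", self.patient_ids),
            ("labels", self.labels),
        ):
            if arr.shape != (n,):
                raise ConsistencyError(f"{name} length {arr.shape} != n rows {n}")
        if len(set(self.spectrum_ids)) != n:
            raise ConsistencyError("spectrum_ids are not unique")
        bad = set(self.labels) - set(CLASS_CODES)
        if bad:
            raise ConsistencyError(f"unknown class labels: {sorted(bad)}")
        per_patient: dict[str, str] = {}
        for pid, lab in zip(self.patient_ids, self.labels):
            if per_patient.setdefault(pid, lab) != lab:
                raise ConsistencyError(f"patient {pid!r} carries conflicting labels")
        if self.stage_tag not in STAGE_TAGS:
            raise ValueError(f"unknown stage_tag {self.stage_tag!r}")

    # -- convenience ------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    @property
    def spacing(self) -> float:
        """Absolute axis step; requires a uniform axis."""
        steps = np.abs(np.diff(self.wavenumbers))
        if steps.size == 0:
            raise ValueError("axis with a single point has no spacing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("axis is not uniformly spaced")
        return float(steps[0])

    def patients(self) -> list[str]:
        """Unique patient IDs in first-appearance order."""
        seen: dict[str, None] = {}
        for pid in self.patient_ids:
            seen.setdefault(pid, None)
        return list(seen)

    def label_of_patient(self, patient_id: str) -> str:
        idx = np.flatnonzero(self.patient_ids == patient_id)
        if idx.size == 0:
            raise KeyError(patient_id)
        return str(self.labels[idx[0]])

    def with_intensities(
        self, intensities: np.ndarray, stage_tag: str | None = None
    ) -> "SpectralDataset":
        return replace(
            self,
            intensities=intensities,
            stage_tag=self.stage_tag if stage_tag is None else stage_tag,
        )

    def take(self, rows: np.ndarray | Sequence[int]) -> "SpectralDataset":
        rows = np.asarray(rows)
        return replace(
            self,
            intensities=self.intensities[rows],
            spectrum_ids=self.spectrum_ids[rows],
            patient_ids=self.patient_ids[rows],
            labels=self.labels[rows],
        )

    def column_index(self, wavenumber: float, tol: float | None = None) -> int:
        """Index of the axis point nearest ``wavenumber``.

        Raises ``KeyError`` if the nearest point is farther than ``tol``
        (default: half the axis spacing).
        """
        j = int(np.argmin(np.abs(self.wavenumbers - wavenumber)))
        if tol is None:
            tol = self.spacing / 2 if self.n_points > 1 else np.inf
        if abs(self.wavenumbers[j] - wavenumber) > tol + 1e-9:
            raise KeyError(
                f"no axis point within {tol} cm^-1 of {wavenumber} cm^-1"
            )
        return j


@dataclass(frozen=True)
class CohortDesign:
    """Study design of an acquisition campaign.

    ``class_sizes`` maps class code to patient count; each patient contributes
    ``replicates_per_patient`` spectra over the ``axis_lo``..``axis_hi`` cm^-1
    range at ``resolution`` cm^-1 (points are laid at ``point_spacing``,
    typically resolution/2 through zero-filling).
    """

    class_sizes: dict[str, int]
    replicates_per_patient: int = 10
    axis_lo: float = 400.0
    axis_hi: float = 4000.0
    resolution: float = 8.0
    point_spacing: float = 4.0

    def __post_init__(self) -> None:
        if not self.class_sizes:
            raise ValueError("class_sizes must not be empty")
        for code, size in self.class_sizes.items():
            if code not in CLASS_CODES:
                raise ValueError(f"unknown class code {code!r}")
            if size < 1:
                raise ValueError(f"class {code} must have >= 1 patient")
        if self.replicates_per_patient < 1:
            raise ValueError("replicates_per_patient must be >= 1")
        if not self.axis_lo < self.axis_hi:
            raise ValueError("axis_lo must be < axis_hi")
        if self.resolution <= 0 or self.point_spacing <= 0:
            raise ValueError("resolution and point_spacing must be > 0")

    def axis(self) -> np.ndarray:
        """Wavenumber axis, high to low."""
        n = int(round((self.axis_hi - self.axis_lo) / self.point_spacing)) + 1
        return self.axis_hi - self.point_spacing * np.arange(n)


# -- I/O -------------------------------------------------------------------

def read_spectra(path: str | Path, metadata_path: str | Path) -> SpectralDataset:
    """Read a wide-CSV spectra table plus its TSV metadata sidecar.

    The spectra file's first column is ``spectrum_id``; remaining headers are
    wavenumbers.  Metadata must carry exactly the same spectrum IDs.
    """
    try:
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraFormatError(f"malformed spectra file {path}: {exc}") from exc
    try:
        wavenumbers = np.array([float(c) for c in frame.columns])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber header in {path}") from exc
    if len(set(frame.columns)) != len(frame.columns):
        raise SpectraFormatError(f"duplicate wavenumber column in {path}")
    if frame.isna().any().any():
        raise SpectraFormatError(f"missing values (ragged rows?) in {path}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"spectrum_id", "patient_id", "label"}
    if not required.issubset(meta.columns):
        raise SpectraFormatError(
            f"metadata {metadata_path} must have columns {sorted(required)}"
        )
    meta = meta.set_index("spectrum_id")
    spec_ids = [str(i) for i in frame.index]
    missing = set(spec_ids) - set(meta.index)
    if missing:
        raise ConsistencyError(f"spectra without metadata: {sorted(missing)[:5]}")
    extra = set(meta.index) - set(spec_ids)
    if extra:
        raise ConsistencyError(f"metadata without spectra: {sorted(extra)[:5]}")
    meta = meta.loc[spec_ids]
    return SpectralDataset(
        wavenumbers=wavenumbers,
        intensities=frame.to_numpy(dtype=float).reshape(
            len(spec_ids), wavenumbers.size
        ),
        spectrum_ids=np.array(spec_ids, dtype=object),
        patient_ids=meta["patient_id"].to_numpy(dtype=object),
        labels=meta["label"].to_numpy(dtype=object),
        stage_tag="raw",
    )


def write_spectra(
    ds: SpectralDataset, path: str | Path, metadata_path: str | Path
) -> None:
    """Write the dataset in the wide-CSV + TSV-sidecar dialect.

    Round-trips through :func:`read_spectra` losslessly at 17-significant-digit
    text precision.  The ``stage_tag`` is not persisted; re-reading yields ``raw``.
    """
    frame = pd.DataFrame(
        ds.intensities if ds.n_spectra else np.empty((0, ds.n_points)),
        index=pd.Index(ds.spectrum_ids, name="spectrum_id"),
        columns=[f"{w:.17g}" for w in ds.wavenumbers],
    )
    frame.to_csv(path)  # default shortest-repr floats: exact round-trip
    meta = pd.DataFrame(
        {
            "spectrum_id": ds.spectrum_ids,
            "patient_id": ds.patient_ids,
            "label": ds.labels,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def subset(
    ds: SpectralDataset,
    labels: Iterable[str] | None = None,
    patients: Iterable[str] | None = None,
    predicate: Callable[[str, str], bool] | None = None,
) -> SpectralDataset:
    """Row subset by label set, patient set, or arbitrary predicate.

    ``predicate`` receives ``(patient_id, label)`` per row.  Filters compose
    with AND; row order and the axis are preserved.  An empty result is valid.
    """
    mask = np.ones(ds.n_spectra, dtype=bool)
    if labels is not None:
        wanted = set(labels)
        mask &= np.array([lab in wanted for lab in ds.labels])
    if patients is not None:
        wanted_p = set(patients)
        mask &= np.array([pid in wanted_p for pid in ds.patient_ids])
    if predicate is not None:
        mask &= np.array(
            [predicate(pid, lab) for pid, lab in zip(ds.patient_ids, ds.labels)]
        )
    return ds.take(np.flatnonzero(mask))
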