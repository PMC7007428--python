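"""Sample partitioning: Kennard-Stone train/validation selection and
venetian-blinds cross-validation folds.

The default operating unit is the *patient*: replicate spectra of one tissue
sample are strongly correlated, so the Kennard-Stone selection runs on
patient-mean spectra within each class, all of a patient's replicates follow
the patient to one side of the split, and CV folds likewise group patients.
A spectrum-level mode is available to emulate workflows that split replicate
spectra independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import CLASS_CODES, SpectralDataset


def kennard_stone(points: np.ndarray, k: int) -> list[int]:
    """Greedy maximin (Kennard-Stone) selection of ``k`` of ``m`` points.

    The first two selections are the pair at maximal Euclidean distance; each
    further selection maximises its minimal distance to the already-selected
    set.  All ties break to the smallest index, making the output
    deterministic.  Returns indices in selection order.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    m = pts.shape[0]
    if not 0 <= k <= m:
        raise ValueError(f"k={k} out of range for {m} points")
    if k == 0:
        return []
    if m == 1:
        return [0]
    if k < 2:
        raise ValueError("k must be >= 2 when selecting from > 1 candidates")

    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    # farthest pair, ties -> lexicographically smallest (i, j)
    best = np.unravel_index(np.argmax(d2), d2.shape)  # argmax is first maximum
    i, j = sorted(best)
    selected = [int(i), int(j)]
    remaining = [t for t in range(m) if t not in selected]
    mind2 = np.minimum(d2[i], d2[j])
    while len(selected) < k:
        cand = remaining[int(np.argmax([mind2[t] for t in remaining]))]
        selected.append(cand)
        remaining.remove(cand)
        mind2 = np.minimum(mind2, d2[cand])
    return selected


def venetian_blinds(n_objects: int, n_splits: int = 10) -> list[np.ndarray]:
    """Interleaved CV folds: fold j holds objects j, j+n_splits, j+2*n_splits...

    Folds are disjoint and exhaustive; sizes differ by at most one.
    """
    if n_objects < n_splits:
        raise ValueError(f"need >= {n_splits} objects, have {n_objects}")
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    return [np.arange(j, n_objects, n_splits) for j in range(n_splits)]


@dataclass(frozen=True)
class Partition:
    """Train/validation object split plus CV folds over the training objects.

    ``level`` says what an object is ("patient" or "spectrum"); the object
    IDs are patient IDs or spectrum IDs accordingly.  ``cv_folds`` index into
    ``train_objects``.
    """

    train_objects: tuple[str, ...]
    validation_objects: tuple[str, ...]
    cv_folds: tuple[tuple[int, ...], ...]
    level: str = "patient"
    scheme: str = "kennard_stone"
    cv_scheme: str = "venetian_blinds"
    n_splits: int = 10

    # Mapping to dataset rows -------------------------------------------
    def _object_ids(self, ds: SpectralDataset) -> np.ndarray:
        return ds.patient_ids if self.level == "patient" else ds.spectrum_ids

    def train_indices(self, ds: SpectralDataset) -> np.ndarray:
        ids = self._object_ids(ds)
        wanted = set(self.train_objects)
        return np.flatnonzero([i in wanted for i in ids])

    def validation_indices(self, ds: SpectralDataset) -> np.ndarray:
        ids = self._object_ids(ds)
        wanted = set(self.validation_objects)
        return np.flatnonzero([i in wanted for i in ids])

    def cv_fold_indices(self, ds: SpectralDataset) -> list[np.ndarray]:
        """CV folds expanded to absolute dataset row indices."""
        ids = self._object_ids(ds)
        out = []
        for fold in self.cv_folds:
            objs = {self.train_objects[t] for t in fold}
            out.append(np.flatnonzero([i in objs for i in ids]))
        return out


def split_dataset(
    ds: SpectralDataset,
    train_fraction: float = 0.7,
    n_splits: int = 10,
    level: str = "patient",
) -> Partition:
    """Kennard-Stone split, stratified by class, plus venetian-blinds folds.

    For each class the selection runs over that class's objects (patients by
    default, represented by their mean spectrum); ``round(train_fraction * n)``
    objects per class go to training.  Folds are venetian blinds over the
    training objects in dataset order.
    """
    if level not in ("patient", "spectrum"):
        raise ValueError("level must be 'patient' or 'spectrum'")
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    if train_fraction == 1.0:
        warnings.warn("train_fraction 1.0 leaves an empty validation set", stacklevel=2)

    train: list[str] = []
    validation: list[str] = []
    for code in [c for c in CLASS_CODES if c in set(ds.labels)]:
        if level == "patient":
            objs = [p for p in ds.patients() if ds.label_of_patient(p) == code]
            reps = np.vstack(
                [ds.intensities[ds.patient_ids == p].mean(axis=0) for p in objs]
            )
        else:
            rows = np.flatnonzero(ds.labels == code)
            objs = [str(s) for s in ds.spectrum_ids[rows]]
            reps = ds.intensities[rows]
        if len(objs) < 2:
            raise ValueError(
                f"class {code} has a single {level}; cannot split it"
            )
        k = int(round(train_fraction * len(objs)))
        k = min(max(k, 2), len(objs))
        chosen = kennard_stone(reps, k)
        chosen_set = set(chosen)
        train += [objs[i] for i in sorted(chosen_set)]
        validation += [objs[i] for i in range(len(objs)) if i not in chosen_set]

    # training objects in dataset order, then interleaved folds
    order = {o: i for i, o in enumerate(
        ds.patients() if level == "patient" else [str(s) for s in ds.spectrum_ids]
    )}
    train_sorted = tuple(sorted(train, key=order.__getitem__))
    folds = tuple(
        tuple(int(i) for i in fold)
        for fold in venetian_blinds(len(train_sorted), min(n_splits, len(train_sorted)))
    )
    return Partition(
        train_objects=train_sorted,
        validation_objects=tuple(sorted(validation, key=order.__getitem__)),
        cv_folds=folds,
        level=level,
        n_splits=n_splits,
    )
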