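"""Spectral-marker extraction.

Three complementary tools operate on preprocessed (second-derivative,
vector-normalised) spectra:

* the difference-between-mean (DBM) spectrum of two classes, with an
  absolute-coefficient threshold (default 0.01 on the normalised-derivative
  scale) that flags candidate marker wavenumbers;
* an automatic peak detector over a PLS-DA regression vector that returns
  the ``n`` most relevant peaks (largest local |coefficient| extrema);
* per-wavenumber one-way ANOVA p-values and up/down direction calls, which
  together with the peaks form a marker table (wavenumber, tentative
  assignment, relative-intensity arrow, p-value with significance tag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpectralDataset
from .models import PlsDaModel

#: Annotation-only lookup of tentative band assignments (cm^-1 -> text).
ASSIGNMENTS = {
    1750.0: "v(C=O) in lipids",
    1650.0: "Amide I",
    1550.0: "Amide II",
    1470.0: "d(CH2) bending",
    1400.0: "vs(COO-) of amino acids",
    1260.0: "Amide III",
    1225.0: "vas(PO2-)",
    1155.0: "v(C-O) in carbohydrates",
    1080.0: "vs(PO2-)",
    1030.0: "v(C-O) in glycogen",
    970.0: "protein phosphorylation",
}


def assignment_text(wavenumber: float, tol: float = 30.0) -> str:
    """Nearest tabulated assignment within ``tol`` cm^-1, else empty."""
    keys = np.array(list(ASSIGNMENTS))
    j = int(np.argmin(np.abs(keys - wavenumber)))
    return ASSIGNMENTS[float(keys[j])] if abs(keys[j] - wavenumber) <= tol else ""


@dataclass
class DbmSpectrum:
    """Difference of class-mean preprocessed spectra (positive minus
    negative class), with super-threshold wavenumbers flagged."""

    wavenumbers: np.ndarray
    coefficients: np.ndarray
    threshold: float
    class_pos: str
    class_neg: str

    @property
    def flagged(self) -> list[tuple[float, int]]:
        """(wavenumber, sign) for every |coefficient| strictly > threshold."""
        idx = np.flatnonzero(np.abs(self.coefficients) > self.threshold)
        return [
            (float(self.wavenumbers[j]), int(np.sign(self.coefficients[j])))
            for j in idx
        ]


@dataclass
class MarkerTable:
    """Rows sorted by |coefficient| descending.

    ``direction`` is "up" when the first (positive) class has the higher mean
    preprocessed intensity; significance tags: ``**`` p<0.001, ``*`` p<0.05.
    """

    frame: pd.DataFrame  # wavenumber, coefficient, direction, p_value, significance, assignment
    class_pos: str
    class_neg: str

    def __len__(self) -> int:
        return len(self.frame)

    def wavenumbers(self) -> np.ndarray:
        return self.frame["wavenumber"].to_numpy()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def dbm(
    ds: SpectralDataset,
    class_pos: str,
    class_neg: str,
    threshold: float = 0.01,
) -> DbmSpectrum:
    """DBM spectrum: mean(class_pos) - mean(class_neg), per wavenumber."""
    for c in (class_pos, class_neg):
        if not np.any(ds.labels == c):
            raise ValueError(f"class {c!r} absent from dataset")
    mean_pos = ds.intensities[ds.labels == class_pos].mean(axis=0)
    mean_neg = ds.intensities[ds.labels == class_neg].mean(axis=0)
    return DbmSpectrum(
        wavenumbers=ds.wavenumbers.copy(),
        coefficients=mean_pos - mean_neg,
        threshold=threshold,
        class_pos=class_pos,
        class_neg=class_neg,
    )


def _local_extrema(a: np.ndarray) -> list[int]:
    """Indices of strict local maxima of ``a``; a plateau counts once, at its
    leftmost point.  Endpoints are not candidates."""
    idx = []
    n = a.size
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and a[j + 1] == a[j]:
            j += 1
        # run [i, j] of equal values; peak if strictly above both sides
        if a[i - 1] < a[i] and j + 1 < n and a[j + 1] < a[j]:
            idx.append(i)
        i = j + 1
    return idx


def top_peaks(
    regression_vector: np.ndarray,
    wavenumbers: np.ndarray,
    n_peaks: int = 8,
) -> pd.DataFrame:
    """The ``n_peaks`` largest local |coefficient| extrema of a coefficient
    vector, sorted by |coefficient| descending.

    If no interior extremum exists (monotone |coefficients|), the endpoints
    serve as fallback candidates, with a warning.  Fewer candidates than
    requested are all returned, with a warning.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    coefs = np.asarray(regression_vector, dtype=float)
    wn = np.asarray(wavenumbers, dtype=float)
    if coefs.size != wn.size:
        raise ValueError("coefficient vector does not match the axis")
    if coefs.size < 3:
        raise ValueError("axis must have at least 3 points")
    mag = np.abs(coefs)
    cand = _local_extrema(mag)
    if not cand:
        warnings.warn(
            "no interior |coefficient| extremum; falling back to endpoints",
            stacklevel=2,
        )
        cand = [0, coefs.size - 1]
    if len(cand) < n_peaks:
        warnings.warn(
            f"only {len(cand)} candidate peaks for n_peaks={n_peaks}",
            stacklevel=2,
        )
    order = sorted(cand, key=lambda j: (-mag[j], j))[:n_peaks]
    return pd.DataFrame(
        {"wavenumber": wn[order], "coefficient": coefs[order]}
    )


def marker_anova(
    ds: SpectralDataset,
    wavenumber: float,
    groups: np.ndarray | None = None,
) -> float:
    """One-way fixed-effects ANOVA p-value at one wavenumber.

    Observations are the individual preprocessed spectra; ``groups`` defaults
    to the dataset's class labels.  The wavenumber must hit an axis point
    within half a spacing.
    """
    j = ds.column_index(wavenumber)
    g = np.asarray(ds.labels if groups is None else groups, dtype=object)
    values = ds.intensities[:, j]
    samples = [values[g == code] for code in sorted(set(g))]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations each")
    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    if ss_between == 0.0:
        return 1.0  # identical group means: F = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*samples)
    return float(p)


def direction(
    ds: SpectralDataset,
    wavenumber: float,
    class_a: str,
    class_b: str,
) -> str:
    """"up" iff class_a's mean preprocessed intensity exceeds class_b's at
    the wavenumber; an exact tie is called "down" with a warning."""
    j = ds.column_index(wavenumber)
    mean_a = ds.intensities[ds.labels == class_a, j].mean()
    mean_b = ds.intensities[ds.labels == class_b, j].mean()
    if mean_a == mean_b:
        warnings.warn(
            f"exact mean tie at {wavenumber} cm^-1; calling 'down'", stacklevel=2
        )
        return "down"
    return "up" if mean_a > mean_b else "down"


def significance_tag(p_value: float) -> str:
    if p_value < 0.001:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def build_marker_table(
    model: PlsDaModel,
    ds: SpectralDataset,
    n_peaks: int = 8,
) -> MarkerTable:
    """Marker table from a fitted PLS-DA model and the preprocessed data it
    was trained on: top coefficient peaks, up/down direction of the positive
    class relative to the negative, and per-wavenumber ANOVA p-values."""
    if model.wavenumbers.size != ds.n_points or not np.allclose(
        model.wavenumbers, ds.wavenumbers
    ):
        raise ValueError("model axis does not match the dataset axis")
    neg, pos = model.classes
    peaks = top_peaks(model.regression_vector, ds.wavenumbers, n_peaks)
    rows = []
    for wn, coef in zip(peaks["wavenumber"], peaks["coefficient"]):
        p = marker_anova(ds, wn)
        rows.append(
            {
                "wavenumber": float(wn),
                "coefficient": float(coef),
                "direction": direction(ds, wn, pos, neg),
                "p_value": p,
                "significance": significance_tag(p),
                "assignment": assignment_text(wn),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "wavenumber", "coefficient", "direction",
            "p_value", "significance", "assignment",
        ],
    )
    return MarkerTable(frame=frame, class_pos=pos, class_neg=neg)
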