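"""Recurrence-trend screening of grade I patients.

Given a marker table from the grade I vs. grade I-recurrence comparison,
each grade I patient's mean preprocessed spectrum is compared against the
grade I class mean (leave-one-out: the patient under test is excluded from
the class mean to avoid self-bias).  At each marker wavenumber the patient
"matches" when the sign of their deviation equals the marker's recurrence
direction (up = higher in recurring tumours); exact-zero deviations do not
match.  Patients are flagged by rule:

* ``all`` (default, strictest): every marker must match — under pure noise a
  patient matches each marker with probability ~0.5, so the null flag rate
  is ~0.5**n_markers;
* ``majority``: more than half the markers match;
* ``fraction:q``: matched fraction >= q.

Flagged patients are candidates whose spectral profile follows the
recurrence trend; this is a screening hypothesis, not a clinical claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarkers import MarkerTable
from .core import SpectralDataset


@dataclass
class ScreenResult:
    flagged_patients: list[str]
    per_patient: pd.DataFrame  # patient, matched, total, fraction, flagged
    rule: str
    reference_markers: MarkerTable

    @property
    def flagged_percent(self) -> float:
        return 100.0 * len(self.flagged_patients) / len(self.per_patient)


def _rule_threshold(rule: str, total: int) -> float:
    """Minimum matched count implied by the rule."""
    if rule == "all":
        return total
    if rule == "majority":
        return np.nextafter(total / 2.0, np.inf)
    if rule.startswith("fraction:"):
        q = float(rule.split(":", 1)[1])
        if not 0.0 <= q <= 1.0:
            raise ValueError("fraction rule needs q in [0, 1]")
        return q * total
    raise ValueError(f"unknown rule {rule!r}")


def screen(
    ds: SpectralDataset,
    markers: MarkerTable,
    rule: str = "all",
    target_label: str = "G1",
) -> ScreenResult:
    """Flag ``target_label`` patients whose marker-wavenumber deviations all
    (or per ``rule``) follow the recurrence direction.

    ``ds`` must be preprocessed and contain the target class; ``markers``
    must be non-empty, with direction "up" meaning higher intensity in the
    recurrence class.
    """
    if len(markers) == 0:
        raise ValueError("marker table is empty")
    if ds.stage_tag != "normalized":
        raise ValueError("screen expects preprocessed (normalized) spectra")
    target_rows = np.flatnonzero(ds.labels == target_label)
    if target_rows.size == 0:
        raise ValueError(f"no {target_label} spectra in dataset")

    cols = [ds.column_index(w) for w in markers.frame["wavenumber"]]
    signs = np.array(
        [1.0 if d == "up" else -1.0 for d in markers.frame["direction"]]
    )
    X = ds.intensities[target_rows][:, cols]  # (n_target_spectra, n_markers)
    pids = ds.patient_ids[target_rows]
    patients = []
    seen: dict[str, None] = {}
    for p in pids:
        seen.setdefault(p, None)
    patients = list(seen)

    total = len(cols)
    need = _rule_threshold(rule, total)
    records = []
    flagged = []
    for p in patients:
        own = X[pids == p]
        rest = X[pids != p]
        if rest.shape[0] == 0:
            raise ValueError("leave-one-out class mean needs >= 2 patients")
        deviation = own.mean(axis=0) - rest.mean(axis=0)
        matched = int(np.sum(signs * deviation > 0))
        is_flagged = matched >= need
        if is_flagged:
            flagged.append(str(p))
        records.append(
            {
                "patient": str(p),
                "matched": matched,
                "total": total,
                "fraction": matched / total,
                "flagged": bool(is_flagged),
            }
        )
    return ScreenResult(
        flagged_patients=flagged,
        per_patient=pd.DataFrame(records),
        rule=rule,
        reference_markers=markers,
    )
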