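"""PCA-model outlier screening with Hotelling's T2 and the Q residual.

A PCA model with ``k`` components splits each (mean-centred) spectrum into an
in-model part, summarised by Hotelling's T2 (score distance weighted by the
per-component variances), and an off-model part, summarised by the Q
statistic (squared residual norm).  Control limits come from the classical
F-distribution form for T2 and the Jackson-Mudholkar approximation for Q.
A spectrum is flagged only when it exceeds BOTH limits; this conservative
AND rule keeps the false-flag rate near alpha**2 on clean data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpectralDataset


@dataclass
class OutlierReport:
    spectrum_ids: np.ndarray
    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    flags: np.ndarray
    n_components: int
    alpha: float

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spectrum_id": self.spectrum_ids,
                "t2": self.t2,
                "q": self.q,
                "flag": self.flags,
            }
        )


def _q_limit_jackson_mudholkar(discarded_eigs: np.ndarray, alpha: float) -> float:
    """Upper control limit for Q from the discarded eigenvalues."""
    lam = discarded_eigs[discarded_eigs > 0]
    if lam.size == 0:
        return 0.0
    t1, t2_, t3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    h0 = 1.0 - 2.0 * t1 * t3 / (3.0 * t2_**2)
    if h0 <= 0:  # heavy-tailed eigenvalue spectrum; fall back per Jackson
        h0 = 1e-3
    c = stats.norm.ppf(1.0 - alpha)
    inner = (
        c * np.sqrt(2.0 * t2_ * h0**2) / t1 + 1.0 + t2_ * h0 * (h0 - 1.0) / t1**2
    )
    return float(t1 * max(inner, 0.0) ** (1.0 / h0))


def t2q_test(
    ds: SpectralDataset,
    n_components: int | None = None,
    alpha: float = 0.05,
    explained_variance: float = 0.95,
) -> OutlierReport:
    """Hotelling T2 versus Q residual outlier screen on a spectra matrix.

    ``n_components`` defaults to the smallest k reaching ``explained_variance``
    cumulative explained variance (capped at rank - 1 so Q is informative).
    Reports only; removal is the caller's decision.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    X = ds.intensities
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 spectra")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigs = s**2 / (n - 1)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components is None:
        evr = np.cumsum(eigs) / eigs.sum()
        n_components = int(np.searchsorted(evr, explained_variance) + 1)
        n_components = min(n_components, max(rank - 1, 1))
    k = int(n_components)
    if not 1 <= k < min(n, p):
        raise ValueError(f"n_components={k} must be in [1, min(n, p))")

    scores = U[:, :k] * s[:k]
    t2 = np.sum(scores**2 / eigs[:k], axis=1)
    resid = Xc - scores @ Vt[:k]
    q = np.sum(resid**2, axis=1)

    t2_limit = (
        k * (n - 1) * (n + 1) / (n * (n - k)) * stats.f.ppf(1.0 - alpha, k, n - k)
    )
    q_limit = _q_limit_jackson_mudholkar(eigs[k:rank], alpha)
    flags = (t2 > t2_limit) & (q > q_limit)
    return OutlierReport(
        spectrum_ids=ds.spectrum_ids.copy(),
        t2=t2,
        q=q,
        t2_limit=float(t2_limit),
        q_limit=float(q_limit),
        flags=flags,
        n_components=k,
        alpha=alpha,
    )
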