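"""End-to-end driver for the three pairwise grade comparisons.

``run_pipeline`` executes, on a simulated or loaded cohort:

    simulate/read -> preprocess -> T2/Q outlier report -> per comparison:
    Kennard-Stone split -> PCA-LDA + PLS-DA (fixed or CV-selected component
    counts) -> training/validation metrics and ROC -> DBM + marker table ->
    recurrence screen (when the comparison is grade I vs. its recurrence)

and writes all artifacts as deterministic JSON/TSV/CSV to an output
directory.  Conventions: the PLS/DBM positive ("+") class is G2 for
G1-vs-G2, G1R for G1-vs-G1R and G2 for G2-vs-G1R; metric tables take the
comparison's first-listed (larger) class as the positive class, which is
the orientation under which an imbalance-skewed model shows high
sensitivity and low specificity.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .biomarkers import build_marker_table, dbm
from .core import SpectralDataset, read_spectra, subset, write_spectra
from .evaluate import evaluate
from .models import (
    fit_pca_lda,
    fit_pls_da,
    model_to_dict,
    pls_cv_threshold,
    predict_pca_lda,
    predict_pls_da,
    select_components,
)
from .partition import split_dataset
from .preprocess import PreprocessParams, preprocess
from .qc import t2q_test
from .screen import screen
from .synth import default_study_design, generate_cohort

#: comparison name -> (first class, second class, model "+" class)
COMPARISONS = {
    "G1_vs_G2": ("G1", "G2", "G2"),
    "G1_vs_G1R": ("G1", "G1R", "G1R"),
    "G2_vs_G1R": ("G2", "G1R", "G2"),
}


@dataclass
class RunConfig:
    """Run settings; defaults reproduce the standard analysis profile
    (7-point quadratic SG 2nd derivative over 1800-900 cm^-1, 70/30
    Kennard-Stone split, 10-split venetian blinds, DBM threshold 0.01,
    8 marker peaks)."""

    seed: int = 1
    simulate: bool = True
    spectra_path: str | None = None
    metadata_path: str | None = None
    fp_lo: float = 900.0
    fp_hi: float = 1800.0
    window: int = 7
    polyorder: int = 2
    deriv: int = 2
    train_fraction: float = 0.7
    cv_splits: int = 10
    split_level: str = "patient"
    qc_alpha: float = 0.05
    qc_evr: float = 0.95
    comparisons: tuple[str, ...] = tuple(COMPARISONS)
    k_policy: str = "auto"  # "auto" (CV 1-SE rule) or "fixed"
    fixed_k: dict = field(
        default_factory=lambda: {  # per comparison: (PCA-LDA PCs, PLS-DA LVs)
            "G1_vs_G2": (10, 11),
            "G1_vs_G1R": (17, 17),
            "G2_vs_G1R": (12, 13),
        }
    )
    k_max: int = 12
    lda_priors: str = "proportional"
    dbm_threshold: float = 0.01
    n_peaks: int = 8
    screen_rule: str = "all"
    outdir: str | None = None

    def validate(self) -> None:
        for c in self.comparisons:
            if c not in COMPARISONS:
                raise ValueError(f"unknown comparison {c!r}")
        if self.simulate and self.seed is None:
            raise ValueError("seed is mandatory when simulating")
        if not self.simulate and not (self.spectra_path and self.metadata_path):
            raise ValueError("need spectra_path and metadata_path when not simulating")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serialisable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=1, sort_keys=True, default=_json_default) + "\n"
    )


def _report_dict(rep) -> dict:
    d = {
        "tp": rep.tp, "fp": rep.fp, "tn": rep.tn, "fn": rep.fn,
        "accuracy": rep.accuracy,
        "sensitivity": rep.sensitivity,
        "specificity": rep.specificity,
        "positive_class": rep.positive_class,
        "dataset": rep.dataset_tag,
    }
    if rep.auc is not None:
        d["auc"] = rep.auc
    if rep.patient_level is not None:
        d["patient_level"] = rep.patient_level
    return d


def _run_comparison(pp: SpectralDataset, name: str, config: RunConfig) -> dict:
    class_a, class_b, positive = COMPARISONS[name]
    sub = subset(pp, labels=[class_a, class_b])
    part = split_dataset(
        sub, config.train_fraction, config.cv_splits, config.split_level
    )
    tr = part.train_indices(sub)
    va = part.validation_indices(sub)
    X, y, wn = sub.intensities, sub.labels, sub.wavenumbers
    folds_abs = part.cv_fold_indices(sub)
    pos_of = {int(i): j for j, i in enumerate(tr)}
    folds = [np.array([pos_of[int(i)] for i in f]) for f in folds_abs]

    out: dict = {
        "comparison": name,
        "classes": [class_a, class_b],
        "model_positive_class": positive,
        "metrics_positive_class": class_a,
        "partition": {
            "train": list(part.train_objects),
            "validation": list(part.validation_objects),
            "level": part.level,
        },
        "models": {},
        "metrics": [],
    }

    if config.k_policy == "fixed":
        k_lda, k_pls = config.fixed_k[name]
        selection = None
    else:
        k_max = min(config.k_max, len(tr) - max(len(f) for f in folds) - 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel_lda = select_components(
                X[tr], y[tr], folds, k_max, "pcalda",
                positive_class=positive, priors=config.lda_priors,
            )
            sel_pls = select_components(
                X[tr], y[tr], folds, k_max, "plsda", positive_class=positive
            )
        k_lda, k_pls = sel_lda.n_components_chosen, sel_pls.n_components_chosen
        selection = {
            "pcalda": sel_lda.cv_accuracy_by_k.to_dict(orient="list"),
            "plsda": sel_pls.cv_accuracy_by_k.to_dict(orient="list"),
        }
    out["n_components"] = {"pcalda": int(k_lda), "plsda": int(k_pls)}
    if selection is not None:
        out["cv_selection"] = selection

    # ---- PCA-LDA
    lda = fit_pca_lda(
        X[tr], y[tr], k_lda, wavenumbers=wn,
        positive_class=positive, priors=config.lda_priors,
    )
    out["models"]["pcalda"] = model_to_dict(lda)
    out["explained_variance_pcalda"] = float(lda.explained_variance.sum())
    # ---- PLS-DA with CV-estimated threshold
    thr = pls_cv_threshold(X[tr], y[tr], k_pls, folds, positive_class=positive)
    pls = fit_pls_da(
        X[tr], y[tr], k_pls, wavenumbers=wn,
        positive_class=positive, threshold=thr,
    )
    out["models"]["plsda"] = model_to_dict(pls)
    out["explained_variance_plsda"] = float(pls.x_explained_variance.sum())

    sign = 1.0 if class_a == positive else -1.0  # orient scores to class_a
    for algo, model, predict in (
        ("pcalda", lda, predict_pca_lda),
        ("plsda", pls, predict_pls_da),
    ):
        for tag, idx in (("training", tr), ("validation", va)):
            pred, score = predict(model, X[idx])
            rep = evaluate(
                y[idx], pred, sign * score, class_a,
                dataset_tag=tag, patient_ids=sub.patient_ids[idx],
            )
            row = _report_dict(rep)
            row["algorithm"] = algo
            out["metrics"].append(row)
            if algo == "plsda" and tag == "validation" and rep.roc_points is not None:
                out["roc_validation_plsda"] = rep.roc_points.tolist()

    # ---- biomarkers on the training spectra
    d = dbm(sub.take(tr), positive, class_a if positive != class_a else class_b,
            config.dbm_threshold)
    out["dbm"] = {
        "class_pos": d.class_pos,
        "class_neg": d.class_neg,
        "threshold": d.threshold,
        "flagged": d.flagged,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = build_marker_table(pls, sub.take(tr), config.n_peaks)
    out["markers"] = table.frame.to_dict(orient="records")
    out["_marker_table"] = table  # in-memory only, for the screen stage
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the artifact bundle as a dict and,
    when ``config.outdir`` is set, writes each artifact there."""
    config.validate()
    if config.simulate:
        design, bands, effects = default_study_design()
        ds = generate_cohort(design, bands, effects, config.seed)
    else:
        ds = read_spectra(config.spectra_path, config.metadata_path)

    params = PreprocessParams(
        fp_lo=config.fp_lo, fp_hi=config.fp_hi,
        window=config.window, polyorder=config.polyorder, deriv=config.deriv,
    )
    pp = preprocess(ds, params)
    qc = t2q_test(pp, alpha=config.qc_alpha, explained_variance=config.qc_evr)

    bundle: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
            "n_spectra": int(pp.n_spectra),
            "n_points": int(pp.n_points),
        },
        "qc": {
            "n_components": qc.n_components,
            "alpha": qc.alpha,
            "t2_limit": qc.t2_limit,
            "q_limit": qc.q_limit,
            "n_flagged": qc.n_flagged,
            "flagged_ids": [str(s) for s in qc.spectrum_ids[qc.flags]],
        },
        "comparisons": {},
    }

    present = set(pp.labels)
    for name in config.comparisons:
        a, b, _ = COMPARISONS[name]
        if a not in present or b not in present:
            continue
        bundle["comparisons"][name] = _run_comparison(pp, name, config)

    if (
        "G1_vs_G1R" in bundle["comparisons"]
        and "G1" in present
        and "G1R" in present
    ):
        table = bundle["comparisons"]["G1_vs_G1R"]["_marker_table"]
        res = screen(pp, table, rule=config.screen_rule)
        bundle["screen"] = {
            "rule": res.rule,
            "flagged_patients": res.flagged_patients,
            "flagged_percent": res.flagged_percent,
            "per_patient": res.per_patient.to_dict(orient="records"),
        }
    for comp in bundle["comparisons"].values():
        comp.pop("_marker_table", None)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if config.simulate:
            write_spectra(ds, outdir / "spectra.csv", outdir / "metadata.tsv")
        qc.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        _write_json(bundle["provenance"], outdir / "provenance.json")
        _write_json(bundle["qc"], outdir / "qc_summary.json")
        for name, comp in bundle["comparisons"].items():
            _write_json(comp, outdir / f"comparison_{name}.json")
        if "screen" in bundle:
            _write_json(bundle["screen"], outdir / "screen.json")
    return bundle
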