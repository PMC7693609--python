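"""Random-forest subject stratification with leave-one-out cross-validation.

Each subject is predicted by a forest trained on all remaining subjects;
the point accuracy is the fraction of correct out-of-fold predictions, the
parenthetical interval is a percentile bootstrap (default 2000 resamples)
over the out-of-fold correctness vector, and the ROC curve/area are
computed from the pooled out-of-fold class-1 probabilities.

Subjects are canonically ordered by subject_id inside every fit, bootstrap
and pooling step, so results are invariant to the row order of the design
matrix at a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ValidationError
from .phantom_sim import CohortRecord

__all__ = [
    "DesignMatrix",
    "EvalReport",
    "build_design_matrix",
    "loocv_random_forest",
    "compare_feature_sets",
    "plot_roc",
]

FAMILY_HISTORY_LEVELS = ("none", "diabetes", "hypertensive", "leukemia")


@dataclass
class DesignMatrix:
    """Subjects x features with binary labels (healthy=0, symptomatic=1)."""

    X: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    feature_names: list[str]
    feature_set: str = "latent_only"     # {latent_only, clinical_only, latent_plus_clinical}

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.labels.size:
            raise ValidationError("X rows must match labels length")
        if len(self.subject_ids) != self.labels.size:
            raise ValidationError("subject_ids must match labels length")
        if not np.all(np.isin(self.labels, [0, 1])):
            raise ValidationError("labels must be binary 0/1")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("design matrix contains missing/non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.labels.size


@dataclass
class EvalReport:
    accuracy: float                          # percent
    accuracy_interval: tuple[float, float]   # percent, (lo, hi)
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_auc: float
    predictions: pd.DataFrame                # subject_id, label, pred, prob
    seed: int
    n_subjects: int
    feature_set: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.accuracy_interval
        if not (lo - 1e-9 <= self.accuracy <= hi + 1e-9):
            raise ValidationError("interval must contain the point accuracy")
        if not 0.0 <= self.roc_auc <= 1.0:
            raise ValidationError("ROC area must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "accuracy": self.accuracy,
            "accuracy_interval": list(self.accuracy_interval),
            "roc_auc": self.roc_auc,
            "roc_fpr": np.asarray(self.roc_fpr).tolist(),
            "roc_tpr": np.asarray(self.roc_tpr).tolist(),
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "predictions": self.predictions.to_dict(orient="list"),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_design_matrix(
    codes: np.ndarray | None,
    records: list[CohortRecord] | None = None,
    subject_ids: list[str] | None = None,
    feature_set: str = "latent_only",
    family_history_any: bool = True,
    include_hormone_therapy: bool = False,
) -> DesignMatrix:
    """Assemble latent codes and/or encoded clinical covariates.

    Clinical covariates: numeric age, family history (any-vs-none by
    default, or one-hot over the four recorded levels), and optionally
    hormone therapy. Labels come from the cohort records.
    """
    if feature_set not in ("latent_only", "clinical_only", "latent_plus_clinical"):
        raise ValidationError(f"unknown feature_set {feature_set!r}")
    use_latent = feature_set != "clinical_only"
    use_clinical = feature_set != "latent_only"
    if use_latent and codes is None:
        raise ValidationError("latent codes required for this feature set")
    if records is None:
        raise ValidationError("cohort records are required (labels)")

    order = {r.subject_id: i for i, r in enumerate(records)}
    if subject_ids is None:
        subject_ids = [r.subject_id for r in records]
    recs = [records[order[sid]] for sid in subject_ids]

    cols, names = [], []
    if use_latent:
        codes = np.asarray(codes, dtype=np.float64)
        if codes.shape[0] != len(subject_ids):
            raise ValidationError("codes rows must match number of subjects")
        cols.append(codes)
        names += [f"latent_{i}" for i in range(codes.shape[1])]
    if use_clinical:
        age = np.array([[r.age] for r in recs])
        cols.append(age)
        names.append("age")
        if family_history_any:
            cols.append(np.array([[float(r.family_history != "none")] for r in recs]))
            names.append("family_history_any")
        else:
            for level in FAMILY_HISTORY_LEVELS[1:]:
                cols.append(np.array([[float(r.family_history == level)] for r in recs]))
                names.append(f"family_history_{level}")
        if include_hormone_therapy:
            cols.append(np.array([[float(r.hormone_therapy)] for r in recs]))
            names.append("hormone_therapy")
    labels = np.array([int(r.label == "symptomatic") for r in recs])
    return DesignMatrix(X=np.hstack(cols), labels=labels, subject_ids=list(subject_ids),
                        feature_names=names, feature_set=feature_set)


def loocv_random_forest(
    dm: DesignMatrix,
    n_trees: int = 1000,
    seed: int = 0,
    n_bootstrap: int = 2000,
) -> EvalReport:
    """Leave-one-out random forest with bootstrap accuracy interval and ROC."""
    n = dm.n_subjects
    if n < 3:
        raise ValidationError("need at least 3 subjects for LOOCV")
    classes = np.unique(dm.labels)
    if classes.size < 2:
        raise ValidationError("both classes must be present")

    # canonical order: invariance to the caller's row order
    order = np.argsort(np.asarray(dm.subject_ids, dtype=object))
    X, y = dm.X[order], dm.labels[order]
    sids = [dm.subject_ids[i] for i in order]

    preds = np.empty(n, dtype=int)
    probs = np.empty(n, dtype=float)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1,
        )
        rf.fit(X[mask], y[mask])
        probs[i] = rf.predict_proba(X[i:i + 1])[0, list(rf.classes_).index(1)] \
            if 1 in rf.classes_ else 0.0
        preds[i] = rf.predict(X[i:i + 1])[0]

    correct = (preds == y).astype(float)
    accuracy = 100.0 * correct.mean()
    rng = np.random.default_rng(seed)
    boot = rng.integers(0, n, size=(n_bootstrap, n))
    boot_acc = 100.0 * correct[boot].mean(axis=1)
    lo, hi = np.percentile(boot_acc, [2.5, 97.5])
    lo, hi = min(lo, accuracy), max(hi, accuracy)

    fpr, tpr, _ = roc_curve(y, probs)
    auc = float(roc_auc_score(y, probs))
    predictions = pd.DataFrame({
        "subject_id": sids, "label": y, "pred": preds, "prob": probs,
    })
    return EvalReport(
        accuracy=float(accuracy), accuracy_interval=(float(lo), float(hi)),
        roc_fpr=fpr, roc_tpr=tpr, roc_auc=auc, predictions=predictions,
        seed=seed, n_subjects=n, feature_set=dm.feature_set,
    )


def compare_feature_sets(
    dm_variants: list[DesignMatrix],
    seed: int = 0,
    n_trees: int = 1000,
    n_bootstrap: int = 2000,
) -> tuple[pd.DataFrame, dict[str, EvalReport]]:
    """One LOOCV report per design-matrix variant, plus a ranked summary."""
    if not dm_variants:
        raise ValidationError("no design matrices supplied")
    ref = dm_variants[0]
    ref_key = sorted(zip(ref.subject_ids, ref.labels))
    for dm in dm_variants[1:]:
        if sorted(zip(dm.subject_ids, dm.labels)) != ref_key:
            raise ValidationError(
                "all variants must share identical subjects and labels"
            )
    reports = {dm.feature_set: loocv_random_forest(dm, n_trees=n_trees, seed=seed,
                                                   n_bootstrap=n_bootstrap)
               for dm in dm_variants}
    rows = [{
        "feature_set": name,
        "accuracy_pct": rep.accuracy,
        "ci_lo_pct": rep.accuracy_interval[0],
        "ci_hi_pct": rep.accuracy_interval[1],
        "roc_auc": rep.roc_auc,
        "n_subjects": rep.n_subjects,
    } for name, rep in reports.items()]
    table = pd.DataFrame(rows).sort_values("accuracy_pct", ascending=False,
                                           kind="stable").reset_index(drop=True)
    return table, reports


def plot_roc(reports: dict[str, EvalReport], path) -> None:
    """Pooled out-of-fold ROC curves for one or more evaluation reports."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        ax.plot(rep.roc_fpr, rep.roc_tpr,
                label=f"{name} (AUC {rep.roc_auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
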