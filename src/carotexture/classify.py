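"""Patient-level leave-one-out gradient-boosted classification.

For each task (PA vs EH; hypertensives vs controls) and feature subset,
every leave-one-out fold trains an XGBoost classifier on all images of
all other patients — each training sample weighted 1/(images of its
patient) so every patient carries unit weight — predicts probabilities
for the held-out patient's images, and aggregates them to one
per-patient probability.  Accuracy and the ROC are computed over
patients.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from xgboost import XGBClassifier

from .features import FEATURE_NAMES

#: clinical / biochemical covariate subsets used as classifier inputs
CLINICAL_FEATURES = ["age", "sex_female", "office_sbp", "office_dbp", "glucose",
                     "cholesterol", "hdl", "ldl", "smoking", "triglycerides"]
IMT_FEATURES = ["cca_imt", "cb_imt", "combined_imt"]
ALDO_FEATURES = ["aldosterone", "renin", "arr"]

FEATURE_SUBSETS: dict[str, list[str]] = {
    "clinical": CLINICAL_FEATURES,
    "clinical_imt": CLINICAL_FEATURES + IMT_FEATURES,
    "texture": list(FEATURE_NAMES),
    "aldo": ALDO_FEATURES,
}

TASKS = ("PA_vs_EH", "HTN_vs_C")
#: positive class per task
POSITIVE = {"PA_vs_EH": "PA", "HTN_vs_C": "HTN"}


@dataclass
class TaskSpec:
    """A classification task plus the feature subset feeding it."""

    task: str
    feature_subset: str | list[str] = "texture"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if isinstance(self.feature_subset, str):
            if self.feature_subset not in FEATURE_SUBSETS:
                raise ValueError(f"unknown feature subset {self.feature_subset!r}")
            if self.feature_subset == "aldo" and self.task == "HTN_vs_C":
                raise ValueError(
                    "aldosterone panel is unavailable for controls; "
                    "'aldo' is invalid for HTN_vs_C")

    @property
    def columns(self) -> list[str]:
        if isinstance(self.feature_subset, str):
            return FEATURE_SUBSETS[self.feature_subset]
        return list(self.feature_subset)

    @property
    def positive_class(self) -> str:
        return POSITIVE[self.task]


@dataclass
class ModelConfig:
    """Gradient-boosted-tree settings; recorded in the result hash."""

    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.3
    subsample: float = 1.0
    # unit-per-patient sample weights shrink hessian sums well below 1,
    # so the library default (1) would veto almost every split
    min_child_weight: float = 0.0
    # exact greedy splits at midpoints between values; the histogram
    # method would pin thresholds to training extremes, which hurts
    # held-out patients falling inside the margin gap
    tree_method: str = "exact"
    aggregation: str = "mean"  # or "vote"

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class LooResult:
    per_patient: pd.DataFrame  # patient_id, true_label, probability, predicted
    accuracy: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    seed: int
    config_hash: str
    task: str = ""
    feature_subset: str = ""


def task_labels(group_label: pd.Series, task: str) -> pd.Series:
    """Binary labels for a task; rows outside the task are dropped upstream."""
    if task == "PA_vs_EH":
        return group_label.map({"PA": 1, "EH": 0})
    return group_label.map({"PA": 1, "EH": 1, "C": 0})


def build_design(table: pd.DataFrame, clinical: pd.DataFrame, spec: TaskSpec) -> pd.DataFrame:
    """Design matrix rows for a task: image-level for texture features,
    patient-level for clinical subsets (one record per patient)."""
    cols = spec.columns
    id_cols = ("image_id", "patient_id", "group_label")
    texture_cols = [c for c in cols if c in table.columns and c not in id_cols]
    clinical_cols = [c for c in cols if c not in texture_cols]
    if texture_cols and clinical_cols:
        merged = table.merge(clinical.drop(columns=["group_label"], errors="ignore"),
                             on="patient_id", how="left")
    elif texture_cols:
        merged = table.copy()
    else:
        merged = clinical.copy()
        merged["image_id"] = merged["patient_id"]
    y = task_labels(merged["group_label"], spec.task)
    merged = merged[y.notna()].copy()
    merged["_label"] = y[y.notna()].astype(int)
    return merged[["image_id", "patient_id", "_label"] + cols]


def aggregate_patient(image_probs, mode: str = "mean") -> tuple[float, bool]:
    """Combine one patient's image probabilities into (probability, label).

    ``mean``: arithmetic-mean probability, positive iff > 0.5.  ``vote``:
    fraction of images voting positive, positive iff > 0.5.  Exact ties
    resolve to the negative (control / EH) class.
    """
    probs = np.asarray(list(image_probs), dtype=float)
    if probs.size == 0:
        raise ValueError("no image probabilities to aggregate")
    if mode == "mean":
        p = float(probs.mean())
    elif mode == "vote":
        p = float((probs > 0.5).mean())
    else:
        raise ValueError(f"unknown aggregation {mode!r}")
    return p, p > 0.5


def _fit_predict(X_tr, y_tr, w_tr, X_te, config: ModelConfig, seed: int) -> np.ndarray:
    model = XGBClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        subsample=config.subsample,
        min_child_weight=config.min_child_weight,
        random_state=seed,
        n_jobs=1,
        tree_method=config.tree_method,
        eval_metric="logloss",
    )
    model.fit(X_tr, y_tr, sample_weight=w_tr)
    return model.predict_proba(X_te)[:, 1]


def loo_evaluate(
    table: pd.DataFrame,
    clinical: pd.DataFrame,
    spec: TaskSpec,
    model_config: ModelConfig | None = None,
    seed: int = 0,
) -> LooResult:
    """Leave-one-patient-out evaluation of one task / feature subset.

    The held-out patient's images never enter the training fold; training
    samples are weighted so each training patient has unit total weight.
    Deterministic for a fixed seed and config.
    """
    config = model_config or ModelConfig()
    design = build_design(table, clinical, spec)
    patients = design.groupby("patient_id")["_label"].first()
    if patients.nunique() < 2 or (patients.value_counts() < 2).any():
        raise ValueError("need at least 2 patients per class")
    cols = spec.columns
    X_all = design[cols].to_numpy(dtype=float)
    y_all = design["_label"].to_numpy()
    pid_all = design["patient_id"].to_numpy()
    n_images = design.groupby("patient_id").size()
    rows = []
    for pid in patients.index:
        test = pid_all == pid
        train = ~test
        y_tr = y_all[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"a class vanishes from the training fold for patient {pid}")
        w_tr = 1.0 / n_images.loc[pid_all[train]].to_numpy(dtype=float)
        probs = _fit_predict(X_all[train], y_tr, w_tr, X_all[test], config, seed)
        p, pos = aggregate_patient(probs, config.aggregation)
        rows.append({"patient_id": pid, "true_label": int(patients.loc[pid]),
                     "probability": p, "predicted": int(pos)})
    per_patient = pd.DataFrame(rows)
    accuracy = float((per_patient["true_label"] == per_patient["predicted"]).mean())
    fpr, tpr, aucv = roc_points(per_patient["true_label"].to_numpy(),
                                per_patient["probability"].to_numpy())
    subset = spec.feature_subset if isinstance(spec.feature_subset, str) else "custom"
    return LooResult(per_patient=per_patient, accuracy=accuracy, fpr=fpr, tpr=tpr,
                     auc=aucv, seed=seed, config_hash=config.hash(),
                     task=spec.task, feature_subset=subset)


def roc_points(y_true: np.ndarray, probs: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC over aggregated patient probabilities, with trapezoidal AUC."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _roc_curve(y_true, probs, drop_intermediate=False)
    return fpr, tpr, float(_auc(fpr, tpr))


def roc_from_loo(result: LooResult) -> tuple[np.ndarray, np.ndarray, float]:
    return roc_points(result.per_patient["true_label"].to_numpy(),
                      result.per_patient["probability"].to_numpy())


def permutation_null(
    table: pd.DataFrame,
    clinical: pd.DataFrame,
    spec: TaskSpec,
    n_permutations: int = 20,
    model_config: ModelConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """LOO accuracies after permuting patient labels (chance baseline).

    Labels are shuffled at the patient level, keeping each patient's
    images together, then the full LOO evaluation reruns.
    """
    rng = np.random.default_rng(seed)
    labels = table.groupby("patient_id")["group_label"].first()
    accs = []
    for _ in range(n_permutations):
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        t = table.copy()
        t["group_label"] = t["patient_id"].map(perm)
        c = clinical.copy()
        if "group_label" in c.columns:
            c["group_label"] = c["patient_id"].map(perm)
        accs.append(loo_evaluate(t, c, spec, model_config, seed=seed).accuracy)
    return np.asarray(accs)


SUBSET_LABELS = {
    "clinical": "Clinical characteristics",
    "clinical_imt": "Clinical characteristics + IMT parameters",
    "texture": "Texture features",
    "aldo": '"Aldo" parameters',
}


def accuracy_table(results: dict[tuple[str, str], LooResult]) -> pd.DataFrame:
    """Accuracy grid: rows = feature subsets, columns = tasks; NA where
    a subset is undefined for a task (aldo panel for HTN vs C)."""
    import warnings

    rows = []
    for subset in ("clinical", "clinical_imt", "texture", "aldo"):
        row = {"parameters": SUBSET_LABELS[subset]}
        any_present = False
        for task in TASKS:
            if subset == "aldo" and task == "HTN_vs_C":
                row[task] = "NA"
                continue
            res = results.get((task, subset))
            if res is None:
                continue
            row[task] = f"{res.accuracy:.2f}"
            any_present = True
        if any_present or subset == "aldo" and ("PA_vs_EH", "aldo") in results:
            rows.append(row)
        else:
            warnings.warn(f"no results for subset {subset!r}; row omitted", stacklevel=2)
    return pd.DataFrame(rows, columns=["parameters", *TASKS])
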