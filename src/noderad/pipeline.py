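"""Patient-level nested cross-validation and the two-arm comparison.

The outer loop partitions patients (never nodes) into k folds; each
iteration holds one fold out as an untouched test set.  All data
preparation is refitted inside each iteration: Min-Max scaling factors
come from the training rows only, SMOTE balances only the training
rows, and hyperparameters (C, sigma) are tuned by an inner patient-level
cross-validation on the training folds.  The final model for the
iteration is a Gaussian-kernel SMO-trained SVM with Platt calibration,
evaluated on the held-out fold.  Pooled out-of-fold predictions cover
every node exactly once.

``compare_models`` runs the baseline (56 conventional features) and the
spatially aware arm (56 + 5 features) under identical fold assignments
and seeds, so the two arms differ only in the feature set.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PatientCase, ValidationError
from .evaluate import delong_test, evaluation_report, paired_correctness_test
from .features import CONVENTIONAL_FEATURE_NAMES, extract_conventional
from .phantom import PhantomConfig, iter_cohort
from .preprocess import apply_minmax, fit_minmax, smote
from .spatial import SPATIAL_FEATURE_NAMES, extract_spatial
from .svm import (
    SVMConfig,
    TrainedSVM,
    decision_function,
    platt_calibrate,
    predict_probability,
    smo_train,
)

logger = logging.getLogger(__name__)

ID_COLUMNS = ("patient_id", "node_id", "label")

DEFAULT_GRID_C = tuple(float(2.0**k) for k in range(-3, 8))
DEFAULT_GRID_SIGMA = tuple(float(2.0**k) for k in range(-4, 5))


@dataclass
class CVConfig:
    outer_k: int = 5
    inner_k: int = 4
    grid_c: tuple[float, ...] = DEFAULT_GRID_C
    grid_sigma: tuple[float, ...] = DEFAULT_GRID_SIGMA
    threshold: float = 0.5
    seed: int = 0
    feature_set: str = "spatial61"  # "conventional56" | "spatial61"
    smote_k: int = 5
    svm_tol: float = 1e-3
    svm_max_passes: int = 5

    def validate(self) -> None:
        if self.outer_k < 2:
            raise ValidationError("outer_k must be >= 2")
        if not self.grid_c or not self.grid_sigma:
            raise ValidationError("hyperparameter grid must be nonempty")
        if not 0 < self.threshold < 1:
            raise ValidationError("threshold must be in (0, 1)")
        if self.feature_set not in ("conventional56", "spatial61"):
            raise ValidationError(f"unknown feature_set {self.feature_set!r}")

    def feature_names(self) -> tuple[str, ...]:
        if self.feature_set == "conventional56":
            return CONVENTIONAL_FEATURE_NAMES
        return CONVENTIONAL_FEATURE_NAMES + SPATIAL_FEATURE_NAMES


def build_feature_table(
    cases_or_config, n_bins: int = 32, include_spatial: bool = True
) -> pd.DataFrame:
    """Extract the per-node feature table for a cohort.

    Accepts either an iterable of :class:`PatientCase` or a
    :class:`~noderad.phantom.PhantomConfig` (streamed patient by
    patient to bound memory).  Rows are nodes; columns are the id
    columns plus the 56 conventional and, optionally, 5 spatial
    features.
    """
    if isinstance(cases_or_config, PhantomConfig):
        cases = (case for _, case in iter_cohort(cases_or_config))
    else:
        cases = iter(cases_or_config)
    rows = []
    for case in cases:
        for i, node in enumerate(case.nodes):
            row: dict[str, object] = {
                "patient_id": case.patient_id,
                "node_id": node.roi_id or f"{case.patient_id}_n{i:02d}",
                "label": 1 if node.label == "malignant" else 0,
            }
            row.update(extract_conventional(case.volume, node, n_bins=n_bins))
            if include_spatial:
                row.update(extract_spatial(case, i).as_dict())
            rows.append(row)
    if not rows:
        raise ValidationError("cohort produced no nodes")
    return pd.DataFrame(rows)


def make_patient_folds(patient_ids, k: int, seed: int) -> dict[str, int]:
    """Seeded balanced partition of patients into k folds (sizes differ <= 1)."""
    ids = sorted(set(map(str, patient_ids)))
    if len(ids) < k:
        raise ValidationError(f"need at least {k} patients, got {len(ids)}")
    rng = np.random.default_rng(np.random.PCG64(seed))
    order = rng.permutation(len(ids))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[ids[idx]] = pos % k
    return assignment


def fold_assignment_hash(folds: dict[str, int]) -> str:
    payload = ";".join(f"{pid}:{f}" for pid, f in sorted(folds.items()))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fit_arm(
    train: pd.DataFrame,
    feature_names: tuple[str, ...],
    C: float,
    sigma: float,
    config: CVConfig,
    seed: int,
):
    """Scale, SMOTE-balance and fit SVM + Platt on one training table."""
    scaler = fit_minmax(train, feature_names)
    train_scaled = apply_minmax(scaler, train)
    X = train_scaled[list(feature_names)].to_numpy(dtype=float)
    y = train_scaled["label"].to_numpy(dtype=int)
    rng = np.random.default_rng(np.random.PCG64((seed, 17)))
    X_bal, y_bal, syn_flags = smote(X, y, k=config.smote_k, rng=rng)
    svm_cfg = SVMConfig(
        C=C,
        sigma=sigma,
        tol=config.svm_tol,
        max_passes=config.svm_max_passes,
        seed=int(seed) % (2**31),
    )
    model = smo_train(X_bal, np.where(y_bal == 1, 1.0, -1.0), svm_cfg)
    scores = decision_function(model, X_bal)
    model.platt_a, model.platt_b = platt_calibrate(
        scores, np.where(y_bal == 1, 1.0, -1.0)
    )
    return model, scaler, syn_flags


def inner_tune(
    train: pd.DataFrame,
    feature_names: tuple[str, ...],
    config: CVConfig,
    seed: int,
) -> tuple[float, float]:
    """Grid-search (C, sigma) by inner patient-level CV accuracy.

    Ties break toward the smallest C, then the smallest sigma.  A
    singleton grid is returned without running the inner loop.
    """
    grid = [(c, s) for c in sorted(config.grid_c) for s in sorted(config.grid_sigma)]
    if len(grid) == 1:
        return grid[0]
    inner_k = min(config.inner_k, train["patient_id"].nunique())
    folds = make_patient_folds(train["patient_id"], inner_k, seed)
    fold_col = train["patient_id"].map(folds)

    best: tuple[float, float] | None = None
    best_acc = -np.inf
    for C, sigma in grid:
        accs = []
        for f in range(inner_k):
            tr = train[fold_col != f]
            va = train[fold_col == f]
            if tr["label"].nunique() < 2 or len(va) == 0:
                logger.warning("inner split %d skipped (missing class)", f)
                continue
            model, scaler, _ = _fit_arm(
                tr, feature_names, C, sigma, config, seed=(seed * 97 + f) % (2**31)
            )
            va_scaled = apply_minmax(scaler, va)
            prob = predict_probability(
                model, va_scaled[list(feature_names)].to_numpy(dtype=float)
            )
            pred = (prob >= config.threshold).astype(int)
            accs.append(float((pred == va["label"].to_numpy()).mean()))
        if not accs:
            raise ValidationError("all inner splits degenerate")
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc = acc
            best = (C, sigma)
    assert best is not None
    return best


@dataclass
class NestedCVResult:
    predictions: pd.DataFrame  # node_id, patient_id, label, score, pred, fold
    models: list[TrainedSVM]
    fold_assignment: dict[str, int]
    chosen_params: list[tuple[float, float]]
    feature_set: str
    fold_info: list[dict] = field(default_factory=list)

    @property
    def fold_hash(self) -> str:
        return fold_assignment_hash(self.fold_assignment)


def run_nested_cv(
    table: pd.DataFrame,
    config: CVConfig,
    folds: dict[str, int] | None = None,
) -> NestedCVResult:
    """Nested patient-level CV producing pooled out-of-fold predictions."""
    config.validate()
    feature_names = config.feature_names()
    missing = [c for c in (*ID_COLUMNS, *feature_names) if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table is missing columns: {missing}")
    if folds is None:
        folds = make_patient_folds(table["patient_id"], config.outer_k, config.seed)
    fold_col = table["patient_id"].map(folds)
    if fold_col.isna().any():
        raise ValidationError("fold assignment does not cover all patients")

    all_preds = []
    models = []
    chosen = []
    fold_info = []
    for f in range(config.outer_k):
        train = table[fold_col != f]
        test = table[fold_col == f]
        # leakage audit: patient-level disjointness is a hard failure
        overlap = set(train["patient_id"]) & set(test["patient_id"])
        if overlap:
            raise AssertionError(f"patient(s) in both train and test: {overlap}")
        if len(test) == 0:
            continue
        C, sigma = inner_tune(
            train, feature_names, config, seed=(config.seed * 1009 + f) % (2**31)
        )
        chosen.append((C, sigma))
        model, scaler, syn_flags = _fit_arm(
            train, feature_names, C, sigma, config, seed=(config.seed * 31 + f) % (2**31)
        )
        # scaler provenance audit: factors must reproduce from train rows alone
        check = fit_minmax(train, feature_names)
        if not (
            np.array_equal(check.mins, scaler.mins)
            and np.array_equal(check.maxs, scaler.maxs)
        ):
            raise AssertionError("scaler was not fitted on training rows only")
        test_scaled = apply_minmax(scaler, test)
        prob = predict_probability(
            model, test_scaled[list(feature_names)].to_numpy(dtype=float)
        )
        preds = pd.DataFrame(
            {
                "node_id": test["node_id"].to_numpy(),
                "patient_id": test["patient_id"].to_numpy(),
                "label": test["label"].to_numpy(),
                "score": prob,
                "pred": (prob >= config.threshold).astype(int),
                "fold": f,
            }
        )
        all_preds.append(preds)
        models.append(model)
        fold_info.append(
            {
                "fold": f,
                "n_train": len(train),
                "n_test": len(test),
                "n_synthetic": int(syn_flags.sum()),
                "C": C,
                "sigma": sigma,
            }
        )

    pooled = pd.concat(all_preds, ignore_index=True)
    # partition audit: predictions are a bijection onto nodes
    if sorted(pooled["node_id"]) != sorted(table["node_id"]):
        raise AssertionError("pooled predictions do not cover every node exactly once")
    return NestedCVResult(
        predictions=pooled,
        models=models,
        fold_assignment=folds,
        chosen_params=chosen,
        feature_set=config.feature_set,
        fold_info=fold_info,
    )


@dataclass
class ComparisonReport:
    baseline: NestedCVResult
    enhanced: NestedCVResult
    baseline_report: dict
    enhanced_report: dict
    delong: dict
    paired_accuracy: dict
    fold_hash: str

    def to_dict(self) -> dict:
        return {
            "fold_hash": self.fold_hash,
            "baseline": self.baseline_report,
            "enhanced": self.enhanced_report,
            "delong": self.delong,
            "paired_accuracy": self.paired_accuracy,
        }


def compare_models(
    table: pd.DataFrame, config: CVConfig, n_boot: int = 1000
) -> ComparisonReport:
    """Baseline (56 features) vs spatially aware (61) under shared folds."""
    config.validate()
    folds = make_patient_folds(table["patient_id"], config.outer_k, config.seed)

    results = {}
    for feature_set in ("conventional56", "spatial61"):
        cfg = CVConfig(**{**config.__dict__, "feature_set": feature_set})
        results[feature_set] = run_nested_cv(table, cfg, folds=folds)
    base = results["conventional56"]
    enh = results["spatial61"]
    assert base.fold_hash == enh.fold_hash  # controlled comparison

    # align node order for the paired tests
    bp = base.predictions.sort_values("node_id").reset_index(drop=True)
    ep = enh.predictions.sort_values("node_id").reset_index(drop=True)
    labels = bp["label"].to_numpy()
    dl = delong_test(labels, ep["score"].to_numpy(), bp["score"].to_numpy())
    pt = paired_correctness_test(
        (ep["pred"] == ep["label"]).to_numpy(int),
        (bp["pred"] == bp["label"]).to_numpy(int),
    )
    base_rep = evaluation_report(
        labels, bp["score"].to_numpy(), config.threshold, n_boot=n_boot, seed=config.seed
    )
    enh_rep = evaluation_report(
        labels, ep["score"].to_numpy(), config.threshold, n_boot=n_boot, seed=config.seed
    )
    return ComparisonReport(
        baseline=base,
        enhanced=enh,
        baseline_report=base_rep.to_dict(),
        enhanced_report=enh_rep.to_dict(),
        delong=dl,
        paired_accuracy=pt,
        fold_hash=base.fold_hash,
    )
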