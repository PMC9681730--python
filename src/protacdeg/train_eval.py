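"""Training, evaluation, ablation / generalization protocols, baselines.

Training follows the reference regime: Adam (lr 1e-4, betas 0.9/0.999),
cross-entropy on two logits, batch size 1 for 30 epochs with per-epoch
shuffling.  For non-unit batch sizes the epoch count is chosen by
validation loss (patience-based early stopping).  Evaluation reports
accuracy at the 0.5 threshold, rank-based AUROC, true positive rate and
precision; repeated runs aggregate as mean ± sample SD.  The classical
baselines are a linear-kernel SVM (C = 1) and a random forest
(100 trees, depth 5) on ternary-complex features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from . import nn
from .baselines import protac_smiles, ternary_features
from .chem_io import pocket_from_structure, read_small_molecule, read_structure
from .dataset import (
    ACTIVE,
    DegradationRecord,
    SplitSpec,
    class_loss_weights,
    split,
)
from .featurize import (
    EncodingTable,
    MolecularGraph,
    TokenSequence,
    default_encoding_table,
    to_graph,
    tokenize,
)
from .model import (
    ACTIVE_INDEX,
    ABLATION_ITEMS,
    ModelConfig,
    ModelParameters,
    ablated_config,
    forward_logits,
    init_model,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 1
    epochs: int = 30
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    loss_mode: str = "normal"  # {normal, weighted}
    seed: int = 0
    patience: int = 5      # early stopping on validation loss (batch != 1)
    max_epochs: int = 300  # cap when epochs are chosen by validation loss
    on_featurize_error: str = "raise"  # {raise, skip}
    assert_balanced: bool = False  # enforce a 1:1 class ratio (oversampling)

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.lr <= 0:
            raise ValueError("epochs and lr must be positive")


@dataclass
class EvalReport:
    """Percent-scale rates plus rank AUROC; ``auroc`` is None when the
    record set is single-class (undefined)."""

    accuracy: float
    auroc: float | None
    tpr: float | None
    precision: float | None
    n: int


@dataclass
class FeaturizedSample:
    """One record reduced to network inputs plus its binary label."""

    record_id: str
    poi_name: str
    inputs: dict[str, object]
    label: int  # 1 = active


# ---------------------------------------------------------------------------
# Featurization of records
# ---------------------------------------------------------------------------

def prepare_samples(
    records: list[DegradationRecord],
    structures_dir: str | Path,
    table: EncodingTable | None = None,
    max_len: int = 100,
    radius: float = 5.0,
    include_variants: bool = False,
    on_error: str = "raise",
) -> list[FeaturizedSample]:
    """Turn manifest records into per-branch network inputs.

    Pocket graphs are cached per structure path (records of the same POI or
    E3 share a pocket).  ``include_variants`` additionally builds the
    whole-PROTAC graph and SMILES inputs for the variant architectures.
    """
    table = table or default_encoding_table()
    base = Path(structures_dir)
    pocket_cache: dict[str, MolecularGraph] = {}
    ligand_cache: dict[str, MolecularGraph] = {}

    def pocket_graph(rel: str) -> MolecularGraph:
        if rel not in pocket_cache:
            path = base / rel
            if not path.exists():
                path = Path(rel)
            complex_rec = read_structure(path)
            _, pocket_rec, _ = pocket_from_structure(complex_rec, radius=radius)
            pocket_cache[rel] = to_graph(pocket_rec, "protein_pocket")
        return pocket_cache[rel]

    def ligand_graph(source: str) -> MolecularGraph:
        if source not in ligand_cache:
            ligand_cache[source] = to_graph(read_small_molecule(source), "ligand")
        return ligand_cache[source]

    samples = []
    for r in records:
        if r.label is None:
            raise ValueError(f"{r.record_id}: record is unlabeled; apply_labels first")
        try:
            inputs: dict[str, object] = {
                "poi_pocket": pocket_graph(r.poi_structure),
                "warhead": ligand_graph(r.warhead),
                "linker": tokenize(r.linker_smiles, table, max_len),
                "e3_ligand": ligand_graph(r.e3_ligand),
                "e3_pocket": pocket_graph(r.e3_structure),
            }
            if include_variants:
                whole = protac_smiles(r.warhead, r.linker_smiles, r.e3_ligand)
                inputs["protac_graph"] = ligand_graph(whole)
                inputs["protac_smiles"] = tokenize(whole, table, max_len)
        except Exception:
            if on_error == "skip":
                logger.exception("featurization failed for %s; skipped", r.record_id)
                continue
            raise
        samples.append(
            FeaturizedSample(
                record_id=r.record_id,
                poi_name=r.poi_name,
                inputs=inputs,
                label=1 if r.label == ACTIVE else 0,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _sample_loss(
    sample: FeaturizedSample,
    params: ModelParameters,
    model_cfg: ModelConfig,
    weights: tuple[float, float],
) -> nn.Tensor:
    logits = forward_logits(sample.inputs, params, model_cfg)
    w = weights[0] if sample.label == 1 else weights[1]
    return nn.cross_entropy_logits(nn.reshape(logits, (-1,)), sample.label, w)


def _epoch(
    samples: list[FeaturizedSample],
    params: ModelParameters,
    model_cfg: ModelConfig,
    opt: nn.Adam,
    weights: tuple[float, float],
    batch_size: int,
    rng: np.random.Generator,
) -> float:
    order = rng.permutation(len(samples))
    total = 0.0
    opt.zero_grad()
    pending = 0
    for k in order:
        loss = _sample_loss(samples[k], params, model_cfg, weights)
        nn.backward(loss)
        total += float(loss.data)
        pending += 1
        if pending == batch_size:
            opt.step()
            opt.zero_grad()
            pending = 0
    if pending:
        opt.step()
        opt.zero_grad()
    return total / len(samples)


def mean_loss(
    samples: list[FeaturizedSample],
    params: ModelParameters,
    model_cfg: ModelConfig,
    weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    return float(
        np.mean(
            [float(_sample_loss(s, params, model_cfg, weights).data) for s in samples]
        )
    )


def train(
    model_cfg: ModelConfig,
    train_samples: list[FeaturizedSample],
    val_samples: list[FeaturizedSample] | None,
    train_cfg: TrainConfig,
) -> tuple[ModelParameters, list[float]]:
    """Train a model from scratch; returns final parameters and the
    per-epoch mean training loss history.

    At batch size 1 the run lasts exactly ``epochs`` epochs; otherwise the
    epoch count is chosen by validation loss with the configured patience
    (up to ``max_epochs``).
    """
    if not train_samples:
        raise ValueError("empty training set")
    if train_cfg.assert_balanced:
        n_active = sum(s.label for s in train_samples)
        if 2 * n_active != len(train_samples):
            raise AssertionError(
                f"training set not 1:1 ({n_active} active of {len(train_samples)})"
            )
    params = init_model(model_cfg, seed=train_cfg.seed)
    opt = nn.Adam(
        params.all_parameters(),
        lr=train_cfg.lr,
        beta1=train_cfg.beta1,
        beta2=train_cfg.beta2,
    )
    weights = class_loss_weights(train_cfg.loss_mode)
    rng = np.random.default_rng(train_cfg.seed)
    history: list[float] = []

    if train_cfg.batch_size == 1 or val_samples is None:
        for _ in range(train_cfg.epochs):
            history.append(
                _epoch(train_samples, params, model_cfg, opt,
                       weights, train_cfg.batch_size, rng)
            )
        return params, history

    best_val = np.inf
    best_state = {k: {n: p.data.copy() for n, p in g.items()}
                  for k, g in params.groups.items()}
    stale = 0
    for _ in range(train_cfg.max_epochs):
        history.append(
            _epoch(train_samples, params, model_cfg, opt,
                   weights, train_cfg.batch_size, rng)
        )
        val = mean_loss(val_samples, params, model_cfg)
        if val < best_val - 1e-9:
            best_val, stale = val, 0
            best_state = {k: {n: p.data.copy() for n, p in g.items()}
                          for k, g in params.groups.items()}
        else:
            stale += 1
            if stale >= train_cfg.patience:
                break
    for k, g in params.groups.items():
        for n, p in g.items():
            p.data[...] = best_state[k][n]
    return params, history


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def predict_proba(
    params: ModelParameters, samples: list[FeaturizedSample]
) -> np.ndarray:
    probs = []
    for s in samples:
        logits = forward_logits(s.inputs, params, params.config).data.ravel()
        probs.append(nn.softmax(logits)[ACTIVE_INDEX])
    return np.array(probs)


def evaluate(
    params: ModelParameters, samples: list[FeaturizedSample]
) -> EvalReport:
    """Accuracy at the 0.5 threshold, rank AUROC over prob_active, TPR and
    precision (percent scale); AUROC is None with a warning on a
    single-class set."""
    if not samples:
        raise ValueError("empty evaluation set")
    y = np.array([s.label for s in samples])
    p = predict_proba(params, samples)
    pred = (p > 0.5).astype(int)
    accuracy = 100.0 * float((pred == y).mean())
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tpr = 100.0 * tp / (tp + fn) if (tp + fn) else None
    precision = 100.0 * tp / (tp + fp) if (tp + fp) else None
    if len(np.unique(y)) < 2:
        logger.warning("single-class evaluation set: AUROC undefined")
        auroc = None
    else:
        auroc = float(roc_auc_score(y, p))
    return EvalReport(accuracy=accuracy, auroc=auroc, tpr=tpr,
                      precision=precision, n=len(samples))


def roc_points(params: ModelParameters, samples: list[FeaturizedSample]) -> pd.DataFrame:
    """FPR/TPR pairs for ROC export."""
    from sklearn.metrics import roc_curve

    y = np.array([s.label for s in samples])
    p = predict_proba(params, samples)
    fpr, tpr, thr = roc_curve(y, p)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def aggregate_reports(reports: list[EvalReport]) -> dict:
    """Mean ± sample SD (ddof=1) over repeated runs."""
    def agg(vals):
        vals = [v for v in vals if v is not None]
        if not vals:
            return (None, None)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return (mean, sd)

    acc = agg([r.accuracy for r in reports])
    auc = agg([r.auroc for r in reports])
    return {
        "accuracy_mean": acc[0], "accuracy_sd": acc[1],
        "auroc_mean": auc[0], "auroc_sd": auc[1],
        "n_runs": len(reports),
    }


def paired_ttest(a: list[float], b: list[float]) -> tuple[float, float]:
    """Two-sided paired t-test between matched runs of two configurations
    (no multiple-comparison adjustment)."""
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def run_ablation_suite(
    train_samples: list[FeaturizedSample],
    test_samples: list[FeaturizedSample],
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    items: tuple[int, ...] = tuple(ABLATION_ITEMS),
    repeats: int = 3,
) -> pd.DataFrame:
    """Retrain with each ablated configuration (full retraining, not
    inference masking) and report mean ± SD over ``repeats`` seeds."""
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    rows = []
    for item in items:
        cfg = ablated_config(model_cfg, item)
        reports = []
        for rep in range(repeats):
            tc = replace(train_cfg, seed=train_cfg.seed + rep)
            params, _ = train(cfg, train_samples, None, tc)
            reports.append(evaluate(params, test_samples))
        agg = aggregate_reports(reports)
        rows.append(
            {
                "item": item,
                "branches": ",".join(cfg.active_branches),
                **agg,
                "per_run_accuracy": [r.accuracy for r in reports],
                "per_run_auroc": [r.auroc for r in reports],
            }
        )
    return pd.DataFrame(rows)


def leave_one_target_out(
    samples: list[FeaturizedSample],
    target_name: str,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    test_ratio: float = 0.2,
) -> tuple[EvalReport, EvalReport]:
    """Hold out every record of one POI; train on a split of the rest and
    evaluate on (held-out target, residual test set)."""
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    held = [s for s in samples if s.poi_name == target_name]
    rest = [s for s in samples if s.poi_name != target_name]
    if not held:
        raise ValueError(f"no records with poi_name {target_name!r}")
    if not rest:
        raise ValueError("no residual records to train on")
    tr, te = split(rest, SplitSpec((1 - test_ratio, test_ratio), seed=train_cfg.seed))
    params, _ = train(model_cfg, tr, None, train_cfg)
    return evaluate(params, held), evaluate(params, te)


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------

def train_svm(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> SVC:
    """Linear-kernel SVM, C = 1, with probability scores for AUROC."""
    clf = SVC(kernel="linear", C=1.0, probability=True, random_state=seed)
    clf.fit(features, labels)
    return clf


def train_rf(
    features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> RandomForestClassifier:
    """Random forest: 100 estimators, max depth 5."""
    clf = RandomForestClassifier(n_estimators=100, max_depth=5, random_state=seed)
    clf.fit(features, labels)
    return clf


def baseline_features(
    records: list[DegradationRecord],
    poi_sequences: dict[str, str],
    e3_sequences: dict[str, str],
    fp_kind: str = "morgan",
) -> tuple[np.ndarray, np.ndarray]:
    """Ternary-complex feature matrix (POI ACC, E3 ACC, PROTAC fingerprint)
    plus binary labels for the classical models."""
    feats, labels = [], []
    for r in records:
        if r.label is None:
            raise ValueError(f"{r.record_id}: unlabeled record")
        whole = protac_smiles(r.warhead, r.linker_smiles, r.e3_ligand)
        fv = ternary_features(
            poi_sequences[r.poi_name], e3_sequences[r.e3_name], whole, fp_kind
        )
        feats.append(fv.values)
        labels.append(1 if r.label == ACTIVE else 0)
    return np.stack(feats), np.array(labels)


def evaluate_classifier(clf, features: np.ndarray, labels: np.ndarray) -> EvalReport:
    p = clf.predict_proba(features)[:, 1]
    pred = (p > 0.5).astype(int)
    accuracy = 100.0 * float((pred == labels).mean())
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tpr = 100.0 * tp / (tp + fn) if (tp + fn) else None
    precision = 100.0 * tp / (tp + fp) if (tp + fp) else None
    auroc = (
        float(roc_auc_score(labels, p)) if len(np.unique(labels)) > 1 else None
    )
    return EvalReport(accuracy=accuracy, auroc=auroc, tpr=tpr,
                      precision=precision, n=len(labels))
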