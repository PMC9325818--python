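"""AUROC evaluation, heterogeneous confidence, and the RF-on-ECFP4 baseline.

AUROC is the probability that a randomly chosen positive outscores a
randomly chosen negative, with ties counted half. The "heterogeneous
confidence" half-width aggregates per-dataset AUCs as 1.96 * sd / sqrt(n) —
analogous to a 95% interval, though values pooled across heterogeneous
targets are not true standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from salqsar import chem
from salqsar.data import ActivityDataset, SplitResult

logger = logging.getLogger(__name__)


def auroc(labels, scores) -> float:
    """Midrank AUROC of binary ``labels`` against real-valued ``scores``."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def heterogeneous_confidence(auc_values) -> float:
    """1.96 * sample sd / sqrt(n) over per-dataset AUC values."""
    vals = np.asarray(auc_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 AUC values")
    return float(1.96 * vals.std(ddof=1) / np.sqrt(vals.size))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-slice AUC for one model on one chronological split."""

    auc: dict[str, float]
    n: dict[str, int]
    settings: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice": list(self.auc),
                "auc": list(self.auc.values()),
                "n": [self.n[k] for k in self.auc],
            }
        )


def evaluate_scores(
    dataset: ActivityDataset, split: SplitResult, score_fn, settings: dict | None = None
) -> EvaluationReport:
    """Score each evaluation slice of a split with ``score_fn(smiles_list)``.

    Slices: validation, test_early, test_late, and the combined full test.
    Slices with a single class get AUC ``nan`` (logged) rather than an error.
    """
    slices = {
        "validation": list(split.validation_ids),
        "test_early": list(split.test_early_ids),
        "test_late": list(split.test_late_ids),
        "test": list(split.test_ids),
    }
    auc, counts = {}, {}
    for name, ids in slices.items():
        sub = dataset.subset(ids)
        labels = sub.df["label"].to_numpy()
        counts[name] = len(ids)
        if len(set(labels.tolist())) < 2:
            logger.warning("slice %s has a single class; AUC undefined", name)
            auc[name] = float("nan")
            continue
        scores = score_fn(sub.df["smiles"].tolist())
        auc[name] = auroc(labels, scores)
    return EvaluationReport(auc=auc, n=counts, settings=settings or {})


def ecfp4_features(smiles_list, n_bits: int = 2048) -> np.ndarray:
    """Stack ECFP4 fingerprints into a dense 0/1 feature matrix."""
    out = np.zeros((len(smiles_list), n_bits), dtype=np.float32)
    for i, smi in enumerate(smiles_list):
        fp = chem.ecfp4(chem.parse_smiles(smi), n_bits=n_bits)
        out[i, list(fp.bits)] = 1.0
    return out


class ECFP4Featurizer:
    """Minimal sklearn-style transformer: SMILES -> ECFP4 bit matrix."""

    def __init__(self, n_bits: int = 2048):
        self.n_bits = n_bits

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        return ecfp4_features(list(X), n_bits=self.n_bits)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.transform(X)

    def get_params(self, deep=True):
        return {"n_bits": self.n_bits}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


def train_rf_baseline(
    dataset: ActivityDataset,
    split: SplitResult,
    n_trees: int = 100,
    seed: int = 0,
    n_bits: int = 2048,
) -> tuple[RandomForestClassifier, EvaluationReport]:
    """Random forest on ECFP4 bits of the chronological training slice.

    Trains on the earliest 80% (train + validation) and reports per-slice
    AUC; deterministic given ``seed``.
    """
    train_sub = dataset.subset(list(split.final_train_ids))
    labels = train_sub.df["label"].to_numpy()
    if len(set(labels.tolist())) < 2:
        raise ValueError("training slice must contain both classes")
    featurizer = ECFP4Featurizer(n_bits=n_bits)
    x_train = featurizer.transform(train_sub.df["smiles"].tolist())
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(x_train, labels)

    def score_fn(smiles_list):
        return model.predict_proba(featurizer.transform(smiles_list))[:, 1]

    report = evaluate_scores(
        dataset,
        split,
        score_fn,
        settings={
            "model": "random_forest",
            "n_trees": n_trees,
            "seed": seed,
            "n_bits": n_bits,
            "criterion": model.criterion,
            "max_features": model.max_features,
        },
    )
    return model, report
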