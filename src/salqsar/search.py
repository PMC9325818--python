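"""Greedy Gaussian hyperparameter search over (L2, conv1, conv2, conv3).

Despite the name it shares with surrogate-model methods, this is literal
Gaussian perturbation sampling around a greedy incumbent: each iteration
draws ``n`` candidates from independent Gaussians centered on the seed
vector (relative sigma 0.2 per dimension; L2 perturbed on the log scale,
layer sizes rounded and clamped to [4, 256]), evaluates them, and the best
vector — incumbent included — seeds the next iteration. No surrogate is
fit anywhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np

from salqsar.data import ActivityDataset, chronological_split
from salqsar.evaluate import auroc
from salqsar.gcnn import GCNNConfig, GraphConvClassifier

logger = logging.getLogger(__name__)

SIZE_BOUNDS = (4, 256)


@dataclass(frozen=True)
class HyperVector:
    """A point in the four-dimensional search space."""

    l2: float
    conv_sizes: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.l2 <= 0:
            raise ValueError("l2 must be positive")
        lo, hi = SIZE_BOUNDS
        if len(self.conv_sizes) != 3 or any(
            not lo <= s <= hi for s in self.conv_sizes
        ):
            raise ValueError(f"conv sizes must be three integers in [{lo}, {hi}]")


@dataclass
class SearchIteration:
    seed: HyperVector
    candidates: list[HyperVector]
    objectives: list[float]
    incumbent: HyperVector
    incumbent_objective: float


@dataclass
class SearchHistory:
    iterations: list[SearchIteration]

    def incumbent_trace(self) -> list[float]:
        return [it.incumbent_objective for it in self.iterations]

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for i, it in enumerate(self.iterations):
                for cand, obj in zip(it.candidates, it.objectives):
                    fh.write(
                        json.dumps(
                            {
                                "iteration": i,
                                "l2": cand.l2,
                                "conv_sizes": list(cand.conv_sizes),
                                "objective": obj,
                            }
                        )
                        + "\n"
                    )


def sample_candidates(
    seed: HyperVector,
    n: int = 80,
    rng: np.random.Generator | None = None,
    sigma: float = 0.2,
) -> list[HyperVector]:
    """Draw ``n`` Gaussian perturbations of the seed vector.

    L2 is perturbed multiplicatively (Gaussian on the log scale, sigma in
    log units); each conv size is drawn from N(value, sigma * value),
    rounded to the nearest integer and clamped to [4, 256]. ``sigma=0``
    returns copies of the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    lo, hi = SIZE_BOUNDS
    out = []
    for _ in range(n):
        l2 = float(seed.l2 * np.exp(sigma * rng.standard_normal()))
        sizes = tuple(
            int(np.clip(round(s + sigma * s * rng.standard_normal()), lo, hi))
            for s in seed.conv_sizes
        )
        out.append(HyperVector(l2=l2, conv_sizes=sizes))
    return out


def greedy_search(
    objective,
    seed: HyperVector,
    iterations: int = 10,
    n: int = 80,
    rng: np.random.Generator | None = None,
    sigma: float = 0.2,
) -> tuple[HyperVector, SearchHistory]:
    """Greedy Gaussian search: perturb, evaluate, keep the best, repeat.

    The incumbent is retained without re-evaluation, so its objective trace
    is non-decreasing by construction. A candidate whose objective raises is
    skipped with a log message, never fatal.
    """
    rng = np.random.default_rng() if rng is None else rng
    incumbent = seed
    incumbent_obj = objective(seed)
    history = SearchHistory(iterations=[])
    for it in range(iterations):
        iter_seed = incumbent
        candidates = sample_candidates(incumbent, n=n, rng=rng, sigma=sigma)
        objectives = []
        for cand in candidates:
            try:
                objectives.append(float(objective(cand)))
            except Exception as exc:  # noqa: BLE001 - candidate failures are data
                logger.warning("candidate %s failed: %s", cand, exc)
                objectives.append(float("-inf"))
        best_idx = int(np.argmax(objectives))
        if objectives[best_idx] > incumbent_obj:
            incumbent = candidates[best_idx]
            incumbent_obj = objectives[best_idx]
        history.iterations.append(
            SearchIteration(
                seed=iter_seed,
                candidates=candidates,
                objectives=objectives,
                incumbent=incumbent,
                incumbent_objective=incumbent_obj,
            )
        )
        logger.info(
            "iteration %d/%d: incumbent %s objective %.4f",
            it + 1,
            iterations,
            incumbent,
            incumbent_obj,
        )
    return incumbent, history


def qsar_objective(
    datasets: list[ActivityDataset],
    template: GCNNConfig,
    fractions: tuple[float, float, float] = (0.7, 0.8, 0.9),
):
    """Objective: mean validation-slice AUC across datasets.

    For each dataset, trains on the earliest 70% with the candidate's L2 and
    conv sizes (everything else from the template) and scores the 70-80%
    validation slice. Datasets that fail (e.g. a single-class slice) are
    skipped with a log message.
    """
    if not datasets:
        raise ValueError("qsar_objective needs at least one dataset")
    splits = [chronological_split(ds, fractions) for ds in datasets]

    def objective(vec: HyperVector) -> float:
        aucs = []
        for ds, split in zip(datasets, splits):
            try:
                cfg = replace(template, l2=vec.l2, conv_sizes=vec.conv_sizes)
                train = ds.subset(list(split.train_ids))
                model = GraphConvClassifier.from_config(cfg)
                model.fit(train.df["smiles"].tolist(), train.df["label"].to_numpy())
                val = ds.subset(list(split.validation_ids))
                scores = model.predict_proba(val.df["smiles"].tolist())[:, 1]
                aucs.append(auroc(val.df["label"].to_numpy(), scores))
            except ValueError as exc:
                logger.warning("dataset skipped in objective: %s", exc)
        if not aucs:
            raise RuntimeError("every dataset failed in the objective")
        return float(np.mean(aucs))

    return objective


def retrain_final(
    dataset: ActivityDataset,
    best: HyperVector,
    template: GCNNConfig,
    fractions: tuple[float, float, float] = (0.7, 0.8, 0.9),
    retrain_on_full_train: bool = True,
) -> GraphConvClassifier:
    """Fit the final model with the best vector before test evaluation.

    By default retrains on the full earliest-80% training slice; with
    ``retrain_on_full_train=False`` keeps the hyperopt-era 70% slice.
    """
    split = chronological_split(dataset, fractions)
    ids = split.final_train_ids if retrain_on_full_train else split.train_ids
    train = dataset.subset(list(ids))
    cfg = replace(template, l2=best.l2, conv_sizes=best.conv_sizes)
    model = GraphConvClassifier.from_config(cfg)
    return model.fit(train.df["smiles"].tolist(), train.df["label"].to_numpy())
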