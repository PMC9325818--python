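"""Activity datasets, chronological splits, and similarity diagnostics.

A chronological split orders records by deposition date and cuts at fixed
date-rank fractions: the earliest 70% train the model during hyperparameter
search, the 70-80% slice validates it, and the latest 20% — further divided
into an "early" (80-90%) and "late" (90-100%) slice — is the held-out test
set. Final models retrain on the full earliest 80%. Splitting by time rather
than at random drives train/test molecular similarity down, which is the
point: it emulates predicting activity for future compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from salqsar import chem

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "smiles", "label", "date")


@dataclass
class ActivityDataset:
    """Ordered activity records (id, SMILES, binary label, deposition date)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        if self.df["id"].duplicated().any():
            dupes = self.df.loc[self.df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate ids in dataset: {dupes[:5]}")
        bad = ~self.df["label"].isin([0, 1])
        if bad.any():
            raise ValueError(
                f"non-binary labels for ids: {self.df.loc[bad, 'id'].tolist()[:5]}"
            )
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    def subset(self, ids: list[str]) -> "ActivityDataset":
        """Rows for the given ids, in the given order."""
        sub = self.df.set_index("id").loc[ids].reset_index()
        return ActivityDataset(sub)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "ActivityDataset":
        """Read a dataset table (CSV, or TSV when the file ends in .tsv).

        Requires columns id, smiles, label, date (ISO-8601 dates).
        """
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, dtype={"id": str})
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        parsed = pd.to_datetime(df["date"], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            raise ValueError(
                f"{path}: unparseable dates for ids {df.loc[bad, 'id'].tolist()[:5]}"
            )
        df["date"] = parsed
        df["label"] = df["label"].astype(int)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class SplitResult:
    """Chronological partition of a dataset into four ordered id lists."""

    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    test_early_ids: tuple[str, ...]
    test_late_ids: tuple[str, ...]
    boundaries: tuple[float, float, float]

    @property
    def final_train_ids(self) -> tuple[str, ...]:
        """Training ids for final models: train + validation (earliest 80%)."""
        return self.train_ids + self.validation_ids

    @property
    def test_ids(self) -> tuple[str, ...]:
        """Full held-out test set (latest 20%)."""
        return self.test_early_ids + self.test_late_ids

    @property
    def all_ids(self) -> tuple[str, ...]:
        return (
            self.train_ids
            + self.validation_ids
            + self.test_early_ids
            + self.test_late_ids
        )


def chronological_split(
    dataset: ActivityDataset, fractions: tuple[float, float, float] = (0.7, 0.8, 0.9)
) -> SplitResult:
    """Split a dataset by date rank at the given cumulative fractions.

    Records are stably sorted by (date, id) — ties in date fall back to
    lexicographic id — and cut at ``floor(f * N)``. With the default
    fractions the slices are train (0-70%), validation (70-80%), early test
    (80-90%) and late test (90-100%).
    """
    if len(dataset) < 5:
        raise ValueError("chronological_split needs at least 5 records")
    df = dataset.df
    if df["date"].isna().any():
        bad = df.loc[df["date"].isna(), "id"].tolist()
        raise ValueError(f"records with missing dates: {bad}")
    order = df.sort_values(["date", "id"], kind="mergesort")
    ids = order["id"].tolist()
    n = len(ids)
    f1, f2, f3 = fractions
    if not 0 < f1 < f2 < f3 < 1:
        raise ValueError(f"fractions must be increasing in (0,1): {fractions}")
    c1, c2, c3 = (int(np.floor(f * n)) for f in fractions)
    train_smiles = set(order["smiles"].iloc[:c2])
    test_smiles = set(order["smiles"].iloc[c2:])
    shared = train_smiles & test_smiles
    if shared:
        logger.warning(
            "%d SMILES appear on both sides of the train/test boundary "
            "(kept, not deduplicated)",
            len(shared),
        )
    return SplitResult(
        train_ids=tuple(ids[:c1]),
        validation_ids=tuple(ids[c1:c2]),
        test_early_ids=tuple(ids[c2:c3]),
        test_late_ids=tuple(ids[c3:]),
        boundaries=fractions,
    )


def _fp_matrix(fps: list[chem.BitFingerprint]) -> np.ndarray:
    n_bits = fps[0].n_bits
    mat = np.zeros((len(fps), n_bits), dtype=np.float32)
    for i, fp in enumerate(fps):
        if fp.n_bits != n_bits:
            raise ValueError("fingerprints have mismatched lengths")
        mat[i, list(fp.bits)] = 1.0
    return mat


def mean_nn_similarity(
    set_a: list[chem.BitFingerprint],
    set_b: list[chem.BitFingerprint],
    exclude_self: bool = False,
) -> float:
    """Mean nearest-neighbor Tanimoto similarity of set_a against set_b.

    For each fingerprint in ``set_a``, take the maximum Tanimoto similarity
    to any member of ``set_b`` (with ``exclude_self``, skip the same record
    position when the two lists are the same length — used for self
    comparisons), then average.
    """
    if not set_a or not set_b:
        raise ValueError("mean_nn_similarity requires non-empty sets")
    if exclude_self and len(set_a) < 2:
        raise ValueError("exclude_self requires at least 2 members")
    a = _fp_matrix(set_a)
    b = _fp_matrix(set_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("fingerprints have mismatched lengths")
    inter = a @ b.T
    pop_a = a.sum(axis=1)[:, None]
    pop_b = b.sum(axis=1)[None, :]
    union = pop_a + pop_b - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-12), 1.0)
    if exclude_self:
        np.fill_diagonal(sim, -1.0)
    return float(sim.max(axis=1).mean())


def similarity_report(
    dataset: ActivityDataset,
    split: SplitResult,
    n_bits: int = 2048,
) -> pd.DataFrame:
    """Mean nearest-neighbor Tanimoto similarity table for a split.

    Rows: train-train and test-test self comparisons (self-excluded),
    train-test, and each test time slice (validation, early, late) against
    the train set. "Train" here is the earliest 70% and "test" the remaining
    30%, i.e. the slices diagnosed are the ones the split actually holds out.
    """
    fps = {
        rec_id: chem.ecfp4(chem.parse_smiles(smi), n_bits=n_bits)
        for rec_id, smi in zip(dataset.df["id"], dataset.df["smiles"])
    }
    grp = {
        "train": [fps[i] for i in split.train_ids],
        "validation": [fps[i] for i in split.validation_ids],
        "test_early": [fps[i] for i in split.test_early_ids],
        "test_late": [fps[i] for i in split.test_late_ids],
    }
    test = grp["validation"] + grp["test_early"] + grp["test_late"]
    rows = [
        ("train-train", mean_nn_similarity(grp["train"], grp["train"], True)),
        ("test-test", mean_nn_similarity(test, test, True)),
        ("train-test", mean_nn_similarity(test, grp["train"], False)),
        ("validation-train", mean_nn_similarity(grp["validation"], grp["train"], False)),
        ("test_early-train", mean_nn_similarity(grp["test_early"], grp["train"], False)),
        ("test_late-train", mean_nn_similarity(grp["test_late"], grp["train"], False)),
    ]
    report = pd.DataFrame(rows, columns=["comparison", "mean_nn_tanimoto"])
    logger.info("similarity report:\n%s", report.to_string(index=False))
    return report
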