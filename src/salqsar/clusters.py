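"""Confusion-quadrant partitioning and substructure clustering.

Test molecules are split into the four confusion-matrix quadrants by label
l and model softmax output o (TP: l=1, o>0.5; FP: l=0, o>0.5; TN: l=0,
o<0.5; FN: l=1, o<0.5; the o=0.5 boundary counts as predicted-negative).
Each quadrant's salient fragments — fragment SMILES of the selected
neighborhoods, converted to ECFP4 — are clustered with density peak
clustering (DPC, the Rodriguez–Laio procedure on Jaccard distances), with a
minimal k-means (k=2) fallback when the data are too sparse for densities
to be computed. Clusters are ranked by population, high to low.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from salqsar import chem
from salqsar.data import ActivityDataset
from salqsar.gcnn import GraphConvClassifier
from salqsar.saliency import SalientNeighborhood, explain

logger = logging.getLogger(__name__)

MIN_POINTS_FOR_DPC = 8


class QuadrantLabel(str, enum.Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"


def assign_quadrant(label: int, output: float) -> QuadrantLabel:
    """Confusion quadrant for a (reference label, softmax output) pair.

    ``output == 0.5`` exactly is treated as a negative prediction.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    predicted_active = output > 0.5
    if label == 1:
        return QuadrantLabel.TP if predicted_active else QuadrantLabel.FN
    return QuadrantLabel.FP if predicted_active else QuadrantLabel.TN


@dataclass(frozen=True)
class DPCResult:
    """Cluster assignments plus the per-point DPC statistics."""

    assignments: tuple[int, ...]
    centers: tuple[int, ...]
    rho: tuple[float, ...]
    delta: tuple[float, ...]
    gamma: tuple[float, ...]


def _distance_matrix(fps: list[chem.BitFingerprint]) -> np.ndarray:
    n = len(fps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - chem.tanimoto(fps[i], fps[j])
    return d


def default_dc(distances: np.ndarray, percentile: float = 2.0) -> float:
    """Cutoff distance heuristic: the Rodriguez-Laio 1-2% neighbor rule.

    Takes a low percentile of the strictly positive pairwise distances so
    each point has on the order of ``percentile`` percent of the data as
    neighbors. Zero distances (duplicate fingerprints) are excluded from
    the percentile, otherwise tight duplicate groups would drag the cutoff
    to zero.
    """
    n = distances.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = distances[iu]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 0.5
    return float(np.percentile(vals, percentile))


def dpc_cluster(
    fingerprints: list[chem.BitFingerprint],
    d_c: float | None = None,
    n_centers: int | None = None,
    d_c_percentile: float = 2.0,
) -> DPCResult:
    """Density peak clustering on 1 - Tanimoto distances.

    Rodriguez–Laio statistics: rho_i counts neighbors closer than ``d_c``;
    delta_i is the distance to the nearest higher-density point (the global
    maximum distance for the densest point); gamma_i = rho_i * delta_i.
    Cluster centers are the points above the largest relative gap in the
    sorted gamma sequence (or exactly ``n_centers`` when given); every other
    point joins the cluster of its nearest higher-density neighbor.
    """
    n = len(fingerprints)
    if n == 0:
        raise ValueError("dpc_cluster requires at least one fingerprint")
    if n == 1:
        return DPCResult((0,), (0,), (0.0,), (0.0,), (0.0,))
    dist = _distance_matrix(fingerprints)
    if d_c is None:
        d_c = default_dc(dist, percentile=d_c_percentile)
    rho = (dist < d_c).sum(axis=1).astype(float) - 1.0  # exclude self
    # deterministic ordering: by density desc, index asc
    order = sorted(range(n), key=lambda i: (-rho[i], i))
    delta = np.zeros(n)
    nearest_higher = np.full(n, -1, dtype=int)
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = dist[i].max()
            continue
        higher = order[:pos]
        dists_to_higher = dist[i, higher]
        best = int(np.argmin(dists_to_higher))
        delta[i] = float(dists_to_higher[best])
        nearest_higher[i] = higher[best]
    gamma = rho * delta
    if np.allclose(gamma, gamma[0]):
        # degenerate (e.g. all points identical): a single cluster
        centers = [order[0]]
    elif n_centers is not None:
        by_gamma = sorted(range(n), key=lambda i: (-gamma[i], i))
        centers = sorted(by_gamma[: max(1, n_centers)])
    else:
        centers = _centers_by_gamma_gap(gamma)
    assignments = np.full(n, -1, dtype=int)
    center_ids = {c: k for k, c in enumerate(sorted(centers))}
    for c, k in center_ids.items():
        assignments[c] = k
    for i in order:  # descending density: parents are assigned first
        if assignments[i] == -1:
            assignments[i] = assignments[nearest_higher[i]]
    return DPCResult(
        assignments=tuple(int(a) for a in assignments),
        centers=tuple(sorted(center_ids)),
        rho=tuple(rho),
        delta=tuple(delta),
        gamma=tuple(gamma),
    )


def _centers_by_gamma_gap(gamma: np.ndarray) -> list[int]:
    """Centers = points above the largest relative gap in sorted gamma.

    The search is confined to the top ceil(sqrt(n)) positions: near the tail
    gamma approaches zero and relative gaps there are spuriously large,
    which would shatter the data into singletons.
    """
    n = len(gamma)
    by_gamma = sorted(range(n), key=lambda i: (-gamma[i], i))
    vals = gamma[by_gamma]
    max_centers = max(1, int(np.ceil(np.sqrt(n))))
    best_gap, cut = -1.0, 1
    for k in range(1, min(n, max_centers + 1)):
        hi, lo = vals[k - 1], vals[k]
        gap = (hi - lo) / (abs(hi) + 1e-12)
        if gap > best_gap:
            best_gap, cut = gap, k
    return sorted(by_gamma[:cut])


def kmeans_fallback(
    fingerprints: list[chem.BitFingerprint], seed: int = 0, max_iter: int = 100
) -> tuple[int, ...]:
    """Minimal k-means (k=2) on fingerprints as 0/1 vectors.

    Farthest-pair initialization makes the result deterministic given the
    seed (the seed only breaks exact ties). Fewer than 2 points, or all
    points identical, degenerate to a single cluster (logged).
    """
    n = len(fingerprints)
    if n == 0:
        raise ValueError("kmeans_fallback requires at least one fingerprint")
    if n == 1:
        logger.info("k-means fallback: single point, single cluster")
        return (0,)
    n_bits = fingerprints[0].n_bits
    x = np.zeros((n, n_bits))
    for i, fp in enumerate(fingerprints):
        x[i, list(fp.bits)] = 1.0
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    if d2.max() == 0:
        logger.info("k-means fallback: all points identical, single cluster")
        return tuple([0] * n)
    i0, j0 = np.unravel_index(int(d2.argmax()), d2.shape)
    centers = np.stack([x[min(i0, j0)], x[max(i0, j0)]])
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist_to_centers = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist_to_centers.argmin(axis=1)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for k in range(2):
            if (labels == k).any():
                centers[k] = x[labels == k].mean(axis=0)
    return tuple(int(v) for v in labels)


@dataclass(frozen=True)
class SubstructureCluster:
    """Population-ranked group of salient fragments within one quadrant."""

    quadrant: QuadrantLabel
    members: tuple[tuple[str, SalientNeighborhood, chem.BitFingerprint], ...]
    rank: int

    @property
    def population(self) -> int:
        return len(self.members)


def quadrant_partition(
    dataset: ActivityDataset, model: GraphConvClassifier, ids: list[str]
) -> dict[QuadrantLabel, list[str]]:
    """Assign each test molecule id to its confusion quadrant."""
    sub = dataset.subset(ids)
    probs = model.predict_proba(sub.df["smiles"].tolist())[:, 1]
    out: dict[QuadrantLabel, list[str]] = {q: [] for q in QuadrantLabel}
    for rec_id, label, o in zip(sub.df["id"], sub.df["label"], probs):
        out[assign_quadrant(int(label), float(o))].append(rec_id)
    return out


def cluster_quadrant(
    dataset: ActivityDataset,
    model: GraphConvClassifier,
    quadrant: QuadrantLabel,
    test_ids: list[str],
    d_c: float | None = None,
    d_c_percentile: float = 2.0,
    k_max: int = 5,
    n_bits: int = 2048,
    min_points: int = MIN_POINTS_FOR_DPC,
    seed: int = 0,
) -> list[SubstructureCluster]:
    """Cluster the salient fragments of one confusion quadrant.

    Collects every selected neighborhood of the quadrant's molecules,
    fingerprints the fragment SMILES (ECFP4), and runs DPC; when fewer than
    ``min_points`` fragments exist or every density is zero at the chosen
    cutoff, falls back to k-means (k=2). Returns clusters ranked by
    population descending, ties broken by smallest member id.
    """
    quadrants = quadrant_partition(dataset, model, test_ids)
    members_ids = quadrants[quadrant]
    if not members_ids:
        logger.info("quadrant %s is empty; no clusters", quadrant.value)
        return []
    items: list[tuple[str, SalientNeighborhood, chem.BitFingerprint]] = []
    sub = dataset.subset(members_ids)
    for rec_id, smi in zip(sub.df["id"], sub.df["smiles"]):
        graph = chem.parse_smiles(smi)
        for nbh in explain(graph, model, k_max=k_max):
            frag_fp = chem.fragment_fingerprint(nbh.neighborhood.fragment_smiles, n_bits)
            items.append((rec_id, nbh, frag_fp))
    if not items:
        logger.info("quadrant %s produced no salient fragments", quadrant.value)
        return []
    fps = [fp for _, _, fp in items]
    use_fallback = len(fps) < min_points
    if not use_fallback:
        result = dpc_cluster(fps, d_c=d_c, d_c_percentile=d_c_percentile)
        if max(result.rho) <= 0:
            logger.info(
                "densities all zero at d_c; reverting to k-means fallback"
            )
            use_fallback = True
        else:
            labels = result.assignments
    if use_fallback:
        logger.info("quadrant %s: sparse data, k-means (k=2) fallback", quadrant.value)
        labels = kmeans_fallback(fps, seed=seed)
    groups: dict[int, list[tuple[str, SalientNeighborhood, chem.BitFingerprint]]] = {}
    for item, lab in zip(items, labels):
        groups.setdefault(lab, []).append(item)
    ordered = sorted(
        groups.values(), key=lambda g: (-len(g), min(m[0] for m in g))
    )
    return [
        SubstructureCluster(quadrant=quadrant, members=tuple(g), rank=r + 1)
        for r, g in enumerate(ordered)
    ]


def clusters_to_json(clusters: list[SubstructureCluster]) -> dict:
    """JSON-serializable view: quadrant -> clusters -> members."""
    out: dict[str, list] = {}
    for cl in clusters:
        out.setdefault(cl.quadrant.value, []).append(
            {
                "rank": cl.rank,
                "population": cl.population,
                "members": [
                    {
                        "molecule_id": mol_id,
                        "center": nbh.center,
                        "fragment_smiles": nbh.neighborhood.fragment_smiles,
                        "score": nbh.score,
                    }
                    for mol_id, nbh, _ in cl.members
                ],
            }
        )
    return out
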