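"""Rank salient atomic neighborhoods from a saliency tensor.

Each of the 128 fingerprint components is "won" by the atom whose saliency
row carries the largest amplitude in that column (columns that are exactly
zero everywhere carry no evidence and are skipped). Atoms are then scored by

    score(a) = frequency(a) * softmax_over_winning_atoms(mean winning amplitude)(a)

— a frequency-weighted amplitude modulated by a standard softmax — and the
top-k (default 5) atoms, materialized as their radius-3 bonded
neighborhoods, are the molecule's salient neighborhoods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from salqsar.chem import MolecularGraph, Neighborhood, atom_neighborhood
from salqsar.gcnn import GraphConvClassifier, SaliencyTensor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SalientNeighborhood:
    """One ranked salient atomic neighborhood.

    ``frequency`` counts the fingerprint columns this atom won; ``amplitude``
    is the mean of its winning amplitudes; ``score`` the softmax-modulated
    frequency-weighted value used for ranking (1-based ``rank``).
    """

    center: int
    neighborhood: Neighborhood | None
    frequency: int
    amplitude: float
    score: float
    rank: int


def rank_neighborhoods(
    tensor: SaliencyTensor, top_m: int = 1
) -> list[SalientNeighborhood]:
    """Rank candidate salient atoms from a saliency tensor.

    Per column, the ``top_m`` highest-amplitude atoms (default 1, i.e. the
    column argmax) register a win with their amplitude. Ties in score break
    toward the lower atom index. Returns candidates sorted by descending
    score with contiguous 1-based ranks; an all-zero tensor yields an empty
    list (an untrained or dead encoder produces no evidence).
    """
    values = tensor.values
    if values.ndim != 2:
        raise ValueError("saliency tensor must be a 2-D matrix")
    n_atom = values.shape[0]
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    wins: dict[int, list[float]] = {}
    nonzero_cols = np.flatnonzero(values.max(axis=0) > 0)
    for j in nonzero_cols:
        col = values[:, j]
        if top_m == 1:
            winners = [int(col.argmax())]
        else:
            order = np.argsort(-col, kind="stable")[:top_m]
            winners = [int(a) for a in order if col[a] > 0]
        for a in winners:
            wins.setdefault(a, []).append(float(col[a]))
    if not wins:
        logger.info("all-zero saliency tensor: no salient neighborhoods")
        return []
    atoms = sorted(wins)
    freqs = np.array([len(wins[a]) for a in atoms], dtype=float)
    amps = np.array([float(np.mean(wins[a])) for a in atoms])
    shifted = amps - amps.max()
    softmax = np.exp(shifted) / np.exp(shifted).sum()
    scores = freqs * softmax
    order = sorted(range(len(atoms)), key=lambda i: (-scores[i], atoms[i]))
    return [
        SalientNeighborhood(
            center=atoms[i],
            neighborhood=None,
            frequency=int(freqs[i]),
            amplitude=float(amps[i]),
            score=float(scores[i]),
            rank=rank + 1,
        )
        for rank, i in enumerate(order)
    ]


def select_salient(
    candidates: list[SalientNeighborhood],
    graph: MolecularGraph,
    k_max: int = 5,
    radius: int = 3,
) -> list[SalientNeighborhood]:
    """Keep the top ``min(k_max, len(candidates))`` neighborhoods.

    Materializes each survivor's radius-3 neighborhood (members + canonical
    fragment SMILES). An empty candidate list returns an empty list.
    """
    if not candidates:
        logger.info("no salient neighborhood candidates to select")
        return []
    selected = []
    for cand in candidates[:k_max]:
        nbh = atom_neighborhood(graph, cand.center, radius=radius)
        selected.append(
            SalientNeighborhood(
                center=cand.center,
                neighborhood=nbh,
                frequency=cand.frequency,
                amplitude=cand.amplitude,
                score=cand.score,
                rank=cand.rank,
            )
        )
    return selected


def explain(
    graph: MolecularGraph,
    model: GraphConvClassifier,
    k_max: int = 5,
    top_m: int = 1,
    radius: int = 3,
) -> list[SalientNeighborhood]:
    """Encode, rank and select: the full saliency procedure for one molecule."""
    tensor, _ = model.encode(graph)
    candidates = rank_neighborhoods(tensor, top_m=top_m)
    return select_salient(candidates, graph, k_max=k_max, radius=radius)


def explanation_record(
    molecule_id: str,
    graph: MolecularGraph,
    model: GraphConvClassifier,
    k_max: int = 5,
    top_m: int = 1,
) -> dict:
    """JSON-serializable explanation for one molecule."""
    neighborhoods = explain(graph, model, k_max=k_max, top_m=top_m)
    return {
        "molecule_id": molecule_id,
        "smiles": graph.smiles,
        "prediction": model.predict_one(graph),
        "neighborhoods": [
            {
                "rank": nb.rank,
                "center": nb.center,
                "member_atoms": sorted(nb.neighborhood.members),
                "fragment_smiles": nb.neighborhood.fragment_smiles,
                "frequency": nb.frequency,
                "amplitude": nb.amplitude,
                "score": nb.score,
            }
            for nb in neighborhoods
        ],
    }


def write_explanations(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
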