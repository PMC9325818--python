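"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reference to the package's
own implementations: plain loops, no shared helpers, so each oracle is an
independent re-derivation of the quantity it checks.
"""

from __future__ import annotations

import zlib
from collections import deque

import numpy as np


def brute_force_auroc(labels, scores) -> float:
    """Pairwise-counting AUROC: wins + half-ties over all pos/neg pairs."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_salient_ranking(values: np.ndarray):
    """Enumerate every column's argmax and recompute scores independently.

    Returns a list of (atom, frequency, amplitude, score) sorted by score
    descending with lower atom index breaking ties.
    """
    n_atom, n_cols = values.shape
    won: dict[int, list[float]] = {}
    for j in range(n_cols):
        col = values[:, j]
        if max(col) <= 0:
            continue
        best_atom = 0
        for i in range(1, n_atom):
            if col[i] > col[best_atom]:
                best_atom = i
        won.setdefault(best_atom, []).append(float(col[best_atom]))
    if not won:
        return []
    atoms = sorted(won)
    amps = [sum(won[a]) / len(won[a]) for a in atoms]
    mx = max(amps)
    exps = [np.exp(a - mx) for a in amps]
    z = sum(exps)
    rows = [
        (a, len(won[a]), amp, len(won[a]) * e / z)
        for a, amp, e in zip(atoms, amps, exps)
    ]
    rows.sort(key=lambda r: (-r[3], r[0]))
    return rows


def brute_force_dpc(dist: np.ndarray, d_c: float):
    """Independent O(n^2) re-derivation of the density-peak statistics.

    Returns (rho, delta, gamma, nearest_higher) where nearest_higher[i] is
    the closest point of strictly higher density (density ties broken by
    lower index counting as "higher"), or -1 for the top point.
    """
    n = dist.shape[0]
    rho = []
    for i in range(n):
        count = 0
        for j in range(n):
            if j != i and dist[i, j] < d_c:
                count += 1
        rho.append(float(count))
    order = sorted(range(n), key=lambda i: (-rho[i], i))
    delta = [0.0] * n
    nearest = [-1] * n
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = max(dist[i, j] for j in range(n))
            continue
        best_j, best_d = None, None
        for j in order[:pos]:
            if best_d is None or dist[i, j] < best_d:
                best_d, best_j = dist[i, j], j
        delta[i] = best_d
        nearest[i] = best_j
    gamma = [r * d for r, d in zip(rho, delta)]
    return rho, delta, gamma, nearest


def bfs_ball(n_atoms: int, edges, center: int, radius: int) -> set[int]:
    """Graph-library BFS ball, independent of the package's BFS."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n_atoms))
    g.add_edges_from(edges)
    lengths = nx.single_source_shortest_path_length(g, center, cutoff=radius)
    return set(lengths)


def morgan_identifier_count(smiles: str, radius: int = 2) -> int:
    """Independent Morgan identifier loop with environment deduplication.

    Counts the distinct circular-environment identifiers of a molecule up to
    the given radius, dropping environments whose bond set duplicates one
    already seen (the standard collision rule). With a collision-free hash
    this equals the popcount of the hashed binary fingerprint.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)

    def h(obj) -> int:
        return zlib.crc32(repr(obj).encode())

    def env_bonds(center: int, rad: int) -> frozenset[int]:
        if rad == 0:
            return frozenset()
        dists = {center: 0}
        queue = deque([center])
        bonds = set()
        while queue:
            u = queue.popleft()
            if dists[u] >= rad:
                continue
            for b in mol.GetAtomWithIdx(u).GetBonds():
                v = b.GetOtherAtomIdx(u)
                bonds.add(b.GetIdx())
                if v not in dists:
                    dists[v] = dists[u] + 1
                    queue.append(v)
        return frozenset(bonds)

    cur = {}
    for a in mol.GetAtoms():
        cur[a.GetIdx()] = h(
            (
                a.GetAtomicNum(),
                a.GetDegree(),
                a.GetTotalNumHs(),
                a.GetFormalCharge(),
                int(a.IsInRing()),
            )
        )
    idents = set(cur.values())
    seen_envs: set[frozenset[int]] = set()
    prev_env = {a.GetIdx(): frozenset() for a in mol.GetAtoms()}
    for r in range(1, radius + 1):
        nxt = {}
        for a in mol.GetAtoms():
            i = a.GetIdx()
            nbr = sorted(
                (int(b.GetBondTypeAsDouble() * 10), cur[b.GetOtherAtomIdx(i)])
                for b in a.GetBonds()
            )
            nxt[i] = h((r, cur[i], tuple(nbr)))
        round_envs: dict[frozenset[int], int] = {}
        for i in sorted(nxt, key=lambda i: nxt[i]):
            env = env_bonds(i, r)
            if env == prev_env[i]:
                continue
            if env in seen_envs or env in round_envs:
                continue
            round_envs[env] = nxt[i]
        seen_envs |= set(round_envs)
        idents |= set(round_envs.values())
        prev_env = {i: env_bonds(i, r) for i in nxt}
        cur = nxt
    return len(idents)
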