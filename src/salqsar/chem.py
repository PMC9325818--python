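"""Molecular graphs, circular fingerprints, similarity and bonded neighborhoods.

SMILES parsing and fingerprinting are delegated to RDKit; this module fixes
the conventions the rest of the package relies on:

* heavy-atom graphs only, hydrogens implicit;
* atom indices are canonicalized at parse time and stay stable for the life
  of a :class:`MolecularGraph`, so saliency rows map back to atoms;
* ECFP4 = Morgan radius 2, hashed to ``n_bits`` binary bits (default 2048);
* atomic neighborhoods are BFS balls of bond distance <= radius (default 3),
  serialized as canonical fragment SMILES.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

INFINITE_DISTANCE = math.inf

_morgan_generators: dict[int, object] = {}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""


@dataclass(frozen=True)
class AtomInfo:
    """Per-atom attributes used for featurization."""

    element: str
    formal_charge: int
    aromatic: bool
    implicit_h: int
    in_ring: bool
    degree: int


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with stable, canonicalized atom indexing.

    Attributes
    ----------
    atoms : list of AtomInfo
        Atom attributes, indexed 0..n_atom-1.
    bonds : list of (int, int, float)
        Undirected bonds (i, j, bond order) with i < j.
    mol : rdkit.Chem.Mol
        The underlying RDKit molecule, atom order matching ``atoms``.
    """

    atoms: list[AtomInfo]
    bonds: list[tuple[int, int, float]]
    mol: Chem.Mol
    smiles: str
    _neighbors: list[list[int]] = field(default_factory=list, repr=False)

    @property
    def n_atom(self) -> int:
        return len(self.atoms)

    @property
    def neighbors(self) -> list[list[int]]:
        if not self._neighbors:
            nbrs: list[list[int]] = [[] for _ in range(self.n_atom)]
            for i, j, _ in self.bonds:
                nbrs[i].append(j)
                nbrs[j].append(i)
            self._neighbors = [sorted(v) for v in nbrs]
        return self._neighbors


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary fingerprint stored as a set of set-bit positions."""

    bits: frozenset[int]
    n_bits: int

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.n_bits for b in self.bits):
            raise ValueError("bit position outside [0, n_bits)")

    @property
    def popcount(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class Neighborhood:
    """Induced subgraph of all atoms within ``radius`` bonds of ``center``."""

    center: int
    radius: int
    members: frozenset[int]
    fragment_smiles: str


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Atom indices follow the order the atoms appear in the SMILES string and
    are fixed for the life of the graph, so saliency rows and neighborhood
    centers map straight back to the input. Hydrogens stay implicit.

    Raises
    ------
    SmilesParseError
        If the string is empty, unparsable, or violates valence rules.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"SMILES has no heavy atoms: {smiles!r}")
    return _graph_from_mol(mol, smiles)


def _graph_from_mol(mol: Chem.Mol, smiles: str | None = None) -> MolecularGraph:
    atoms = [
        AtomInfo(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            implicit_h=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
            degree=a.GetDegree(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        bonds.append((i, j, b.GetBondTypeAsDouble()))
    bonds.sort()
    return MolecularGraph(
        atoms=atoms,
        bonds=bonds,
        mol=mol,
        smiles=smiles if smiles is not None else Chem.MolToSmiles(mol),
    )


def from_rdkit(mol: Chem.Mol) -> MolecularGraph:
    """Wrap an existing RDKit molecule (e.g. from an SDF record) as a graph."""
    mol = Chem.Mol(mol)
    Chem.SanitizeMol(mol)
    return _graph_from_mol(mol)


def read_sdf(path: str) -> list[MolecularGraph]:
    """Read molecules from an SDF file, one graph per record (first block)."""
    supplier = Chem.SDMolSupplier(str(path))
    graphs = []
    for mol in supplier:
        if mol is not None:
            graphs.append(from_rdkit(mol))
    return graphs


def ecfp4(graph: MolecularGraph, n_bits: int = 2048) -> BitFingerprint:
    """Hashed radius-2 circular (ECFP4) fingerprint of a molecule.

    Deterministic and invariant to the atom ordering of the input SMILES.
    """
    gen = _morgan_generators.get(n_bits)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        _morgan_generators[n_bits] = gen
    fp = gen.GetFingerprint(graph.mol)
    return BitFingerprint(bits=frozenset(fp.GetOnBits()), n_bits=n_bits)


def ecfp4_from_smiles(smiles: str, n_bits: int = 2048) -> BitFingerprint:
    """Convenience: parse then fingerprint."""
    return ecfp4(parse_smiles(smiles), n_bits=n_bits)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto similarity |a & b| / |a | b|.

    Two empty fingerprints are treated as identical (returns 1.0) to avoid
    an undefined 0/0.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def bond_distance(graph: MolecularGraph, i: int, j: int) -> float:
    """Shortest path length in bonds between atoms i and j.

    Returns ``math.inf`` when the atoms lie in disconnected fragments.
    """
    n = graph.n_atom
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range: {i}, {j} (n_atom={n})")
    if i == j:
        return 0
    dists = _bfs_distances(graph, i, max_radius=None)
    return dists.get(j, INFINITE_DISTANCE)


def _bfs_distances(
    graph: MolecularGraph, source: int, max_radius: int | None
) -> dict[int, int]:
    dists = {source: 0}
    queue = deque([source])
    nbrs = graph.neighbors
    while queue:
        u = queue.popleft()
        if max_radius is not None and dists[u] >= max_radius:
            continue
        for v in nbrs[u]:
            if v not in dists:
                dists[v] = dists[u] + 1
                queue.append(v)
    return dists


def atom_neighborhood(
    graph: MolecularGraph, center: int, radius: int = 3
) -> Neighborhood:
    """All atoms within ``radius`` bonds of ``center``, as an induced subgraph.

    The fragment SMILES keeps every bond between member atoms and is written
    canonically without atom maps.
    """
    if not (0 <= center < graph.n_atom):
        raise IndexError(f"center {center} out of range (n_atom={graph.n_atom})")
    members = frozenset(_bfs_distances(graph, center, max_radius=radius))
    frag = fragment_smiles(graph, members)
    return Neighborhood(
        center=center, radius=radius, members=members, fragment_smiles=frag
    )


def fragment_smiles(graph: MolecularGraph, members: frozenset[int]) -> str:
    """Canonical SMILES of the subgraph induced by ``members``."""
    return Chem.MolFragmentToSmiles(
        graph.mol, atomsToUse=sorted(members), canonical=True
    )


def fragment_fingerprint(smiles: str, n_bits: int = 2048) -> BitFingerprint:
    """ECFP4 of a fragment SMILES, tolerating broken aromaticity.

    Fragments cut out of aromatic rings keep the parent's aromatic flags and
    may not survive full valence/kekulization sanitization; those are parsed
    leniently (kekulization skipped) before fingerprinting. Deterministic.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        if mol is None:
            raise SmilesParseError(f"unparsable fragment SMILES: {smiles!r}")
        Chem.SanitizeMol(
            mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
        )
        mol.UpdatePropertyCache(strict=False)
        Chem.GetSymmSSSR(mol)
    gen = _morgan_generators.get(n_bits)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        _morgan_generators[n_bits] = gen
    fp = gen.GetFingerprint(mol)
    return BitFingerprint(bits=frozenset(fp.GetOnBits()), n_bits=n_bits)
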