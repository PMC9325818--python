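"""Synthetic planted-motif chemistry: labeled, dated SMILES datasets.

Generates drug-like small molecules by fragment assembly — a ring scaffold
drawn from one of four scaffold families, decorated with small substituents
joined by single bonds — so every emitted SMILES is chemically valid by
construction. Actives receive an activity *motif* (default: a sulfonamide)
grafted at a random attachment point, which makes the true
structure-activity relationship known exactly and lets every downstream
stage (training, saliency, clustering) be validated against planted ground
truth.

Temporal structure emulates public bioactivity archives: deposition dates
span ten years, and both the scaffold-family and decoration sampling
weights are softmax functions of the date rank with soft per-family time
windows, so chronologically late molecules come from chemotypes
under-represented early on. ``drift`` controls how localized the windows
are; ``drift=0`` turns the shift off entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from rdkit import Chem

from salqsar.data import ActivityDataset

logger = logging.getLogger(__name__)

# Scaffold families (SMILES; attachment happens at free-valence C/N atoms).
# Families are ordered by the era they trend in: the drift schedule assigns
# each family a soft time window, so with drift > 0 chemotypes turn over as
# deposition dates advance — the way lead series succeed one another in
# public archives.
SCAFFOLD_FAMILIES: tuple[tuple[str, ...], ...] = (
    ("c1ccccc1", "Cc1ccccc1"),              # benzenoid
    ("c1ccc2ccccc2c1",),                    # naphthalene
    ("c1ccncc1", "c1cncnc1"),               # azine
    ("c1ccc2ncccc2c1",),                    # quinoline
    ("C1CCNCC1", "C1CNCCN1"),               # piperidine / piperazine
    ("C1COCCN1", "C1CCOCC1"),               # morpholine / oxane
    ("c1ccoc1", "c1ccsc1"),                 # 5-ring heteroaryl
    ("C1CCCCC1", "C1CCCC1"),                # saturated carbocycle
    ("c1cscn1", "c1cocn1"),                 # azole
)

# Window centers on the date-rank axis, one per family. Sampling weight is a
# softmax of -drift * ((u - c_f) / width)^2: flat at drift = 0, increasingly
# time-localized as drift grows. The last centers sit beyond the end of the
# date range so chemotype turnover keeps going through the latest slice
# instead of saturating.
_FAMILY_CENTERS = np.linspace(0.05, 1.15, len(SCAFFOLD_FAMILIES))
_FAMILY_WINDOW = 0.2

# Decorations: (SMILES, attachment atom index, carbon-only attachment flag).
# No fragment contains a sulfonamide or carboxyl group, so motif presence is
# controlled solely by the grafting step. The late-trending methylsulfone is
# a deliberate decoy: it shares circular-fingerprint environments with the
# default sulfonamide motif without matching it, the way novel late-era
# chemotypes confound models trained on earlier data. Its carbon-only flag
# prevents an N-S bond that would accidentally complete a sulfonamide.
DECORATIONS: tuple[tuple[str, int, bool], ...] = (
    ("C", 0, False),          # methyl
    ("CC", 0, False),         # ethyl
    ("CCC", 0, False),        # propyl
    ("CO", 0, False),         # hydroxymethyl
    ("COC", 0, False),        # methoxymethyl
    ("CC(=O)N", 0, False),    # acetamide tail (attached via alkyl C)
    ("NC(C)=O", 0, False),    # acetamido (attached via N)
    ("CN", 0, False),         # aminomethyl
    ("F", 0, False),
    ("Cl", 0, False),
    ("S(C)(=O)=O", 0, True),  # methylsulfone decoy (late era)
)

# Decoration windows on the date-rank axis: like scaffold families, the
# substituent palette drifts with deposition date, which smooths the
# train/test similarity decay that real archives show.
_DECORATION_CENTERS = np.linspace(0.05, 0.95, len(DECORATIONS))
_DECORATION_WINDOW = 0.25

DEFAULT_MOTIF = "S(=O)(=O)N"  # primary sulfonamide, grafted at the sulfur


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic activity dataset.

    Parameters
    ----------
    n : int
        Number of molecules (default 600, within the 71-7839 per-target
        range typical of curated public QSAR sets).
    motif : str
        Fragment SMILES grafted onto actives; its first atom is the
        attachment point.
    label_noise : float
        Probability of flipping each label, in [0, 0.5).
    drift : float
        Strength of the temporal scaffold-family shift; 0 disables drift.
    active_fraction : float
        Target prevalence of actives, in (0, 1).
    seed : int
        Seed for all randomness in the generator.
    """

    n: int = 600
    motif: str = DEFAULT_MOTIF
    label_noise: float = 0.0
    drift: float = 1.0
    active_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.active_fraction < 1:
            raise ValueError("active_fraction must be in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if Chem.MolFromSmiles(self.motif) is None:
            raise ValueError(f"motif does not parse: {self.motif!r}")


def _attachable_atoms(mol: Chem.Mol, carbon_only: bool = False) -> list[int]:
    """Indices of atoms that can accept one more single bond."""
    allowed = ("C",) if carbon_only else ("C", "N")
    out = []
    for a in mol.GetAtoms():
        if a.GetTotalNumHs() >= 1 and a.GetSymbol() in allowed:
            out.append(a.GetIdx())
    return out


def _attach(core: Chem.Mol, frag: Chem.Mol, core_idx: int, frag_idx: int) -> Chem.Mol:
    """Join two molecules with a single bond; returns the sanitized combo."""
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    combo.AddBond(core_idx, core.GetNumAtoms() + frag_idx, Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _family_weights(u: float, drift: float) -> np.ndarray:
    logits = -drift * ((u - _FAMILY_CENTERS) / _FAMILY_WINDOW) ** 2
    w = np.exp(logits - logits.max())
    return w / w.sum()


def _decoration_weights(u: float, drift: float) -> np.ndarray:
    logits = -drift * ((u - _DECORATION_CENTERS) / _DECORATION_WINDOW) ** 2
    w = np.exp(logits - logits.max())
    return w / w.sum()


def _assemble_molecule(
    rng: np.random.Generator, date_rank: float, drift: float, motif_mol: Chem.Mol | None
) -> str:
    """Build one molecule: scaffold + 2-4 decorations (+ motif if active)."""
    weights = _family_weights(date_rank, drift)
    dec_weights = _decoration_weights(date_rank, drift)
    # decoration count drifts upward with date rank (molecular-size
    # inflation): Binomial(2, p) extra substituents on top of a base of 2,
    # with p shifting from below to above 1/2 across the date range
    p_extra = float(np.clip(0.5 + 0.25 * drift * (date_rank - 0.5), 0.0, 1.0))
    while True:
        family = SCAFFOLD_FAMILIES[rng.choice(len(SCAFFOLD_FAMILIES), p=weights)]
        mol = Chem.MolFromSmiles(family[rng.integers(len(family))])
        n_dec = 2 + int(rng.binomial(2, p_extra))
        for _ in range(n_dec):
            dec_smiles, dec_idx, carbon_only = DECORATIONS[
                rng.choice(len(DECORATIONS), p=dec_weights)
            ]
            sites = _attachable_atoms(mol, carbon_only=carbon_only)
            if not sites:
                continue
            dec = Chem.MolFromSmiles(dec_smiles)
            mol = _attach(mol, dec, sites[rng.integers(len(sites))], dec_idx)
        if motif_mol is None:
            break
        sites = _attachable_atoms(mol)
        if sites:  # rare: a small, fully halogenated scaffold has no site left
            mol = _attach(mol, motif_mol, sites[rng.integers(len(sites))], 0)
            break
    return Chem.MolToSmiles(mol)


def generate_dataset(spec: GeneratorSpec) -> ActivityDataset:
    """Generate a labeled, dated activity dataset with a planted motif.

    With ``label_noise == 0`` the label equals motif presence exactly; noisy
    labels flip independently with the configured probability. Dates are
    uniform over a ten-year window, and with ``drift > 0`` the scaffold-family
    mixture shifts with date rank. Deterministic given ``spec.seed``.
    """
    return _generate(spec, motifs=(spec.motif,))


def two_motif_dataset(spec: GeneratorSpec, motif_b: str) -> ActivityDataset:
    """Variant with actives split evenly between ``spec.motif`` and ``motif_b``.

    Used to exercise substructure-cluster separation: each active contains
    exactly one of the two motifs. The motifs must be mutually
    non-substructures.
    """
    mol_a = Chem.MolFromSmiles(spec.motif)
    mol_b = Chem.MolFromSmiles(motif_b)
    if mol_b is None:
        raise ValueError(f"motif does not parse: {motif_b!r}")
    if mol_a.HasSubstructMatch(mol_b) or mol_b.HasSubstructMatch(mol_a):
        raise ValueError("motifs must be mutually non-substructures")
    return _generate(spec, motifs=(spec.motif, motif_b))


def _graft_unit(motif: str) -> Chem.Mol:
    """The fragment actually grafted onto actives: ethyl linker + motif.

    Pharmacophoric groups usually hang off a scaffold through a short
    linker rather than fusing into it; the linker also keeps the motif's
    local (radius-3) environment consistent across actives, which is what
    lets salient fragments of one motif family resemble each other.
    """
    linker = Chem.MolFromSmiles("CC")
    return _attach(linker, Chem.MolFromSmiles(motif), 1, 0)


def _generate(spec: GeneratorSpec, motifs: tuple[str, ...]) -> ActivityDataset:
    rng = np.random.default_rng(spec.seed)
    motif_mols = [_graft_unit(m) for m in motifs]
    date_ranks = rng.uniform(0.0, 1.0, size=spec.n)
    active = rng.uniform(size=spec.n) < spec.active_fraction
    flips = rng.uniform(size=spec.n) < spec.label_noise
    start = pd.Timestamp("2008-01-01")
    span_days = 3652  # ten years

    rows = []
    active_count = 0
    for i in range(spec.n):
        motif_mol = None
        if active[i]:
            motif_mol = motif_mols[active_count % len(motif_mols)]
            active_count += 1
        smiles = _assemble_molecule(rng, float(date_ranks[i]), spec.drift, motif_mol)
        label = int(active[i]) ^ int(flips[i])
        date = (start + pd.Timedelta(days=round(date_ranks[i] * span_days))).date()
        rows.append((f"M{i:05d}", smiles, label, date))

    df = pd.DataFrame(rows, columns=["id", "smiles", "label", "date"])
    df["date"] = pd.to_datetime(df["date"])
    return ActivityDataset(df)


def motif_atoms(smiles: str, motif: str) -> tuple[int, ...]:
    """Atom indices (in canonical parse order) matching ``motif`` in ``smiles``.

    Empty when the motif is absent. Uses the first substructure match.
    """
    from salqsar.chem import parse_smiles

    graph = parse_smiles(smiles)
    query = Chem.MolFromSmiles(motif)
    match = graph.mol.GetSubstructMatch(query)
    return tuple(match)


def has_motif(smiles: str, motif: str) -> bool:
    """Whether ``motif`` occurs as a substructure of ``smiles``."""
    mol = Chem.MolFromSmiles(smiles)
    query = Chem.MolFromSmiles(motif)
    return mol.HasSubstructMatch(query)


def with_seed(spec: GeneratorSpec, seed: int) -> GeneratorSpec:
    """Copy of ``spec`` with a different seed (convenience for replicates)."""
    return replace(spec, seed=seed)
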