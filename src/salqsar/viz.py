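"""Atom highlight maps and 2-D depictions of salient neighborhoods.

A selected neighborhood with center c and score s contributes
``s * decay**d(c, a)`` to every atom a within 3 bonds of c (and nothing
beyond); overlapping neighborhoods simply sum. The default decay factor is
0.8 per bond. Color is presentation-only: amplitudes are normalized to the
maximum at render time and drawn as a single-hue orange ramp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit.Chem.Draw import rdMolDraw2D

from salqsar.chem import MolecularGraph, _bfs_distances
from salqsar.saliency import SalientNeighborhood

logger = logging.getLogger(__name__)

MAX_HIGHLIGHT_BONDS = 3
ORANGE = (1.0, 0.6, 0.1)


@dataclass(frozen=True)
class HighlightMap:
    """Per-atom non-negative highlight amplitudes for one molecule."""

    amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("highlight amplitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.amplitudes)


def highlight_amplitudes(
    graph: MolecularGraph,
    neighborhoods: list[SalientNeighborhood],
    decay: float = 0.8,
    mode: str = "multiplicative",
) -> HighlightMap:
    """Superpose per-neighborhood decaying highlights into one map.

    ``mode="multiplicative"`` (default) applies ``decay**d`` per bond;
    ``mode="additive"`` applies the alternative linear ramp
    ``max(0, 1 - (1 - decay) * d)``. Both are cut off beyond 3 bonds.
    """
    if not 0 < decay <= 1:
        raise ValueError("decay must be in (0, 1]")
    if mode not in ("multiplicative", "additive"):
        raise ValueError(f"unknown decay mode: {mode!r}")
    amps = np.zeros(graph.n_atom)
    for nbh in neighborhoods:
        if not 0 <= nbh.center < graph.n_atom:
            raise IndexError(
                f"neighborhood center {nbh.center} not in molecule "
                f"(n_atom={graph.n_atom})"
            )
        dists = _bfs_distances(graph, nbh.center, max_radius=MAX_HIGHLIGHT_BONDS)
        for atom, d in dists.items():
            if mode == "multiplicative":
                amps[atom] += nbh.score * decay**d
            else:
                amps[atom] += nbh.score * max(0.0, 1.0 - (1.0 - decay) * d)
    return HighlightMap(amplitudes=tuple(float(a) for a in amps))


def render(
    graph: MolecularGraph,
    highlight: HighlightMap,
    out_path: str | Path,
    size: tuple[int, int] = (350, 300),
) -> Path:
    """Write a 2-D depiction with orange atom shading scaled to the max amplitude.

    The output format follows the file extension: ``.svg`` (preferred) or
    ``.png``.
    """
    if len(highlight) != graph.n_atom:
        raise ValueError("highlight map length does not match molecule")
    out_path = Path(out_path)
    amps = np.asarray(highlight.amplitudes)
    peak = amps.max()
    atoms, colors = [], {}
    if peak > 0:
        for i, a in enumerate(amps):
            if a > 0:
                frac = a / peak
                # blend white -> orange with intensity
                colors[i] = tuple(1.0 - frac * (1.0 - c) for c in ORANGE)
                atoms.append(i)
    if out_path.suffix.lower() == ".png":
        drawer = rdMolDraw2D.MolDraw2DCairo(*size)
    else:
        drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, graph.mol, highlightAtoms=atoms, highlightAtomColors=colors
    )
    drawer.FinishDrawing()
    data = drawer.GetDrawingText()
    if isinstance(data, str):
        out_path.write_text(data)
    else:
        out_path.write_bytes(data)
    return out_path


def render_cluster_pages(
    members: list[tuple[MolecularGraph, HighlightMap]],
    out_dir: str | Path,
    prefix: str = "cluster",
    per_page: int = 4,
    size: tuple[int, int] = (300, 250),
) -> list[Path]:
    """Render molecules four per page, one SVG file per page."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pages = []
    for page_no, start in enumerate(range(0, len(members), per_page), start=1):
        chunk = members[start : start + per_page]
        cols = min(2, len(chunk))
        rows = (len(chunk) + 1) // 2
        drawer = rdMolDraw2D.MolDraw2DSVG(
            size[0] * cols, size[1] * rows, size[0], size[1]
        )
        mols, highlight_atoms, highlight_colors = [], [], []
        for graph, hmap in chunk:
            amps = np.asarray(hmap.amplitudes)
            peak = amps.max()
            colors = {}
            atoms = []
            if peak > 0:
                for i, a in enumerate(amps):
                    if a > 0:
                        frac = a / peak
                        colors[i] = tuple(1.0 - frac * (1.0 - c) for c in ORANGE)
                        atoms.append(i)
            mols.append(graph.mol)
            highlight_atoms.append(atoms)
            highlight_colors.append(colors)
        drawer.DrawMolecules(
            mols,
            highlightAtoms=highlight_atoms,
            highlightAtomColors=highlight_colors,
        )
        drawer.FinishDrawing()
        path = out_dir / f"{prefix}_page{page_no}.svg"
        path.write_text(drawer.GetDrawingText())
        pages.append(path)
    return pages
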