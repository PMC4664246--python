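"""Residue interaction networks from side-chain atom contacts.

Two residues i, j interact with normalized strength

    I_ij = n_ij / (N_i · N_j) × 100            (product form, default)
    I_ij = n_ij / sqrt(N_i · N_j) × 100        (sqrt variant)

where n_ij counts distinct heavy side-chain atom pairs within 4.5 Å and the
N are residue-type normalization factors accounting for side-chain size.
Edges connect pairs with I_ij ≥ I_min (default 2.5%); covalent sequence
neighbours never form edges. Glycine's "side chain" is its Cα — otherwise
glycine could never join the network.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import networkx as nx
import pandas as pd

from .structure_io import (
    ConsistencyError,
    ResidueKey,
    Structure,
    StructuralEnsemble,
)

__all__ = [
    "NormalizationTable",
    "InteractionMatrix",
    "EnsembleGraphSet",
    "CoverageError",
    "STANDARD_RESIDUES",
    "sidechain_atom_indices",
    "atom_contact_counts",
    "contact_count_matrix",
    "derive_normalization_table",
    "read_normalization_table",
    "write_normalization_table",
    "interaction_strengths",
    "build_graph",
    "lcc_transition_scan",
    "ensemble_graphs",
]

logger = logging.getLogger("allonet")

STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

#: heavy-atom contact distance cutoff (Å), inclusive
CONTACT_CUTOFF = 4.5


class CoverageError(KeyError):
    """A residue type lacks a normalization factor or correlation entry."""


@dataclasses.dataclass
class NormalizationTable:
    """Residue-type → N_i normalization factors (interaction-pair capacity)."""

    factors: dict[str, float]

    def __post_init__(self) -> None:
        for t, v in self.factors.items():
            if v <= 0:
                raise ValueError(f"N must be positive (got {v} for {t})")

    def __getitem__(self, residue_type: str) -> float:
        try:
            return self.factors[residue_type]
        except KeyError:
            raise CoverageError(f"no normalization factor for {residue_type}")


@dataclasses.dataclass
class InteractionMatrix:
    """Symmetric residue-residue interaction strengths I_ij (percent)."""

    residues: list[ResidueKey]
    strengths: np.ndarray  # (n, n) percent
    counts: np.ndarray  # (n, n) raw n_ij
    cutoff: float = CONTACT_CUTOFF

    def __post_init__(self) -> None:
        n = len(self.residues)
        if self.strengths.shape != (n, n) or self.counts.shape != (n, n):
            raise ConsistencyError("matrix shape mismatch")


@dataclasses.dataclass
class EnsembleGraphSet:
    """Per-snapshot residue graphs with edge persistence fractions."""

    graphs: list[nx.Graph]
    persistence: dict[tuple[ResidueKey, ResidueKey], float]
    n_snapshots: int


def _canonical_edge(a: ResidueKey, b: ResidueKey) -> tuple[ResidueKey, ResidueKey]:
    return (a, b) if a <= b else (b, a)


def sidechain_atom_indices(structure: Structure) -> dict[ResidueKey, np.ndarray]:
    """Heavy side-chain atom indices per residue; glycine falls back to Cα."""
    side: dict[ResidueKey, list[int]] = {}
    ca: dict[ResidueKey, list[int]] = {}
    for a in structure.atoms:
        if not a.is_heavy:
            continue
        if a.atom_name == "CA":
            ca.setdefault(a.residue_key, []).append(a.atom_index)
        if not a.is_backbone:
            side.setdefault(a.residue_key, []).append(a.atom_index)
    out: dict[ResidueKey, np.ndarray] = {}
    for key in structure.residue_keys():
        atoms = side.get(key) or ca.get(key) or []
        out[key] = np.asarray(atoms, dtype=int)
    return out


def _sequence_adjacent(order: Mapping[ResidueKey, int], a: ResidueKey, b: ResidueKey) -> bool:
    # covalent neighbours: same chain, residue numbers differing by 1
    return a[0] == b[0] and abs(a[1] - b[1]) == 1


def atom_contact_counts(
    structure: Structure,
    i: ResidueKey,
    j: ResidueKey,
    cutoff: float = CONTACT_CUTOFF,
) -> int:
    """Number of heavy side-chain atom pairs of residues i, j within the
    cutoff (inclusive). Sequence neighbours return 0 by convention."""
    if i == j:
        raise ValueError("i and j must differ")
    keys = structure.residue_keys()
    order = {k: n for n, k in enumerate(keys)}
    if _sequence_adjacent(order, i, j):
        return 0
    side = sidechain_atom_indices(structure)
    ai, aj = side.get(i), side.get(j)
    if ai is None or aj is None or len(ai) == 0 or len(aj) == 0:
        return 0
    d = np.linalg.norm(
        structure.coordinates[ai][:, None, :] - structure.coordinates[aj][None, :, :],
        axis=-1,
    )
    return int((d <= cutoff).sum())


def contact_count_matrix(
    structure: Structure, cutoff: float = CONTACT_CUTOFF
) -> tuple[list[ResidueKey], np.ndarray]:
    """All-pairs n_ij (vectorized over side-chain atoms)."""
    keys = structure.residue_keys()
    side = sidechain_atom_indices(structure)
    all_idx: list[int] = []
    res_of: list[int] = []
    for r, key in enumerate(keys):
        for a in side[key]:
            all_idx.append(int(a))
            res_of.append(r)
    n_res = len(keys)
    counts = np.zeros((n_res, n_res), dtype=int)
    if not all_idx:
        return keys, counts
    coords = structure.coordinates[all_idx]
    res_of_arr = np.asarray(res_of)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    close = d <= cutoff
    np.fill_diagonal(close, False)
    ii, jj = np.nonzero(close)
    for a, b in zip(res_of_arr[ii], res_of_arr[jj]):
        if a != b:
            counts[a, b] += 1
    # each unordered atom pair was counted once per direction
    counts = (counts + counts.T) // 2
    # zero out covalent sequence neighbours and diagonal
    order = {k: n for n, k in enumerate(keys)}
    for r in range(n_res):
        for q in range(r + 1, n_res):
            if _sequence_adjacent(order, keys[r], keys[q]):
                counts[r, q] = counts[q, r] = 0
    np.fill_diagonal(counts, 0)
    return keys, counts


def derive_normalization_table(
    structures: Iterable[Structure],
    percentile: float = 100.0,
    cutoff: float = CONTACT_CUTOFF,
    override: "NormalizationTable | None" = None,
) -> NormalizationTable:
    """Data-derived normalization factors.

    N for a residue type is the given percentile (default max) over residues
    of that type of its total heavy-atom interaction-pair count with all
    non-adjacent residues (main-chain and side-chain atoms both counted, per
    the size-capacity interpretation). A supplied ``override`` table wins.
    """
    if override is not None:
        return override
    per_type: dict[str, list[int]] = {}
    structures = list(structures)
    if not structures:
        raise CoverageError("empty structure set")
    for s in structures:
        keys = s.residue_keys()
        types = s.residue_types()
        by_res = s.atom_indices_by_residue()
        heavy = s.heavy_mask()
        order = {k: n for n, k in enumerate(keys)}
        coords = s.coordinates
        for key in keys:
            idx_i = np.asarray([a for a in by_res[key] if heavy[a]])
            if len(idx_i) == 0:
                continue
            total = 0
            for other in keys:
                if other == key or _sequence_adjacent(order, key, other):
                    continue
                idx_j = np.asarray([a for a in by_res[other] if heavy[a]])
                if len(idx_j) == 0:
                    continue
                d = np.linalg.norm(
                    coords[idx_i][:, None, :] - coords[idx_j][None, :, :], axis=-1
                )
                total += int((d <= cutoff).sum())
            per_type.setdefault(types[key], []).append(total)
    factors = {}
    for t, counts in per_type.items():
        val = float(np.percentile(counts, percentile))
        factors[t] = max(val, 1.0)  # capacity at least 1 pair
    logger.warning("normalization table derived from input structures: %s", factors)
    return NormalizationTable(factors)


def write_normalization_table(table: NormalizationTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.factors.items()), columns=["residue_type", "N"]
    ).to_csv(path, sep="\t", index=False)


def read_normalization_table(path: str | Path) -> NormalizationTable:
    df = pd.read_csv(path, sep="\t")
    return NormalizationTable(dict(zip(df["residue_type"], df["N"].astype(float))))


def interaction_strengths(
    structure: Structure,
    norm: NormalizationTable,
    denominator: str = "product",
    cutoff: float = CONTACT_CUTOFF,
) -> InteractionMatrix:
    """Normalized interaction matrix I_ij (percent).

    ``denominator="product"`` follows the printed N_i×N_j form;
    ``"sqrt_product"`` uses sqrt(N_i·N_j) as in the methodology literature.
    """
    if denominator not in ("product", "sqrt_product"):
        raise ValueError(f"unknown denominator '{denominator}'")
    keys, counts = contact_count_matrix(structure, cutoff)
    types = structure.residue_types()
    n_vec = np.array([norm[types[k]] for k in keys], dtype=float)
    denom = np.outer(n_vec, n_vec)
    if denominator == "sqrt_product":
        denom = np.sqrt(denom)
    strengths = counts / denom * 100.0
    np.fill_diagonal(strengths, 0.0)
    return InteractionMatrix(keys, strengths, counts, cutoff)


def build_graph(interactions: InteractionMatrix, i_min: float = 2.5) -> nx.Graph:
    """Residue graph with an edge wherever I_ij ≥ I_min (inclusive)."""
    if i_min < 0:
        raise ValueError("I_min must be >= 0")
    g = nx.Graph(i_min=i_min)
    g.add_nodes_from(interactions.residues)
    n = len(interactions.residues)
    for a in range(n):
        for b in range(a + 1, n):
            s = interactions.strengths[a, b]
            if s > 0 and s >= i_min:
                g.add_edge(
                    interactions.residues[a],
                    interactions.residues[b],
                    strength=float(s),
                    n_ij=int(interactions.counts[a, b]),
                )
    return g


def lcc_transition_scan(
    interactions: InteractionMatrix,
    grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Largest-connected-component size across an I_min grid (default
    1–15%) and the transition point = steepest backward decrease (ties →
    smaller I_min). Returns (scan table, transition or None)."""
    if grid is None:
        grid = np.arange(1.0, 15.0 + 1e-9, 0.5)
    grid = np.asarray(sorted(grid), dtype=float)
    sizes = []
    for i_min in grid:
        g = build_graph(interactions, i_min)
        if g.number_of_edges() == 0:
            sizes.append(1 if g.number_of_nodes() else 0)
        else:
            sizes.append(max(len(c) for c in nx.connected_components(g)))
    sizes_arr = np.asarray(sizes)
    drops = sizes_arr[:-1] - sizes_arr[1:]
    table = pd.DataFrame({"I_min": grid, "lcc_size": sizes_arr})
    if len(drops) == 0 or drops.max() <= 0:
        logger.warning("LCC curve is flat: transition undefined")
        return table, None
    transition = float(grid[1:][int(np.argmax(drops))])
    return table, transition


def ensemble_graphs(
    ensemble: StructuralEnsemble,
    norm: NormalizationTable,
    i_min: float = 2.5,
    max_snapshots: int = 1000,
    stride: int = 1,
    denominator: str = "product",
    cutoff: float = CONTACT_CUTOFF,
) -> EnsembleGraphSet:
    """Per-snapshot residue graphs and per-edge persistence fractions.

    Frames are taken every ``stride`` up to ``max_snapshots`` snapshots.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frame_ids = list(range(0, ensemble.n_frames, stride))[:max_snapshots]
    graphs: list[nx.Graph] = []
    edge_counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    for f in frame_ids:
        s = ensemble.structure(f)
        g = build_graph(interaction_strengths(s, norm, denominator, cutoff), i_min)
        graphs.append(g)
        for u, v in g.edges:
            edge_counts[_canonical_edge(u, v)] = (
                edge_counts.get(_canonical_edge(u, v), 0) + 1
            )
    n = len(frame_ids)
    persistence = {e: c / n for e, c in edge_counts.items()}
    return EnsembleGraphSet(graphs, persistence, n)
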