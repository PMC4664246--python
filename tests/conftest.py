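"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the production code paths: betweenness
by exhaustive simple-path enumeration, contact counts by a plain double
loop, surface exposure by all-against-all point testing.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from allonet import synthetic_ensembles as syn
from allonet.structure_io import AtomRecord, Structure, StructuralEnsemble


@pytest.fixture(scope="session")
def toy_helix():
    return syn.build_toy_protein(20, "helix", 3, seed=7)


@pytest.fixture(scope="session")
def anm_model(toy_helix):
    return syn.anm_covariance(toy_helix)


@pytest.fixture(scope="session")
def anm_ensemble(anm_model):
    return syn.sample_gaussian_ensemble(anm_model, 2000, seed=11)


def make_point_structure(coords, residue_of=None, atom_names=None, restypes=None):
    """Structure from bare coordinates: one atom per row, heavy carbons.

    ``residue_of[i]`` assigns atom i to residue number residue_of[i]
    (default: one residue per atom).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    residue_of = residue_of if residue_of is not None else list(range(1, n + 1))
    atoms = []
    for i in range(n):
        name = atom_names[i] if atom_names else "CA"
        rtype = restypes[i] if restypes else "ALA"
        atoms.append(
            AtomRecord(
                atom_index=i,
                atom_name=name,
                element="C",
                residue_key=("A", int(residue_of[i]), ""),
                residue_type=rtype,
                is_backbone=name in ("N", "CA", "C", "O"),
                is_heavy=True,
            )
        )
    return Structure(atoms, coords)


def make_ca_ensemble(frames):
    """Ensemble of Cα-only frames from an (F, N, 3) array."""
    frames = np.asarray(frames, dtype=float)
    topo = [
        AtomRecord(i, "CA", "C", ("A", i + 1, ""), "ALA", True, True)
        for i in range(frames.shape[1])
    ]
    return StructuralEnsemble(topo, frames)


# ---------------------------------------------------------------------------
# Brute-force betweenness oracle
# ---------------------------------------------------------------------------


def brute_force_betweenness(g: nx.Graph, tol: float = 1e-9) -> dict:
    """Normalized betweenness by exhaustive simple-path enumeration."""
    nodes = list(g.nodes)
    comp_of = {}
    for comp in nx.connected_components(g):
        for u in comp:
            comp_of[u] = comp
    raw = {u: 0.0 for u in nodes}
    for j, k in combinations(nodes, 2):
        if k not in comp_of[j]:
            continue
        paths = list(nx.all_simple_paths(g, j, k))
        lengths = [
            sum(g[u][v].get("weight", 1.0) for u, v in zip(p, p[1:])) for p in paths
        ]
        best = min(lengths)
        shortest = [
            p
            for p, L in zip(paths, lengths)
            if L - best <= tol * max(1.0, abs(best))
        ]
        g_jk = len(shortest)
        for i in nodes:
            if i in (j, k):
                continue
            g_jk_i = sum(1 for p in shortest if i in p)
            raw[i] += g_jk_i / g_jk
    out = {}
    for u in nodes:
        n = len(comp_of[u])
        out[u] = raw[u] / ((n - 1) * (n - 2) / 2.0) if n >= 3 else 0.0
    return out


# ---------------------------------------------------------------------------
# Brute-force contact counting
# ---------------------------------------------------------------------------


def brute_force_contacts(structure, i, j, cutoff=4.5):
    """O(n²) double loop over heavy side-chain atoms (Cα for glycine)."""
    from allonet.structure_network import sidechain_atom_indices

    keys = structure.residue_keys()
    order = {k: n for n, k in enumerate(keys)}
    if i[0] == j[0] and abs(order[i] - order[j]) == 1:
        return 0
    side = sidechain_atom_indices(structure)
    count = 0
    for a in side[i]:
        for b in side[j]:
            d = np.linalg.norm(structure.coordinates[a] - structure.coordinates[b])
            if d <= cutoff:
                count += 1
    return count


# ---------------------------------------------------------------------------
# Brute-force surface/depth oracle
# ---------------------------------------------------------------------------


def brute_force_atom_depths(structure, probe=1.4, points_per_atom=256):
    """Exhaustive exposed-point search with no neighbour pruning."""
    from allonet.residue_depth import atom_radii, fibonacci_sphere

    s = structure.select(structure.heavy_mask())
    coords = s.coordinates
    radii = atom_radii(s) + probe
    unit = fibonacci_sphere(points_per_atom)
    exposed_points = []
    for i in range(s.n_atoms):
        for p in coords[i] + radii[i] * unit:
            ok = True
            for j in range(s.n_atoms):
                if j == i:
                    continue
                if np.linalg.norm(p - coords[j]) < radii[j] - 1e-9:
                    ok = False
                    break
            if ok:
                exposed_points.append(p)
    exposed_points = np.asarray(exposed_points)
    depths = np.empty(s.n_atoms)
    for i in range(s.n_atoms):
        dmin = np.min(np.linalg.norm(exposed_points - coords[i], axis=1))
        depths[i] = max(dmin - radii[i], 0.0)
    return depths
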