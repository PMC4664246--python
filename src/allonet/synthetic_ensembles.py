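"""Synthetic ensembles, graphs and energy tables with known ground truth.

Every analysis stage in the package gets its oracle here: an anisotropic
elastic-network model (ANM) whose Gaussian fluctuation covariance is known in
closed form, two-state conformational mixtures with set populations, planted
community graphs, toy proteins with pseudo side chains (so atom-contact
counting is nontrivial), and Gaussian per-snapshot energy tables.

All generators are deterministic under a fixed seed; each operation draws
from its own named stream derived from ``(seed, operation name)`` so that
pipeline stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import networkx as nx
import pandas as pd

from .structure_io import (
    AtomRecord,
    ConsistencyError,
    Structure,
    StructuralEnsemble,
)

__all__ = [
    "KB_KCAL",
    "AnmModel",
    "TwoStateSpec",
    "PlantedGraphSpec",
    "ModelError",
    "build_toy_protein",
    "anm_covariance",
    "sample_gaussian_ensemble",
    "analytic_cross_correlation",
    "analytic_bfactors",
    "make_two_state_ensemble",
    "planted_community_graph",
    "synthetic_energy_table",
]

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹.
KB_KCAL = 0.0019872041


class ModelError(ValueError):
    """Elastic-network model cannot be built from the given nodes."""


def _rng(seed: int, operation: str) -> np.random.Generator:
    """Named stream: independent reproducibility per pipeline stage."""
    import zlib

    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(operation.encode()) & 0x7FFFFFFF]
    )
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Toy protein construction
# ---------------------------------------------------------------------------

# 1-letter-free rotation of residue names so the toy carries several types,
# giving residue-type-dependent contact counts for normalization testing.
_TOY_RESTYPES = ["ALA", "LEU", "SER", "PHE", "GLY", "LYS", "VAL", "THR"]

# alpha-helix: rise 1.5 Å per residue, 100° twist, Cα radius 2.3 Å
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)
_HELIX_RADIUS = 2.3
_EXTENDED_STEP = 3.8


def build_toy_protein(
    n_residues: int,
    geometry: str = "helix",
    sidechain_atoms: int = 3,
    seed: int = 0,
    chain: str = "A",
) -> Structure:
    """Build a toy polypeptide with backbone (N, CA, C, O) plus pseudo
    side-chain heavy atoms.

    ``geometry`` is ``"helix"`` (ideal α-helical Cα trace) or ``"extended"``
    (straight chain with constant 3.8 Å Cα–Cα step). Each residue carries
    ``sidechain_atoms`` pseudo carbons on a deterministic tetrahedral fan off
    the Cβ direction; glycine positions get side chains too (the toy is a
    statistical stand-in, not chemistry). Deterministic given ``seed``.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if geometry not in ("helix", "extended"):
        raise ValueError(f"unknown geometry '{geometry}'")
    if sidechain_atoms < 0:
        raise ValueError("sidechain_atoms must be >= 0")

    rng = _rng(seed, "build_toy_protein")

    if geometry == "helix":
        t = np.arange(n_residues)
        ca = np.stack(
            [
                _HELIX_RADIUS * np.cos(_HELIX_TWIST * t),
                _HELIX_RADIUS * np.sin(_HELIX_TWIST * t),
                _HELIX_RISE * t,
            ],
            axis=1,
        )
    else:
        ca = np.zeros((n_residues, 3))
        ca[:, 0] = _EXTENDED_STEP * np.arange(n_residues)
        # small fixed zig-zag off-axis so the chain is not collinear
        ca[:, 1] = 0.5 * (np.arange(n_residues) % 2)

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    idx = 0

    # local frames along the chain for placing backbone satellites
    for i in range(n_residues):
        nxt = ca[min(i + 1, n_residues - 1)] - ca[max(i - 1, 0)]
        tangent = nxt / np.linalg.norm(nxt)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(tangent @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        normal = np.cross(tangent, ref)
        normal /= np.linalg.norm(normal)
        binormal = np.cross(tangent, normal)

        key = (chain, i + 1, "")
        rtype = _TOY_RESTYPES[i % len(_TOY_RESTYPES)]

        def add(name: str, pos: np.ndarray, backbone: bool) -> None:
            nonlocal idx
            atoms.append(
                AtomRecord(
                    atom_index=idx,
                    atom_name=name,
                    element="C" if name not in ("N", "O") else name,
                    residue_key=key,
                    residue_type=rtype,
                    is_backbone=backbone,
                    is_heavy=True,
                )
            )
            coords.append(pos)
            idx += 1

        add("N", ca[i] - 1.0 * tangent + 0.6 * normal, True)
        add("CA", ca[i], True)
        add("C", ca[i] + 1.0 * tangent + 0.4 * normal, True)
        add("O", ca[i] + 1.2 * tangent + 1.4 * normal, True)

        # pseudo side chain: Cβ off the helix axis, then a tetrahedral fan
        cb_dir = -normal if geometry == "helix" else binormal
        jitter = rng.normal(scale=0.05, size=3)
        cb = ca[i] + 1.53 * cb_dir + jitter
        if sidechain_atoms >= 1:
            add("CB", cb, False)
        fan_axes = [binormal, -tangent, normal]
        for s in range(1, sidechain_atoms):
            axis = fan_axes[(s - 1) % 3]
            pos = cb + 1.4 * s * (0.7 * cb_dir + 0.5 * axis) / np.linalg.norm(
                0.7 * cb_dir + 0.5 * axis
            )
            add(f"C{s}X", pos, False)

    return Structure(atoms, np.asarray(coords))


# ---------------------------------------------------------------------------
# Anisotropic network model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AnmModel:
    """ANM over Cα-like nodes with closed-form Gaussian covariance.

    ``covariance`` is the 3N×3N matrix k_B·T·H⁺ where H is the ANM Hessian
    and the pseudo-inverse discards the six rigid-body modes.
    """

    coordinates: np.ndarray  # (n, 3) node positions (Å)
    cutoff: float
    gamma: float
    temperature: float
    hessian: np.ndarray  # (3n, 3n)
    covariance: np.ndarray  # (3n, 3n), kB*T * pinv(H)
    eigenvalues: np.ndarray  # Hessian eigenvalues ascending
    n_zero_modes: int

    @property
    def n_nodes(self) -> int:
        return self.coordinates.shape[0]

    def node_variance(self) -> np.ndarray:
        """Per-node positional variance ⟨|Δr_i|²⟩ (Ų)."""
        n = self.n_nodes
        blocks = self.covariance.reshape(n, 3, n, 3)
        return np.einsum("iaia->i", blocks)


def _anm_hessian(coords: np.ndarray, cutoff: float, gamma: float) -> np.ndarray:
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    contact = (dist <= cutoff) & (dist > 0)
    if not _connected(contact):
        raise ModelError("contact graph disconnected at this cutoff")
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            if not contact[i, j]:
                continue
            d = diff[i, j]
            block = -gamma * np.outer(d, d) / (dist[i, j] ** 2)
            hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hess


def _connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        u = stack.pop()
        for v in np.flatnonzero(adj[u]):
            if not seen[v]:
                seen[v] = True
                stack.append(v)
    return bool(seen.all())


#: relative eigenvalue threshold below which a mode counts as rigid-body
RIGID_MODE_RTOL = 1e-8


def anm_covariance(
    structure: Structure | np.ndarray,
    cutoff: float = 13.0,
    gamma: float = 1.0,
    temperature: float = 300.0,
) -> AnmModel:
    """Build an ANM on Cα nodes and return its analytic covariance.

    Accepts either a :class:`Structure` (Cα atoms are extracted) or a raw
    ``(n, 3)`` coordinate array. Requires a connected contact graph and at
    least 3 non-collinear nodes; exactly six rigid-body modes are discarded
    in the pseudo-inverse (eigenvalues below ``1e-8`` of the largest).
    """
    if isinstance(structure, Structure):
        coords = structure.coordinates[structure.ca_mask()]
    else:
        coords = np.asarray(structure, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ModelError("need at least 3 nodes")
    # collinearity check: rank of centered coordinates
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ModelError("nodes are collinear; ANM is degenerate")

    hess = _anm_hessian(coords, cutoff, gamma)
    evals, evecs = np.linalg.eigh(hess)
    thresh = RIGID_MODE_RTOL * evals[-1]
    zero = evals < thresh
    n_zero = int(zero.sum())
    if n_zero != 6:
        raise ModelError(
            f"expected 6 rigid-body modes, found {n_zero}; "
            "geometry is degenerate or the graph is disconnected"
        )
    inv = np.zeros_like(evals)
    inv[~zero] = 1.0 / evals[~zero]
    cov = KB_KCAL * temperature * (evecs * inv) @ evecs.T
    cov = 0.5 * (cov + cov.T)
    return AnmModel(
        coordinates=coords,
        cutoff=cutoff,
        gamma=gamma,
        temperature=temperature,
        hessian=hess,
        covariance=cov,
        eigenvalues=evals,
        n_zero_modes=n_zero,
    )


def sample_gaussian_ensemble(
    model: AnmModel,
    n_frames: int,
    seed: int = 0,
    topology: list[AtomRecord] | None = None,
) -> StructuralEnsemble:
    """Draw frames = mean coordinates + Gaussian deviates with the model
    covariance (exact factorization through the Hessian eigenbasis)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _rng(seed, "sample_gaussian_ensemble")
    n = model.n_nodes
    evals, evecs = np.linalg.eigh(model.hessian)
    thresh = RIGID_MODE_RTOL * evals[-1]
    live = evals >= thresh
    scale = np.sqrt(KB_KCAL * model.temperature / evals[live])
    z = rng.standard_normal((n_frames, live.sum()))
    dev = (z * scale) @ evecs[:, live].T  # (n_frames, 3n)
    frames = model.coordinates[None, :, :] + dev.reshape(n_frames, n, 3)
    if topology is None:
        topology = [
            AtomRecord(i, "CA", "C", ("A", i + 1, ""), "ALA", True, True)
            for i in range(n)
        ]
    return StructuralEnsemble(topology, frames)


def analytic_cross_correlation(model: AnmModel) -> np.ndarray:
    """Closed-form DCCM: C_ij = tr Σ_ij / sqrt(tr Σ_ii · tr Σ_jj)."""
    n = model.n_nodes
    blocks = model.covariance.reshape(n, 3, n, 3)
    traces = np.einsum("iaja->ij", blocks)
    diag = np.diag(traces)
    if np.any(diag <= 0):
        raise ModelError("zero-variance node: correlation undefined")
    denom = np.sqrt(np.outer(diag, diag))
    corr = traces / denom
    np.fill_diagonal(corr, 1.0)
    return 0.5 * (corr + corr.T)


def analytic_bfactors(model: AnmModel) -> np.ndarray:
    """Closed-form B-factors (8π²/3)·⟨|Δr_i|²⟩ (Ų)."""
    return (8.0 * np.pi**2 / 3.0) * model.node_variance()


# ---------------------------------------------------------------------------
# Two-state mixtures
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TwoStateSpec:
    """A two-conformer population mixture with isotropic positional noise."""

    conformer_a: Structure
    conformer_b: Structure
    population_a: float
    noise_sd: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.population_a <= 1.0:
            raise ValueError("population_a must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def make_two_state_ensemble(spec: TwoStateSpec) -> StructuralEnsemble:
    """Mixture ensemble: each frame is conformer A with probability p, else B,
    plus isotropic Gaussian noise; ``frame_labels`` record the true state."""
    a, b = spec.conformer_a, spec.conformer_b
    if [(x.atom_name, x.residue_key) for x in a.atoms] != [
        (x.atom_name, x.residue_key) for x in b.atoms
    ]:
        raise ConsistencyError("conformers do not share a topology")
    rng = _rng(spec.seed, "make_two_state_ensemble")
    picks = rng.random(spec.n_frames) < spec.population_a
    frames = np.where(
        picks[:, None, None], a.coordinates[None], b.coordinates[None]
    ).astype(float)
    if spec.noise_sd > 0:
        frames = frames + rng.normal(scale=spec.noise_sd, size=frames.shape)
    labels = ["A" if p else "B" for p in picks]
    return StructuralEnsemble(a.atoms, frames, labels)


# ---------------------------------------------------------------------------
# Planted community graphs and energy tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PlantedGraphSpec:
    """Planted-block random graph: dense communities, sparse background."""

    communities: list[set]
    intra_p: float
    inter_p: float
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.intra_p, self.inter_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def planted_community_graph(spec: PlantedGraphSpec) -> nx.Graph:
    """Random graph with planted dense blocks; deterministic by seed."""
    rng = _rng(spec.seed, "planted_community_graph")
    g = nx.Graph()
    nodes = sorted({n for block in spec.communities for n in block})
    g.add_nodes_from(nodes)
    membership: dict = {}
    for ci, block in enumerate(spec.communities):
        for n in block:
            membership.setdefault(n, set()).add(ci)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            shared = membership[u] & membership[v]
            p = spec.intra_p if shared else spec.inter_p
            if rng.random() < p:
                g.add_edge(u, v)
    return g


def synthetic_energy_table(
    n_frames: int,
    term_means: dict,
    term_sds: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian per-frame energy terms (one column per term, kcal/mol).

    Column keys may be plain term names or ``(partition, term)`` tuples; in
    the latter case the result carries a two-level column index compatible
    with the energetics aggregation.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if set(term_means) != set(term_sds):
        raise ValueError("term_means and term_sds must share keys")
    for k, sd in term_sds.items():
        if sd < 0:
            raise ValueError(f"negative sd for term {k!r}")
    rng = _rng(seed, "synthetic_energy_table")
    data = {
        k: term_means[k] + term_sds[k] * rng.standard_normal(n_frames)
        for k in term_means
    }
    df = pd.DataFrame(data)
    if all(isinstance(k, tuple) for k in term_means):
        df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df
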