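"""Ensemble post-processing: superposition, B-factors, cross-correlation,
PCA, low-mode mobility, rigid-body decomposition and density-of-states
population analysis.

Conventions: "lowest-frequency modes" are the largest-variance principal
components (amplitude inversely related to frequency). Superposition uses
proper rotations only (Kabsch with det=+1 enforcement) and an iterative
mean-structure reference (fit → mean → refit).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .structure_io import ConsistencyError, ResidueKey, StructuralEnsemble

__all__ = [
    "CrossCorrelationMatrix",
    "PcaResult",
    "DensityOfStates",
    "kabsch_rotation",
    "superpose_ensemble",
    "bfactor_profile",
    "cross_correlation",
    "pca_modes",
    "mode_mobility_profile",
    "rigid_body_decomposition",
    "density_of_states",
]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det=+1) aligning centered ``mobile`` onto
    centered ``reference`` in the least-squares sense."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def _fit_frame(
    frame: np.ndarray, ref: np.ndarray, fit_idx: np.ndarray
) -> np.ndarray:
    mob_c = frame[fit_idx].mean(axis=0)
    ref_c = ref[fit_idx].mean(axis=0)
    rot = kabsch_rotation(frame[fit_idx] - mob_c, ref[fit_idx] - ref_c)
    return (frame - mob_c) @ rot.T + ref_c


def _selection_indices(
    ensemble: StructuralEnsemble, selection: Sequence[ResidueKey] | None
) -> np.ndarray:
    if selection is None:
        return np.arange(ensemble.n_atoms)
    wanted = set(selection)
    idx = [a.atom_index for a in ensemble.topology if a.residue_key in wanted]
    return np.asarray(idx, dtype=int)


def superpose_ensemble(
    ensemble: StructuralEnsemble,
    fit_selection: Sequence[ResidueKey] | None = None,
    reference: int | str = "mean",
    max_iter: int = 30,
    tol: float = 1e-10,
) -> StructuralEnsemble:
    """Least-squares superpose every frame onto a common reference.

    ``reference`` is a frame index or ``"mean"`` (iterative: fit to frame 0,
    recompute the mean, refit until the mean converges). Only atoms of
    ``fit_selection`` residues enter the fit; the transform is applied to all
    atoms.
    """
    fit_idx = _selection_indices(ensemble, fit_selection)
    if len(fit_idx) < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    sub = ensemble.frames[0][fit_idx]
    if np.linalg.matrix_rank(sub - sub.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("fit selection is collinear/degenerate")

    frames = ensemble.frames.copy()
    if isinstance(reference, int):
        ref = frames[reference]
        frames = np.stack([_fit_frame(f, ref, fit_idx) for f in frames])
    else:
        # anchor the gauge at the current mean: a converged ensemble is a
        # fixed point, making repeated superposition idempotent
        ref = frames.mean(axis=0)
        for _ in range(max_iter):
            frames = np.stack([_fit_frame(f, ref, fit_idx) for f in frames])
            new_ref = frames.mean(axis=0)
            if np.max(np.abs(new_ref - ref)) < tol:
                ref = new_ref
                break
            ref = new_ref
    return StructuralEnsemble(ensemble.topology, frames, ensemble.frame_labels)


# ---------------------------------------------------------------------------
# B-factors and cross-correlation
# ---------------------------------------------------------------------------


def _atom_selection_mask(ensemble: StructuralEnsemble, atom_mode: str) -> np.ndarray:
    if atom_mode == "CA":
        mask = np.array(
            [a.atom_name == "CA" and a.is_heavy for a in ensemble.topology]
        )
    elif atom_mode == "heavy":
        mask = np.array([a.is_heavy for a in ensemble.topology])
    elif atom_mode == "backbone":
        mask = np.array([a.is_backbone and a.is_heavy for a in ensemble.topology])
    else:
        raise ValueError(f"unknown atom mode '{atom_mode}'")
    if not mask.any():
        raise ValueError(f"no atoms selected by mode '{atom_mode}'")
    return mask


def bfactor_profile(
    ensemble: StructuralEnsemble, atom_mode: str = "CA"
) -> dict[ResidueKey, float]:
    """Per-residue B-factors B = (8π²/3)·⟨|Δr|²⟩ (Ų), averaged over the
    selected atoms of each residue. The ensemble must be superposed."""
    if ensemble.n_frames < 2:
        warnings.warn("single-frame ensemble: B-factors are all zero")
    mask = _atom_selection_mask(ensemble, atom_mode)
    dev = ensemble.frames - ensemble.frames.mean(axis=0, keepdims=True)
    msf = np.einsum("fak,fak->a", dev, dev) / ensemble.n_frames  # ⟨|Δr|²⟩ per atom
    b_atom = (8.0 * np.pi**2 / 3.0) * msf
    out: dict[ResidueKey, list[float]] = {}
    for a in ensemble.topology:
        if mask[a.atom_index]:
            out.setdefault(a.residue_key, []).append(b_atom[a.atom_index])
    return {k: float(np.mean(v)) for k, v in out.items()}


@dataclasses.dataclass
class CrossCorrelationMatrix:
    """Residue-indexed DCCM with entries in [−1, 1]."""

    residues: list[ResidueKey]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.residues)
        if self.matrix.shape != (n, n):
            raise ConsistencyError("matrix shape does not match residue list")

    def entry(self, i: ResidueKey, j: ResidueKey) -> float:
        ii = self.residues.index(i)
        jj = self.residues.index(j)
        return float(self.matrix[ii, jj])


def cross_correlation(
    ensemble: StructuralEnsemble, atom_mode: str = "CA"
) -> CrossCorrelationMatrix:
    """Dynamic cross-correlation map C_ij = ⟨Δr_i·Δr_j⟩ /
    sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over one selected atom per residue (Cα).

    Zero-variance residues get C = 0 off-diagonal with a warning.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames")
    mask = _atom_selection_mask(ensemble, atom_mode)
    idx = np.flatnonzero(mask)
    residues = [ensemble.topology[i].residue_key for i in idx]
    coords = ensemble.frames[:, idx, :]
    dev = coords - coords.mean(axis=0, keepdims=True)
    cov = np.einsum("fik,fjk->ij", dev, dev) / ensemble.n_frames
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-variance residues: C set to 0")
        var[zero] = 1.0
    corr = cov / np.sqrt(np.outer(var, var))
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    return CrossCorrelationMatrix(residues, corr)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PcaResult:
    """Principal components of the coordinate covariance."""

    eigenvalues: np.ndarray  # (m,) descending, Ų
    modes: np.ndarray  # (m, 3k) orthonormal rows
    mean: np.ndarray  # (k, 3)
    variance_fraction: np.ndarray
    residues: list[ResidueKey]

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def pca_modes(ensemble: StructuralEnsemble, atom_set: str = "CA") -> PcaResult:
    """PCA of the superposed coordinate covariance over Cα or backbone atoms;
    modes sorted by descending eigenvalue (largest variance = lowest
    frequency)."""
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames for PCA")
    mask = _atom_selection_mask(ensemble, atom_set)
    idx = np.flatnonzero(mask)
    coords = ensemble.frames[:, idx, :].reshape(ensemble.n_frames, -1)
    mean = coords.mean(axis=0)
    dev = coords - mean
    cov = dev.T @ dev / ensemble.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    modes = evecs[:, order].T
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    residues = [ensemble.topology[i].residue_key for i in idx]
    return PcaResult(evals, modes, mean.reshape(-1, 3), frac, residues)


def mode_mobility_profile(pca: PcaResult, n_modes: int = 3) -> dict[ResidueKey, float]:
    """Per-residue displacement amplitude sqrt(Σ_m λ_m |v_m,i|²) in the top
    ``n_modes`` largest-variance (lowest-frequency) modes (Å).

    Residues contributing several atoms to the PCA (backbone mode) are
    reported as the root-mean amplitude over their atoms.
    """
    if n_modes > pca.n_modes:
        raise ValueError("n_modes exceeds available modes")
    v = pca.modes[:n_modes].reshape(n_modes, -1, 3)
    amp2 = np.einsum("m,mak->a", pca.eigenvalues[:n_modes], v**2)
    out: dict[ResidueKey, list[float]] = {}
    for a_pos, key in enumerate(pca.residues):
        out.setdefault(key, []).append(amp2[a_pos])
    return {k: float(np.sqrt(np.mean(v))) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Rigid-body decomposition
# ---------------------------------------------------------------------------


def rigid_body_decomposition(
    ensemble: StructuralEnsemble,
    fit_selection: Sequence[ResidueKey],
    probe_selection: Sequence[ResidueKey],
    reference: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame rigid-body RMSD (Å) and rotation angle (°) of a probe
    region after superposing each frame on ``fit_selection``.

    The angle is that of the optimal proper rotation mapping the probe's
    reference pose onto its pose in the frame.
    """
    fit_idx = _selection_indices(ensemble, fit_selection)
    probe_idx = _selection_indices(ensemble, probe_selection)
    if len(probe_idx) < 3:
        raise ValueError("probe selection needs at least 3 atoms for an angle")
    ref = ensemble.frames[reference]
    rmsds = np.empty(ensemble.n_frames)
    angles = np.empty(ensemble.n_frames)
    ref_probe = ref[probe_idx]
    ref_probe_c = ref_probe - ref_probe.mean(axis=0)
    for f in range(ensemble.n_frames):
        fitted = _fit_frame(ensemble.frames[f], ref, fit_idx)
        probe = fitted[probe_idx]
        diff = probe - ref_probe
        rmsds[f] = np.sqrt((diff**2).sum() / len(probe_idx))
        rot = kabsch_rotation(probe - probe.mean(axis=0), ref_probe_c)
        cos = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
        angles[f] = np.degrees(np.arccos(cos))
    return rmsds, angles


# ---------------------------------------------------------------------------
# Density of states
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DensityOfStates:
    """2-D histogram over (per-frame energy, rigid-body RMSD) with detected
    peaks and their basin population fractions."""

    counts: np.ndarray  # (nx, ny)
    x_edges: np.ndarray
    y_edges: np.ndarray
    peaks: list[tuple[float, float]]  # bin centers
    peak_heights: list[int]
    peak_fractions: list[float]

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())


def density_of_states(
    energy_series: np.ndarray,
    rmsd_series: np.ndarray,
    bins: int | tuple[int, int] = 50,
    peak_threshold: float = 0.10,
) -> DensityOfStates:
    """Population analysis on the (energy, RMSD) plane.

    Peaks are 8-neighbour local maxima of the 2-D histogram above
    ``peak_threshold`` of the global maximum; every occupied bin is assigned
    to its nearest peak (in bin-index space) and basin fractions are the
    assigned counts over the total frame count.
    """
    e = np.asarray(energy_series, dtype=float)
    r = np.asarray(rmsd_series, dtype=float)
    if e.shape != r.shape:
        raise ConsistencyError("energy and RMSD series lengths differ")
    counts, x_edges, y_edges = np.histogram2d(e, r, bins=bins)

    # 8-neighbour local maxima (strictly >= neighbours, > at least one)
    nx_, ny_ = counts.shape
    cmax = counts.max()
    thresh = peak_threshold * cmax
    peak_bins: list[tuple[int, int]] = []
    for i in range(nx_):
        for j in range(ny_):
            c = counts[i, j]
            if c <= 0 or c < thresh:
                continue
            neigh = counts[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
            if (neigh > c).any():
                continue
            # plateau handling: one peak per adjacent plateau
            if any(abs(pi - i) <= 1 and abs(pj - j) <= 1 for pi, pj in peak_bins):
                continue
            peak_bins.append((i, j))

    x_centers = 0.5 * (x_edges[:-1] + x_edges[1:])
    y_centers = 0.5 * (y_edges[:-1] + y_edges[1:])
    peaks = [(float(x_centers[i]), float(y_centers[j])) for i, j in peak_bins]
    heights = [int(counts[i, j]) for i, j in peak_bins]

    fractions: list[float] = [0.0] * len(peak_bins)
    if peak_bins:
        occupied = np.argwhere(counts > 0)
        pk = np.asarray(peak_bins, dtype=float)
        for i, j in occupied:
            d2 = (pk[:, 0] - i) ** 2 + (pk[:, 1] - j) ** 2
            fractions[int(np.argmin(d2))] += counts[i, j]
        total = counts.sum()
        fractions = [float(f / total) for f in fractions]

    return DensityOfStates(counts, x_edges, y_edges, peaks, heights, fractions)
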