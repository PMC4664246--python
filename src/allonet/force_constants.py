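"""Residue-level rigidity profiling.

Converts fluctuations of the mean distance between a residue (or atom) and
the rest of the protein into an effective force constant

    k_i = 3 k_B T / Var(d_i),        d_i = <d_ij>_{j*}

where the variance is taken over the ensemble and j* runs over partners
outside the residue itself. High k marks rigid sites (hinge candidates);
peaks of the profile are located with a simple windowed local-maximum
detector shared with the centrality profiles.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np

from .structure_io import ResidueKey, StructuralEnsemble
from .synthetic_ensembles import KB_KCAL

__all__ = [
    "ForceConstantProfile",
    "PeakSet",
    "mean_distance_series",
    "force_constant_profile",
    "detect_profile_peaks",
]

#: sentinel force constant for zero-variance (rigid) units, kcal·mol⁻¹·Å⁻²
K_CAP = 1e6


@dataclasses.dataclass
class ForceConstantProfile:
    """Per-residue force constants k_i (kcal·mol⁻¹·Å⁻²)."""

    values: dict[ResidueKey, float]
    temperature: float
    kbt: float
    mode: str  # "all-atom" | "CA"


@dataclasses.dataclass
class PeakSet:
    """Local maxima of a per-residue profile."""

    residues: list[ResidueKey]
    heights: list[float]
    window: int
    min_prominence: float


def _ca_positions(ensemble: StructuralEnsemble) -> tuple[list[ResidueKey], np.ndarray]:
    idx = [a.atom_index for a in ensemble.topology if a.atom_name == "CA" and a.is_heavy]
    keys = [ensemble.topology[i].residue_key for i in idx]
    return keys, ensemble.frames[:, idx, :]


def mean_distance_series(
    ensemble: StructuralEnsemble,
    unit: str = "residue",
    target_index: int = 0,
) -> np.ndarray:
    """Per-frame mean distance d from one unit to the rest of the protein (Å).

    ``unit="residue"`` uses Cα positions and excludes the sequence
    neighbours i±1 (their distances are nearly constant); ``unit="atom"``
    uses the atom's own position against all heavy atoms of other residues.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if unit == "residue":
        keys, ca = _ca_positions(ensemble)
        n = len(keys)
        if n < 4:
            raise ValueError("need at least 4 residues in CA mode")
        partners = [j for j in range(n) if abs(j - target_index) > 1]
        diff = ca[:, partners, :] - ca[:, [target_index], :]
        return np.linalg.norm(diff, axis=-1).mean(axis=1)
    elif unit == "atom":
        target_res = ensemble.topology[target_index].residue_key
        partners = [
            a.atom_index
            for a in ensemble.topology
            if a.is_heavy and a.residue_key != target_res
        ]
        if not partners:
            raise ValueError("no partner atoms outside the target residue")
        diff = ensemble.frames[:, partners, :] - ensemble.frames[:, [target_index], :]
        return np.linalg.norm(diff, axis=-1).mean(axis=1)
    raise ValueError(f"unknown unit '{unit}'")


def force_constant_from_series(d_series: np.ndarray, temperature: float = 300.0) -> float:
    """k = 3 k_B T / Var(d) with the population variance over frames."""
    var = float(np.var(np.asarray(d_series, dtype=float)))
    kbt = KB_KCAL * temperature
    if var <= 0:
        return K_CAP
    return min(3.0 * kbt / var, K_CAP)


def force_constant_profile(
    ensemble: StructuralEnsemble,
    mode: str = "all-atom",
    temperature: float = 300.0,
) -> ForceConstantProfile:
    """Residue force-constant profile.

    ``mode="all-atom"`` computes an atom-level k for every heavy atom (mean
    distance to heavy atoms of other residues) and averages over the
    residue's atoms; ``mode="CA"`` uses Cα-only distances with sequence
    neighbours excluded. Zero-variance units are capped at ``K_CAP``.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames")
    kbt = KB_KCAL * temperature
    values: dict[ResidueKey, float] = {}

    if mode == "CA":
        keys, ca = _ca_positions(ensemble)
        n = len(keys)
        if n < 4:
            raise ValueError("need at least 4 residues in CA mode")
        dist = np.linalg.norm(ca[:, :, None, :] - ca[:, None, :, :], axis=-1)
        for i, key in enumerate(keys):
            partners = [j for j in range(n) if abs(j - i) > 1]
            d = dist[:, i, partners].mean(axis=1)
            values[key] = force_constant_from_series(d, temperature)
    elif mode == "all-atom":
        heavy = [a for a in ensemble.topology if a.is_heavy]
        coords = ensemble.frames[:, [a.atom_index for a in heavy], :]
        keys_order: list[ResidueKey] = []
        for a in heavy:
            if a.residue_key not in keys_order:
                keys_order.append(a.residue_key)
        res_index = {k: i for i, k in enumerate(keys_order)}
        res_ids = np.array([res_index[a.residue_key] for a in heavy])
        dist = np.linalg.norm(
            coords[:, :, None, :] - coords[:, None, :, :], axis=-1
        )  # (F, A, A)
        same = res_ids[:, None] == res_ids[None, :]
        k_atom = np.empty(len(heavy))
        for ai in range(len(heavy)):
            partners = ~same[ai]
            d = dist[:, ai, partners].mean(axis=1)
            var = float(np.var(d))
            k_atom[ai] = min(3.0 * kbt / var, K_CAP) if var > 0 else K_CAP
        if np.any(k_atom >= K_CAP):
            warnings.warn("zero-variance atoms: force constant capped")
        for key in keys_order:
            sel = res_ids == res_index[key]
            values[key] = float(k_atom[sel].mean())
    else:
        raise ValueError(f"unknown mode '{mode}'")

    return ForceConstantProfile(values, temperature, kbt, mode)


def detect_profile_peaks(
    profile: Mapping[ResidueKey, float] | Sequence[float],
    window: int = 3,
    min_prominence: float = 0.5,
) -> PeakSet:
    """Local maxima of a per-residue profile.

    A residue is a peak if its value strictly exceeds every other value
    within ±``window`` positions and is at least ``min_prominence`` of the
    profile maximum.
    """
    if isinstance(profile, Mapping):
        keys = list(profile.keys())
        vals = np.array([profile[k] for k in keys], dtype=float)
    else:
        vals = np.asarray(profile, dtype=float)
        keys = [("A", i + 1, "") for i in range(len(vals))]
    if len(vals) < window:
        raise ValueError("profile shorter than window")
    vmax = vals.max() if len(vals) else 0.0
    peaks: list[ResidueKey] = []
    heights: list[float] = []
    for i, v in enumerate(vals):
        if i == 0 or i == len(vals) - 1:
            continue  # endpoints have no flanking window on one side
        if vmax > 0 and v < min_prominence * vmax:
            continue
        lo, hi = max(0, i - window), min(len(vals), i + window + 1)
        neighbours = np.concatenate([vals[lo:i], vals[i + 1 : hi]])
        if neighbours.size and v > neighbours.max():
            peaks.append(keys[i])
            heights.append(float(v))
    return PeakSet(peaks, heights, window, min_prominence)
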