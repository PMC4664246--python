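"""Ensemble-averaged residue depth and HDX-protection comparison.

Residue depth (RD) measures how far a residue's heavy atoms sit below the
solvent-accessible surface: atom depth is the distance from the atom to the
nearest exposed surface point minus the atom's own accessible radius
(clamped at 0), so surface atoms score ≈ 0 and buried atoms score their
burial distance. The surface is sampled deterministically with a Fibonacci
lattice on each atom's solvent-accessible sphere (radius r_vdw + probe);
a point is exposed iff it lies outside every other atom's accessible
sphere. Differential depth ΔRD = RD_A − RD_B maps state-dependent
protection and is compared sign-wise with hydrogen-deuterium-exchange (HDX)
peak-intensity ratios.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .structure_io import (
    ConsistencyError,
    ResidueKey,
    Structure,
    StructuralEnsemble,
    ValidationError,
)

__all__ = [
    "VDW_RADII",
    "DEFAULT_PROBE",
    "DepthProfile",
    "HdxTable",
    "fibonacci_sphere",
    "surface_points",
    "residue_depth_profile",
    "differential_depth",
    "read_hdx_table",
    "hdx_sign_agreement",
]

#: built-in van der Waals radii (Å) per element
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4


def atom_radii(structure: Structure, heavy_only: bool = True) -> np.ndarray:
    radii = []
    for a in structure.atoms:
        radii.append(VDW_RADII.get(a.element.upper(), _DEFAULT_RADIUS))
    return np.asarray(radii)


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere sampling (no RNG)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _heavy_structure(structure: Structure) -> Structure:
    return structure.select(structure.heavy_mask())


def surface_points(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    points_per_atom: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Exposed solvent-accessible surface points of the heavy atoms.

    Returns ``(points, owner)`` where ``owner[p]`` is the index of the heavy
    atom whose accessible sphere carries point ``p``. A point is exposed iff
    it lies outside every other atom's accessible sphere (strictly inside
    removes it; tangency keeps it).
    """
    s = _heavy_structure(structure)
    if s.n_atoms == 0:
        raise ValueError("no heavy atoms")
    coords = s.coordinates
    radii = atom_radii(s) + probe
    unit = fibonacci_sphere(points_per_atom)
    pts_out = []
    owner_out = []
    # neighbour lists: only atoms whose accessible spheres can overlap
    rmax = radii.max()
    for i in range(s.n_atoms):
        pts = coords[i] + radii[i] * unit
        d_atoms = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.flatnonzero((d_atoms < radii[i] + rmax) & (d_atoms > 0))
        exposed = np.ones(len(pts), dtype=bool)
        for j in neigh:
            dj = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= dj >= radii[j] - 1e-9
        if exposed.any():
            pts_out.append(pts[exposed])
            owner_out.append(np.full(int(exposed.sum()), i))
    if not pts_out:
        raise RuntimeError("no exposed surface points (fully enclosed system?)")
    return np.concatenate(pts_out), np.concatenate(owner_out)


@dataclasses.dataclass
class DepthProfile:
    """Per-residue mean depth (Å), averaged over heavy atoms and snapshots."""

    values: dict[ResidueKey, float]
    probe: float
    points_per_atom: int


def _frame_atom_depths(
    structure: Structure, probe: float, points_per_atom: int
) -> tuple[list[ResidueKey], np.ndarray]:
    s = _heavy_structure(structure)
    pts, _ = surface_points(s, probe, points_per_atom)
    radii = atom_radii(s) + probe
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    dmin, _ = tree.query(s.coordinates)
    depths = np.clip(dmin - radii, 0.0, None)
    return [a.residue_key for a in s.atoms], depths


def residue_depth_profile(
    ensemble: StructuralEnsemble | Structure,
    probe: float = DEFAULT_PROBE,
    points_per_atom: int = 256,
) -> DepthProfile:
    """Ensemble-averaged residue depth: atom depths averaged over each
    residue's heavy atoms, then over snapshots."""
    if isinstance(ensemble, Structure):
        ensemble = StructuralEnsemble(ensemble.atoms, ensemble.coordinates[None])
    sums: dict[ResidueKey, float] = {}
    for f in range(ensemble.n_frames):
        keys, depths = _frame_atom_depths(ensemble.structure(f), probe, points_per_atom)
        per_res: dict[ResidueKey, list[float]] = {}
        for k, d in zip(keys, depths):
            per_res.setdefault(k, []).append(d)
        for k, v in per_res.items():
            sums[k] = sums.get(k, 0.0) + float(np.mean(v))
    values = {k: v / ensemble.n_frames for k, v in sums.items()}
    return DepthProfile(values, probe, points_per_atom)


def differential_depth(
    profile_a: DepthProfile | Mapping[ResidueKey, float],
    profile_b: DepthProfile | Mapping[ResidueKey, float],
) -> dict[ResidueKey, float]:
    """ΔRD = RD_A − RD_B per residue; positive means more buried in A."""
    a = profile_a.values if isinstance(profile_a, DepthProfile) else dict(profile_a)
    b = profile_b.values if isinstance(profile_b, DepthProfile) else dict(profile_b)
    if set(a) != set(b):
        raise ConsistencyError("profiles cover different residues")
    return {k: a[k] - b[k] for k in a}


@dataclasses.dataclass
class HdxTable:
    """HDX peak-intensity ratios with two one-sided protection thresholds."""

    ratios: dict[ResidueKey, float]
    protected_a_above: float = 1.1
    protected_b_below: float = 1.0

    def __post_init__(self) -> None:
        for k, r in self.ratios.items():
            if r <= 0:
                raise ValidationError(f"HDX ratio must be positive ({k}: {r})")

    def classify(self, key: ResidueKey) -> str | None:
        """"A", "B", or None for the indeterminate band."""
        r = self.ratios[key]
        if r > self.protected_a_above:
            return "A"
        if r < self.protected_b_below:
            return "B"
        return None


def read_hdx_table(path: str | Path, chain: str = "A") -> HdxTable:
    """Read a 2-column TSV (residue number, peak ratio)."""
    df = pd.read_csv(path, sep="\t")
    ratios = {
        (chain, int(row.iloc[0]), ""): float(row.iloc[1]) for _, row in df.iterrows()
    }
    return HdxTable(ratios)


def hdx_sign_agreement(
    delta: Mapping[ResidueKey, float],
    hdx: HdxTable,
) -> dict:
    """Sign agreement between differential depth and HDX protection.

    A residue predicted protected-in-A (ΔRD > 0) agrees with an HDX ratio
    above the A-threshold; ΔRD < 0 agrees with a ratio below the
    B-threshold. Ratios in the indeterminate band and ΔRD exactly 0 are
    excluded from the denominator.
    """
    overlap = [k for k in delta if k in hdx.ratios]
    if not overlap:
        raise ValidationError("no residues shared between ΔRD profile and HDX table")
    n_agree = n_disagree = n_excluded = 0
    contingency = {("A", "A"): 0, ("A", "B"): 0, ("B", "A"): 0, ("B", "B"): 0}
    for k in overlap:
        hdx_class = hdx.classify(k)
        d = delta[k]
        pred = "A" if d > 0 else ("B" if d < 0 else None)
        if hdx_class is None or pred is None:
            n_excluded += 1
            continue
        contingency[(pred, hdx_class)] += 1
        if pred == hdx_class:
            n_agree += 1
        else:
            n_disagree += 1
    total = n_agree + n_disagree
    return {
        "n_overlap": len(overlap),
        "n_agree": n_agree,
        "n_disagree": n_disagree,
        "n_excluded": n_excluded,
        "agreement_fraction": (n_agree / total) if total else float("nan"),
        "contingency": contingency,
    }
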