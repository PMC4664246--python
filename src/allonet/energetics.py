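"""MM-GBSA-style binding free energy aggregation and alanine scanning.

The binding free energy of a complex is assembled from per-snapshot terms

    ΔG_bind = ⟨ΔG_MM⟩ + ⟨ΔG_solv⟩ − ⟨TΔS⟩

with ΔG_MM the gas-phase molecular-mechanics difference (complex − receptor
− ligand; in the single-trajectory protocol the intramolecular terms cancel
exactly), ΔG_solv = ΔG_np + ΔG_elec,solv, the nonpolar part σ·SASA with
σ = 0.0072 kcal·mol⁻¹·Å⁻², and the entropy entered as a user-supplied
scalar. Energies come from a pluggable backend; the built-in pairwise
backend uses Lennard-Jones 12-6 plus Coulomb with a distance-dependent
dielectric ε(r) = 4r. Absolute values are not comparable to a full
force-field/GB treatment — the machinery, bookkeeping and alanine-scan
logic are the point.

Computational alanine scanning truncates a residue's side chain beyond Cβ
on every snapshot of the wild-type ensemble and recomputes
ΔΔG = ΔG_mut − ΔG_WT with the same backend.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .residue_depth import DEFAULT_PROBE, atom_radii, fibonacci_sphere
from .structure_io import (
    ResidueKey,
    Structure,
    StructuralEnsemble,
    ValidationError,
)

__all__ = [
    "SIGMA_NP",
    "COULOMB_KCAL",
    "EnergyTerms",
    "SnapshotEnergyTable",
    "BindingFreeEnergy",
    "AlaScanResult",
    "PairParams",
    "shrake_sasa",
    "nonpolar_solvation",
    "simple_pair_backend",
    "snapshot_energy_table",
    "mmgbsa_aggregate",
    "alanine_scan",
]

#: nonpolar solvation surface-tension coefficient, kcal·mol⁻¹·Å⁻²
SIGMA_NP = 0.0072
#: Coulomb constant, kcal·Å·mol⁻¹·e⁻²
COULOMB_KCAL = 332.06

TERM_NAMES = [
    "E_bond",
    "E_vdw",
    "E_elec",
    "dE_vdw",
    "dE_elec",
    "dG_np_solv",
    "dG_elec_solv",
    "TdS",
]


@dataclasses.dataclass
class EnergyTerms:
    """Per-snapshot energy terms (kcal/mol)."""

    E_bond: float = 0.0
    E_vdw: float = 0.0
    E_elec: float = 0.0
    dE_vdw: float = 0.0
    dE_elec: float = 0.0
    dG_np_solv: float = 0.0
    dG_elec_solv: float = 0.0
    TdS: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in TERM_NAMES}


@dataclasses.dataclass
class SnapshotEnergyTable:
    """One EnergyTerms row per snapshot for complex, receptor and ligand."""

    complex: pd.DataFrame
    receptor: pd.DataFrame
    ligand: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.complex)
        if len(self.receptor) != n or len(self.ligand) != n:
            raise ValidationError("partitions have different snapshot counts")

    @property
    def n_snapshots(self) -> int:
        return len(self.complex)


@dataclasses.dataclass
class BindingFreeEnergy:
    """ΔG_bind with its additive components (kcal/mol)."""

    dG_bind: float
    dG_mm: float
    dG_solv: float
    TdS: float
    n_snapshots: int
    components: dict[str, float]


@dataclasses.dataclass
class AlaScanResult:
    """Per-residue ΔΔG_bind with component breakdown (kcal/mol)."""

    ddG: dict[ResidueKey, float]
    components: dict[ResidueKey, dict[str, float]]
    notes: dict[ResidueKey, str]


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def shrake_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    points_per_atom: int = 256,
) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area (Ų) by deterministic
    Fibonacci-lattice sampling over the heavy atoms.

    Returns (per-atom SASA over heavy atoms, total SASA).
    """
    s = structure.select(structure.heavy_mask())
    if s.n_atoms == 0:
        raise ValueError("no heavy atoms")
    coords = s.coordinates
    radii = atom_radii(s) + probe
    unit = fibonacci_sphere(points_per_atom)
    areas = np.zeros(s.n_atoms)
    rmax = radii.max()
    for i in range(s.n_atoms):
        pts = coords[i] + radii[i] * unit
        d_atoms = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.flatnonzero((d_atoms < radii[i] + rmax) & (d_atoms > 0))
        exposed = np.ones(points_per_atom, dtype=bool)
        for j in neigh:
            dj = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= dj >= radii[j] - 1e-9
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.sum() / points_per_atom
    return areas, float(areas.sum())


def nonpolar_solvation(sasa: float, sigma: float = SIGMA_NP) -> float:
    """ΔG_np = σ·SASA (kcal/mol)."""
    if sasa < 0:
        raise ValueError("SASA must be >= 0")
    return sigma * sasa


# ---------------------------------------------------------------------------
# Pairwise energy backend
# ---------------------------------------------------------------------------

#: generic per-element Lennard-Jones parameters (σ_LJ Å, ε_LJ kcal/mol)
_DEFAULT_LJ: dict[str, tuple[float, float]] = {
    "C": (3.40, 0.105),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.56, 0.250),
    "H": (2.50, 0.030),
    "P": (3.74, 0.200),
}
_FALLBACK_LJ = (3.40, 0.105)


@dataclasses.dataclass
class PairParams:
    """Per-atom nonbonded parameters for the pairwise backend."""

    charges: np.ndarray  # e, per atom of the full topology
    lj_sigma: np.ndarray  # Å
    lj_epsilon: np.ndarray  # kcal/mol

    @classmethod
    def generic(
        cls,
        structure: Structure,
        charges: Mapping[ResidueKey, Mapping[str, float]] | np.ndarray | None = None,
    ) -> "PairParams":
        """Element-based LJ parameters and zero (or supplied) charges."""
        n = structure.n_atoms
        sig = np.empty(n)
        eps = np.empty(n)
        for a in structure.atoms:
            s, e = _DEFAULT_LJ.get(a.element.upper(), _FALLBACK_LJ)
            sig[a.atom_index] = s
            eps[a.atom_index] = e
        if charges is None:
            q = np.zeros(n)
        elif isinstance(charges, np.ndarray):
            q = np.asarray(charges, dtype=float)
        else:
            q = np.zeros(n)
            for a in structure.atoms:
                q[a.atom_index] = charges.get(a.residue_key, {}).get(a.atom_name, 0.0)
        return cls(q, sig, eps)


def _nonbonded_pairs_mask(structure: Structure, atom_idx: np.ndarray) -> np.ndarray:
    """Pairs excluded: within the same residue or between sequence-adjacent
    residues (crude bonded-exclusion for rigid snapshots)."""
    keys = structure.residue_keys()
    order = {k: i for i, k in enumerate(keys)}
    res = np.array([order[structure.atoms[i].residue_key] for i in atom_idx])
    num = np.array([structure.atoms[i].residue_key[1] for i in atom_idx])
    chain = np.array([structure.atoms[i].residue_key[0] for i in atom_idx])
    same_res = res[:, None] == res[None, :]
    adjacent = (np.abs(num[:, None] - num[None, :]) == 1) & (
        chain[:, None] == chain[None, :]
    )
    allowed = ~(same_res | adjacent)
    return np.triu(allowed, k=1)


def simple_pair_backend(
    structure: Structure,
    coordinates: np.ndarray,
    atom_indices: np.ndarray,
    params: PairParams,
    probe: float = DEFAULT_PROBE,
    points_per_atom: int = 64,
    elec_solv_hook: Callable[[np.ndarray], float] | None = None,
) -> EnergyTerms:
    """Pairwise LJ + screened-Coulomb energy of one partition of a frame.

    ``atom_indices`` select the partition's atoms from the full topology;
    ``coordinates`` are the full frame. E_bond is fixed 0 (rigid snapshots);
    electrostatics use ε(r) = 4r; ΔG_np comes from the partition's SASA and
    ΔG_elec_solv from the optional hook (default 0).
    """
    atom_idx = np.asarray(atom_indices, dtype=int)
    heavy = np.array([structure.atoms[i].is_heavy for i in atom_idx])
    coords = np.asarray(coordinates, dtype=float)[atom_idx]
    mask = _nonbonded_pairs_mask(structure, atom_idx)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    with np.errstate(divide="ignore"):
        ii, jj = np.nonzero(mask & (d > 0))
    sig = 0.5 * (params.lj_sigma[atom_idx[ii]] + params.lj_sigma[atom_idx[jj]])
    eps = np.sqrt(params.lj_epsilon[atom_idx[ii]] * params.lj_epsilon[atom_idx[jj]])
    r = d[ii, jj]
    sr6 = (sig / r) ** 6
    e_vdw = float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    q = params.charges
    e_elec = float(
        np.sum(COULOMB_KCAL * q[atom_idx[ii]] * q[atom_idx[jj]] / (4.0 * r * r))
    )

    sub = Structure(
        [dataclasses.replace(structure.atoms[i], atom_index=n) for n, i in enumerate(atom_idx)],
        coords,
    )
    heavy_sub = sub.select(sub.heavy_mask())
    if heavy_sub.n_atoms:
        _, sasa = shrake_sasa(heavy_sub, probe, points_per_atom)
    else:
        sasa = 0.0
    dg_np = nonpolar_solvation(sasa)
    dg_elec_solv = float(elec_solv_hook(coords)) if elec_solv_hook else 0.0
    return EnergyTerms(
        E_bond=0.0,
        E_vdw=e_vdw,
        E_elec=e_elec,
        dG_np_solv=dg_np,
        dG_elec_solv=dg_elec_solv,
    )


# ---------------------------------------------------------------------------
# Tables and aggregation
# ---------------------------------------------------------------------------

Backend = Callable[[Structure, np.ndarray, np.ndarray], EnergyTerms]


def _partition_indices(
    structure: Structure, selection: Sequence[ResidueKey]
) -> np.ndarray:
    wanted = set(selection)
    return np.asarray(
        [a.atom_index for a in structure.atoms if a.residue_key in wanted], dtype=int
    )


def snapshot_energy_table(
    ensemble: StructuralEnsemble,
    receptor_selection: Sequence[ResidueKey],
    ligand_selection: Sequence[ResidueKey],
    backend: Backend,
) -> SnapshotEnergyTable:
    """Backend energies per frame for complex, receptor-alone and
    ligand-alone, all on the same frame coordinates (single-trajectory
    protocol, no re-minimization: intramolecular terms cancel exactly)."""
    rec, lig = set(receptor_selection), set(ligand_selection)
    if rec & lig:
        raise ValidationError("receptor and ligand selections overlap")
    s0 = ensemble.structure(0)
    keys = set(s0.residue_keys())
    if (rec | lig) - keys:
        raise ValidationError("selection references residues outside the complex")
    rec_idx = _partition_indices(s0, sorted(rec))
    lig_idx = _partition_indices(s0, sorted(lig))
    all_idx = np.sort(np.concatenate([rec_idx, lig_idx]))
    rows: dict[str, list[dict[str, float]]] = {"complex": [], "receptor": [], "ligand": []}
    for f in range(ensemble.n_frames):
        frame = ensemble.frames[f]
        rows["complex"].append(backend(s0, frame, all_idx).as_dict())
        rows["receptor"].append(backend(s0, frame, rec_idx).as_dict())
        rows["ligand"].append(backend(s0, frame, lig_idx).as_dict())
    return SnapshotEnergyTable(
        pd.DataFrame(rows["complex"]),
        pd.DataFrame(rows["receptor"]),
        pd.DataFrame(rows["ligand"]),
    )


def mmgbsa_aggregate(table: SnapshotEnergyTable, TdS: float = 0.0) -> BindingFreeEnergy:
    """Combine per-snapshot terms into ΔG_bind (kcal/mol).

    Per frame, ΔG_MM = ΔE_intra + ΔE_vdw + ΔE_elec with the Δ taken
    complex − receptor − ligand; ΔG_solv likewise; the reported value is the
    snapshot mean, and ΔG_bind = ⟨ΔG_MM⟩ + ⟨ΔG_solv⟩ − TΔS holds exactly.
    """
    if table.n_snapshots == 0:
        raise ValidationError("empty energy table")
    diff = {
        col: table.complex[col] - table.receptor[col] - table.ligand[col]
        for col in ("E_bond", "E_vdw", "E_elec", "dG_np_solv", "dG_elec_solv")
    }
    dE_intra = diff["E_bond"].mean()
    dE_vdw = diff["E_vdw"].mean()
    dE_elec = diff["E_elec"].mean()
    dg_mm = float(dE_intra + dE_vdw + dE_elec)
    dg_solv = float(diff["dG_np_solv"].mean() + diff["dG_elec_solv"].mean())
    dg_bind = dg_mm + dg_solv - TdS
    return BindingFreeEnergy(
        dG_bind=dg_bind,
        dG_mm=dg_mm,
        dG_solv=dg_solv,
        TdS=TdS,
        n_snapshots=table.n_snapshots,
        components={
            "dE_intra": float(dE_intra),
            "dE_vdw": float(dE_vdw),
            "dE_elec": float(dE_elec),
            "dG_np": float(diff["dG_np_solv"].mean()),
            "dG_elec_solv": float(diff["dG_elec_solv"].mean()),
        },
    )


# ---------------------------------------------------------------------------
# Alanine scanning
# ---------------------------------------------------------------------------

_SCAN_KEEP = {"N", "CA", "C", "O", "OXT", "CB"}
_NO_SIDECHAIN = {"GLY", "ALA"}


def _truncate_to_ala(ensemble: StructuralEnsemble, residue: ResidueKey) -> StructuralEnsemble:
    keep = [
        a.atom_index
        for a in ensemble.topology
        if a.residue_key != residue or a.atom_name in _SCAN_KEEP or not a.is_heavy
    ]
    keep_arr = np.asarray(keep, dtype=int)
    topo = [
        dataclasses.replace(ensemble.topology[i], atom_index=n)
        for n, i in enumerate(keep_arr)
    ]
    return StructuralEnsemble(topo, ensemble.frames[:, keep_arr, :], ensemble.frame_labels)


def alanine_scan(
    ensemble: StructuralEnsemble,
    residues: Sequence[ResidueKey],
    receptor_selection: Sequence[ResidueKey],
    ligand_selection: Sequence[ResidueKey],
    backend_factory: Callable[[StructuralEnsemble], Backend],
    TdS: float = 0.0,
) -> AlaScanResult:
    """Computational alanine scanning by Cβ truncation.

    For each residue, every snapshot of the wild-type ensemble is rebuilt
    with heavy side-chain atoms beyond Cβ removed, the energy table is
    recomputed with the same backend, and ΔΔG = ΔG_mut − ΔG_WT. Glycine and
    alanine report 0 with a note. ``backend_factory`` builds a backend bound
    to a (possibly truncated) topology so parameters track atom removal.
    """
    rec, lig = set(receptor_selection), set(ligand_selection)
    wt_table = snapshot_energy_table(
        ensemble, sorted(rec), sorted(lig), backend_factory(ensemble)
    )
    wt = mmgbsa_aggregate(wt_table, TdS)
    ddg: dict[ResidueKey, float] = {}
    components: dict[ResidueKey, dict[str, float]] = {}
    notes: dict[ResidueKey, str] = {}
    types = ensemble.structure(0).residue_types()
    for res in residues:
        if res not in rec and res not in lig:
            raise ValidationError(f"residue {res} is in neither selection")
        if types.get(res) in _NO_SIDECHAIN:
            ddg[res] = 0.0
            components[res] = {k: 0.0 for k in ("dE_vdw", "dE_elec", "dG_np", "dG_elec_solv")}
            notes[res] = f"{types.get(res)}: no side chain beyond Cβ"
            continue
        mut_ens = _truncate_to_ala(ensemble, res)
        mut_table = snapshot_energy_table(
            mut_ens, sorted(rec), sorted(lig), backend_factory(mut_ens)
        )
        mut = mmgbsa_aggregate(mut_table, TdS)
        ddg[res] = mut.dG_bind - wt.dG_bind
        components[res] = {
            k: mut.components[k] - wt.components[k] for k in wt.components
        }
        notes[res] = ""
    return AlaScanResult(ddg, components, notes)


def make_pair_backend_factory(
    charges: Mapping[ResidueKey, Mapping[str, float]] | None = None,
    points_per_atom: int = 64,
    include_solvation: bool = True,
) -> Callable[[StructuralEnsemble], Backend]:
    """Factory for the built-in pairwise backend, rebinding parameters to
    each (possibly truncated) topology.

    ``include_solvation=False`` drops the σ·SASA nonpolar term, leaving a
    pure gas-phase molecular-mechanics backend (useful when solvation is
    supplied externally or for decomposition analyses).
    """

    def factory(ensemble: StructuralEnsemble) -> Backend:
        s0 = ensemble.structure(0)
        params = PairParams.generic(s0, charges)

        def backend(structure: Structure, frame: np.ndarray, atom_idx: np.ndarray) -> EnergyTerms:
            terms = simple_pair_backend(
                structure, frame, atom_idx, params, points_per_atom=points_per_atom
            )
            if not include_solvation:
                terms = dataclasses.replace(terms, dG_np_solv=0.0, dG_elec_solv=0.0)
            return terms

        return backend

    return factory
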