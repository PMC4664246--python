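"""Structure and ensemble I/O.

Defines the residue/atom indexing contract shared by every analysis module:
residues are identified by ``(chain, resnum, icode)`` keys, atoms by a dense
0-based index, and a :class:`StructuralEnsemble` is an ordered stack of
coordinate frames over one fixed atom table.

PDB reading/writing stands on :mod:`biotite.structure.io.pdb`; waters and
hetero records are stripped on load by default and alternate locations are
resolved to the highest-occupancy conformer (ties broken alphabetically).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

__all__ = [
    "AtomRecord",
    "Structure",
    "StructuralEnsemble",
    "DomainAnnotation",
    "FormatError",
    "ConsistencyError",
    "ValidationError",
    "BACKBONE_ATOMS",
    "read_structure",
    "read_ensemble",
    "write_ensemble",
    "parse_domain_annotation",
    "write_profile",
    "read_profile",
    "write_edge_list",
    "read_edge_list",
]

#: Protein backbone heavy-atom names (OXT counts as backbone terminus).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class FormatError(ValueError):
    """Input file could not be interpreted in the expected format."""


class ConsistencyError(ValueError):
    """Frames/topologies that must agree do not."""


class ValidationError(ValueError):
    """Semantically invalid configuration or annotation."""


ResidueKey = tuple[str, int, str]


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology."""

    atom_index: int
    atom_name: str
    element: str
    residue_key: ResidueKey
    residue_type: str
    is_backbone: bool
    is_heavy: bool


@dataclasses.dataclass
class Structure:
    """A single conformation: an ordered atom table plus coordinates in Å."""

    atoms: list[AtomRecord]
    coordinates: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise ConsistencyError(
                f"coordinate shape {self.coordinates.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ConsistencyError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_keys(self) -> list[ResidueKey]:
        """Unique residue keys in topology order."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_types(self) -> dict[ResidueKey, str]:
        out: dict[ResidueKey, str] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, a.residue_type)
        return out

    def atom_indices_by_residue(self) -> dict[ResidueKey, np.ndarray]:
        groups: dict[ResidueKey, list[int]] = {}
        for a in self.atoms:
            groups.setdefault(a.residue_key, []).append(a.atom_index)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def select(self, mask: np.ndarray) -> "Structure":
        """Sub-structure of the atoms where ``mask`` is True (reindexed)."""
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        atoms = [
            dataclasses.replace(self.atoms[i], atom_index=new)
            for new, i in enumerate(idx)
        ]
        return Structure(atoms, self.coordinates[idx])

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def ca_mask(self) -> np.ndarray:
        return np.array(
            [a.atom_name == "CA" and a.is_heavy for a in self.atoms], dtype=bool
        )


@dataclasses.dataclass
class StructuralEnsemble:
    """Ordered coordinate snapshots over one fixed atom table."""

    topology: list[AtomRecord]
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ConsistencyError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ConsistencyError("ensemble needs at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise ConsistencyError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology size {len(self.topology)}"
            )
        if self.frame_labels is not None and len(self.frame_labels) != len(self.frames):
            raise ConsistencyError("frame_labels length mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def structure(self, frame: int = 0) -> Structure:
        return Structure(self.topology, self.frames[frame].copy())

    def residue_keys(self) -> list[ResidueKey]:
        return self.structure(0).residue_keys()

    @classmethod
    def from_structures(
        cls,
        structures: Sequence[Structure],
        frame_labels: list[str] | None = None,
    ) -> "StructuralEnsemble":
        if not structures:
            raise ConsistencyError("no structures given")
        n0 = structures[0].n_atoms
        for s in structures[1:]:
            if s.n_atoms != n0:
                raise ConsistencyError(
                    f"frame atom counts differ: {s.n_atoms} vs {n0}"
                )
        frames = np.stack([s.coordinates for s in structures])
        return cls(structures[0].atoms, frames, frame_labels)


@dataclasses.dataclass
class DomainAnnotation:
    """Named, non-overlapping residue segments (e.g. subdomains IA, IB, SBD-β)."""

    segments: dict[str, set[ResidueKey]]
    colors: dict[str, str] = dataclasses.field(default_factory=dict)

    def segment_of(self, key: ResidueKey) -> str | None:
        for name, members in self.segments.items():
            if key in members:
                return name
        return None


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

_HYDROGEN = {"H", "D"}


def _atom_array_to_structure(arr: bst.AtomArray) -> Structure:
    atoms: list[AtomRecord] = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip().upper()
        name = str(arr.atom_name[i]).strip()
        icode = str(arr.ins_code[i]).strip() if "ins_code" in arr.get_annotation_categories() else ""
        key = (str(arr.chain_id[i]).strip(), int(arr.res_id[i]), icode)
        atoms.append(
            AtomRecord(
                atom_index=i,
                atom_name=name,
                element=element or name[:1],
                residue_key=key,
                residue_type=str(arr.res_name[i]).strip(),
                is_backbone=name in BACKBONE_ATOMS,
                is_heavy=element not in _HYDROGEN,
            )
        )
    return Structure(atoms, np.asarray(arr.coord, dtype=float))


def _load_pdb(path: str | Path) -> bst.AtomArrayStack:
    try:
        pdb = bpdb.PDBFile.read(str(path))
        stack = pdb.get_structure(altloc="occupancy", extra_fields=["occupancy"])
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise FormatError(f"{path}: no ATOM records")
    return stack


def _strip(stack: bst.AtomArrayStack, keep_hetero: bool) -> bst.AtomArrayStack:
    mask = ~bst.filter_solvent(stack)
    if not keep_hetero:
        mask &= ~stack.hetero
    if not mask.any():
        raise FormatError("no atoms left after removing waters/hetero records")
    return stack[..., mask]


def read_structure(
    path: str | Path,
    model: int | None = None,
    keep_hetero: bool = False,
) -> Structure:
    """Read one model of a PDB file.

    ``model`` is 1-based as in the PDB format; default is the first model.
    Waters are always removed; other hetero records are dropped unless
    ``keep_hetero``. Alternate locations keep the highest-occupancy conformer.
    """
    stack = _strip(_load_pdb(path), keep_hetero)
    n_models = stack.stack_depth()
    idx = 0 if model is None else model - 1
    if idx < 0 or idx >= n_models:
        raise FileNotFoundError(
            f"model {model} not present ({n_models} models in {path})"
        )
    return _atom_array_to_structure(stack[idx])


def read_ensemble(path: str | Path, keep_hetero: bool = False) -> StructuralEnsemble:
    """Read a multi-model PDB as an ensemble (frames in file order)."""
    stack = _strip(_load_pdb(path), keep_hetero)
    structures = [_atom_array_to_structure(stack[i]) for i in range(stack.stack_depth())]
    topo0 = [(a.atom_name, a.residue_key) for a in structures[0].atoms]
    for k, s in enumerate(structures[1:], start=2):
        if [(a.atom_name, a.residue_key) for a in s.atoms] != topo0:
            raise ConsistencyError(f"model {k} topology differs from model 1")
    return StructuralEnsemble.from_structures(structures)


def _structure_to_atom_array(structure: Structure) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(structure.coordinates, dtype=np.float32)
    arr.chain_id = np.array([a.residue_key[0] for a in structure.atoms])
    arr.res_id = np.array([a.residue_key[1] for a in structure.atoms])
    arr.ins_code = np.array([a.residue_key[2] for a in structure.atoms])
    arr.res_name = np.array([a.residue_type for a in structure.atoms])
    arr.atom_name = np.array([a.atom_name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_ensemble(ensemble: StructuralEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file."""
    arrays = [
        _structure_to_atom_array(ensemble.structure(i)) for i in range(ensemble.n_frames)
    ]
    stack = bst.stack(arrays)
    pdb = bpdb.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Domain annotations
# ---------------------------------------------------------------------------


def _expand_range(spec: str, chain: str) -> set[ResidueKey]:
    keys: set[ResidueKey] = set()
    for part in str(spec).split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo_s, hi_s = part.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(part)
        if hi < lo:
            raise ValidationError(f"range '{part}' is reversed")
        for r in range(lo, hi + 1):
            keys.add((chain, r, ""))
    return keys


def parse_domain_annotation(
    source: str | Path | Mapping[str, str],
    topology_keys: Iterable[ResidueKey] | None = None,
    chain: str = "A",
    strict: bool = True,
    colors: Mapping[str, str] | None = None,
) -> DomainAnnotation:
    """Parse a segment-name → residue-range mapping into a DomainAnnotation.

    ``source`` is either a mapping like ``{"IA": "1-10", "IB": "11-20"}`` or
    the path of a YAML file containing one. Ranges may list several
    comma-separated spans. Overlapping segments are rejected; residues absent
    from ``topology_keys`` raise in strict mode and are dropped with a
    warning otherwise.
    """
    import warnings

    if isinstance(source, (str, Path)):
        import yaml

        with open(source) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"{source}: expected a name → range mapping")
    else:
        data = dict(source)

    segments: dict[str, set[ResidueKey]] = {}
    seen: dict[ResidueKey, str] = {}
    known = set(topology_keys) if topology_keys is not None else None
    for name, rng in data.items():
        keys = _expand_range(rng, chain)
        for k in keys:
            if k in seen:
                raise ValidationError(
                    f"segment '{name}' overlaps '{seen[k]}' at residue {k}"
                )
            seen[k] = str(name)
        if known is not None:
            missing = keys - known
            if missing:
                if strict:
                    raise ValidationError(
                        f"segment '{name}' references unknown residues: "
                        f"{sorted(missing)[:5]}"
                    )
                warnings.warn(
                    f"segment '{name}': dropping {len(missing)} unknown residues"
                )
                keys &= known
        segments[str(name)] = keys
    return DomainAnnotation(segments, dict(colors or {}))


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = ["chain", "resnum", "icode", "restype", "value"]


def write_profile(
    profile: Mapping[ResidueKey, float],
    path: str | Path,
    residue_types: Mapping[ResidueKey, str] | None = None,
    value_name: str = "value",
) -> None:
    """Write a per-residue numeric series as TSV.

    Non-finite values are written as the tokens ``inf``/``-inf``/``nan`` and
    recovered exactly on read-back.
    """
    rows = []
    for key, value in profile.items():
        chain, resnum, icode = key
        restype = (residue_types or {}).get(key, "UNK")
        rows.append((chain, resnum, icode or ".", restype, repr(float(value))))
    df = pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
    df = df.rename(columns={"value": value_name})
    df.to_csv(path, sep="\t", index=False)


def read_profile(path: str | Path) -> dict[ResidueKey, float]:
    """Read a profile TSV written by :func:`write_profile`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[ResidueKey, float] = {}
    value_col = df.columns[-1]
    for _, row in df.iterrows():
        icode = "" if row["icode"] == "." else row["icode"]
        key = (row["chain"], int(row["resnum"]), icode)
        out[key] = float(row[value_col])
    return out


def write_edge_list(
    edges: Iterable[tuple[ResidueKey, ResidueKey, float, float]],
    path: str | Path,
) -> None:
    """Write (residue A, residue B, interaction %, weight) rows as TSV."""
    rows = []
    for a, b, strength, weight in edges:
        rows.append(
            (a[0], a[1], a[2] or ".", b[0], b[1], b[2] or ".",
             repr(float(strength)), repr(float(weight)))
        )
    df = pd.DataFrame(
        rows,
        columns=["chainA", "resA", "icodeA", "chainB", "resB", "icodeB",
                 "I_ij", "weight"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[tuple[ResidueKey, ResidueKey, float, float]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        a = (row["chainA"], int(row["resA"]), "" if row["icodeA"] == "." else row["icodeA"])
        b = (row["chainB"], int(row["resB"]), "" if row["icodeB"] == "." else row["icodeB"])
        out.append((a, b, float(row["I_ij"]), float(row["weight"])))
    return out
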