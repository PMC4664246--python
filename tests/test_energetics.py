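"""SASA, the pairwise backend, MM-GBSA bookkeeping, alanine scanning."""

import numpy as np
import pandas as pd
import pytest

from allonet import energetics as en
from allonet import synthetic_ensembles as syn
from allonet.structure_io import StructuralEnsemble, ValidationError
from conftest import make_point_structure


def test_single_sphere_sasa_closed_form():
    s = make_point_structure([[0.0, 0, 0]])
    _, total = en.shrake_sasa(s, probe=1.4, points_per_atom=256)
    r = 1.70 + 1.4
    assert total == pytest.approx(4 * np.pi * r**2, rel=0.01)


def test_buried_atom_zero_sasa():
    from allonet.residue_depth import fibonacci_sphere

    shell = fibonacci_sphere(200) * 2.5
    s = make_point_structure(np.vstack([[[0.0, 0, 0]], shell]))
    areas, _ = en.shrake_sasa(s, points_per_atom=64)
    assert areas[0] == 0.0


def test_sasa_additive_when_far_apart():
    s1 = make_point_structure([[0.0, 0, 0]])
    s2 = make_point_structure([[0.0, 0, 0], [500.0, 0, 0]])
    _, a1 = en.shrake_sasa(s1, points_per_atom=128)
    _, a2 = en.shrake_sasa(s2, points_per_atom=128)
    assert a2 == pytest.approx(2 * a1, rel=1e-9)


def test_nonpolar_solvation_linear():
    assert en.nonpolar_solvation(0.0) == 0.0
    assert en.nonpolar_solvation(1000.0) == pytest.approx(7.2)
    assert en.nonpolar_solvation(2000.0) == pytest.approx(2 * en.nonpolar_solvation(1000.0))
    with pytest.raises(ValueError):
        en.nonpolar_solvation(-1.0)


def test_lj_minimum_energy_exact():
    # two carbons at the LJ minimum 2^(1/6)σ, in non-adjacent residues
    sig, eps = 3.40, 0.105
    r_min = 2 ** (1 / 6) * sig
    s = make_point_structure([[0.0, 0, 0], [r_min, 0, 0]], residue_of=[1, 3])
    params = en.PairParams.generic(s)
    terms = en.simple_pair_backend(s, s.coordinates, np.arange(2), params)
    assert terms.E_vdw == pytest.approx(-eps, rel=1e-12)


def test_coulomb_distance_dependent_dielectric():
    s = make_point_structure([[0.0, 0, 0], [5.0, 0, 0]], residue_of=[1, 3])
    q = np.array([1.0, -1.0])
    params = en.PairParams.generic(s, q)
    terms = en.simple_pair_backend(s, s.coordinates, np.arange(2), params)
    expected = 332.06 * (-1.0) / (4 * 5.0 * 5.0)
    # subtract the LJ part to isolate electrostatics
    assert terms.E_elec == pytest.approx(expected, rel=1e-12)


def test_backend_deterministic():
    toy = syn.build_toy_protein(6, "helix", 2, seed=1)
    params = en.PairParams.generic(toy)
    idx = np.arange(toy.n_atoms)
    t1 = en.simple_pair_backend(toy, toy.coordinates, idx, params)
    t2 = en.simple_pair_backend(toy, toy.coordinates, idx, params)
    assert t1 == t2


def _complex_ensemble(n_frames=2, separation=8.0):
    """Toy complex: residues 1-4 receptor, residue 6 ligand nearby."""
    rng = np.random.default_rng(0)
    rec = [[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]]
    lig = [[5.7, separation, 0]]
    coords = np.array(rec + lig)
    frames = coords[None] + rng.normal(scale=0.05, size=(n_frames, 5, 3))
    s = make_point_structure(coords, residue_of=[1, 2, 3, 4, 6])
    return StructuralEnsemble(s.atoms, frames)


def test_interaction_vanishes_for_distant_ligand():
    ens = _complex_ensemble(separation=500.0)
    keys = ens.residue_keys()
    factory = en.make_pair_backend_factory()
    table = en.snapshot_energy_table(ens, keys[:4], keys[4:], factory(ens))
    result = en.mmgbsa_aggregate(table)
    assert abs(result.components["dE_vdw"]) < 1e-6
    assert abs(result.components["dE_elec"]) < 1e-12
    # SASA of separated partition equals sum of parts -> dG_np ~ 0
    assert abs(result.components["dG_np"]) < 1e-9


def test_table_row_count_and_intra_cancellation():
    ens = _complex_ensemble(n_frames=3)
    keys = ens.residue_keys()
    factory = en.make_pair_backend_factory()
    table = en.snapshot_energy_table(ens, keys[:4], keys[4:], factory(ens))
    assert table.n_snapshots == 3
    # single-trajectory: intra (bonded) terms cancel exactly
    assert (table.complex["E_bond"] - table.receptor["E_bond"] - table.ligand["E_bond"]).abs().max() == 0


def test_overlapping_selections_rejected():
    ens = _complex_ensemble()
    keys = ens.residue_keys()
    with pytest.raises(ValidationError):
        en.snapshot_energy_table(
            ens, keys[:4], keys[3:], en.make_pair_backend_factory()(ens)
        )


def _hand_table(rows_complex, rows_receptor, rows_ligand):
    return en.SnapshotEnergyTable(
        pd.DataFrame(rows_complex),
        pd.DataFrame(rows_receptor),
        pd.DataFrame(rows_ligand),
    )


def test_mmgbsa_two_row_hand_arithmetic():
    zero = {k: 0.0 for k in en.TERM_NAMES}
    c1 = dict(zero, E_vdw=-30.0, E_elec=-12.0, dG_np_solv=9.0, dG_elec_solv=4.0)
    c2 = dict(zero, E_vdw=-34.0, E_elec=-10.0, dG_np_solv=11.0, dG_elec_solv=6.0)
    r = dict(zero, E_vdw=-10.0, E_elec=-4.0, dG_np_solv=7.0, dG_elec_solv=3.0)
    l = dict(zero, E_vdw=-2.0, E_elec=-1.0, dG_np_solv=4.0, dG_elec_solv=2.0)
    table = _hand_table([c1, c2], [r, r], [l, l])
    res = en.mmgbsa_aggregate(table, TdS=0.0)
    # by hand: dE_vdw = mean(-30,-34) - (-10) - (-2) = -20; dE_elec = -6
    # dG_np = mean(9,11) - 7 - 4 = -1; dG_elec_solv = mean(4,6) - 3 - 2 = 0
    assert res.dG_mm == pytest.approx(-26.0)
    assert res.dG_solv == pytest.approx(-1.0)
    assert res.dG_bind == pytest.approx(-27.0)


def test_entropy_sign_and_identity():
    zero = {k: 0.0 for k in en.TERM_NAMES}
    table = _hand_table([zero], [zero], [zero])
    base = en.mmgbsa_aggregate(table, TdS=0.0)
    shifted = en.mmgbsa_aggregate(table, TdS=5.0)
    assert base.dG_bind == 0.0
    assert shifted.dG_bind == pytest.approx(base.dG_bind - 5.0)
    # exact bookkeeping identity
    assert shifted.dG_bind == shifted.dG_mm + shifted.dG_solv - shifted.TdS


def test_frame_order_permutation_invariance():
    ens = _complex_ensemble(n_frames=4)
    keys = ens.residue_keys()
    factory = en.make_pair_backend_factory()
    t1 = en.snapshot_energy_table(ens, keys[:4], keys[4:], factory(ens))
    perm = [2, 0, 3, 1]
    ens2 = StructuralEnsemble(ens.topology, ens.frames[perm])
    t2 = en.snapshot_energy_table(ens2, keys[:4], keys[4:], factory(ens2))
    r1 = en.mmgbsa_aggregate(t1)
    r2 = en.mmgbsa_aggregate(t2)
    assert r1.dG_bind == pytest.approx(r2.dG_bind, rel=1e-12)


def _sidechain_complex(n_frames=2):
    """Receptor residues 1-3 where residue 2's side chain makes the only
    ligand contact; ligand residue 5 within reach of that side chain only."""
    rng = np.random.default_rng(5)
    coords = [
        [0.0, 0.0, 0],  # res1 CA
        [3.8, 0.0, 0],  # res2 CA
        [3.8, 2.0, 0],  # res2 CB (side chain, near ligand)
        [3.8, 3.5, 0],  # res2 CG (side chain, nearest ligand)
        [7.6, 0.0, 0],  # res3 CA
        [3.8, 7.0, 0],  # res5 = ligand atom
    ]
    names = ["CA", "CA", "CB", "CG", "CA", "CA"]
    residue_of = [1, 2, 2, 2, 3, 5]
    s = make_point_structure(coords, residue_of, names)
    frames = np.asarray(coords)[None] + rng.normal(scale=0.02, size=(n_frames, 6, 3))
    return StructuralEnsemble(s.atoms, frames)


def test_alanine_scan_of_alanine_is_zero():
    ens = _complex_ensemble()
    keys = ens.residue_keys()
    res = en.alanine_scan(
        ens, [keys[1]], keys[:4], keys[4:], en.make_pair_backend_factory()
    )
    assert res.ddG[keys[1]] == 0.0
    assert "side chain" in res.notes[keys[1]]


def test_alanine_scan_single_contact_equals_removed_interaction():
    ens = _sidechain_complex()
    keys = ens.residue_keys()
    rec = [k for k in keys if k[1] in (1, 2, 3)]
    lig = [k for k in keys if k[1] == 5]
    # pure-MM backend so the decomposition oracle applies exactly
    factory = en.make_pair_backend_factory(include_solvation=False)
    # residue 2 has LEU-like name by default restype ALA -> rename to force scan
    for a in ens.topology:
        if a.residue_key[1] == 2:
            object.__setattr__(a, "residue_type", "LEU")
    res = en.alanine_scan(ens, [("A", 2, "")], rec, lig, factory)

    # brute-force oracle: mean cross interaction of the removed CG atom with
    # every ligand atom, via the backend formulas
    s0 = ens.structure(0)
    params = en.PairParams.generic(s0)
    removed = [a.atom_index for a in ens.topology
               if a.residue_key[1] == 2 and a.atom_name == "CG"]
    lig_idx = [a.atom_index for a in ens.topology if a.residue_key[1] == 5]
    cross = []
    for f in range(ens.n_frames):
        e = 0.0
        for i in removed:
            for j in lig_idx:
                r = np.linalg.norm(ens.frames[f, i] - ens.frames[f, j])
                sig = 0.5 * (params.lj_sigma[i] + params.lj_sigma[j])
                eps = np.sqrt(params.lj_epsilon[i] * params.lj_epsilon[j])
                sr6 = (sig / r) ** 6
                e += 4 * eps * (sr6**2 - sr6)
        cross.append(e)
    assert res.ddG[("A", 2, "")] == pytest.approx(-np.mean(cross), abs=1e-10)


def test_alanine_scan_far_residue_negligible():
    ens = _sidechain_complex()
    # add a distant receptor residue with a side chain
    topo = list(ens.topology)
    import dataclasses as dc

    far = [
        dc.replace(topo[2], atom_index=len(topo), residue_key=("A", 9, ""),
                   atom_name="CB", residue_type="LEU"),
        dc.replace(topo[3], atom_index=len(topo) + 1, residue_key=("A", 9, ""),
                   atom_name="CG", residue_type="LEU"),
    ]
    new_coords = np.concatenate(
        [ens.frames, np.tile(np.array([[-40.0, 0, 0], [-41.5, 0, 0]])[None], (ens.n_frames, 1, 1))],
        axis=1,
    )
    ens2 = StructuralEnsemble(topo + far, new_coords)
    keys = ens2.residue_keys()
    rec = [k for k in keys if k[1] in (1, 2, 3, 9)]
    lig = [k for k in keys if k[1] == 5]
    factory = en.make_pair_backend_factory(include_solvation=False)
    res = en.alanine_scan(ens2, [("A", 9, "")], rec, lig, factory)
    assert abs(res.ddG[("A", 9, "")]) < 0.05


def test_synthetic_table_aggregation_single_row():
    terms = {("complex", t): 0.0 for t in en.TERM_NAMES}
    terms[("complex", "E_vdw")] = -25.0
    terms.update({("receptor", t): 0.0 for t in en.TERM_NAMES})
    terms.update({("ligand", t): 0.0 for t in en.TERM_NAMES})
    sds = {k: 0.0 for k in terms}
    df = syn.synthetic_energy_table(1, terms, sds, seed=0)
    table = en.SnapshotEnergyTable(
        df["complex"], df["receptor"], df["ligand"]
    )
    res = en.mmgbsa_aggregate(table)
    assert res.dG_bind == pytest.approx(-25.0)
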