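"""Superposition, B-factors, DCCM, PCA, rigid-body and density-of-states."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allonet import ensemble_dynamics as dyn
from allonet import synthetic_ensembles as syn
from conftest import make_ca_ensemble


def _random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


# -- superposition ----------------------------------------------------------


def test_superpose_recovers_rigid_copy():
    rng = np.random.default_rng(0)
    ref = rng.normal(size=(10, 3)) * 5
    rot = _random_rotation(1)
    moved = ref @ rot.T + np.array([3.0, -2.0, 7.0])
    ens = dyn.superpose_ensemble(make_ca_ensemble([ref, moved]), reference=0)
    rmsd = np.sqrt(((ens.frames[1] - ref) ** 2).sum() / 10)
    assert rmsd < 1e-8


def test_superpose_single_frame_unchanged():
    rng = np.random.default_rng(2)
    f = rng.normal(size=(5, 3))
    ens = dyn.superpose_ensemble(make_ca_ensemble([f]), reference=0)
    np.testing.assert_allclose(ens.frames[0], f, atol=1e-12)


def test_superpose_beats_exhaustive_rotation_grid():
    # 3-atom toy: least-squares fit must beat every rotation on a coarse grid
    rng = np.random.default_rng(3)
    ref = rng.normal(size=(3, 3)) * 3
    other = ref + rng.normal(size=(3, 3)) * 0.5
    ens = dyn.superpose_ensemble(make_ca_ensemble([ref, other]), reference=0)
    fit_rmsd = np.sqrt(((ens.frames[1] - ref) ** 2).sum() / 3)
    cent = other - other.mean(axis=0)
    ref_cent = ref - ref.mean(axis=0)
    for a in np.linspace(0, 2 * np.pi, 10, endpoint=False):
        for b in np.linspace(0, np.pi, 5):
            for c in np.linspace(0, 2 * np.pi, 10, endpoint=False):
                rot = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                rmsd = np.sqrt(((cent @ rot.T - ref_cent) ** 2).sum() / 3)
                assert fit_rmsd <= rmsd + 1e-9


def test_superposition_idempotent(anm_model):
    ens = syn.sample_gaussian_ensemble(anm_model, 50, seed=5)
    once = dyn.superpose_ensemble(ens)
    twice = dyn.superpose_ensemble(once)
    assert np.abs(twice.frames - once.frames).max() < 1e-8


def test_profiles_invariant_to_global_rigid_motion(anm_model):
    ens = syn.sample_gaussian_ensemble(anm_model, 200, seed=6)
    rot = _random_rotation(7)
    moved = make_ca_ensemble(ens.frames @ rot.T + np.array([5.0, 1.0, -4.0]))
    b1 = dyn.bfactor_profile(dyn.superpose_ensemble(ens))
    b2 = dyn.bfactor_profile(dyn.superpose_ensemble(moved))
    np.testing.assert_allclose(
        [b1[k] for k in b1], [b2[k] for k in b1], rtol=1e-8
    )


# -- B-factors --------------------------------------------------------------


def test_bfactor_zero_for_identical_frames():
    f = np.zeros((3, 4, 3))
    b = dyn.bfactor_profile(make_ca_ensemble(f))
    assert all(v == 0.0 for v in b.values())


def test_bfactor_isotropic_jitter_closed_form():
    rng = np.random.default_rng(8)
    base = rng.normal(size=(6, 3)) * 10
    frames = base[None] + rng.normal(scale=np.sqrt(0.1), size=(10_000, 6, 3))
    b = dyn.bfactor_profile(make_ca_ensemble(frames))
    expected = 8 * np.pi**2 * 0.1
    for v in b.values():
        assert v == pytest.approx(expected, rel=0.05)


def test_bfactor_variance_scaling():
    rng = np.random.default_rng(9)
    base = np.zeros((4, 3))
    noise = rng.normal(size=(4000, 4, 3))
    b1 = dyn.bfactor_profile(make_ca_ensemble(base[None] + 0.2 * noise))
    b2 = dyn.bfactor_profile(make_ca_ensemble(base[None] + 0.4 * noise))
    for k in b1:
        assert b2[k] == pytest.approx(4 * b1[k], rel=1e-9)


# -- cross-correlation ------------------------------------------------------


def test_dccm_diagonal_and_common_motion():
    rng = np.random.default_rng(10)
    shift = rng.normal(size=(500, 1, 3))
    base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
    frames = base[None] + shift  # both residues move identically
    c = dyn.cross_correlation(make_ca_ensemble(frames))
    np.testing.assert_allclose(np.diag(c.matrix), 1.0)
    assert c.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_dccm_zero_variance_policy():
    frames = np.zeros((10, 3, 3))
    frames[:, 0, 0] = np.linspace(0, 1, 10)  # only residue 0 moves
    with pytest.warns(UserWarning):
        c = dyn.cross_correlation(make_ca_ensemble(frames))
    assert c.matrix[1, 2] == 0.0
    assert c.matrix[1, 1] == 1.0


def test_dccm_matches_analytic_oracle(anm_model):
    c_true = syn.analytic_cross_correlation(anm_model)
    ens = syn.sample_gaussian_ensemble(anm_model, 50_000, seed=11)
    c = dyn.cross_correlation(dyn.superpose_ensemble(ens))
    assert np.abs(c.matrix - c_true).max() < 0.02


# -- PCA --------------------------------------------------------------------


def test_pca_single_direction_motion():
    rng = np.random.default_rng(12)
    base = rng.normal(size=(5, 3)) * 4
    direction = rng.normal(size=15)
    direction /= np.linalg.norm(direction)
    amps = rng.normal(size=(300, 1))
    frames = (base.ravel()[None] + amps * direction[None]).reshape(300, 5, 3)
    pca = dyn.pca_modes(make_ca_ensemble(frames))
    assert abs(pca.modes[0] @ direction) > 0.999
    assert pca.eigenvalues[1] < 1e-10 * pca.eigenvalues[0]
    # spectral identity
    coords = frames.reshape(300, -1)
    dev = coords - coords.mean(axis=0)
    trace = np.trace(dev.T @ dev / 300)
    assert pca.eigenvalues.sum() == pytest.approx(trace, rel=1e-8)


def test_pca_modes_orthonormal(anm_ensemble):
    pca = dyn.pca_modes(dyn.superpose_ensemble(anm_ensemble))
    gram = pca.modes @ pca.modes.T
    np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)


def test_pca_top_eigenvalue_matches_model(anm_model):
    ens = syn.sample_gaussian_ensemble(anm_model, 50_000, seed=13)
    pca = dyn.pca_modes(dyn.superpose_ensemble(ens))
    top_model = np.linalg.eigvalsh(anm_model.covariance)[-1]
    assert pca.eigenvalues[0] == pytest.approx(top_model, rel=0.10)


def test_mode_mobility_completeness_identity(anm_ensemble):
    ens = dyn.superpose_ensemble(anm_ensemble)
    pca = dyn.pca_modes(ens)
    mob = dyn.mode_mobility_profile(pca, n_modes=pca.n_modes)
    b = dyn.bfactor_profile(ens)
    for k in mob:
        assert mob[k] == pytest.approx(np.sqrt(b[k] * 3 / (8 * np.pi**2)), rel=1e-6)


# -- rigid-body decomposition -----------------------------------------------


def test_rigid_body_identity_frame():
    rng = np.random.default_rng(14)
    f = rng.normal(size=(12, 3)) * 5
    ens = make_ca_ensemble([f, f])
    keys = ens.residue_keys()
    rmsd, ang = dyn.rigid_body_decomposition(ens, keys[:6], keys[6:], reference=0)
    assert rmsd[1] == pytest.approx(0.0, abs=1e-10)
    assert ang[1] == pytest.approx(0.0, abs=1e-6)


def test_rigid_body_detects_constructed_rotation():
    rng = np.random.default_rng(15)
    fit_part = rng.normal(size=(6, 3)) * 4
    probe_part = rng.normal(size=(5, 3)) * 3 + np.array([20.0, 0, 0])
    ref = np.vstack([fit_part, probe_part])
    axis = np.array([0.0, 0.0, 1.0])
    rot = Rotation.from_rotvec(np.deg2rad(30) * axis).as_matrix()
    centroid = probe_part.mean(axis=0)
    moved_probe = (probe_part - centroid) @ rot.T + centroid
    frame = np.vstack([fit_part, moved_probe])
    ens = make_ca_ensemble([ref, frame])
    keys = ens.residue_keys()
    rmsd, ang = dyn.rigid_body_decomposition(ens, keys[:6], keys[6:], reference=0)
    assert ang[1] == pytest.approx(30.0, abs=1e-6)


def test_rigid_body_rmsd_invariant_to_global_rotation():
    rng = np.random.default_rng(16)
    ref = rng.normal(size=(10, 3)) * 5
    frame = ref + rng.normal(size=(10, 3)) * 0.3
    rot = _random_rotation(17)
    ens1 = make_ca_ensemble([ref, frame])
    ens2 = make_ca_ensemble([ref, frame @ rot.T + 3.0])
    keys = ens1.residue_keys()
    r1, _ = dyn.rigid_body_decomposition(ens1, keys[:5], keys[5:], 0)
    r2, _ = dyn.rigid_body_decomposition(ens2, keys[:5], keys[5:], 0)
    assert r1[1] == pytest.approx(r2[1], abs=1e-8)


# -- density of states ------------------------------------------------------


def test_dos_single_state():
    e = np.full(100, 2.5)
    r = np.full(100, 1.0)
    d = dyn.density_of_states(e, r, bins=10)
    assert d.counts.sum() == 100
    assert len(d.peaks) == 1
    assert d.peak_fractions[0] == pytest.approx(1.0)


def test_dos_length_mismatch():
    with pytest.raises(Exception):
        dyn.density_of_states(np.zeros(5), np.zeros(6))


def test_dos_two_state_population_recovery():
    a = syn.build_toy_protein(10, "helix", 1, seed=0)
    b = syn.build_toy_protein(10, "extended", 1, seed=0)
    spec = syn.TwoStateSpec(a, b, population_a=0.7, noise_sd=0.3, n_frames=2000, seed=21)
    ens = syn.make_two_state_ensemble(spec)
    # scalar series: RMSD of each frame to each conformer
    e = np.sqrt(((ens.frames - a.coordinates) ** 2).sum(axis=(1, 2)) / ens.n_atoms)
    r = np.sqrt(((ens.frames - b.coordinates) ** 2).sum(axis=(1, 2)) / ens.n_atoms)
    d = dyn.density_of_states(e, r, bins=50)
    assert d.counts.sum() == 2000
    assert len(d.peaks) == 2
    true_frac = ens.frame_labels.count("A") / 2000
    se = np.sqrt(0.7 * 0.3 / 2000)
    assert max(d.peak_fractions) == pytest.approx(true_frac, abs=3 * se)
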