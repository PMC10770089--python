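import numpy as np
import pytest

from geompot import network as net
from geompot.network import (
    ModelConfig,
    cosine_cutoff,
    dipole_moment,
    embedding_state,
    expand_directions,
    init_params,
    load_checkpoint,
    predict_dipole,
    predict_energy,
    predict_energy_forces,
    predict_scalar,
    predict_spatial_extent,
    save_checkpoint,
    spatial_extent,
    total_energy,
)
from geompot.rgc import _real_sh_batch
from geompot.structures_io import AtomicConfiguration
from geompot.synthetic import apply_transform, random_cluster, random_rigid_transform


class TestModelConfig:
    def test_head_divisibility(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=30, n_heads=8)

    def test_l_max_range(self):
        with pytest.raises(ValueError):
            ModelConfig(l_max=3)

    def test_vector_components(self):
        assert ModelConfig(l_max=1).n_vector_components == 3
        assert ModelConfig(l_max=2).n_vector_components == 8


class TestCosineCutoff:
    def test_boundary_values(self):
        assert float(cosine_cutoff(np.array([0.0]), 5.0)[0]) == pytest.approx(1.0)
        assert float(cosine_cutoff(np.array([5.0]), 5.0)[0]) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_monotone_nonincreasing(self):
        r = np.linspace(0, 5, 400)
        vals = np.asarray(cosine_cutoff(r, 5.0))
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all(vals >= 0)


class TestDirectionExpansion:
    def test_matches_reference_harmonics(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(50, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        U = np.asarray(expand_directions(u, 2))
        # l = 1 block is Cartesian-ordered: (x, y, z) vs reference (y, z, x)
        np.testing.assert_allclose(U[:, [1, 2, 0]], _real_sh_batch(u, 1), atol=1e-12)
        np.testing.assert_allclose(U[:, 3:], _real_sh_batch(u, 2), atol=1e-12)


class TestEmbeddingBlock:
    def test_isolated_atom(self, tiny_model):
        cfg, params = tiny_model
        config = AtomicConfiguration(np.array([6]), np.zeros((1, 3)))
        state = embedding_state(params, cfg, config)
        assert state.h.shape == (1, cfg.hidden_dim)
        assert state.f.shape == (0, cfg.hidden_dim)
        assert np.all(state.v == 0)

    def test_permutation_equivariance(self, tiny_model):
        cfg, params = tiny_model
        config = random_cluster(5, seed=3)
        state = embedding_state(params, cfg, config)
        perm = np.array([2, 0, 4, 1, 3])
        permuted = AtomicConfiguration(
            config.atomic_numbers[perm], config.coordinates[perm]
        )
        state_p = embedding_state(params, cfg, permuted)
        np.testing.assert_allclose(state_p.h, state.h[perm], atol=1e-12)

    def test_distance_sensitivity(self, tiny_model):
        cfg, params = tiny_model
        at = np.array([1, 1])
        near = embedding_state(
            params, cfg, AtomicConfiguration(at, [[0, 0, 0], [1, 0, 0]])
        )
        far = embedding_state(
            params, cfg, AtomicConfiguration(at, [[0, 0, 0], [2, 0, 0]])
        )
        assert np.abs(near.h - far.h).max() > 1e-6

    def test_unknown_species_rejected(self, tiny_model):
        cfg, params = tiny_model
        config = AtomicConfiguration(np.array([92]), np.zeros((1, 3)))
        with pytest.raises(ValueError, match="embedding table"):
            predict_energy(params, cfg, config)


class TestEnergyHead:
    def test_single_atom_is_species_scalar(self, small_model):
        cfg, params = small_model
        e_c = predict_energy(
            params, cfg, AtomicConfiguration(np.array([6]), np.zeros((1, 3)))
        )
        e_c2 = predict_energy(
            params, cfg, AtomicConfiguration(np.array([6]), np.ones((1, 3)) * 7)
        )
        e_o = predict_energy(
            params, cfg, AtomicConfiguration(np.array([8]), np.zeros((1, 3)))
        )
        assert e_c == pytest.approx(e_c2, abs=1e-12)  # translation invariant
        assert e_c != pytest.approx(e_o)  # species dependent

    def test_size_extensive_at_infinite_separation(self, small_model):
        cfg, params = small_model
        mol = random_cluster(4, box_scale=3.0, seed=5)
        e1 = predict_energy(params, cfg, mol)
        doubled = AtomicConfiguration(
            np.concatenate([mol.atomic_numbers, mol.atomic_numbers]),
            np.concatenate([mol.coordinates, mol.coordinates + 100.0]),
        )
        assert predict_energy(params, cfg, doubled) == pytest.approx(
            2 * e1, abs=1e-9
        )

    def test_pair_exactly_at_cutoff_decouples(self, small_model):
        cfg, params = small_model
        a = AtomicConfiguration(np.array([6]), np.zeros((1, 3)))
        b = AtomicConfiguration(np.array([8]), np.zeros((1, 3)))
        pair = AtomicConfiguration(
            np.array([6, 8]), [[0, 0, 0], [cfg.cutoff, 0, 0]]
        )
        e_pair = predict_energy(params, cfg, pair)
        e_sum = predict_energy(params, cfg, a) + predict_energy(params, cfg, b)
        assert e_pair == pytest.approx(e_sum, abs=1e-10)

    def test_cutoff_crossing_continuity(self, small_model):
        cfg, params = small_model
        at = np.array([6, 8])
        energies = []
        for r in (cfg.cutoff - 1e-4, cfg.cutoff, cfg.cutoff + 1e-4):
            energies.append(
                predict_energy(
                    params, cfg, AtomicConfiguration(at, [[0, 0, 0], [r, 0, 0]])
                )
            )
        assert abs(energies[0] - energies[1]) < 1e-6
        assert abs(energies[2] - energies[1]) < 1e-6

    def test_locality_receptive_field(self, small_model):
        cfg, params = small_model
        mol = random_cluster(3, box_scale=2.5, seed=6)
        far_1 = AtomicConfiguration(
            np.append(mol.atomic_numbers, 1),
            np.vstack([mol.coordinates, [200.0, 0, 0]]),
        )
        far_2 = AtomicConfiguration(
            np.append(mol.atomic_numbers, 1),
            np.vstack([mol.coordinates, [200.5, 0, 0]]),
        )
        # moving an atom far outside every receptive field changes nothing
        assert predict_energy(params, cfg, far_1) == pytest.approx(
            predict_energy(params, cfg, far_2), abs=1e-10
        )


class TestSymmetry:
    @pytest.mark.parametrize("l_max", [1, 2])
    def test_energy_invariant_forces_equivariant(self, l_max):
        cfg = ModelConfig(
            n_blocks=2, hidden_dim=32, n_heads=4, n_rbf=8, l_max=l_max, cutoff=5.0
        )
        params = init_params(cfg, seed=2)
        mol = random_cluster(6, box_scale=4.0, seed=7)
        e0, f0 = predict_energy_forces(params, cfg, mol)
        for seed in range(5):
            t = random_rigid_transform(seed=seed, n_atoms=6)
            moved = apply_transform(mol, t)
            e1, f1 = predict_energy_forces(params, cfg, moved)
            assert e1 == pytest.approx(e0, abs=1e-10)
            expected_f = (f0 @ t.rotation.T)[t.permutation]
            np.testing.assert_allclose(f1, expected_f, atol=1e-10)

    def test_improper_pathway_keeps_symmetry(self):
        cfg = ModelConfig(
            n_blocks=2,
            hidden_dim=32,
            n_heads=4,
            n_rbf=8,
            l_max=1,
            use_improper=True,
        )
        params = init_params(cfg, seed=3)
        mol = random_cluster(5, box_scale=3.5, seed=8)
        e0, f0 = predict_energy_forces(params, cfg, mol)
        t = random_rigid_transform(seed=11, n_atoms=5)
        e1, f1 = predict_energy_forces(params, cfg, apply_transform(mol, t))
        assert e1 == pytest.approx(e0, abs=1e-10)
        np.testing.assert_allclose(f1, (f0 @ t.rotation.T)[t.permutation], atol=1e-10)


class TestForces:
    def test_net_force_zero(self, small_model):
        cfg, params = small_model
        mol = random_cluster(7, box_scale=4.0, seed=9)
        _, forces = predict_energy_forces(params, cfg, mol)
        np.testing.assert_allclose(forces.sum(axis=0), 0.0, atol=1e-10)

    def test_finite_difference_consistency(self, small_model):
        cfg, params = small_model
        mol = random_cluster(5, box_scale=3.5, seed=10)
        _, forces = predict_energy_forces(params, cfg, mol)
        h = 1e-4
        fd = np.zeros_like(forces)
        for i in range(mol.n_atoms):
            for a in range(3):
                rp = mol.coordinates.copy()
                rm = mol.coordinates.copy()
                rp[i, a] += h
                rm[i, a] -= h
                fd[i, a] = -(
                    float(total_energy(params, cfg, mol, rp))
                    - float(total_energy(params, cfg, mol, rm))
                ) / (2 * h)
        scale = max(np.abs(fd).max(), 1e-10)
        assert np.abs(forces - fd).max() / scale < 1e-5

    def test_coincident_atoms_error(self, small_model):
        cfg, params = small_model
        mol = AtomicConfiguration(np.array([1, 1]), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            predict_energy_forces(params, cfg, mol)


class TestPropertyHeads:
    def test_dipole_hand_computed(self):
        h = np.array([1.0, -1.0])
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        masses = np.array([1.0, 1.0])
        mu = dipole_moment(h, np.zeros((2, 3)), coords, masses)
        assert mu == pytest.approx(1.0, abs=1e-12)

    def test_dipole_zero_state(self):
        coords = np.random.default_rng(0).normal(size=(3, 3))
        mu = dipole_moment(np.zeros(3), np.zeros((3, 3)), coords, np.ones(3))
        assert mu == 0.0

    def test_dipole_rigid_motion_invariant(self, small_model):
        cfg, params = small_model
        mol = random_cluster(5, box_scale=3.5, seed=11)
        mu0 = predict_dipole(params, cfg, mol)
        t = random_rigid_transform(seed=21)
        assert predict_dipole(params, cfg, apply_transform(mol, t)) == pytest.approx(
            mu0, abs=1e-10
        )

    def test_spatial_extent_single_atom_zero(self, small_model):
        cfg, params = small_model
        mol = AtomicConfiguration(np.array([6]), np.array([[3.0, 1.0, -2.0]]))
        assert predict_spatial_extent(params, cfg, mol) == pytest.approx(0.0, abs=1e-12)

    def test_spatial_extent_quadratic_scaling(self):
        h = np.array([0.7, 0.3])
        coords = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        masses = np.ones(2)
        base = spatial_extent(h, coords, masses)
        assert spatial_extent(h, 2 * coords, masses) == pytest.approx(4 * base)

    def test_spatial_extent_translation_invariant(self, small_model):
        cfg, params = small_model
        mol = random_cluster(4, box_scale=3.0, seed=12)
        r0 = predict_spatial_extent(params, cfg, mol)
        shifted = mol.replace(coordinates=mol.coordinates + [10.0, -4.0, 2.0])
        assert predict_spatial_extent(params, cfg, shifted) == pytest.approx(
            r0, abs=1e-9
        )

    def test_scalar_head_matches_energy_reduction(self, small_model):
        cfg, params = small_model
        mol = random_cluster(5, box_scale=3.5, seed=13)
        assert predict_scalar(params, cfg, mol) == pytest.approx(
            predict_energy(params, cfg, mol), abs=1e-12
        )

    def test_scalar_permutation_invariant(self, small_model):
        cfg, params = small_model
        mol = random_cluster(5, box_scale=3.5, seed=14)
        perm = np.array([4, 2, 0, 1, 3])
        permuted = AtomicConfiguration(
            mol.atomic_numbers[perm], mol.coordinates[perm]
        )
        assert predict_scalar(params, cfg, permuted) == pytest.approx(
            predict_scalar(params, cfg, mol), abs=1e-10
        )


class TestDeterminismAndCheckpoint:
    def test_init_deterministic(self):
        cfg = ModelConfig(n_blocks=1, hidden_dim=16, n_heads=2, n_rbf=4)
        p1 = init_params(cfg, seed=5)
        p2 = init_params(cfg, seed=5)
        np.testing.assert_array_equal(p1["atom_emb"], p2["atom_emb"])
        np.testing.assert_array_equal(
            p1["blocks"][0]["Wq"]["W"], p2["blocks"][0]["Wq"]["W"]
        )

    def test_prediction_bitwise_reproducible(self, small_model):
        cfg, params = small_model
        mol = random_cluster(6, seed=15)
        e1, f1 = predict_energy_forces(params, cfg, mol)
        e2, f2 = predict_energy_forces(params, cfg, mol)
        assert e1 == e2
        np.testing.assert_array_equal(f1, f2)

    def test_checkpoint_round_trip(self, small_model, tmp_path):
        cfg, params = small_model
        mol = random_cluster(5, seed=16)
        e0, f0 = predict_energy_forces(params, cfg, mol)
        save_checkpoint(tmp_path / "model.npz", cfg, params)
        cfg2, params2 = load_checkpoint(tmp_path / "model.npz")
        assert cfg2 == cfg
        e1, f1 = predict_energy_forces(params2, cfg2, mol)
        assert e1 == e0
        np.testing.assert_array_equal(f1, f0)
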