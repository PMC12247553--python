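import numpy as np
import pytest

from qmtsim.exceptions import DegenerateVoxelError
from qmtsim.crb import LABELS
from qmtsim.estimation import (build_dictionary, compress, fit_map,
                               fit_monoexp, fit_voxel, nearest_atom_init,
                               subspace)
from qmtsim.mt_core import SystemPars, TissuePars
from qmtsim.sequence_engine import _signal, default_train
from qmtsim.spectral import exact_apparent_rates


@pytest.fixture(scope="module")
def wm_dict(train_tiny, wm, grid):
    spec = {"m0s": [0.1, 0.2, 0.3], "R1f": [0.4, 0.55, 0.7]}
    return build_dictionary(spec, train_tiny, base_tissue=wm, grid=grid)


class TestDictionary:
    def test_single_atom_equals_fingerprint(self, train_tiny, wm, sys0, grid):
        d = build_dictionary({"m0s": [wm.m0s]}, train_tiny, base_tissue=wm,
                             base_sys=sys0, grid=grid)
        assert d.n_atoms == 1
        ref = _signal(train_tiny, wm, sys0, grid)
        assert np.array_equal(d.atoms[:, 0], ref)

    def test_deterministic_rebuild(self, train_tiny, wm, grid):
        spec = {"m0s": [0.1, 0.3]}
        d1 = build_dictionary(spec, train_tiny, base_tissue=wm, grid=grid)
        d2 = build_dictionary(spec, train_tiny, base_tissue=wm, grid=grid)
        assert np.array_equal(d1.atoms, d2.atoms)
        assert d1.meta["train_hash"] == d2.meta["train_hash"]

    def test_grid_matches_individual_simulations(self, wm_dict, train_tiny,
                                                 wm, grid):
        k = 0
        for m0s in [0.1, 0.2, 0.3]:
            for r1f in [0.4, 0.55, 0.7]:
                ref = _signal(train_tiny, wm.replace(m0s=m0s, R1f=r1f),
                              SystemPars(), grid)
                assert np.array_equal(wm_dict.atoms[:, k], ref)
                k += 1

    def test_empty_grid_rejected(self, train_tiny):
        with pytest.raises(ValueError):
            build_dictionary({}, train_tiny)
        with pytest.raises(ValueError):
            build_dictionary({"m0s": []}, train_tiny)

    def test_nonincreasing_axis_rejected(self, train_tiny):
        with pytest.raises(ValueError):
            build_dictionary({"m0s": [0.3, 0.1]}, train_tiny)


class TestSubspace:
    def test_full_rank_zero_projection_error(self, train_tiny, wm, grid):
        spec = {"m0s": np.linspace(0.05, 0.4, 6),
                "R1f": np.linspace(0.3, 1.0, 8)}
        d = build_dictionary(spec, train_tiny, base_tissue=wm, grid=grid)
        sub = subspace(d, rank=train_tiny.n_pulses)
        assert sub.worst_projection_error < 1e-10

    def test_orthonormal_basis(self, wm_dict):
        sub = subspace(wm_dict, rank=4)
        gram = sub.basis.conj().T @ sub.basis
        assert np.abs(gram - np.eye(4)).max() < 1e-10

    def test_rank_exceeding_atoms_rejected(self, wm_dict):
        with pytest.raises(ValueError):
            subspace(wm_dict, rank=wm_dict.n_atoms + 1)

    def test_rank15_projection_error_regression(self, train200, wm, grid):
        spec = {"m0s": [0.05, 0.15, 0.25, 0.35], "R1f": [0.3, 0.6, 1.0],
                "T2s": [8e-6, 12e-6, 16e-6], "omega_z": [-50.0, 0.0, 50.0],
                "b1": [0.85, 1.0, 1.15]}
        d = build_dictionary(spec, train200, base_tissue=wm, grid=grid)
        sub = subspace(d, rank=15)
        assert sub.worst_projection_error < 2e-3  # stored regression bound


class TestCompress:
    def test_basis_column_maps_to_unit_vector(self, wm_dict):
        sub = subspace(wm_dict, rank=5)
        for k in range(5):
            c = compress(sub.basis[:, k], sub)
            ek = np.zeros(5, complex)
            ek[k] = 1.0
            assert np.abs(c - ek).max() < 1e-12

    def test_norm_preserved_for_in_subspace_signal(self, wm_dict):
        sub = subspace(wm_dict, rank=5)
        coef = np.array([0.5, -0.2, 0.1j, 0.3, -0.4j])
        f = sub.basis @ coef
        c = compress(f, sub)
        assert np.linalg.norm(c) == pytest.approx(np.linalg.norm(f), rel=1e-12)

    def test_normalization_removes_global_scale(self, wm_dict):
        sub = subspace(wm_dict, rank=5)
        f = wm_dict.atoms[:, 0]
        c1 = compress(f, sub, normalize=True)
        c2 = compress((0.3 - 1.7j) * f, sub, normalize=True)
        assert np.abs(c1 - c2).max() < 1e-12

    def test_zero_first_coefficient_error(self, wm_dict):
        sub = subspace(wm_dict, rank=3)
        f = sub.basis[:, 2]  # orthogonal to first basis vector
        with pytest.raises(DegenerateVoxelError):
            compress(f, sub, normalize=True)


class TestFitVoxel:
    def test_truth_init_noiseless_returns_truth(self, train_tiny, wm,
                                                sys_off, grid):
        obs = _signal(train_tiny, wm, sys_off, grid)
        init = {lab: v for lab, v in zip(
            LABELS, [wm.m0s, wm.R1f, wm.R2f, wm.Rx, wm.R1s, wm.T2s,
                     sys_off.omega_z, sys_off.b1, sys_off.M0.real,
                     sys_off.M0.imag])}
        res = fit_voxel(obs, train_tiny, init=init, grid=grid)
        assert res.converged
        assert res.residual < 1e-10
        for lab in ("m0s", "R1f", "R2f", "Rx", "R1s", "T2s"):
            assert res.estimates[lab] == pytest.approx(init[lab], rel=1e-8)

    def test_perturbed_init_recovery(self, train200, wm, sys0, grid):
        obs = _signal(train200, wm, sys0, grid)
        init = {"m0s": wm.m0s * 1.2, "R1f": wm.R1f * 0.8,
                "R2f": wm.R2f * 1.2, "Rx": wm.Rx * 0.8,
                "R1s": wm.R1s * 1.2, "T2s": wm.T2s * 0.8,
                "omega_z": 5.0, "b1": 1.05, "M0_re": 0.9, "M0_im": 0.05}
        res = fit_voxel(obs, train200, init=init, grid=grid)
        assert res.converged
        for lab in ("m0s", "R1f", "R2f", "Rx", "R1s", "T2s"):
            truth = getattr(wm, lab)
            assert abs(res.estimates[lab] - truth) / truth < 1e-3

    def test_constrained_fit_underestimates_m0s(self, sys0, grid):
        # generating model has R1s >> R1f; forcing R1s := R1f biases m0s low
        # (direction of the apparent-pool-size expansion).  Encoding must be
        # recovery-dominated for the bias direction to show; 400 pulses of
        # the default pattern suffice.
        train = default_train(n_pulses=400)
        gen = TissuePars(m0s=0.2, R1f=0.5, R2f=13.0, Rx=15.0, R1s=3.0,
                         T2s=1e-5)
        obs = _signal(train, gen, sys0, grid)
        res = fit_voxel(obs, train, free=("m0s", "R1f", "Rx", "M0_re",
                                          "M0_im"),
                        tied={"R1s": "R1f"},
                        init={"m0s": 0.2, "R1f": 0.5, "R2f": 13.0,
                              "Rx": 15.0, "T2s": 1e-5}, grid=grid)
        assert res.estimates["m0s"] < gen.m0s
        assert res.estimates["R1s"] == res.estimates["R1f"]
        assert res.estimates["R1f"] > gen.R1f  # apparent rate exceeds R1f

    def test_all_zero_observation_error(self, train_tiny, grid):
        with pytest.raises(DegenerateVoxelError):
            fit_voxel(np.zeros(train_tiny.n_pulses, complex), train_tiny,
                      grid=grid)

    def test_tied_and_free_conflict(self, train_tiny, wm, sys0, grid):
        obs = _signal(train_tiny, wm, sys0, grid)
        with pytest.raises(ValueError):
            fit_voxel(obs, train_tiny, tied={"R1s": "R1f"}, grid=grid)

    def test_length_mismatch_error(self, train_tiny, grid):
        with pytest.raises(ValueError):
            fit_voxel(np.ones(5, complex), train_tiny, grid=grid)

    def test_normalization_removes_m0(self, train100, wm, grid):
        # on first-coefficient-normalized data, fits with and without M0
        # free agree on the tissue parameters
        sysr = SystemPars(M0=1.3 - 0.4j)
        obs = _signal(train100, wm, sysr, grid)
        obs_n = obs / obs[0]
        init = {"m0s": wm.m0s * 1.05, "R1f": wm.R1f * 0.95,
                "R2f": wm.R2f, "Rx": wm.Rx, "R1s": wm.R1s, "T2s": wm.T2s}
        tissue_labels = ("m0s", "R1f", "R2f", "Rx", "R1s", "T2s")
        res_nom0 = fit_voxel(obs_n, train100, free=tissue_labels, init=init,
                             normalize=True, grid=grid)
        res_m0 = fit_voxel(obs_n, train100,
                           free=tissue_labels + ("M0_re", "M0_im"),
                           init=init, normalize=True, grid=grid)
        for lab in tissue_labels:
            a, b = res_nom0.estimates[lab], res_m0.estimates[lab]
            assert abs(a - b) / abs(a) < 1e-4

    def test_subspace_fit_close_to_full_fit(self, train200, wm, grid):
        spec = {"m0s": [0.1, 0.2, 0.3], "R1f": [0.4, 0.55, 0.7],
                "T2s": [1e-5, 1.5e-5]}
        d = build_dictionary(spec, train200, base_tissue=wm, grid=grid)
        sub = subspace(d, rank=10)
        obs = _signal(train200, wm, SystemPars(), grid)
        init = {"m0s": wm.m0s * 1.1, "R1f": wm.R1f * 0.9, "R2f": wm.R2f,
                "Rx": wm.Rx, "R1s": wm.R1s, "T2s": wm.T2s}
        full = fit_voxel(obs, train200, init=init, grid=grid)
        comp = fit_voxel(compress(obs, sub), train200, sub=sub, init=init,
                         grid=grid)
        for lab in ("m0s", "R1f", "R2f"):
            a, b = full.estimates[lab], comp.estimates[lab]
            assert abs(a - b) / abs(a) < \
                max(10 * sub.worst_projection_error, 1e-4)

    def test_nearest_atom_init(self, wm_dict, train_tiny, wm, grid):
        obs = 2.0 * wm_dict.atoms[:, 4]  # atom 4 scaled
        init = nearest_atom_init(obs, wm_dict)
        t4, _ = wm_dict.pars[4]
        assert init["m0s"] == t4.m0s and init["R1f"] == t4.R1f
        assert init["M0_re"] == pytest.approx(2.0, rel=1e-10)


class TestFitMap:
    def test_two_voxel_image_matches_scalar_fits(self, train_tiny, wm, gm,
                                                 sys0, grid):
        img = np.stack([_signal(train_tiny, wm, sys0, grid),
                        _signal(train_tiny, gm, sys0, grid)])[:, :]
        img = img.reshape(2, 1, train_tiny.n_pulses)
        mask = np.ones((2, 1), bool)
        init_maps = {lab: np.array([[getattr(t, lab)] for t in (wm, gm)])
                     for lab in ("m0s", "R1f", "R2f", "Rx", "R1s", "T2s")}
        maps, diag = fit_map(img, mask, train_tiny, init_policy=init_maps,
                             grid=grid)
        assert diag["n_failed"] == 0
        for i, t in enumerate((wm, gm)):
            scalar = fit_voxel(img[i, 0], train_tiny,
                               init={lab: m[i, 0] for lab, m in
                                     init_maps.items()}, grid=grid)
            for lab in ("m0s", "R1f", "R2f"):
                assert maps[lab][i, 0] == pytest.approx(
                    scalar.estimates[lab], rel=1e-10)

    def test_masked_voxels_untouched(self, train_tiny, wm, sys0, grid):
        img = np.tile(_signal(train_tiny, wm, sys0, grid), (2, 2, 1))
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        maps, diag = fit_map(img, mask, train_tiny, grid=grid, max_nfev=5)
        assert np.isnan(maps["m0s"][1, 1])
        assert np.isfinite(maps["m0s"][0, 0])
        assert diag["n_fitted"] == 1

    def test_shape_mismatch_error(self, train_tiny, grid):
        with pytest.raises(ValueError):
            fit_map(np.zeros((2, 2, 10), complex), np.ones((3, 3), bool),
                    train_tiny, grid=grid)


class TestFitMonoexp:
    def test_exact_exponential_recovery(self):
        t = np.linspace(0, 5, 40)
        y = 0.7 - 1.4 * np.exp(-1.3 * t)
        assert fit_monoexp(t, y) == pytest.approx(1.3, abs=1e-8)

    def test_constant_signal_zero_rate(self):
        t = np.linspace(0, 2, 10)
        assert fit_monoexp(t, np.full(10, 0.42)) == 0.0

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            fit_monoexp([0.0, 1.0], [0.0, 1.0])

    def test_biexponential_recovery_matches_apparent_rate(self, wm):
        # both pools equally inverted, sampled at TI >> 1/Rx_a: the
        # longitudinal recovery is effectively mono-exponential at R1f_a
        from scipy.linalg import expm
        from qmtsim.spectral import longitudinal_hamiltonian
        H = longitudinal_hamiltonian(wm)
        x0 = np.array([-wm.m0f, -wm.m0s, 1.0])  # zf/m0f = zs/m0s = -1
        r1fa, rxa = exact_apparent_rates(wm)
        times = np.linspace(5.0 / rxa, 4.0, 60)
        zf = np.array([(expm(H * t) @ x0)[0] for t in times])
        r_fit = fit_monoexp(times, zf)
        assert abs(r_fit - r1fa) / r1fa < 0.01
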