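import numpy as np
import pytest

from msdager import encoding, evaluation, gp, sampling, simulator
from msdager.encoding import ImageSeries
from msdager.reconstruction import (ReconConfig, joint_objective,
                                    msdager_reconstruct, reconstruct,
                                    solve_joint_quadratic, _subset_dataset)
from msdager.scheme import QSpaceScheme, two_shell_scheme


def _toy_dataset(phantom, coils, n_per_shell=2, R=1, SMS=1, noise_sd=0.0,
                 phase=None, seed=0):
    sch = two_shell_scheme(n_per_shell, n_b0=0, seed=1)
    fam = sampling.enumerate_patterns(R, SMS)
    a = sampling.assign_patterns(sch, fam, seed=0, n_restarts=1)
    ds = simulator.simulate_acquisition(phantom, sch, coils, a,
                                        noise_sd=noise_sd, phase=phase,
                                        seed=seed)
    return ds


class TestJointSolve:
    def test_lambda_zero_reduces_to_cg_sense(self, phantom, coils):
        """With the GP signal variance at zero the prior disappears and the
        joint solve equals per-direction CG-SENSE (checked on a determined
        R=2 problem where both CG runs converge to the unique solution)."""
        ds = _toy_dataset(phantom, coils, n_per_shell=1, R=2, SMS=1,
                          noise_sd=0.02, seed=2)
        nvox = int(np.prod(phantom.grid_shape))
        h = gp.GPHyperparameters(a=1.0, l=1.0, lambda_=0.0,
                                 sigma_n2=np.array([1.0, 1.0]))
        models = {"white": gp.build_covariance(ds.scheme, h)}
        labels = np.full(nvox, "white")
        mu = np.zeros((nvox, 2))
        phase = np.zeros((2,) + phantom.grid_shape)
        sol, _ = solve_joint_quadratic(ds, phase, models, mu, labels,
                                       np.array([1.0, 1.0]), tol=1e-12,
                                       max_iter=300)
        ref = encoding.sense_reconstruct(ds, tol=1e-12, max_iter=300)
        num = np.linalg.norm(sol.data - ref.data)
        assert num / np.linalg.norm(ref.data) < 1e-6

    def test_information_transfer_between_identical_directions(self, phantom,
                                                               coils):
        """Two identical directions, one fully sampled and one unsampled,
        noiseless: as the GP noise goes to zero the unsampled direction's
        reconstruction approaches the sampled one's."""
        v = np.array([1.0, 0, 0])
        sch = QSpaceScheme([1000, 1000], np.vstack([v, v]))
        nz, ny, nx = phantom.grid_shape
        img = simulator.phantom_signal(phantom, sch)
        full = sampling.SamplingPattern(1, 1, 0, 0)
        sens = coils
        masks = np.stack([full.mask(ny, nz),
                          np.zeros((nz, ny), dtype=bool)])
        data = np.zeros((2, sens.shape[0], nz, ny, nx), dtype=complex)
        data[0] = encoding.forward(img.data[0], sens, masks[0])
        from msdager.encoding import KSpaceDataset
        ds = KSpaceDataset(data, masks, sens, sch)
        h = gp.GPHyperparameters(a=1.0, l=1.0, lambda_=1.0,
                                 sigma_n2=np.array([1e-10]))
        models = {"white": gp.build_covariance(sch, h)}
        nvox = nz * ny * nx
        labels = np.full(nvox, "white")
        mu = np.zeros((nvox, 2))
        phase = np.zeros((2, nz, ny, nx))
        sol, _ = solve_joint_quadratic(ds, phase, models, mu, labels,
                                       np.array([1e-8]), tol=1e-12,
                                       max_iter=200)
        diff = np.linalg.norm(sol.data[1] - sol.data[0])
        assert diff / np.linalg.norm(sol.data[0]) < 0.01

    def test_objective_matches_dense_oracle_and_solution_optimal(self, rng):
        """On an 8x8, 2-coil, 3-direction toy the solver's solution matches a
        dense normal-equation solve and the objective value matches an
        independent dense evaluation."""
        nz, ny, nx = 1, 8, 8
        nvox = nz * ny * nx
        sch = QSpaceScheme([1000, 1000, 2000],
                           [[1, 0, 0], [0, 1, 0], [0.6, 0.8, 0]])
        sens = simulator.make_coil_sensitivities((nz, ny, nx), 2, seed=0)
        fam = sampling.enumerate_patterns(2, 1)
        masks = np.stack([fam[0].mask(ny, 1), fam[1].mask(ny, 1),
                          fam[0].mask(ny, 1)])
        truth = rng.normal(size=(3, nz, ny, nx)) + 0j
        phase = rng.normal(0, 0.5, (3, nz, ny, nx))
        data = np.stack([encoding.forward(truth[j], sens, masks[j], phase[j])
                         for j in range(3)])
        from msdager.encoding import KSpaceDataset
        ds = KSpaceDataset(data, masks, sens, sch)
        h = gp.GPHyperparameters(a=1.2, l=1.0, lambda_=0.8,
                                 sigma_n2=np.array([0.1, 0.1]))
        model = gp.build_covariance(sch, h)
        models = {"white": model}
        labels = np.full(nvox, "white")
        mu = rng.normal(size=(nvox, 3))
        sk2 = np.array([0.05, 0.07])

        sol, _ = solve_joint_quadratic(ds, phase, models, mu, labels, sk2,
                                       tol=1e-12, max_iter=500)

        # dense oracle: build the full system matrix explicitly
        def forward_flat(u_flat):
            u = u_flat.reshape(3, nz, ny, nx)
            return np.concatenate([
                (encoding.forward(u[j], sens, masks[j], phase[j]).ravel()
                 / np.sqrt(sk2[0 if sch.bvals[j] < 1500 else 1]))
                for j in range(3)])

        n_unknown = 3 * nvox
        A = np.zeros((forward_flat(np.zeros(n_unknown, complex)).size,
                      n_unknown), dtype=complex)
        for k in range(n_unknown):
            e = np.zeros(n_unknown, dtype=complex)
            e[k] = 1.0
            A[:, k] = forward_flat(e)
        d_flat = np.concatenate([
            (ds.data[j].ravel() / np.sqrt(sk2[0 if sch.bvals[j] < 1500 else 1]))
            for j in range(3)])
        S = model.cov_sigma + 1e-8 * h.lambda_ * np.eye(3)
        Sinv = np.linalg.inv(S)
        P = np.kron(np.eye(nvox), Sinv)  # voxel-major (v, direction) blocks
        # unknown ordering in solver is (direction, voxel); build permutation
        idx = np.arange(n_unknown).reshape(3, nvox).T.ravel()
        lhs = (A.conj().T @ A)
        lhs[np.ix_(idx, idx)] += P
        mu_flat = np.zeros(n_unknown, dtype=complex)
        mu_dirmajor = mu.T.ravel()  # (direction, voxel)
        rhs = A.conj().T @ d_flat
        rhs[idx] += P @ mu_dirmajor[idx]
        u_oracle = np.linalg.solve(lhs, rhs).reshape(3, nz, ny, nx)

        rel = np.linalg.norm(sol.data - u_oracle) / np.linalg.norm(u_oracle)
        assert rel < 1e-8

        # objective agreement at the solution
        obj_pkg = joint_objective(ds, phase, models, mu, labels, sk2, sol.data)

        def dense_objective(u):
            u_flat = u.reshape(3, nvox).T.ravel()  # voxel-major
            mu_vm = mu.ravel()
            r = A @ u.reshape(-1) - d_flat
            pr = u_flat - mu_vm
            return 0.5 * float((r.conj() @ r).real) + \
                0.5 * float((pr.conj() @ (np.kron(np.eye(nvox), Sinv) @ pr)).real)

        obj_dense = dense_objective(sol.data)
        assert obj_pkg == pytest.approx(obj_dense, rel=1e-8)

    def test_objective_nonincreasing_along_cg(self, phantom, coils):
        """The joint objective, evaluated independently, does not increase
        across inner CG iterations."""
        ds = _toy_dataset(phantom, coils, n_per_shell=2, R=3, SMS=4,
                          noise_sd=0.05, seed=5)
        nvox = int(np.prod(phantom.grid_shape))
        h = gp.GPHyperparameters(a=1.0, l=1.0, lambda_=0.05,
                                 sigma_n2=np.array([0.01, 0.01]))
        models = {"white": gp.build_covariance(ds.scheme, h)}
        labels = np.full(nvox, "white")
        mu = np.zeros((nvox, 4))
        phase = np.zeros((4,) + phantom.grid_shape)
        objs = []
        for iters in (1, 3, 6, 12, 25):
            sol, _ = solve_joint_quadratic(ds, phase, models, mu, labels,
                                           np.array([2.5e-3] * 2), tol=1e-14,
                                           max_iter=iters)
            objs.append(joint_objective(ds, phase, models, mu, labels,
                                        np.array([2.5e-3] * 2), sol.data))
        assert all(b <= a + abs(a) * 1e-9 for a, b in zip(objs, objs[1:]))


class TestOuterLoop:
    def test_noiseless_fully_sampled_recovers_truth(self, phantom, coils):
        ds = _toy_dataset(phantom, coils, n_per_shell=2, R=1, SMS=1)
        cfg = ReconConfig(outer_iters=1, max_fit_voxels=300, fit_maxiter=30,
                          refine_phase=False)
        img, diag = msdager_reconstruct(ds, cfg)
        truth = simulator.phantom_signal(phantom, ds.scheme)
        err = (np.linalg.norm(np.abs(img.data) - np.abs(truth.data))
               / np.linalg.norm(truth.data))
        assert err < 1e-5

    def test_dager_improves_on_sense_at_high_acceleration(self, phantom, coils):
        sch = two_shell_scheme(12, n_b0=1, seed=0)
        fam = sampling.enumerate_patterns(3, 4)
        a = sampling.assign_patterns(sch, fam, seed=0)
        s0 = phantom.s0_map[phantom.tissue_mask("white")].mean()
        ds = simulator.simulate_acquisition(phantom, sch, coils, a,
                                            noise_sd=s0 / 20, seed=3)
        obj = phantom.tissue_label > 0
        truth = simulator.phantom_signal(phantom, sch)
        dwi = sch.dwi_indices
        cfg = ReconConfig(outer_iters=2, max_fit_voxels=500, fit_maxiter=50,
                          inner_max_iter=200)
        sense_img, _ = reconstruct(ds, "sense", cfg)
        ms_img, _ = reconstruct(ds, "ms-dager", cfg)
        e_sense = evaluation.nrmse(sense_img.data[dwi], truth.data[dwi], obj)
        e_ms = evaluation.nrmse(ms_img.data[dwi], truth.data[dwi], obj)
        assert e_ms < e_sense

    def test_diagnostics_record_iterations(self, phantom, coils):
        ds = _toy_dataset(phantom, coils, n_per_shell=2, R=3, SMS=4,
                          noise_sd=0.05, seed=1)
        cfg = ReconConfig(outer_iters=2, max_fit_voxels=200, fit_maxiter=20,
                          inner_max_iter=30)
        _, diag = msdager_reconstruct(ds, cfg)
        assert len(diag.iterations) == 2
        for rec in diag.iterations:
            assert "hyper" in rec and "sigma_k2" in rec
            assert rec["sigma0"] > 0

    def test_invalid_method_rejected(self, phantom, coils):
        ds = _toy_dataset(phantom, coils)
        with pytest.raises(ValueError, match="unknown method"):
            reconstruct(ds, "grappa")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(outer_iters=0)
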