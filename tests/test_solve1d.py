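"""1D ADMM solver: oracle equivalence, regularization behavior, determinism."""

import numpy as np
import pytest

from drcsi._spatial import masked_laplacian
from drcsi.kernel import build_kernel
from drcsi.protocol import build_grid, make_protocol_preset
from drcsi.preprocess import extract_1d_subset
from drcsi.solve1d import (
    SolverConfig1D,
    nnls_oracle,
    objective_1d,
    solve_1d_admm,
)
from drcsi.volumes import SignalVolume


def _t1_sub_protocol():
    prot = make_protocol_preset("t1t2")
    sel = np.where(prot.TE == 4.5)[0]
    return prot.subset(sel)


def _single_voxel_volume(M, prot):
    data = M.reshape(1, 1, 1, -1)
    return SignalVolume(
        data=data, mask=np.ones((1, 1, 1), bool), protocol=prot,
        polarity_corrected=True, powder_averaged=True, normalized=True,
    )


class TestNnlsOracle:
    def test_identity_kernel_passthrough(self):
        F = nnls_oracle(np.array([0.3, 0.7]), np.eye(2))
        np.testing.assert_allclose(F, [0.3, 0.7])

    def test_negative_component_clipped(self):
        F = nnls_oracle(np.array([-0.5, 1.0]), np.eye(2))
        np.testing.assert_allclose(F, [0.0, 1.0])

    def test_matches_projected_gradient_on_random_kernel(self):
        """Active-set NNLS and a long projected-gradient run agree on the
        objective to 1e-8."""
        rng = np.random.default_rng(42)
        K = rng.random((8, 60)) * 0.5
        M = K @ (rng.random(60) * (rng.random(60) < 0.1))
        M += rng.normal(0, 0.01, 8)
        F = nnls_oracle(M, K)

        # independent projected-gradient minimization
        x = np.zeros(60)
        step = 1.0 / np.linalg.norm(K.T @ K, 2)
        for _ in range(60000):
            x = np.maximum(x - step * 2 * (K.T @ (K @ x - M)), 0.0)
        obj_as = np.sum((M - K @ F) ** 2)
        obj_pg = np.sum((M - K @ x) ** 2)
        assert obj_as <= obj_pg + 1e-8


class TestAdmmSolver:
    def test_unregularized_matches_nnls_objective(self):
        """lambda_s = 0: ADMM must reach the NNLS oracle objective."""
        prot = _t1_sub_protocol()
        grid = build_grid(["T1"])
        kern = build_kernel(prot, grid)
        rng = np.random.default_rng(0)
        F_true = np.zeros(60)
        F_true[[5, 19]] = [0.2, 0.8]
        M = kern.matrix @ F_true + rng.normal(0, 0.01, prot.P)
        sv = _single_voxel_volume(M, prot)
        field = solve_1d_admm(sv, kern, SolverConfig1D(lambda_s=0.0))
        F = field.masked()[0]
        obj_admm = np.sum((M - kern.matrix @ F) ** 2)
        obj_nnls = np.sum((M - kern.matrix @ nnls_oracle(M, kern)) ** 2)
        assert obj_admm <= obj_nnls * (1 + 1e-6) + 1e-12

    def test_noiseless_delta_recovered(self):
        """A single on-grid component is recovered with >= 99% of its mass
        at the true index (lambda_s = 0, single voxel)."""
        prot = _t1_sub_protocol()
        grid = build_grid(["T1"])
        kern = build_kernel(prot, grid)
        q = 19  # T1 = 1000 ms
        M = kern.matrix[:, q].copy()
        sv = _single_voxel_volume(M, prot)
        field = solve_1d_admm(sv, kern, SolverConfig1D(lambda_s=0.0))
        F = field.masked()[0]
        assert F[q] / F.sum() >= 0.99

    def test_identical_neighbor_voxels_get_identical_spectra(self):
        prot = _t1_sub_protocol()
        grid = build_grid(["T1"])
        kern = build_kernel(prot, grid)
        M = kern.matrix[:, 10] * 0.6 + kern.matrix[:, 40] * 0.4
        data = np.tile(M, (2, 1, 1, 1))
        sv = SignalVolume(
            data, np.ones((2, 1, 1), bool), prot,
            polarity_corrected=True, powder_averaged=True, normalized=True,
        )
        for lam in (0.0, 0.5, 2.0):
            field = solve_1d_admm(sv, kern, SolverConfig1D(lambda_s=lam))
            F = field.masked()
            np.testing.assert_allclose(F[0], F[1], atol=1e-8)

    def test_objective_never_worse_than_zero_spectrum(self, small_t1_fit):
        spec, sv, sub, res = small_t1_fit
        M = sub.masked()
        K = res.model.kernel.matrix
        L = masked_laplacian(sub.mask)
        obj = objective_1d(res.spectra.masked(), M, K, L, 0.5)
        obj_zero = objective_1d(np.zeros_like(res.spectra.masked()), M, K, L, 0.5)
        assert obj <= obj_zero

    def test_spatial_coupling_decreases_with_lambda(self, small_conditioned):
        """The neighbor-difference term at the solution is non-increasing in
        lambda_s over {0, 0.1, 0.5, 2}."""
        spec, sv = small_conditioned
        sub = extract_1d_subset(sv, "T1")
        grid = build_grid(["T1"])
        kern = build_kernel(sub.protocol, grid)
        L = masked_laplacian(sub.mask)
        coupling = []
        for lam in (0.0, 0.1, 0.5, 2.0):
            field = solve_1d_admm(sub, kern, SolverConfig1D(lambda_s=lam))
            F = field.masked()
            coupling.append(2.0 * float(np.sum(F * (L @ F))))
        for a, b in zip(coupling, coupling[1:]):
            assert b <= a * 1.01 + 1e-12

    def test_solution_invariant_to_voxel_enumeration(self):
        """Transposing a 3 x 3 patch permutes voxel order but not the
        spectra each voxel receives."""
        prot = _t1_sub_protocol()
        grid = build_grid(["T1"])
        kern = build_kernel(prot, grid)
        rng = np.random.default_rng(8)
        F_true = rng.random((3, 3, 1, 60)) * (rng.random((3, 3, 1, 60)) < 0.05)
        data = F_true @ kern.matrix.T + rng.normal(0, 0.005, (3, 3, 1, 8))
        mask = np.ones((3, 3, 1), bool)
        sv = SignalVolume(data, mask, prot, polarity_corrected=True,
                          powder_averaged=True, normalized=True)
        svT = SignalVolume(np.transpose(data, (1, 0, 2, 3)), mask, prot,
                           polarity_corrected=True, powder_averaged=True,
                           normalized=True)
        cfg = SolverConfig1D(lambda_s=0.5)
        FA = solve_1d_admm(sv, kern, cfg).data
        FB = solve_1d_admm(svT, kern, cfg).data
        np.testing.assert_allclose(FA, np.transpose(FB, (1, 0, 2, 3)), atol=1e-6)

    def test_deterministic_given_config(self):
        prot = _t1_sub_protocol()
        grid = build_grid(["T1"])
        kern = build_kernel(prot, grid)
        rng = np.random.default_rng(2)
        data = rng.random((4, 4, 1, 8)) * 0.3
        sv = SignalVolume(data, np.ones((4, 4, 1), bool), prot,
                          polarity_corrected=True, powder_averaged=True,
                          normalized=True)
        a = solve_1d_admm(sv, kern, SolverConfig1D())
        b = solve_1d_admm(sv, kern, SolverConfig1D())
        np.testing.assert_array_equal(a.data, b.data)

    def test_nonfinite_signals_rejected(self):
        prot = _t1_sub_protocol()
        kern = build_kernel(prot, build_grid(["T1"]))
        data = np.full((1, 1, 1, 8), np.nan)
        sv = SignalVolume(data, np.ones((1, 1, 1), bool), prot)
        with pytest.raises(ValueError, match="finite"):
            solve_1d_admm(sv, kern)

    def test_convergence_log_reported(self):
        prot = _t1_sub_protocol()
        kern = build_kernel(prot, build_grid(["T1"]))
        M = kern.matrix[:, 12]
        sv = _single_voxel_volume(M, prot)
        field, log = solve_1d_admm(sv, kern, SolverConfig1D(max_iter=5),
                                   full_output=True)
        assert not log.converged and log.n_iter == 5
        assert len(log.objective) == 5
        frame = log.to_frame()
        assert list(frame.columns) == [
            "iteration", "primal_residual", "dual_residual", "objective",
        ]
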