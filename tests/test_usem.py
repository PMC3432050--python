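"""uSEM estimation: lagged covariance, ML fit, indices, modification indices."""

import numpy as np
import pytest
from scipy import optimize, stats

from aglnet.simulate import (
    ConnectivityGroundTruth,
    make_schedule,
    simulate_subject,
)
from aglnet.usem import (
    LaggedCovariance,
    USEMModel,
    UnifiedSEM,
    build_lagged_covariance,
    fit_indices,
    implied_covariance,
    modification_indices,
    pool_group_covariance,
)


def white_noise_truth(p=4, sd=1.0):
    return ConnectivityGroundTruth(
        A=np.zeros((p, p)), Phi=np.zeros((p, p)), noise_sd=np.full(p, sd)
    )


class TestLaggedCovariance:
    def test_output_is_8x8_for_4_rois(self, planted_group):
        S, n = build_lagged_covariance(planted_group[0])
        assert S.shape == (8, 8)
        assert n == 8 * 12  # 12 within-block pairs per 13-scan task block

    def test_white_noise_has_near_zero_off_diagonals(self):
        sched = make_schedule(60, 2.0)
        s = simulate_subject(white_noise_truth(), sched, seed=0)
        S, n = build_lagged_covariance(s, condition_filter={"task", "fixation"})
        off = S[~np.eye(8, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(n))
        assert np.allclose(np.diag(S), 1.0, atol=0.1)

    def test_ar_coefficient_appears_as_standardized_lag_entry(self):
        truth = white_noise_truth()
        Phi = np.zeros((4, 4))
        Phi[0, 0] = 0.5
        truth = ConnectivityGroundTruth(A=truth.A, Phi=Phi, noise_sd=np.ones(4))
        sched = make_schedule(300, 2.0)
        s = simulate_subject(truth, sched, seed=1)
        S, n = build_lagged_covariance(s, condition_filter={"task", "fixation"})
        # correlation of ROI1 with itself one scan later
        assert S[4, 0] == pytest.approx(0.5, abs=0.05)

    def test_pairs_do_not_span_condition_boundaries(self, truth):
        sched = make_schedule(8, 2.0)
        s = simulate_subject(truth, sched, seed=2)
        _, n_task = build_lagged_covariance(s, {"task"})
        _, n_fix = build_lagged_covariance(s, {"fixation"})
        assert n_task == 8 * (13 - 1)
        assert n_fix == 9 * (8 - 1)

    def test_too_few_pairs_is_an_error(self, truth):
        from aglnet.simulate import DesignSchedule, ROITimeSeries

        # 20 scans with task split into 2-scan islands: 5 usable pairs only
        labels = (("fixation",) * 2 + ("task",) * 2) * 5
        sched = DesignSchedule(
            tr_seconds=2.0, n_blocks=5, block_seconds=4,
            instruction_seconds=0, rest_seconds=4,
            condition_labels=labels, instruction_scans=(False,) * 20,
        )
        rng = np.random.default_rng(3)
        series = ROITimeSeries(
            subject_id="s", data=rng.normal(size=(20, 4)),
            tr_seconds=2.0, schedule=sched,
        )
        with pytest.raises(ValueError, match="pairs"):
            build_lagged_covariance(series, {"task"})


class TestPooling:
    def test_identical_matrices_pool_to_themselves(self):
        S = np.eye(8)
        pooled = pool_group_covariance([S, S, S], [50, 50, 50])
        assert np.allclose(pooled.S, S)
        assert pooled.n_effective == 150 - 3

    def test_equal_counts_give_elementwise_mean(self):
        rng = np.random.default_rng(0)
        A1 = rng.normal(size=(8, 8))
        S1, S2 = A1 @ A1.T, np.eye(8)
        pooled = pool_group_covariance([S1, S2], [30, 30])
        assert np.allclose(pooled.S, (S1 + S2) / 2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="8x8"):
            pool_group_covariance([np.eye(6)], [20])


class TestImpliedCovariance:
    @staticmethod
    def model(A, Phi, psi, exog):
        p = A.shape[0]
        names = tuple(f"R{i}" for i in range(p))
        return USEMModel(
            A=A, Phi=Phi, psi=psi, exog_cov=exog,
            free_mask_a=A != 0, free_mask_phi=Phi != 0,
            se_a=np.zeros((p, p)), se_phi=np.zeros((p, p)), roi_names=names,
        )

    def test_null_model_implies_identity(self):
        m = self.model(np.zeros((4, 4)), np.zeros((4, 4)), np.ones(4), np.eye(4))
        assert np.allclose(implied_covariance(m), np.eye(8))

    def test_single_lagged_path_cross_entry(self):
        Phi = np.zeros((4, 4))
        Phi[2, 1] = 0.5
        exog = np.diag([1.0, 2.0, 1.0, 1.0])
        m = self.model(np.zeros((4, 4)), Phi, np.ones(4), exog)
        sigma = implied_covariance(m)
        # cov(eta_{t+1} ROI3, eta_t ROI2) = 0.5 * var(ROI2)
        assert sigma[4 + 2, 1] == pytest.approx(0.5 * 2.0)

    def test_saturated_fit_reproduces_sample_exactly(self):
        rng = np.random.default_rng(3)
        X = rng.multivariate_normal(np.zeros(8), np.eye(8), size=200)
        S = np.cov(X, rowvar=False)
        est = UnifiedSEM(free_a="full", free_phi="full").fit_covariance(
            LaggedCovariance(S=S, n_effective=200)
        )
        assert est.discrepancy_ == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(est.implied_cov_, S, atol=1e-5)
        assert est.fit_indices_.saturated

    def test_singular_i_minus_a_raises(self):
        A = np.zeros((2, 2))
        A[0, 1] = A[1, 0] = 1.0  # (I-A) singular
        m = USEMModel(
            A=A, Phi=np.zeros((2, 2)), psi=np.ones(2), exog_cov=np.eye(2),
            free_mask_a=A != 0, free_mask_phi=np.zeros((2, 2), bool),
            se_a=np.zeros((2, 2)), se_phi=np.zeros((2, 2)),
            roi_names=("R0", "R1"),
        )
        with pytest.raises(np.linalg.LinAlgError):
            implied_covariance(m)


class TestMLFit:
    def test_chi2_over_df_near_one_under_true_null(self):
        """White-noise data fitted with the empty mask: mean chi2/df ~ 1."""
        ratios = []
        for r in range(60):
            rng = np.random.default_rng(100 + r)
            X = rng.multivariate_normal(np.zeros(8), np.eye(8), size=400)
            S = np.cov(X, rowvar=False)
            est = UnifiedSEM(free_a=None, free_phi=None).fit_covariance(
                LaggedCovariance(S=S, n_effective=400)
            )
            ratios.append(est.chi2_ / est.df_)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_estimates_within_two_se_of_truth(self, truth, planted_data):
        """True-mask fit on the planted group: ~95% coverage of 2-SE bands.

        The series are standardized per subject, so compare against the
        correlation-scale truth coefficients implied by the stationary
        covariance."""
        from aglnet.simulate import stationary_covariance

        V = stationary_covariance(truth)
        d = np.sqrt(np.diag(V))
        A_std = truth.A * (d[None, :] / d[:, None])
        Phi_std = truth.Phi * (d[None, :] / d[:, None])
        est = UnifiedSEM(
            free_a=truth.A != 0, free_phi=truth.Phi != 0
        ).fit_covariance(planted_data)
        m = est.model_
        hits, total = 0, 0
        for i in range(4):
            for j in range(4):
                if truth.A[i, j] != 0:
                    total += 1
                    hits += abs(m.A[i, j] - A_std[i, j]) < 2.5 * m.se_a[i, j]
                if truth.Phi[i, j] != 0:
                    total += 1
                    hits += abs(m.Phi[i, j] - Phi_std[i, j]) < 2.5 * m.se_phi[i, j]
        assert hits / total >= 0.9

    def test_nonpsd_input_rejected(self):
        S = np.eye(8)
        S[0, 0] = -1.0
        with pytest.raises(ValueError, match="positive definite"):
            UnifiedSEM().fit_covariance(LaggedCovariance(S=S, n_effective=100))

    def test_ml_fit_agrees_with_brute_force_optimization(self):
        """Three-ROI toys: the analytic-gradient fit matches an independent
        Nelder-Mead minimization of the discrepancy to 1e-4."""
        p = 3
        free_a = np.zeros((p, p), dtype=bool)
        free_a[1, 0] = True
        free_phi = np.eye(p, dtype=bool)

        def implied(theta):
            # independent reconstruction of the implied covariance
            S_xx = np.zeros((p, p))
            idx = np.tril_indices(p)
            S_xx[idx] = theta[:6]
            S_xx = S_xx + np.tril(S_xx, -1).T
            psi = theta[6:9]
            A = np.zeros((p, p))
            A[1, 0] = theta[9]
            Phi = np.diag(theta[10:13])
            B = np.linalg.inv(np.eye(p) - A)
            syx = B @ Phi @ S_xx
            syy = B @ (Phi @ S_xx @ Phi.T + np.diag(psi)) @ B.T
            return np.block([[S_xx, syx.T], [syx, syy]])

        def discrepancy(theta, S):
            sigma = implied(theta)
            try:
                np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                return 1e6
            _, logdet = np.linalg.slogdet(sigma)
            return (
                logdet
                + np.trace(S @ np.linalg.inv(sigma))
                - np.linalg.slogdet(S)[1]
                - 2 * p
            )

        rng = np.random.default_rng(7)
        for _ in range(3):
            G = rng.normal(size=(2 * p, 2 * p))
            S = G @ G.T / (2 * p) + 0.5 * np.eye(2 * p)
            est = UnifiedSEM(free_a=free_a, free_phi=free_phi).fit_covariance(
                LaggedCovariance(
                    S=S, n_effective=100, roi_names=("R0", "R1", "R2")
                )
            )
            start = np.concatenate(
                [S[:p, :p][np.tril_indices(p)], np.diag(S[p:, p:]), [0.0], [0, 0, 0]]
            )
            best = None
            for jitter in range(4):
                x0 = start * (1 + 0.05 * jitter) + 0.01 * jitter
                res = optimize.minimize(
                    discrepancy, x0, args=(S,), method="Nelder-Mead",
                    options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
                )
                if best is None or res.fun < best.fun:
                    best = res
            assert est.discrepancy_ == pytest.approx(best.fun, abs=1e-4)
            assert est.model_.A[1, 0] == pytest.approx(best.x[9], abs=1e-3)


class TestFitIndices:
    def test_perfect_fit(self):
        out = fit_indices(0.0, 10, 500.0, 28, np.eye(8), np.eye(8), 200)
        assert out.rmsea == 0.0
        assert out.cfi == 1.0

    def test_chi2_equal_df_gives_zero_rmsea(self):
        out = fit_indices(10.0, 10, 500.0, 28, np.eye(8), np.eye(8), 200)
        assert out.rmsea == 0.0

    def test_worked_example(self):
        out = fit_indices(20.0, 10, 500.0, 28, np.eye(8), np.eye(8), 201)
        assert out.rmsea == pytest.approx(np.sqrt(10 / 2000), abs=1e-12)

    def test_srmr_of_exact_fit_is_zero(self):
        S = np.eye(8) * 2.0
        out = fit_indices(0.0, 10, 500.0, 28, S, S.copy(), 200)
        assert out.srmr == 0.0

    def test_saturated_flagged_at_zero_df(self):
        out = fit_indices(0.0, 0, 500.0, 28, np.eye(8), np.eye(8), 200)
        assert out.saturated and out.rmsea == 0.0 and out.cfi == 1.0


class TestModificationIndices:
    def test_strong_omitted_path_ranks_first(self):
        """Data generated with one strong contemporaneous path: freeing that
        path has the largest expected chi2 drop."""
        p = 4
        A = np.zeros((p, p))
        A[1, 0] = 0.6
        truth = ConnectivityGroundTruth(
            A=A, Phi=np.eye(p) * 0.3, noise_sd=np.ones(p)
        )
        sched = make_schedule(60, 2.0)
        s = simulate_subject(truth, sched, seed=0)
        S, n = build_lagged_covariance(s, {"task", "fixation"})
        data = LaggedCovariance(S=S, n_effective=n)
        est = UnifiedSEM(free_a=None, free_phi="ar").fit_covariance(data)
        mis = modification_indices(est)
        top = mis[0]
        assert (top["kind"], top["source"], top["target"]) == (
            "contemporaneous", "IFG", "INS",
        )

    def test_all_indices_nonnegative(self, planted_data):
        est = UnifiedSEM(free_a=None, free_phi="ar").fit_covariance(planted_data)
        assert all(rec["mi"] >= 0 for rec in modification_indices(est))

    def test_saturated_model_has_no_candidates(self):
        rng = np.random.default_rng(5)
        X = rng.multivariate_normal(np.zeros(8), np.eye(8), size=200)
        S = np.cov(X, rowvar=False)
        est = UnifiedSEM(free_a="full", free_phi="full").fit_covariance(
            LaggedCovariance(S=S, n_effective=200)
        )
        assert modification_indices(est) == []
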