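import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

from adrpath import inference
from .conftest import logistic_instance


def unpenalized_oracle(X, y):
    """Generic convex-optimizer fit of the plain logistic likelihood."""
    def nll(w):
        eta = w[0] + X @ w[1:]
        return np.mean(np.logaddexp(0.0, eta) - y * eta)
    res = minimize(nll, np.zeros(X.shape[1] + 1), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    return res.x


class TestLambdaMax:
    def test_hand_arithmetic_two_points(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, 0.0])
        assert inference.compute_lambda_max(X, y) == pytest.approx(0.5)

    def test_orthogonal_feature_gives_zero(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])  # X'(y - ybar) = 0
        assert inference.compute_lambda_max(X, y) == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            inference.compute_lambda_max(np.ones((3, 1)), np.ones(3))

    def test_fit_above_lambda_max_is_exactly_zero(self):
        rng = np.random.default_rng(1)
        X, y = logistic_instance(rng, 80, 6)
        lam_max = inference.compute_lambda_max(X, y)
        fit = inference.fit_l1_logistic(X, y, 1.01 * lam_max)
        assert np.all(fit.weights == 0.0)
        assert fit.converged


class TestL1Fit:
    def test_kkt_certificate_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            X, y = logistic_instance(rng, rng.integers(40, 120), rng.integers(2, 10))
            lam_max = inference.compute_lambda_max(X, y)
            for rel in (0.05, 0.3, 0.8):
                fit = inference.fit_l1_logistic(X, y, rel * lam_max)
                assert fit.converged
                assert fit.kkt_residual <= 1e-6

    def test_unpenalized_matches_convex_oracle(self):
        rng = np.random.default_rng(13)
        X, y = logistic_instance(rng, 150, 5)
        fit = inference.fit_l1_logistic(X, y, 0.0)
        ref = unpenalized_oracle(X, y)
        np.testing.assert_allclose(np.r_[fit.intercept, fit.weights], ref, atol=1e-4)

    def test_l1_norm_monotone_along_penalty_path(self):
        rng = np.random.default_rng(21)
        X, y = logistic_instance(rng, 100, 8)
        lam_max = inference.compute_lambda_max(X, y)
        norms = [
            np.abs(inference.fit_l1_logistic(X, y, rel * lam_max).weights).sum()
            for rel in (0.02, 0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            inference.fit_l1_logistic(np.ones((4, 1)), np.array([0, 1, 0, 1.0]), -0.1)


def make_xy_frames(rng, n=120, p=6, informative=(0,), effect=1.5, n_adrs=2):
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"d{i}" for i in range(n)],
        columns=[f"pw{j}" for j in range(p)],
    )
    Y = {}
    for a in range(n_adrs):
        eta = -0.5 + sum(effect * X.iloc[:, j] for j in informative)
        Y[f"adr{a}"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, pd.DataFrame(Y, index=X.index)


class TestPhase1:
    def test_rel_lambda_one_returns_nothing(self):
        rng = np.random.default_rng(3)
        X, Y = make_xy_frames(rng)
        assert len(inference.phase1_select(X, Y, rel_lambda=1.0)) == 0

    def test_planted_signal_is_screened_in(self):
        rng = np.random.default_rng(4)
        X, Y = make_xy_frames(rng, effect=2.0)
        cands = inference.phase1_select(X, Y, rel_lambda=0.1)
        for adr in Y.columns:
            assert "pw0" in set(cands[cands.adr_group == adr].pathway_id)

    def test_candidate_count_nonincreasing_in_penalty(self):
        rng = np.random.default_rng(5)
        X, Y = make_xy_frames(rng)
        counts = [
            len(inference.phase1_select(X, Y, rel_lambda=rel))
            for rel in (0.05, 0.1, 0.3, 0.6, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_single_class_adr_skipped(self):
        rng = np.random.default_rng(6)
        X, Y = make_xy_frames(rng)
        Y["dead"] = 0
        cands = inference.phase1_select(X, Y, rel_lambda=0.1)
        assert "dead" not in set(cands.adr_group)


def exhaustive_best_aic(X_cand, y):
    """Independent oracle: fit every subset, return the minimal AIC."""
    Z, mask = inference.standardize(X_cand.to_numpy(dtype=float))
    names = [n for n, m in zip(X_cand.columns, mask) if m]
    Z = Z[:, mask]
    best = (np.inf, ())
    for k in range(len(names) + 1):
        for subset in itertools.combinations(range(len(names)), k):
            design = sm.add_constant(Z[:, list(subset)], has_constant="add")
            try:
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            except Exception:
                continue
            if res.mle_retvals.get("converged", False) and np.abs(res.params).max() < 1e3:
                if res.aic < best[0]:
                    best = (float(res.aic), tuple(names[j] for j in subset))
    return best


class TestStepwiseAIC:
    def test_empty_candidates_gives_intercept_only(self):
        y = np.array([0, 1, 0, 1, 1.0])
        fit = inference.stepwise_aic(pd.DataFrame(index=range(5)), y)
        assert fit.selected == []
        # intercept-only AIC = 2 - 2 lnL at p = mean(y)
        p = y.mean()
        ll = len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p))
        assert fit.aic == pytest.approx(2 - 2 * ll, rel=1e-10)

    def test_selects_informative_feature(self):
        rng = np.random.default_rng(8)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        eta = -0.3 + 2.0 * X.a
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = inference.stepwise_aic(X, y)
        assert "a" in fit.selected
        assert fit.wald_p["a"] < 1e-4

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            X, y = logistic_instance(rng, 120, 5)
            Xf = pd.DataFrame(X, columns=[f"f{j}" for j in range(5)])
            fit = inference.stepwise_aic(Xf, y)
            best_aic, best_set = exhaustive_best_aic(Xf, y)
            assert fit.aic >= best_aic - 1e-8
            if set(best_set) == set(fit.selected):
                assert fit.aic == pytest.approx(best_aic, rel=1e-9)

    def test_aic_formula(self):
        rng = np.random.default_rng(10)
        X, y = logistic_instance(rng, 90, 3)
        Xf = pd.DataFrame(X, columns=list("abc"))
        fit = inference.stepwise_aic(Xf, y)
        Z, mask = inference.standardize(Xf[fit.selected].to_numpy()) if fit.selected else (np.empty((90, 0)), None)
        design = sm.add_constant(Z, has_constant="add")
        res = sm.Logit(y, design).fit(disp=0)
        k = len(fit.selected) + 1
        assert fit.aic == pytest.approx(2 * k - 2 * res.llf, rel=1e-9)

    def test_perfect_separation_flagged(self):
        X = pd.DataFrame({"s": np.r_[np.ones(10), -np.ones(10)]})
        y = np.r_[np.ones(10), np.zeros(10)]
        fit = inference.stepwise_aic(X, y)
        for name in fit.separated:
            assert fit.wald_p[name] == 1.0


def brute_force_bh(p, fdr):
    """Direct statement of the step-up rule."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * fdr / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBH:
    def test_hand_step_up(self):
        q, reject = inference.bh_adjust([0.01, 0.02, 0.03, 0.5], fdr=0.05)
        assert reject.tolist() == [True, True, True, False]

    def test_boundary_single_p(self):
        _, reject = inference.bh_adjust([0.02], fdr=0.02)
        assert reject.tolist() == [True]

    def test_all_ones_none_rejected(self):
        _, reject = inference.bh_adjust([1.0, 1.0, 1.0], fdr=0.1)
        assert not reject.any()

    def test_empty_list(self):
        q, reject = inference.bh_adjust([], fdr=0.02)
        assert len(q) == 0 and len(reject) == 0

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            m = rng.integers(1, 30)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            p = np.clip(p, 1e-12, 1.0)
            fdr = rng.uniform(0.01, 0.2)
            _, reject = inference.bh_adjust(p, fdr=fdr)
            np.testing.assert_array_equal(reject, brute_force_bh(p, fdr))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            inference.bh_adjust([0.0, 0.5])


class TestInferAssociations:
    def test_candidate_universe_arithmetic(self):
        pathways = [f"pw{i}" for i in range(176)]
        adrs = [f"a{i}" for i in range(506)]
        assert sum(1 for _ in inference.candidate_universe(pathways, adrs)) == 89_056

    def test_deterministic(self, small_xy):
        X, Y = small_xy
        a1 = inference.infer_associations(X, Y)
        a2 = inference.infer_associations(X, Y)
        pd.testing.assert_frame_equal(a1, a2)

    def test_planted_effects_recovered(self, small_bundle, small_xy):
        # at this fixture's size power is partial: every planted pair must
        # survive the phase-1 screen, and at least one must reach significance
        X, Y = small_xy
        assoc = inference.infer_associations(X, Y, rel_lambda=0.1, fdr=0.02)
        cands = {(r.pathway_id, r.adr_group) for r in assoc.itertuples()}
        sig = {(r.pathway_id, r.adr_group) for r in assoc.itertuples() if r.significant}
        assert small_bundle.truth.planted <= cands
        assert small_bundle.truth.planted & sig

    def test_phase2_fields_only_for_stepwise_survivors(self, small_xy):
        X, Y = small_xy
        assoc = inference.infer_associations(X, Y)
        dropped = assoc[assoc.p_value.isna()]
        assert not dropped.significant.any()
        assert dropped.q_value.isna().all()
        sig = assoc[assoc.significant]
        assert (sig.q_value <= 0.02 + 1e-12).all()

    def test_misaligned_drug_ordering_rejected(self, small_xy):
        X, Y = small_xy
        with pytest.raises(ValueError):
            inference.infer_associations(X.iloc[::-1], Y)

    def test_fdr_range_validated(self, small_xy):
        X, Y = small_xy
        with pytest.raises(ValueError):
            inference.infer_associations(X, Y, fdr=0.0)
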