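"""ML estimation: discrepancy function, optimizer, standardization, indices.

The independent oracle for estimation correctness is the classical
equivalence, for recursive observed-variable models with uncorrelated
disturbances and a saturated exogenous block, between covariance-structure
ML and equation-wise ordinary least squares: each endogenous variable's
coefficients are the OLS solution from the sample moments, and the implied
covariance follows by direct recursion over the causal order.  That oracle
is implemented here from scratch (closed-form linear algebra, no shared
code with the fitting routine).
"""

import numpy as np
import pandas as pd
import pytest

import traitsem as ts
from traitsem.fit import FitError, baseline_fit, fit_indices

# ---------------------------------------------------------------------------
# helpers


def _random_corr(p: int, seed: int, n: int = 120) -> np.ndarray:
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    return np.corrcoef(x, rowvar=False)


def _random_recursive_model(p: int, seed: int) -> ts.ModelSpec:
    """Random DAG over p observed variables, saturated exogenous block."""
    rng = np.random.default_rng(seed)
    names = tuple(f"v{j}" for j in range(p))
    paths = []
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < 0.5:
                paths.append((names[i], names[j]))
    if not paths:  # ensure at least one edge
        paths.append((names[0], names[-1]))
    targets = {t for _, t in paths}
    exog = [v for v in names if v not in targets]
    covs = [
        (exog[a], exog[b])
        for a in range(len(exog))
        for b in range(a + 1, len(exog))
    ]
    return ts.ModelSpec(names, {}, tuple(paths), tuple(covs))


def _ols_oracle(spec: ts.ModelSpec, sample: np.ndarray):
    """Equation-wise OLS estimates and the implied covariance by recursion."""
    names = list(spec.observed)
    idx = {v: i for i, v in enumerate(names)}
    coef: dict[tuple[str, str], float] = {}
    resid: dict[str, float] = {}
    for v in names:
        parents = spec.parents(v)
        if not parents:
            continue
        pi = [idx[u] for u in parents]
        b = np.linalg.solve(sample[np.ix_(pi, pi)], sample[pi, idx[v]])
        for u, bu in zip(parents, b):
            coef[(u, v)] = float(bu)
        resid[v] = float(
            sample[idx[v], idx[v]] - b @ sample[np.ix_(pi, pi)] @ b
        )
    # implied covariance by recursion over the causal order
    implied = np.zeros_like(sample)
    for v in spec.topological_order():
        i = idx[v]
        parents = spec.parents(v)
        if not parents:
            # exogenous block is saturated: implied moments = sample moments
            for u in names:
                if not spec.parents(u):
                    implied[i, idx[u]] = implied[idx[u], i] = sample[i, idx[u]]
            continue
        for u in names:
            j = idx[u]
            cov = sum(coef[(w, v)] * implied[idx[w], j] for w in parents)
            if u == v:
                cov += resid[v]
            implied[i, j] = implied[j, i] = cov
    return coef, implied


# ---------------------------------------------------------------------------
# implied covariance and discrepancy


class TestImpliedCovariance:
    def test_no_paths_returns_shock_block(self):
        spec = ts.ModelSpec(("X", "Y"))
        ram = ts.build_ram(spec)
        sigma = ts.implied_covariance(ram, np.array([1.0, 1.0]))
        np.testing.assert_allclose(sigma, np.eye(2))

    def test_single_path_algebra(self):
        spec = ts.parse_model_spec("path X -> Y")
        ram = ts.build_ram(spec)
        b = 0.6
        theta = np.zeros(3)
        theta[ram.labels.index("X→Y")] = b
        theta[ram.labels.index("var(X)")] = 1.0
        theta[ram.labels.index("var(eY)")] = 1 - b * b
        sigma = ts.implied_covariance(ram, theta)
        np.testing.assert_allclose(sigma, [[1, b], [b, 1]], atol=1e-14)

    def test_chain_matches_monte_carlo(self):
        """cov(X, Z) in a chain X->M->Z equals b1*b2, checked by simulation."""
        b1, b2 = 0.7, -0.5
        spec = ts.parse_model_spec("path X -> M\npath M -> Z")
        sim = ts.SimSpec(
            spec=spec, values={"X→M": b1, "M→Z": b2}, n=1_000_000, seed=42
        )
        tab = ts.simulate_model(sim)
        x = tab.values()
        got = np.cov(x[:, 0], x[:, 2])[0, 1]
        se = 3.0 / np.sqrt(sim.n)  # CLT width for a unit-variance product
        assert abs(got - b1 * b2) < 3 * se + 3e-3


class TestMlDiscrepancy:
    def test_zero_iff_equal(self):
        s = _random_corr(4, 1)
        assert ts.ml_discrepancy(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self):
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        f = ts.ml_discrepancy(s, np.eye(2))
        assert f == pytest.approx(-np.log(0.75), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_positive_on_distinct_pd_pairs(self, seed):
        s = _random_corr(4, seed)
        sigma = _random_corr(4, seed + 100)
        assert ts.ml_discrepancy(s, sigma) > 0

    def test_invariant_under_joint_reordering(self):
        s = _random_corr(5, 3)
        sigma = _random_corr(5, 7)
        perm = np.array([3, 0, 4, 1, 2])
        f1 = ts.ml_discrepancy(s, sigma)
        f2 = ts.ml_discrepancy(s[np.ix_(perm, perm)], sigma[np.ix_(perm, perm)])
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_non_pd_input_suggests_repair(self):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(FitError, match="nearest_psd"):
            ts.ml_discrepancy(bad, np.eye(2))


# ---------------------------------------------------------------------------
# fitting


class TestFitMl:
    def test_recovers_generating_parameters(self, models):
        """Fitting the implied covariance of known parameters returns them."""
        spec = models["nmass_final"]
        ram = ts.build_ram(spec)
        rng = np.random.default_rng(2)
        theta = np.zeros(ram.n_free)
        for k, label in enumerate(ram.labels):
            if label.startswith("var("):
                theta[k] = 0.5 + rng.random()
            elif label.startswith("load("):
                theta[k] = 0.8
            elif label.startswith("cov("):
                theta[k] = 0.2
            else:
                theta[k] = rng.uniform(-0.5, 0.5)
        sigma = ts.implied_covariance(ram, theta)
        moments = ts.CorrMatrix(
            names=spec.observed, values=sigma, n=90, is_correlation=False
        )
        fit = ts.fit_ml(spec, moments, seed=0, compute_se=False)
        assert fit.converged
        assert fit.f_min < 1e-10
        assert fit.chi2 == pytest.approx(0.0, abs=1e-7)
        np.testing.assert_allclose(fit.theta, theta, atol=1e-4)

    def test_saturated_model_chi2_zero(self):
        spec = ts.parse_model_spec("path X -> Y")
        s = np.array([[1.0, -0.4], [-0.4, 1.0]])
        fit = ts.fit_ml(
            spec, ts.CorrMatrix(("X", "Y"), s, n=50), compute_se=False
        )
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.pvalue == 1.0

    def test_single_path_standardized_equals_correlation(self):
        spec = ts.parse_model_spec("path X -> Y")
        r = 0.37
        s = np.array([[1.0, r], [r, 1.0]])
        fit = ts.fit_ml(
            spec, ts.CorrMatrix(("X", "Y"), s, n=50), compute_se=False
        )
        assert fit.std_path("X", "Y") == pytest.approx(r, abs=1e-8)
        assert fit.r2["Y"] == pytest.approx(r * r, abs=1e-8)

    def test_standardized_solution_scale_invariant(self, models, study_moments):
        """Rescaling the input covariance by any positive diagonal leaves the
        standardized solution unchanged."""
        spec = models["narea_final"]
        base = ts.fit_ml(spec, study_moments, seed=1, compute_se=False)
        sub = study_moments.submatrix(list(spec.observed))
        rng = np.random.default_rng(9)
        d = rng.uniform(0.5, 3.0, size=sub.p)
        scaled = ts.CorrMatrix(
            names=sub.names,
            values=sub.values * np.outer(d, d),
            n=sub.n,
            is_correlation=False,
        )
        refit = ts.fit_ml(spec, scaled, seed=1, compute_se=False)
        for label, value in base.std_estimates.items():
            assert refit.std_estimates[label] == pytest.approx(
                value, abs=1e-6
            ), label

    def test_insufficient_sample_size_rejected(self, models, study_moments):
        small = ts.CorrMatrix(
            study_moments.names, study_moments.values, n=5
        )
        with pytest.raises(FitError, match="exceed"):
            ts.fit_ml(models["nmass_final"], small)

    @pytest.mark.parametrize("seed", range(20))
    def test_ols_oracle_equivalence(self, seed):
        """Standardized ML estimates match the closed-form OLS oracle."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 7))
        spec = _random_recursive_model(p, seed)
        sample = _random_corr(p, seed + 1000)
        moments = ts.CorrMatrix(spec.observed, sample, n=200)
        fit = ts.fit_ml(spec, moments, seed=0, n_restarts=2, compute_se=False)
        assert fit.converged
        coef, implied = _ols_oracle(spec, sample)
        sd = np.sqrt(np.diag(implied))
        idx = {v: i for i, v in enumerate(spec.observed)}
        for (u, v), b in coef.items():
            expected = b * sd[idx[u]] / sd[idx[v]]
            assert fit.std_path(u, v) == pytest.approx(
                expected, abs=1e-3
            ), f"{u}->{v} (seed {seed})"

    def test_parameter_recovery_large_sample(self, models, nmass_fit):
        """Simulated data at n=5000 from the fitted Nmass system refits to
        standardized paths within +-0.03 of the truth."""
        spec = models["nmass_final"]
        truth = ts.values_from_fit(nmass_fit)
        tab = ts.simulate_model(
            ts.SimSpec(spec=spec, values=truth, n=5000, seed=77)
        )
        refit = ts.fit_ml(
            spec, ts.pearson_matrix(tab), seed=0, compute_se=False
        )
        assert refit.converged
        for s, t in spec.paths:
            assert refit.std_path(s, t) == pytest.approx(
                nmass_fit.std_path(s, t), abs=0.03
            ), f"{s}->{t}"


# ---------------------------------------------------------------------------
# baseline, indices, standard errors


class TestIndices:
    def test_baseline_identity_input(self):
        m = ts.CorrMatrix(("a", "b", "c"), np.eye(3), n=40)
        chi2_b, df_b = baseline_fit(m)
        assert chi2_b == pytest.approx(0.0, abs=1e-12)
        assert df_b == 3

    def test_baseline_closed_form(self):
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        chi2_b, _ = baseline_fit(ts.CorrMatrix(("a", "b"), s, n=51))
        assert chi2_b == pytest.approx(50 * -np.log(0.75), abs=1e-10)

    def test_baseline_dominates_nested_models(self, nmass_fit):
        chi2_b, _ = baseline_fit(nmass_fit.moments)
        assert chi2_b >= nmass_fit.chi2

    def test_perfect_fit_gives_rmsea_zero_cfi_one(self, models):
        spec = models["nmass_final"]
        ram = ts.build_ram(spec)
        theta = np.full(ram.n_free, 0.3)
        theta[ram.is_variance()] = 0.8
        sigma = ts.implied_covariance(ram, theta)
        moments = ts.CorrMatrix(
            spec.observed, sigma, n=90, is_correlation=False
        )
        fit = ts.fit_ml(spec, moments, compute_se=False)
        assert fit.indices["rmsea"] == pytest.approx(0.0, abs=1e-9)
        assert fit.indices["cfi"] == 1.0

    def test_agfi_below_gfi_below_one(self, nmass_fit, narea_fit):
        for fit in (nmass_fit, narea_fit):
            assert fit.indices["agfi"] <= fit.indices["gfi"] <= 1.0

    def test_aic_convention(self, nmass_fit):
        assert nmass_fit.aic == pytest.approx(
            nmass_fit.chi2 + 2 * nmass_fit.n_free
        )


class TestStandardErrors:
    def test_monte_carlo_se_calibration(self):
        """Reported SE of a single path matches the empirical spread of the
        estimator over 200 simulated replicates within 15%."""
        spec = ts.parse_model_spec("path X -> Y")
        truth = {"X→Y": 0.5}
        n = 500
        estimates = []
        reported = []
        for rep in range(200):
            tab = ts.simulate_model(
                ts.SimSpec(spec=spec, values=truth, n=n, seed=rep)
            )
            fit = ts.fit_ml(
                spec, ts.pearson_matrix(tab), n_restarts=1, compute_se=(rep < 25)
            )
            k = fit.ram.labels.index("X→Y")
            estimates.append(fit.theta[k])
            if fit.se is not None:
                reported.append(fit.se[k])
        empirical = np.std(estimates, ddof=1)
        assert np.mean(reported) == pytest.approx(empirical, rel=0.15)

    def test_se_scales_with_sample_size(self, models, study_moments):
        spec = models["nmass_final"]
        f1 = ts.fit_ml(spec, study_moments, seed=1)
        double = ts.CorrMatrix(
            study_moments.names, study_moments.values, n=2 * study_moments.n - 1
        )
        f2 = ts.fit_ml(spec, double, seed=1)
        ratio = np.sqrt((study_moments.n - 1) / (2 * study_moments.n - 2))
        np.testing.assert_allclose(f2.se, f1.se * ratio, rtol=1e-3)

    def test_every_retained_study_path_significant(self, nmass_fit, narea_fit):
        """The selected structures only contain p < 0.05 paths."""
        for fit in (nmass_fit, narea_fit):
            for k, label in enumerate(fit.ram.labels):
                if "→" in label:
                    assert fit.p_params[k] < 0.05, label
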