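"""The IGLS engine: variance step, beta step, full fits, association scan."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from famlong.covariance import (
    CovarianceDesign,
    VarianceComponents,
    assemble_V,
    build_components,
    build_layout,
)
from famlong.igls import (
    CollinearityError,
    _step_variance_est,
    assoc_scan,
    fit_igls,
    igls_step_beta,
    igls_step_variance,
    longitudinal_data_from_table,
    LongitudinalData,
    read_assoc,
    write_assoc,
)
from famlong.pedigree import kinship_matrices, parse_ped
from famlong.reference import ml_fit, step1_fullvec
from famlong.simulate import Nuclear, SimConfig, simulate_dataset

from conftest import make_fit_inputs


def _identity_assembly(design):
    theta = np.zeros(len(design.est_names))
    theta[-1] = 1.0  # within_variance / sigma_e2 is last in both bases
    return assemble_V(design, theta)


class TestVarianceStep:
    def test_single_component_collapses_to_mean_square(self):
        """With only the identity component and V = I the GLS normal
        equations reduce to sigma_e2 = r'r / N."""
        ped = parse_ped("F1 a 0 0 1\nF1 b 0 0 2\n")
        table = pd.DataFrame(
            [("F1", "a", 1, 1.0), ("F1", "a", 2, -2.0), ("F1", "b", 1, 3.0)],
            columns=["FID", "IID", "visit", "y"],
        )
        data = longitudinal_data_from_table(table, ped)
        layout = data.layout
        design = CovarianceDesign(
            layout=layout, names=("sigma_e2",),
            matrices=[{"sigma_e2": np.eye(3)}],
            est_names=("sigma_e2",), serial=False, kinship_scale=2.0,
        )
        V = assemble_V(design, np.array([1.0]))
        beta = np.zeros(1)  # residual is y itself
        theta = _step_variance_est(data, beta, design, V)
        assert theta[0] == pytest.approx(np.mean(data.y**2))

    @pytest.mark.parametrize("seed", range(6))
    def test_trace_form_equals_explicit_kronecker(self, seed):
        """The trace-form normal equations equal the literal full-vec GLS
        with Kronecker weight, matrix by matrix and in solution."""
        cfg = SimConfig(seed=seed, n_families=2, template=Nuclear(1), n_visits=2)
        simdata = simulate_dataset(cfg)
        data, design = make_fit_inputs(simdata)
        beta = np.linalg.lstsq(data.X, data.y, rcond=None)[0]
        rng = np.random.default_rng(seed)
        vc = VarianceComponents(
            rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0.1, 1),
            rng.uniform(-0.3, 0.8), rng.uniform(0.1, 1),
        )
        V = assemble_V(design, vc)
        theta_trace = _step_variance_est(data, beta, design, V)
        M, b, theta_kron = step1_fullvec(data, beta, design, V, basis="est")
        np.testing.assert_allclose(theta_trace, theta_kron, rtol=1e-10, atol=1e-12)

    def test_public_wrapper_returns_raw_components(self, small_dataset):
        data, design = make_fit_inputs(small_dataset)
        beta = np.linalg.lstsq(data.X, data.y, rcond=None)[0]
        V = _identity_assembly(design)
        vc, c2 = igls_step_variance(data, beta, design, V)
        assert vc.within_covariance == pytest.approx(c2)
        assert vc.sigma_v2 == pytest.approx(vc.sigma_e2)  # reporting convention

    def test_collinear_layout_raises(self):
        """Single-visit singletons cannot separate family, polygenic and
        error components."""
        ped = parse_ped("F1 a 0 0 1\nF2 b 0 0 1\nF3 c 0 0 2\n")
        table = pd.DataFrame(
            [("F1", "a", 1, 0.3), ("F2", "b", 1, -1.0), ("F3", "c", 1, 0.5)],
            columns=["FID", "IID", "visit", "y"],
        )
        data = longitudinal_data_from_table(table, ped)
        design = build_components(data.layout, kinship_matrices(ped), serial=False)
        V = _identity_assembly(design)
        with pytest.raises(CollinearityError, match="sigma"):
            _step_variance_est(data, np.zeros(1), design, V)

    def test_ratio_recovers_rho_at_large_n(self):
        """rho_hat = (rho*sigma_v2)/sigma_v2 is consistent when the serial
        and error variances are equal (the subfamily the reporting
        convention identifies exactly)."""
        vc = VarianceComponents(0.5, 1.0, 0.8, 0.5, 0.8)
        cfg = SimConfig(seed=99, n_families=420, template=Nuclear(2), vc_true=vc)
        simdata = simulate_dataset(cfg)  # ~5000 observations
        data, design = make_fit_inputs(simdata)
        fit = fit_igls(data, design)
        assert fit.vc.rho == pytest.approx(0.5, abs=0.05)


class TestBetaStep:
    @pytest.fixture
    def data_design(self, small_dataset):
        return make_fit_inputs(small_dataset, snv="snv1")

    def test_identity_weight_is_ols(self, data_design):
        data, design = data_design
        V = _identity_assembly(design)
        beta, _ = igls_step_beta(data, V)
        ols = np.linalg.lstsq(data.X, data.y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, rtol=1e-10)

    def test_scale_equivariance(self, data_design):
        data, design = data_design
        V1 = _identity_assembly(design)
        theta4 = np.zeros(len(design.est_names)); theta4[-1] = 4.0
        V4 = assemble_V(design, theta4)
        b1, c1 = igls_step_beta(data, V1)
        b4, c4 = igls_step_beta(data, V4)
        np.testing.assert_allclose(b1, b4, rtol=1e-10)
        np.testing.assert_allclose(4 * c1, c4, rtol=1e-10)

    def test_matches_dense_wls_oracle(self, data_design):
        data, design = data_design
        rng = np.random.default_rng(4)
        vc = VarianceComponents(0.4, 0.7, 0.5, 0.3, 0.9)
        V = assemble_V(design, vc)
        beta, cov = igls_step_beta(data, V)
        # dense oracle: build the full block-diagonal V and invert explicitly
        n = data.layout.n_obs
        Vfull = np.zeros((n, n))
        for k, fid in enumerate(data.layout.families):
            sl = data.layout.family_slices[fid]
            Vfull[sl, sl] = V.blocks[k]
        Vinv = np.linalg.inv(Vfull)
        cov_o = np.linalg.inv(data.X.T @ Vinv @ data.X)
        beta_o = cov_o @ data.X.T @ Vinv @ data.y
        np.testing.assert_allclose(beta, beta_o, rtol=1e-10)
        np.testing.assert_allclose(cov, cov_o, rtol=1e-9)

    def test_rank_deficient_design_rejected(self, small_dataset):
        data, design = make_fit_inputs(small_dataset)
        with pytest.raises(CollinearityError):
            data.with_column("dup", np.full(data.layout.n_obs, 1.0))


class TestFit:
    def test_pure_noise_structure(self):
        vc = VarianceComponents(0.0, 0.0, 0.0, 0.0, 1.0)
        cfg = SimConfig(seed=5, n_families=40, template=Nuclear(2), vc_true=vc)
        simdata = simulate_dataset(cfg)
        data, design = make_fit_inputs(simdata)
        fit = fit_igls(data, design)
        assert fit.converged
        assert fit.vc.sigma_u2 == pytest.approx(0.0, abs=0.1)
        assert fit.vc.sigma_g2 == pytest.approx(0.0, abs=0.15)
        assert fit.vc.within_covariance == pytest.approx(0.0, abs=0.1)
        assert fit.vc.within_variance == pytest.approx(np.var(data.y), abs=0.2)

    def test_agrees_with_numerical_ml(self, small_dataset):
        data, design = make_fit_inputs(small_dataset, snv="snv1")
        fit = fit_igls(data, design, tol=1e-12, max_iter=300, clamp_mode="allow")
        ml = ml_fit(data, design)
        theta_igls = np.array([fit.est[n] for n in design.est_names])
        np.testing.assert_allclose(theta_igls, ml["theta_est"], rtol=1e-4, atol=1e-8)
        np.testing.assert_allclose(fit.beta, ml["beta"], rtol=1e-4, atol=1e-8)

    def test_fixed_point_stability(self, small_dataset):
        """At convergence one extra variance+beta double-step moves no
        parameter by more than the tolerance."""
        tol = 1e-8
        data, design = make_fit_inputs(small_dataset, snv="snv1")
        fit = fit_igls(data, design, tol=tol, max_iter=300, clamp_mode="allow")
        assert fit.converged
        theta = np.array([fit.est[n] for n in design.est_names])
        V = assemble_V(design, theta)
        theta2 = _step_variance_est(data, fit.beta, design, V)
        beta2, _ = igls_step_beta(data, assemble_V(design, theta2))
        prev = np.concatenate([fit.beta, theta])
        cur = np.concatenate([beta2, theta2])
        assert np.max(np.abs(cur - prev) / np.maximum(np.abs(prev), 1e-3)) < 10 * tol

    def test_wald_invariants(self, small_dataset):
        data, design = make_fit_inputs(small_dataset, snv="snv1")
        fit = fit_igls(data, design)
        assert np.all((fit.p >= 0) & (fit.p <= 1))
        np.testing.assert_allclose(fit.z**2, fit.beta**2 / np.diag(fit.cov_beta))
        ev = np.linalg.eigvalsh(fit.cov_beta)
        assert ev.min() > 0

    def test_truncate_mode_clamps_negative_variances(self, small_dataset):
        data, design = make_fit_inputs(small_dataset, snv="snv1")
        fit = fit_igls(data, design, clamp_mode="truncate")
        assert fit.vc.sigma_u2 >= 0 and fit.vc.sigma_g2 >= 0
        lo, hi = fit.vc.rho_interval(data.layout.n_visits_max)
        assert lo <= fit.vc.rho <= hi

    def test_cross_sectional_matches_polygenic_ml(self, small_dataset):
        """Single-visit data with the serial terms dropped is the standard
        polygenic model; IGLS agrees with the ML oracle there too."""
        data, design = make_fit_inputs(small_dataset, snv="snv1", first_visit_only=True)
        assert not design.serial
        fit = fit_igls(data, design, tol=1e-12, max_iter=300, clamp_mode="allow")
        ml = ml_fit(data, design)
        theta_igls = np.array([fit.est[n] for n in design.est_names])
        np.testing.assert_allclose(theta_igls, ml["theta_est"], rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(fit.beta, ml["beta"], rtol=1e-4, atol=1e-8)


class TestScan:
    def test_monomorphic_row(self, small_dataset):
        genotypes = small_dataset.genotypes.copy()
        genotypes.loc["snvmono"] = 1.0
        res = assoc_scan(genotypes, small_dataset.phenotypes, small_dataset.ped)
        row = res[res["snv_id"] == "snvmono"].iloc[0]
        assert np.isnan(row["p"])
        assert row["reason"] == "monomorphic"

    def test_causal_snv_ranks_first(self):
        """1 causal + 9 null SNVs at a strong effect: the causal SNV attains
        the smallest p in at least 90% of 50 replicates."""
        hits = 0
        for rep in range(50):
            cfg = SimConfig(seed=7000 + rep, n_families=20, template=Nuclear(2),
                            n_snvs=10, snv_effects={0: 1.0})
            simdata = simulate_dataset(cfg)
            res = assoc_scan(simdata.genotypes, simdata.phenotypes, simdata.ped)
            best = res.loc[res["p"].idxmin(), "snv_id"]
            hits += best == "snv1"
        assert hits >= 45

    def test_covariates_do_not_shift_beta_without_effects(self, small_dataset):
        res0 = assoc_scan(small_dataset.genotypes, small_dataset.phenotypes,
                          small_dataset.ped)
        res1 = assoc_scan(small_dataset.genotypes, small_dataset.phenotypes,
                          small_dataset.ped, covariates=("age", "sex", "medication"))
        # covariate-free generating model: estimates agree to MC noise
        assert abs(res0["beta"].iloc[0] - res1["beta"].iloc[0]) < 2 * res0["se"].iloc[0]

    def test_dosage_out_of_range_rejected(self, small_dataset):
        bad = small_dataset.genotypes.copy()
        bad.iloc[0, 0] = 2.5
        with pytest.raises(ValueError, match="dosage"):
            assoc_scan(bad, small_dataset.phenotypes, small_dataset.ped)

    def test_round_trip(self, tmp_path, small_dataset):
        res = assoc_scan(small_dataset.genotypes, small_dataset.phenotypes,
                         small_dataset.ped)
        path = tmp_path / "assoc.tsv"
        write_assoc(res, path)
        back = read_assoc(path)
        np.testing.assert_allclose(back["p"].to_numpy(), res["p"].to_numpy())
        assert list(back.columns) == list(res.columns)
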