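import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import qrgwas as q
from qrgwas.mixed_model import MixedModelSpec, VarianceComponents


def direct_reml_loglik(df, sigma2, include_gxe=True):
    """Independent restricted log-likelihood from the explicit n x n V matrix
    (Harville form), sharing no code with the MME-based fit path."""
    y = df["value"].to_numpy(float)
    n = len(y)
    envs = sorted(df["environment"].unique())
    X = np.ones((n, len(envs)))
    for j, e in enumerate(envs[1:], start=1):
        X[:, j] = (df["environment"] == e).to_numpy(float)
    V = sigma2["e"] * np.eye(n)
    for name, key in (("genotype", "g"), ("gxe", "ga"), ("block", "b")):
        if name == "gxe" and not include_gxe:
            continue
        if name == "genotype":
            lab = df["genotype"]
        elif name == "gxe":
            lab = df["genotype"] + ":" + df["environment"]
        else:
            lab = df["environment"] + ":" + df["block"]
        Z = pd.get_dummies(lab).to_numpy(float)
        V += sigma2[key] * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    p = X.shape[1]
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldX + y @ P @ y)


@pytest.fixture(scope="module")
def tiny_trial():
    cfg = q.SimConfig(n_geno=8, n_snp=4, n_env=2, n_rep=2, sigma_g_poly=1.5,
                      sigma_ga=0.8, sigma_b=0.5, sigma_e=1.0, seed=21)
    g, _ = q.simulate_genotypes(cfg)
    ph, _ = q.simulate_phenotypes(g, cfg)
    return ph


class TestRemlFit:
    def test_optimum_dominates_coarse_grid_oracle(self, tiny_trial):
        df = tiny_trial.for_trait("trait")
        fit = q.fit_lmm(tiny_trial, MixedModelSpec("trait"))
        # the optimizer's restricted loglik must beat every grid point of an
        # independently computed restricted likelihood
        grid = [0.05, 0.3, 1.0, 2.5, 6.0]
        best_grid = -np.inf
        for sg in grid:
            for sga in grid:
                for sb in grid:
                    ll = direct_reml_loglik(
                        df, {"g": sg, "ga": sga, "b": sb, "e": 1.0})
                    best_grid = max(best_grid, ll)
        assert fit.reml_loglik >= best_grid - 1e-6

    def test_loglik_agrees_with_direct_v_matrix_formula(self, tiny_trial):
        df = tiny_trial.for_trait("trait")
        fit = q.fit_lmm(tiny_trial, MixedModelSpec("trait"))
        ll = direct_reml_loglik(
            df,
            {"g": max(fit.vc.sigma2_g, 1e-10), "ga": max(fit.vc.sigma2_ga, 1e-10),
             "b": max(fit.vc.sigma2_b, 1e-10), "e": fit.vc.sigma2_e},
        )
        assert fit.reml_loglik == pytest.approx(ll, abs=1e-4)

    def test_constant_response_degenerates_to_zero_components(self, tiny_trial):
        df = tiny_trial.data.copy()
        df.loc[df["trait"] == "trait", "value"] = 7.5
        rec = q.PhenotypeRecords(df)
        fit = q.fit_lmm(rec, MixedModelSpec("trait"))
        assert fit.vc.sigma2_g <= 1e-8 and fit.vc.sigma2_e <= 1e-8
        assert fit.fixed_estimates["intercept"] == pytest.approx(7.5)

    def test_full_loglik_dominates_reduced(self, tiny_trial):
        full = q.fit_lmm(tiny_trial, MixedModelSpec("trait", True))
        red = q.fit_lmm(tiny_trial, MixedModelSpec("trait", False))
        assert full.reml_loglik >= red.reml_loglik - 1e-6

    def test_residuals_plus_fitted_reproduce_observations(self, tiny_trial):
        fit = q.fit_lmm(tiny_trial, MixedModelSpec("trait"))
        y = tiny_trial.for_trait("trait")["value"].to_numpy()
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-8)

    def test_blups_sum_to_zero_balanced(self, tiny_trial):
        fit = q.fit_lmm(tiny_trial, MixedModelSpec("trait"))
        for term, b in fit.blups.items():
            assert abs(b.sum()) < 1e-6, term

    def test_single_level_random_term_rejected(self):
        # a single (environment, block) combination leaves the block term
        # with one level
        df = pd.DataFrame({
            "genotype": ["A", "B", "C", "D"],
            "environment": ["E1"] * 4,
            "block": ["B1"] * 4,
            "trait": "t", "value": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(ValueError, match="single level"):
            q.fit_lmm(q.PhenotypeRecords(df), MixedModelSpec("t", include_gxe=False))

    def test_matches_lme4_variance_components(self, tiny_trial, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the lme4 cross-check")
        df = tiny_trial.for_trait("trait")
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(TRUE)[1])
            d$eb <- interaction(d$environment, d$block)
            m <- lmer(value ~ environment + (1|genotype) +
                      (1|genotype:environment) + (1|eb), data=d, REML=TRUE)
            vc <- as.data.frame(VarCorr(m))
            cat(vc$vcov[match(c("genotype:environment","genotype","eb"), vc$grp)],
                sigma(m)^2, sep="\\n")
        """))
        out = subprocess.run(["Rscript", str(script), str(csv)],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ga, g_, b, e = (float(v) for v in out.stdout.split())
        fit = q.fit_lmm(tiny_trial, MixedModelSpec("trait"))
        assert fit.vc.sigma2_g == pytest.approx(g_, rel=0.02, abs=0.02)
        assert fit.vc.sigma2_ga == pytest.approx(ga, rel=0.02, abs=0.02)
        assert fit.vc.sigma2_b == pytest.approx(b, rel=0.02, abs=0.02)
        assert fit.vc.sigma2_e == pytest.approx(e, rel=0.02, abs=0.02)


class TestInformationCriteriaAndLrt:
    def test_aic_bic_formulas(self, tiny_trial):
        fit = q.fit_lmm(tiny_trial, MixedModelSpec("trait"))
        aic, bic = q.information_criteria(fit)
        ll, n = fit.reml_loglik, fit.n_obs
        assert aic == pytest.approx(-2 * ll + 2 * 4)
        assert bic == pytest.approx(-2 * ll + 4 * np.log(n))

    def test_lrt_identity_and_mixture_option(self, tiny_trial):
        full = q.fit_lmm(tiny_trial, MixedModelSpec("trait", True))
        red = q.fit_lmm(tiny_trial, MixedModelSpec("trait", False))
        cmp_ = q.lr_test(full, red)
        assert cmp_.lrt_stat == pytest.approx(
            max(0.0, 2 * (full.reml_loglik - red.reml_loglik)))
        assert cmp_.lrt_pvalue == pytest.approx(stats.chi2.sf(cmp_.lrt_stat, 1))
        mix = q.lr_test(full, red, boundary_mixture=True)
        assert mix.lrt_pvalue == pytest.approx(cmp_.lrt_pvalue / 2)

    def test_lrt_rejects_strong_gxe(self):
        cfg = q.SimConfig(n_geno=80, n_snp=4, sigma_ga=np.sqrt(0.5), seed=31)
        g, _ = q.simulate_genotypes(cfg)
        ph, _ = q.simulate_phenotypes(g, cfg)
        full = q.fit_lmm(ph, MixedModelSpec("trait", True))
        red = q.fit_lmm(ph, MixedModelSpec("trait", False))
        assert q.lr_test(full, red).lrt_pvalue < 0.01

    def test_mismatched_data_rejected(self, tiny_trial):
        cfg = q.SimConfig(n_geno=8, n_snp=4, n_env=2, n_rep=2, seed=99)
        g, _ = q.simulate_genotypes(cfg)
        other, _ = q.simulate_phenotypes(g, cfg)
        full = q.fit_lmm(tiny_trial, MixedModelSpec("trait", True))
        red = q.fit_lmm(other, MixedModelSpec("trait", False))
        with pytest.raises(ValueError, match="same data"):
            q.lr_test(full, red)


class TestHeritability:
    def test_entry_mean_formula(self):
        vc = VarianceComponents(sigma2_g=2, sigma2_b=0.3, sigma2_e=1, sigma2_ga=1)
        assert q.heritability(vc, 4, 3) == pytest.approx(2 / (2 + 0.25 + 1 / 12))

    def test_boundaries(self):
        assert q.heritability(VarianceComponents(0, 0.1, 1.0, 0.5), 4, 3) == 0
        assert q.heritability(VarianceComponents(3.0, 0.0, 0.0, 0.0), 4, 3) == 1

    def test_monotonicity_in_components(self):
        base = q.heritability(VarianceComponents(2, 0.3, 1, 1), 4, 3)
        assert q.heritability(VarianceComponents(3, 0.3, 1, 1), 4, 3) > base
        assert q.heritability(VarianceComponents(2, 0.3, 2, 1), 4, 3) < base

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            q.heritability(VarianceComponents(0, 0, 0, 0), 4, 3)


class TestAdjustedPhenotypes:
    def test_blup_mode_one_value_per_genotype_mean_zero(self, tiny_trial):
        fit = q.fit_lmm(tiny_trial, MixedModelSpec("trait"))
        ys = q.adjusted_phenotypes(fit)
        assert len(ys.values) == 8
        assert ys.values.mean() == pytest.approx(0.0, abs=1e-6)

    def test_blup_monotone_in_raw_genotype_means(self, tiny_trial):
        fit = q.fit_lmm(tiny_trial, MixedModelSpec("trait"))
        ys = q.adjusted_phenotypes(fit)
        raw = tiny_trial.for_trait("trait").groupby("genotype")["value"].mean()
        order_raw = raw.sort_values().index
        order_blup = ys.values.loc[raw.index].sort_values().index
        assert list(order_raw) == list(order_blup)

    def test_plot_sum_mode_matches_obs_minus_fixed(self, tiny_trial):
        fit = q.fit_lmm(tiny_trial, MixedModelSpec("trait"))
        ys = q.adjusted_phenotypes(fit, mode="plot_sum")
        df = tiny_trial.for_trait("trait")
        envs = sorted(df["environment"].unique())
        fe = fit.fixed_estimates
        fixed = fe["intercept"] + df["environment"].map(
            {e: (0.0 if i == 0 else fe[f"env[{e}]"]) for i, e in enumerate(envs)}
        )
        manual = (df["value"] - fixed).groupby(df["genotype"]).mean()
        np.testing.assert_allclose(
            ys.values.sort_index(), manual.sort_index(), atol=1e-8)


class TestGeneticParameters:
    def _two_trait_records(self, rho=0.9, seed=13, n_geno=60):
        rng = np.random.default_rng(seed)
        cfg = q.SimConfig(n_geno=n_geno, n_snp=4, sigma_g_poly=0, seed=seed)
        g, _ = q.simulate_genotypes(cfg)
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        gvals = (rng.normal(size=(n_geno, 2)) @ L.T) * 2.0
        frames = []
        for t in range(2):
            cfg_t = q.SimConfig(n_geno=n_geno, n_snp=4, sigma_g_poly=0,
                                sigma_ga=0.5, sigma_b=0.5, sigma_e=1.0,
                                seed=seed + t, trait_name=f"t{t}")
            ph, _ = q.simulate_phenotypes(g, cfg_t)
            df = ph.data.copy()
            gv = pd.Series(gvals[:, t], index=list(g.genotype_ids))
            df["value"] = df["value"] + df["genotype"].map(gv)
            frames.append(df)
        return q.PhenotypeRecords(pd.concat(frames, ignore_index=True))

    def test_duplicated_trait_correlation_one(self, tiny_trial):
        df = tiny_trial.data
        dup = df.copy(); dup["trait"] = "copy"
        rec = q.PhenotypeRecords(pd.concat([df, dup], ignore_index=True))
        fits = {t: q.fit_lmm(rec, MixedModelSpec(t)) for t in ("trait", "copy")}
        gp = q.genetic_parameters(fits, rec)
        assert gp.genetic_correlations.loc["trait", "copy"] == pytest.approx(1.0)
        assert gp.phenotypic_correlations.loc["trait", "copy"] == pytest.approx(1.0)

    def test_recovers_simulated_genetic_correlation(self):
        rec = self._two_trait_records(rho=0.9)
        fits = {t: q.fit_lmm(rec, MixedModelSpec(t)) for t in rec.traits}
        gp = q.genetic_parameters(fits, rec)
        assert gp.genetic_correlations.loc["t0", "t1"] == pytest.approx(0.9, abs=0.12)
        h2 = gp.heritability
        assert ((h2 >= 0) & (h2 <= 1)).all()

    def test_matrix_shape_and_symmetry(self):
        rec = self._two_trait_records(rho=0.3, seed=17)
        fits = {t: q.fit_lmm(rec, MixedModelSpec(t)) for t in rec.traits}
        gp = q.genetic_parameters(fits, rec)
        for m in (gp.genetic_correlations, gp.phenotypic_correlations):
            np.testing.assert_allclose(m, m.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(m), 1.0)
            assert (np.abs(m.to_numpy()) <= 1 + 1e-12).all()
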