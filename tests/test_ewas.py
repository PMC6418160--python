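"""EWAS tests: design construction, probewise OLS against the
normal-equations oracle, empirical-Bayes moderation (including an
independent limma cross-check through Rscript), FDR, inflation lambda and
surrogate variables."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smokesig import synthdata as sd
from smokesig.ewas import (
    CHI2_1_MEDIAN,
    DesignMatrix,
    EBayesPrior,
    bh_fdr,
    build_design,
    ebayes_moderate,
    estimate_prior,
    estimate_surrogates,
    fit_probewise,
    genomic_inflation,
    model_agreement,
    moderate_variances,
    run_ewas,
)


def _design_from_x(x):
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones(x.size), x])
    return DesignMatrix(X=X, columns=["intercept", "x"], contrasts={"x": 1},
                        sample_ids=[f"s{i}" for i in range(x.size)])


class TestBuildDesign:
    def test_smoking_dummies_and_counts(self):
        """Full cohort design: 3 smoking dummies with never as reference;
        dummy column sums match the printed group sizes (91, 135, 103)."""
        meta = sd.simulate_cohort(390, seed=1)
        design = build_design(meta)
        assert design.X.shape[0] == 390
        assert list(design.contrasts) == ["current", "former_le15", "former_gt15"]
        sums = [design.X[:, design.contrasts[c]].sum() for c in design.contrasts]
        assert sums == [91, 135, 103]
        assert design.columns[0] == "intercept"

    def test_single_level_factor_dropped(self):
        meta = sd.simulate_cohort(40, seed=2)
        meta["plate"] = "plate1"
        design = build_design(meta)
        assert not any(c.startswith("plate") for c in design.columns)

    def test_rank_deficiency_names_columns(self):
        meta = sd.simulate_cohort(60, seed=3)
        meta["plate"] = np.where(meta["smoking"] == "current", "plateA", "plateB")
        with pytest.raises(ValueError, match="plate"):
            build_design(meta)

    def test_missing_covariates_excluded(self):
        meta = sd.simulate_cohort(50, seed=4)
        meta.loc[meta.index[:5], "age"] = np.nan
        design = build_design(meta)
        assert design.X.shape[0] == 45
        assert design.n_dropped == 5


class TestFitProbewise:
    def test_normal_equations_oracle(self):
        """y=(0,1,1,2) on x=(0,1,2,3): slope 0.6, intercept 0.1, s2=0.1, d=2."""
        design = _design_from_x([0, 1, 2, 3])
        beta = pd.DataFrame([[0.0, 1.0, 1.0, 2.0]], index=["p"], columns=design.sample_ids)
        fit = fit_probewise(beta, design)
        assert fit.coef[0] == pytest.approx([0.1, 0.6])
        assert fit.sigma2[0] == pytest.approx(0.1)
        assert fit.df[0] == 2

    def test_exact_fit(self):
        design = _design_from_x([0, 1, 2, 3])
        beta = pd.DataFrame([[0.1, 0.3, 0.5, 0.7]], index=["p"], columns=design.sample_ids)
        fit = fit_probewise(beta, design)
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-25)
        assert fit.coef[0] == pytest.approx([0.1, 0.2])

    def test_intercept_only_is_mean(self):
        X = np.ones((5, 1))
        design = DesignMatrix(X=X, columns=["intercept"], contrasts={},
                              sample_ids=[f"s{i}" for i in range(5)])
        beta = pd.DataFrame([[0.2, 0.4, 0.6, 0.3, 0.5]], index=["p"], columns=design.sample_ids)
        fit = fit_probewise(beta, design)
        assert fit.coef[0, 0] == pytest.approx(0.4)

    def test_missing_values_complete_case(self):
        design = _design_from_x([0, 1, 2, 3, 4, 5])
        y = [0.0, 1.0, 1.0, 2.0, np.nan, np.nan]
        beta = pd.DataFrame([y], index=["p"], columns=design.sample_ids)
        fit = fit_probewise(beta, design)
        assert fit.df[0] == 2
        assert fit.coef[0] == pytest.approx([0.1, 0.6])

    def test_insufficient_df(self):
        design = _design_from_x([0, 1])
        beta = pd.DataFrame([[0.1, 0.2]], index=["p"], columns=design.sample_ids)
        with pytest.raises(ValueError):
            fit_probewise(beta, design)


class TestEmpiricalBayes:
    def test_homogeneous_variances_give_infinite_prior_df(self):
        """No variance heterogeneity: infinite prior df and every posterior
        variance collapses to s0^2 (which carries the log-chi-square bias
        correction, hence is near but not exactly the common value)."""
        prior = estimate_prior(np.full(100, 0.04), np.full(100, 20.0))
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.04, rel=0.10)
        post = moderate_variances(np.full(100, 0.04), np.full(100, 20.0), prior)
        assert np.all(post == prior.s0_sq)

    def test_zero_prior_df_recovers_ols_t(self):
        """Forcing d0 = 0 must reproduce the ordinary t exactly."""
        rng = np.random.default_rng(1)
        design = _design_from_x(rng.normal(size=12))
        beta = pd.DataFrame(rng.normal(0.5, 0.05, size=(30, 12)), columns=design.sample_ids,
                            index=[f"p{i}" for i in range(30)])
        fit = fit_probewise(beta, design)
        _, tab = ebayes_moderate(fit, 1, prior=EBayesPrior(d0=0.0, s0_sq=1.0))
        t_ols = fit.coef[:, 1] / np.sqrt(fit.sigma2 * fit.v[1])
        assert np.allclose(tab["t"], t_ols)
        assert np.allclose(tab["p"], 2 * stats.t.sf(np.abs(t_ols), fit.df))

    def test_prior_recovery(self):
        """Moment estimator recovers (d0, s0^2) from the full two-layer
        model: sigma^2 ~ s0^2 d0 / chi2_d0, s^2 ~ sigma^2 chi2_d / d."""
        rng = np.random.default_rng(2)
        d0, s0_sq, d, G = 4.0, 0.04, 20, 5000
        sigma2 = s0_sq * d0 / rng.chisquare(d0, G)
        s2 = sigma2 * rng.chisquare(d, G) / d
        prior = estimate_prior(s2, np.full(G, float(d)))
        assert prior.d0 == pytest.approx(d0, abs=0.5)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError):
            estimate_prior(np.zeros(50), np.full(50, 10.0))

    def test_matches_limma_oracle(self, tmp_path):
        """Independent cross-check: moderated t, prior df and prior variance
        agree with the Bioconductor reference implementation."""
        rng = np.random.default_rng(42)
        G, n = 200, 20
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2), rng.normal(size=n)])
        sigma2 = 0.04 * 4 / rng.chisquare(4, G)
        B = rng.normal(0, 0.05, size=(G, 3))
        Y = B @ X.T + rng.normal(size=(G, n)) * np.sqrt(sigma2)[:, None]
        beta = pd.DataFrame(Y, index=[f"p{i}" for i in range(G)],
                            columns=[f"s{i}" for i in range(n)])
        design = DesignMatrix(X=X, columns=["intercept", "group", "cov"],
                              contrasts={"group": 1}, sample_ids=list(beta.columns))
        fit = fit_probewise(beta, design)
        prior = estimate_prior(fit.sigma2, fit.df)
        _, tab = ebayes_moderate(fit, 1, prior=prior)

        beta.to_csv(tmp_path / "y.tsv", sep="\t")
        np.savetxt(tmp_path / "X.tsv", X, delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            Y <- as.matrix(read.delim("y.tsv", row.names = 1))
            X <- as.matrix(read.delim("X.tsv", header = FALSE))
            eb <- eBayes(lmFit(Y, X))
            out <- data.frame(t = eb$t[, 2], p = eb$p.value[, 2])
            write.table(out, "limma_out.tsv", sep = "\t")
            writeLines(as.character(c(eb$df.prior, eb$s2.prior)), "limma_prior.txt")
        """)
        (tmp_path / "check.R").write_text(script)
        subprocess.run(["Rscript", "check.R"], cwd=tmp_path, check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")
        d0_ref, s0_ref = [float(v) for v in (tmp_path / "limma_prior.txt").read_text().split()]
        assert prior.d0 == pytest.approx(d0_ref, rel=1e-6)
        assert prior.s0_sq == pytest.approx(s0_ref, rel=1e-6)
        assert np.allclose(tab["t"], ref["t"], atol=1e-10)
        assert np.allclose(tab["p"], ref["p"], atol=1e-10)


class TestBhFdr:
    def test_all_equal(self):
        assert np.allclose(bh_fdr(np.full(7, 0.03)), 0.03)

    def test_step_up_example(self):
        assert np.allclose(bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(size=200))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all((q >= p - 1e-15) & (q <= 1.0))

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.5]))


class TestGenomicInflation:
    def test_definition_at_median(self):
        lam, _, _ = genomic_inflation(np.array([0.5]))
        assert lam == pytest.approx(1.0)

    def test_chi_square_one_everywhere(self):
        lam, _, _ = genomic_inflation(np.full(11, 0.3173105))
        assert lam == pytest.approx(1.0 / CHI2_1_MEDIAN, rel=1e-4)

    def test_null_uniform(self):
        rng = np.random.default_rng(4)
        lam, exp_q, obs_q = genomic_inflation(rng.uniform(size=100_000))
        assert lam == pytest.approx(1.0, abs=0.03)
        assert exp_q.shape == obs_q.shape

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([0.5, 0.0]))


class TestSurrogates:
    def test_recovers_planted_batch(self):
        """Top surrogate variable correlates > 0.9 with an unmodelled batch
        shifting 30% of probes."""
        rng = np.random.default_rng(5)
        n, G = 60, 400
        batch = np.repeat([0.0, 1.0], n // 2)
        Y = rng.normal(0.5, 0.03, size=(G, n))
        hit = rng.random(G) < 0.3
        Y[hit] += 0.08 * batch
        design = DesignMatrix(X=np.ones((n, 1)), columns=["intercept"], contrasts={},
                              sample_ids=[f"s{i}" for i in range(n)])
        beta = pd.DataFrame(Y, columns=design.sample_ids, index=[f"p{i}" for i in range(G)])
        sv = estimate_surrogates(beta, design, n_sv=2)
        assert abs(np.corrcoef(sv[:, 0], batch)[0, 1]) > 0.9

    def test_augments_design(self):
        meta = sd.simulate_cohort(120, seed=6)
        design = build_design(meta)
        sv = np.random.default_rng(0).normal(size=(120, 10))
        aug = build_design(meta, extra=sv)
        assert aug.X.shape[1] == design.X.shape[1] + 10
        assert aug.columns[-1] == "sv10"

    def test_zero_residuals_give_zero_vectors(self):
        design = _design_from_x([0, 1, 2, 3, 4, 5, 6, 7])
        y = np.outer(np.ones(10), 0.1 + 0.05 * np.arange(8))
        beta = pd.DataFrame(y, columns=design.sample_ids, index=[f"p{i}" for i in range(10)])
        sv = estimate_surrogates(beta, design, n_sv=2)
        assert np.all(sv == 0)

    def test_n_sv_too_large(self):
        design = _design_from_x([0, 1, 2, 3])
        beta = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 4)),
                            columns=design.sample_ids)
        with pytest.raises(ValueError):
            estimate_surrogates(beta, design, n_sv=3)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(7)
        design = DesignMatrix(X=np.ones((20, 1)), columns=["intercept"], contrasts={},
                              sample_ids=[f"s{i}" for i in range(20)])
        beta = pd.DataFrame(rng.normal(0.5, 0.05, size=(50, 20)), columns=design.sample_ids)
        sv1 = estimate_surrogates(beta, design, n_sv=3)
        sv2 = estimate_surrogates(beta, design, n_sv=3)
        assert np.array_equal(sv1, sv2)
        assert all(sv1[np.argmax(np.abs(sv1[:, j])), j] > 0 for j in range(3))


class TestModelAgreement:
    def test_identical_and_negated(self):
        v = np.array([0.1, -0.4, 0.3, 0.9])
        assert model_agreement(v, v) == pytest.approx(1.0)
        assert model_agreement(v, -v) == pytest.approx(-1.0)

    def test_hand_oracle(self):
        # sum(dx*dy)=3.5, sum(dx^2)=5, sum(dy^2)=4.75 -> r = 3.5/sqrt(23.75)
        r = model_agreement([1, 2, 3, 4], [2, 4, 5, 4])
        assert r == pytest.approx(3.5 / np.sqrt(5 * 4.75), rel=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            model_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRunEwas:
    def test_surrogate_model_agreement_on_clean_data(self, small_run):
        """On data whose batch structure is already in the model, primary and
        surrogate-augmented coefficient vectors stay highly correlated."""
        cfg, ann, cohort, eff, raw = small_run
        from smokesig import preprocess as pp

        res = pp.preprocess(raw, cohort, ann)
        primary = run_ewas(res.beta, cohort, gap_flags=res.gap_flags)
        meta = cohort[cohort["sample_id"].isin(res.beta.columns)]
        design = primary.design
        sv = estimate_surrogates(res.beta, design, n_sv=5)
        sensitivity = run_ewas(res.beta, cohort, gap_flags=res.gap_flags, extra_covariates=sv)
        r = model_agreement(primary.tables["current"]["estimate"],
                            sensitivity.tables["current"]["estimate"])
        assert r > 0.8

    def test_output_contract(self, small_run):
        cfg, ann, cohort, eff, raw = small_run
        from smokesig import preprocess as pp

        res = pp.preprocess(raw, cohort, ann)
        out = run_ewas(res.beta, cohort, gap_flags=res.gap_flags, annotation=ann)
        tab = out.tables["current"]
        assert set(tab.columns) >= {"estimate", "se", "t", "df_total", "p", "q_fdr",
                                    "avg_meth_pct", "gap_probe", "chrom", "pos", "genes"}
        assert np.allclose(tab["estimate"] / tab["se"], tab["t"])
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()
        assert ((tab["q_fdr"] >= tab["p"] - 1e-12)).all()
        assert set(out.lambdas) == {"current", "former_le15", "former_gt15"}
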