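import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from nestpath.data import StudyFrame
from nestpath.exceptions import AlignmentError, DesignError
from nestpath.phenotype import (
    PathwayPhenotypeModel,
    PhenotypeModelSpec,
    build_design,
)


def make_study(n, sibships, **cols):
    table = pd.DataFrame({"sibship_id": sibships},
                         index=pd.Index([f"s{i}" for i in range(n)],
                                        name="subject_id"))
    for k, v in cols.items():
        table[k] = np.asarray(v, dtype=float)
    return StudyFrame(table)


def make_eb(study, genes, rng):
    return pd.DataFrame(rng.normal(size=(study.n_subjects, len(genes))),
                        index=study.subject_ids, columns=genes)


@pytest.fixture
def lmm_data():
    """200 subjects in 50 sibships of 4 with a known generative model."""
    rng = np.random.default_rng(12)
    n, n_fam = 200, 50
    sib = np.repeat([f"f{i}" for i in range(n_fam)], 4)
    age = rng.normal(50, 10, n)
    smoking = rng.binomial(1, 0.25, n).astype(float)
    eb = rng.normal(0, 0.6, size=(n, 2))
    u = np.repeat(rng.normal(0, np.sqrt(0.3), n_fam), 4)
    y = 1.0 + 0.02 * age + 0.4 * smoking + 0.5 * eb[:, 0] + u + \
        rng.normal(0, 1.0, n)
    study = make_study(n, sib, Age=age, Smoking=smoking, Q=y)
    ebf = pd.DataFrame(eb, index=study.subject_ids, columns=["G1", "G2"])
    return study, ebf


class TestBuildDesign:
    def test_column_count_and_term_map(self, lmm_data):
        study, eb = lmm_data
        X, tm = build_design(study, eb, PhenotypeModelSpec(
            "Q", covariates=("Age",), gene_terms=("G1", "G2")))
        assert X.shape[1] == 4  # intercept + Age + 2 EB columns
        assert tm["gene:G1"] == "EB_G1"
        assert set(tm) == {"intercept", "covariate:Age", "gene:G1", "gene:G2"}

    def test_interaction_column_is_elementwise_product(self, lmm_data):
        study, eb = lmm_data
        spec = PhenotypeModelSpec("Q", covariates=("Age", "Smoking"),
                                  interactions=(("G1", "Smoking"),))
        X, tm = build_design(study, eb, spec)
        np.testing.assert_allclose(
            X["EB_G1:Smoking"],
            X["EB_G1"] * study.column("Smoking"))
        X0, _ = build_design(study, eb, PhenotypeModelSpec(
            "Q", covariates=("Age", "Smoking")))
        assert X.shape[1] == X0.shape[1] + 1

    def test_gene_coefficients_addressable_by_label(self, lmm_data):
        study, eb = lmm_data
        spec = PhenotypeModelSpec("Q", covariates=("Age",))
        res = PathwayPhenotypeModel(study, eb, spec).fit()
        for g in ("G1", "G2"):
            est, se = res.coef(f"gene:{g}")
            assert np.isfinite(est) and se > 0

    def test_misaligned_eb_raises(self, lmm_data):
        study, eb = lmm_data
        bad = eb.copy()
        bad.index = ["x" + i for i in bad.index]
        with pytest.raises(AlignmentError):
            build_design(study, bad, PhenotypeModelSpec("Q"))

    def test_interaction_gene_must_be_tested(self, lmm_data):
        study, eb = lmm_data
        spec = PhenotypeModelSpec("Q", gene_terms=("G2",),
                                  interactions=(("G1", "Age"),))
        with pytest.raises(DesignError):
            build_design(study, eb, spec)

    def test_paper_style_design_has_twelve_columns(self):
        # Age + Smoking + 8 EB genes + KDR x Smoking + intercept = 12
        rng = np.random.default_rng(13)
        genes = ["ARNT", "ELAVL4", "FLT1", "FLT4", "HIF3A", "KDR",
                 "VEGFA", "VEGFC"]
        study = make_study(40, [f"f{i//2}" for i in range(40)],
                           Age=rng.normal(50, 10, 40),
                           Smoking=rng.binomial(1, 0.25, 40),
                           Q1=rng.normal(size=40))
        eb = make_eb(study, genes, rng)
        X, tm = build_design(study, eb, PhenotypeModelSpec(
            "Q1", covariates=("Age", "Smoking"),
            interactions=(("KDR", "Smoking"),)))
        assert X.shape[1] == 12
        assert tm["interaction:KDR:Smoking"] == "EB_KDR:Smoking"


class TestLinearMixedModel:
    def test_ml_matches_profile_likelihood_grid(self, lmm_data):
        """ML solution agrees with a brute-force (s2_u, s2_e) profile grid."""
        study, eb = lmm_data
        spec = PhenotypeModelSpec("Q", covariates=("Age", "Smoking"))
        res = PathwayPhenotypeModel(study, eb, spec).fit()

        X, _ = build_design(study, eb, spec)
        X = X.to_numpy()
        y = study.column("Q")
        groups = study.sibship_ids

        def profile_ll(s2u, s2e):
            # GLS with beta profiled out, per-cluster V = s2u J + s2e I
            XtViX = np.zeros((X.shape[1], X.shape[1]))
            XtViy = np.zeros(X.shape[1])
            logdet = 0.0
            quads = []
            for g in np.unique(groups):
                idx = groups == g
                m = idx.sum()
                V = s2u * np.ones((m, m)) + s2e * np.eye(m)
                Vi = np.linalg.inv(V)
                logdet += np.linalg.slogdet(V)[1]
                XtViX += X[idx].T @ Vi @ X[idx]
                XtViy += X[idx].T @ Vi @ y[idx]
                quads.append((idx, Vi))
            beta = np.linalg.solve(XtViX, XtViy)
            quad = sum(float((y[idx] - X[idx] @ beta) @ Vi
                             @ (y[idx] - X[idx] @ beta))
                       for idx, Vi in quads)
            return -0.5 * (len(y) * np.log(2 * np.pi) + logdet + quad)

        s2u_grid = np.linspace(0.01, 1.0, 34)
        s2e_grid = np.linspace(0.5, 1.8, 34)
        grid_best = max(profile_ll(a, b) for a in s2u_grid for b in s2e_grid)
        assert res.llf >= grid_best - 1e-3
        # and the fit is not wildly above any achievable value nearby
        local = profile_ll(max(res.sibship_variance, 1e-8),
                           res.residual_variance)
        assert res.llf == pytest.approx(local, abs=1e-6)

    def test_singleton_clusters_reduce_to_ols(self):
        rng = np.random.default_rng(14)
        n = 150
        study = make_study(n, [f"f{i}" for i in range(n)],
                           Age=rng.normal(50, 10, n),
                           Q=rng.normal(size=n))
        eb = make_eb(study, ["G1"], rng)
        spec = PhenotypeModelSpec("Q", covariates=("Age",))
        res = PathwayPhenotypeModel(study, eb, spec).fit()
        X, _ = build_design(study, eb, spec)
        ols = sm.OLS(study.column("Q"), X).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ols.params,
                                   atol=1e-8)

    def test_ml_estimates_unbiased_under_generative_model(self):
        """Mean bias of gamma over replicates within 2 Monte-Carlo SEs."""
        rng = np.random.default_rng(15)
        gammas = []
        n, n_fam = 1000, 250
        sib = np.repeat([f"f{i}" for i in range(n_fam)], 4)
        for _ in range(100):
            eb = rng.normal(0, 0.6, size=(n, 1))
            u = np.repeat(rng.normal(0, np.sqrt(0.2), n_fam), 4)
            y = 0.3 * eb[:, 0] + u + rng.normal(0, 1, n)
            study = make_study(n, sib, Q=y)
            ebf = pd.DataFrame(eb, index=study.subject_ids, columns=["G1"])
            res = PathwayPhenotypeModel(study, ebf,
                                        PhenotypeModelSpec("Q")).fit()
            gammas.append(res.coef("gene:G1")[0])
        gammas = np.array(gammas)
        se = gammas.std(ddof=1) / np.sqrt(len(gammas))
        assert abs(gammas.mean() - 0.3) < 2 * se + 1e-12

    def test_missing_trait_rows_dropped(self, lmm_data):
        study, eb = lmm_data
        study.subjects.loc["s0", "Q"] = np.nan
        res = PathwayPhenotypeModel(study, eb, PhenotypeModelSpec(
            "Q", covariates=("Age",))).fit()
        assert res.nobs == study.n_subjects - 1


class TestGee:
    @pytest.fixture
    def binary_data(self):
        rng = np.random.default_rng(16)
        n, n_fam = 400, 100
        sib = np.repeat([f"f{i}" for i in range(n_fam)], 4)
        age = rng.normal(50, 10, n)
        eb = rng.normal(0, 0.6, size=(n, 2))
        u = np.repeat(rng.normal(0, 0.5, n_fam), 4)
        p = 1 / (1 + np.exp(-(-0.5 + 0.02 * (age - 50) + 0.5 * eb[:, 0] + u)))
        y = rng.binomial(1, p).astype(float)
        study = make_study(n, sib, Age=age, D=y)
        ebf = pd.DataFrame(eb, index=study.subject_ids, columns=["G1", "G2"])
        return study, ebf

    def test_size_one_clusters_equal_logit_with_hc_sandwich(self):
        rng = np.random.default_rng(17)
        n = 300
        study = make_study(n, [f"f{i}" for i in range(n)],
                           Age=rng.normal(50, 10, n),
                           D=rng.binomial(1, 0.4, n))
        eb = make_eb(study, ["G1"], rng)
        spec = PhenotypeModelSpec("D", "binary", covariates=("Age",))
        res = PathwayPhenotypeModel(study, eb, spec).fit()
        X, _ = build_design(study, eb, spec)
        logit = sm.Logit(study.column("D"), X).fit(disp=0, cov_type="HC0")
        np.testing.assert_allclose(res.params.to_numpy(), logit.params,
                                   atol=1e-6)
        np.testing.assert_allclose(res.cov_params.to_numpy(),
                                   logit.cov_params(), atol=1e-6)

    def test_exchangeable_rho_equals_moment_estimator(self, binary_data):
        """rho from the fit equals the Pearson-residual moment estimate."""
        study, eb = binary_data
        spec = PhenotypeModelSpec("D", "binary", covariates=("Age",))
        res = PathwayPhenotypeModel(study, eb, spec).fit()
        X, _ = build_design(study, eb, spec)
        Xm = X.to_numpy()
        y = study.column("D")
        mu = 1 / (1 + np.exp(-(Xm @ res.params.to_numpy())))
        r = (y - mu) / np.sqrt(mu * (1 - mu))
        p = Xm.shape[1]
        scale = np.sum(r ** 2) / (len(y) - p)
        num, npairs = 0.0, 0
        for g in np.unique(study.sibship_ids):
            rg = r[study.sibship_ids == g]
            num += (rg.sum() ** 2 - (rg ** 2).sum()) / 2
            npairs += len(rg) * (len(rg) - 1) // 2
        rho_hand = num / (scale * (npairs - p))
        assert res.working_correlation == pytest.approx(rho_hand, abs=1e-6)

    def test_sandwich_invariant_to_cluster_relabeling_and_order(
            self, binary_data):
        study, eb = binary_data
        spec = PhenotypeModelSpec("D", "binary", covariates=("Age",))
        base = PathwayPhenotypeModel(study, eb, spec).fit()

        relabeled = study.subjects.copy()
        relabeled["sibship_id"] = "z_" + relabeled["sibship_id"]
        res_r = PathwayPhenotypeModel(StudyFrame(relabeled), eb, spec).fit()
        np.testing.assert_allclose(base.cov_params.to_numpy(),
                                   res_r.cov_params.to_numpy(), atol=1e-10)

        rng = np.random.default_rng(0)
        perm = np.concatenate([
            rng.permutation(np.where(study.sibship_ids == g)[0])
            for g in pd.unique(study.sibship_ids)])
        shuffled = StudyFrame(study.subjects.iloc[perm].copy())
        res_s = PathwayPhenotypeModel(shuffled, eb.iloc[perm], spec).fit()
        np.testing.assert_allclose(base.cov_params.to_numpy(),
                                   res_s.cov_params.to_numpy(), atol=1e-8)

    def test_robust_close_to_naive_when_correctly_specified(self):
        """At large n with a correct working correlation the sandwich and
        model-based GEE variances should agree within ~20%."""
        rng = np.random.default_rng(18)
        n = 5000
        sib = np.repeat([f"f{i}" for i in range(n // 4)], 4)
        age = rng.normal(0, 1, n)
        eb = rng.normal(0, 0.6, size=(n, 1))
        p = 1 / (1 + np.exp(-(-0.3 + 0.3 * age + 0.4 * eb[:, 0])))
        y = rng.binomial(1, p).astype(float)
        study = make_study(n, sib, Age=age, D=y)
        ebf = pd.DataFrame(eb, index=study.subject_ids, columns=["G1"])
        spec = PhenotypeModelSpec("D", "binary", covariates=("Age",))
        res = PathwayPhenotypeModel(study, ebf, spec).fit()
        naive = np.diag(res._sm.cov_naive)
        robust = np.diag(res._sm.cov_robust)
        assert np.all(np.abs(robust / naive - 1) < 0.20)

    def test_binary_trait_must_be_binary(self, lmm_data):
        study, eb = lmm_data
        with pytest.raises(DesignError):
            PathwayPhenotypeModel(study, eb, PhenotypeModelSpec(
                "Q", "binary"))

    def test_few_clusters_warns(self):
        rng = np.random.default_rng(19)
        n = 12
        study = make_study(n, [f"f{i//3}" for i in range(n)],
                           D=rng.binomial(1, 0.5, n))
        eb = make_eb(study, ["G1"], rng)
        with pytest.warns(UserWarning, match="clusters"):
            PathwayPhenotypeModel(study, eb,
                                  PhenotypeModelSpec("D", "binary")).fit()
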