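"""pPCA, phylogenetic mixed models, selection, CV, R2, and FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from phylodeco import comparative as cm
from phylodeco import trees as tr
from phylodeco.simulate import _FIXTURE_ELEV

from conftest import balanced_ultrametric


@pytest.fixture(scope="module")
def star6():
    return tr.parse_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")


@pytest.fixture(scope="module")
def table6(star6):
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.normal(size=(6, 4)), index=sorted(star6.tip_labels),
                        columns=["w", "x", "y", "z"])


class TestStandardize:
    def test_location_invariance(self, table6):
        a = cm.standardize(table6)
        b = cm.standardize(table6 + 100.0)
        pd.testing.assert_frame_equal(a, b)

    def test_unit_moments_and_roundtrip(self, table6):
        z = cm.standardize(table6)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-12)
        back = z * table6.std(ddof=1) + table6.mean()
        assert np.allclose(back, table6, atol=1e-12)

    def test_zero_variance_named(self, table6):
        t = table6.copy()
        t["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            cm.standardize(t)


class TestPPCA:
    def test_star_tree_equals_ordinary_pca(self, star6, table6):
        a = cm.ppca(table6, tree=star6)
        b = cm.pca(table6)
        assert np.allclose(a.eigenvalues, b.eigenvalues, atol=1e-8)
        assert np.allclose(np.abs(a.loadings), np.abs(b.loadings), atol=1e-8)

    def test_single_trait_is_all_variance(self, star6, table6):
        res = cm.ppca(table6[["x"]], tree=star6)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_three_taxon_gls_oracle(self):
        t = tr.parse_newick("((A:1,B:1):1,C:2);")
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(3, 2)), index=list("ABC"), columns=["u", "v"])
        C = tr.phylo_vcv(t).reorder(list("ABC")).matrix
        Ci = np.linalg.inv(C)
        one = np.ones((3, 1))
        Xm = X.to_numpy()
        a = (one.T @ Ci @ Xm) / (one.T @ Ci @ one)
        R = (Xm - a).T @ Ci @ (Xm - a) / 2
        res = cm.ppca(X, tree=t)
        assert np.allclose(res.ancestral_mean, a.ravel(), atol=1e-10)
        assert np.allclose(res.evolutionary_cov, R, atol=1e-10)
        assert np.allclose(np.sort(res.eigenvalues), np.sort(np.linalg.eigvalsh(R)),
                           atol=1e-10)

    def test_pca_matches_svd(self, table6):
        res = cm.pca(table6)
        Xc = table6.to_numpy() - table6.to_numpy().mean(axis=0)
        sv = np.linalg.svd(Xc, compute_uv=False)
        assert np.allclose(res.eigenvalues, sv**2 / (len(table6) - 1), atol=1e-10)
        assert res.eigenvalues.sum() == pytest.approx(
            float(table6.var(ddof=1).sum()))

    def test_percent_variance_sums_to_100(self, star6, table6):
        assert cm.ppca(table6, tree=star6).percent_variance.sum() == pytest.approx(100.0)


class TestFitPMM:
    def test_np_reduces_to_ols(self, table6):
        y = table6["x"].to_numpy()
        X = np.column_stack([np.ones(6), table6["y"].to_numpy()])
        f = cm.fit_pmm(y, X, random="NP")
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(f.beta, beta, atol=1e-10)
        assert f.sigma2_b == 0.0

    def test_p_on_star_equals_np(self, star6, table6):
        y = table6["x"].to_numpy()
        X = np.ones((6, 1))
        fp = cm.fit_pmm(y, X, tree=star6, random="P", species=list(table6.index))
        fnp = cm.fit_pmm(y, X, random="NP", species=list(table6.index))
        assert fp.loglik == pytest.approx(fnp.loglik, abs=1e-8)

    def test_rank_deficient_design_rejected(self, table6):
        y = table6["x"].to_numpy()
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            cm.fit_pmm(y, X, random="NP")

    def test_full_model_likelihood_dominates_submodels(self, fixture17):
        species = sorted(fixture17.tip_labels)
        rng = np.random.default_rng(5)
        x = rng.normal(size=17)
        y = 0.3 * x + rng.normal(size=17)
        X_full = np.column_stack([np.ones(17), x])
        X_sub = np.ones((17, 1))
        cov = tr.phylo_vcv(fixture17)
        ff = cm.fit_pmm(y, X_full, cov=cov, random="P", species=species)
        fs = cm.fit_pmm(y, X_sub, cov=cov, random="P", species=species)
        assert ff.loglik >= fs.loglik - 1e-9

    def test_beta_recovery_small(self, fixture17):
        """Short parameter-recovery run (the full experiment is in acceptance)."""
        species = sorted(fixture17.tip_labels)
        Ct = fixture17.vcv().reorder(species).matrix
        Ct /= np.max(np.diag(Ct))
        elev = np.array([_FIXTURE_ELEV[s] for s in species])
        x = (elev - elev.mean()) / elev.std(ddof=1)
        X = np.column_stack([np.ones(17), x])
        cov = tr.phylo_vcv(fixture17)
        rng = np.random.default_rng(11)
        L = np.linalg.cholesky(0.1 * Ct)
        est = []
        for _ in range(100):
            y = 1.0 - 0.5 * x + L @ rng.normal(size=17) + rng.normal(0, math.sqrt(0.4), 17)
            est.append(cm.fit_pmm(y, X, cov=cov, random="P", species=species).beta[1])
        se = np.std(est, ddof=1) / 10
        assert np.mean(est) == pytest.approx(-0.5, abs=3 * se)


@pytest.fixture(scope="module")
def star50():
    labels = [f"s{i}" for i in range(50)]
    return tr.parse_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")


class TestBackwardElimination:

    def test_matches_independent_ols_stepwise(self, star50):
        """Dual-route check: selection path equals a statsmodels-OLS AIC stepwise."""
        import statsmodels.api as sm

        def ols_stepwise(tab):
            y = tab["resp"].to_numpy()
            current = cm.full_interaction_terms(["elev", "prec", "temp"])

            def aic(tms):
                X, _ = cm.build_design(tab, tms)
                return sm.OLS(y, X).fit().aic

            best = aic(current)
            while current:
                removable = [t for t in current
                             if not any(cm._contains(u, t) for u in current)]
                cands = [(aic([u for u in current if u != t]), t) for t in removable]
                a, t = min(cands)
                if a < best:
                    best, current = a, [u for u in current if u != t]
                else:
                    break
            return current

        rng = np.random.default_rng(0)
        for _ in range(20):
            tab = pd.DataFrame(
                {"elev": rng.normal(size=50), "prec": rng.normal(size=50),
                 "temp": rng.normal(size=50), "resp": rng.normal(size=50)},
                index=sorted(star50.tip_labels))
            mine = cm.backward_eliminate(tab, "resp", tree=star50, random="NP")
            assert mine.terms[1:] == ols_stepwise(tab)

    def test_strong_effect_retained(self, star50):
        rng = np.random.default_rng(1)
        hits = 0
        n_sims = 40
        for _ in range(n_sims):
            elev = rng.normal(size=50)
            tab = pd.DataFrame(
                {"elev": elev, "prec": rng.normal(size=50),
                 "temp": rng.normal(size=50),
                 "resp": -1.0 * elev + 0.3 * rng.normal(size=50)},
                index=sorted(star50.tip_labels))
            best = cm.backward_eliminate(tab, "resp", tree=star50, random="NP")
            hits += "elev" in best.terms
        assert hits / n_sims >= 0.95

    def test_selected_aic_never_above_full(self, star50):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame(
            {"elev": rng.normal(size=50), "prec": rng.normal(size=50),
             "temp": rng.normal(size=50), "resp": rng.normal(size=50)},
            index=sorted(star50.tip_labels))
        best = cm.backward_eliminate(tab, "resp", tree=star50, random="NP")
        X, names = cm.build_design(tab, cm.full_interaction_terms(["elev", "prec", "temp"]))
        full = cm.fit_pmm(tab["resp"].to_numpy(), X, random="NP", terms=names)
        assert best.aic <= full.aic + 1e-9

    def test_saturated_design_rejected(self):
        labels = [f"s{i}" for i in range(8)]
        star = tr.parse_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(
            {"elev": rng.normal(size=8), "prec": rng.normal(size=8),
             "temp": rng.normal(size=8), "resp": rng.normal(size=8)}, index=labels)
        with pytest.raises(ValueError, match="n="):
            cm.backward_eliminate(tab, "resp", tree=star)


class TestKFoldCV:
    def test_perfect_linear_data_zero_mse(self):
        labels = [f"s{i}" for i in range(12)]
        star = tr.parse_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        tab = pd.DataFrame({"elev": x, "resp": 2.0 + 3.0 * x}, index=labels)
        mse = cm.kfold_cv(tab, "resp", ["elev"], k=3, tree=star, random="NP", seed=0)
        assert mse < 1e-10

    def test_seed_determinism(self, fixture17):
        species = sorted(fixture17.tip_labels)
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({"elev": rng.normal(size=17),
                            "resp": rng.normal(size=17)}, index=species)
        a = cm.kfold_cv(tab, "resp", ["elev"], k=4, tree=fixture17, seed=9)
        b = cm.kfold_cv(tab, "resp", ["elev"], k=4, tree=fixture17, seed=9)
        assert a == b

    def test_k_exceeding_n_rejected(self, fixture17):
        species = sorted(fixture17.tip_labels)
        tab = pd.DataFrame({"elev": np.zeros(17), "resp": np.zeros(17)}, index=species)
        with pytest.raises(ValueError, match="exceeds"):
            cm.kfold_cv(tab, "resp", ["elev"], k=18, tree=fixture17)

    def test_cv_flags_overfit_model(self):
        """CV-MSE of the true 1-term model beats the 8-term model usually."""
        labels = [f"s{i}" for i in range(30)]
        star = tr.parse_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        rng = np.random.default_rng(2)
        wins = 0
        n_sims = 40
        full_terms = cm.full_interaction_terms(["elev", "prec", "temp"])
        for _ in range(n_sims):
            tab = pd.DataFrame(
                {"elev": rng.normal(size=30), "prec": rng.normal(size=30),
                 "temp": rng.normal(size=30)}, index=labels)
            tab["resp"] = -0.8 * tab["elev"] + rng.normal(0, 1.0, 30)
            m_true = cm.kfold_cv(tab, "resp", ["elev"], k=3, tree=star,
                                 random="NP", seed=17)
            m_over = cm.kfold_cv(tab, "resp", full_terms, k=3, tree=star,
                                 random="NP", seed=17)
            wins += m_true < m_over
        assert wins / n_sims >= 0.8


class TestChooseRandomEffect:
    def test_lr_zero_gives_half(self):
        class F:
            terms = ["(Intercept)"]
            loglik = -10.0
            n = 17
        choice, p = cm.choose_random_effect(F(), F())
        assert p == 0.5
        assert choice == "NP"

    def test_mismatched_fixed_effects_rejected(self):
        class F:
            def __init__(self, t):
                self.terms = t
                self.loglik = -1.0
        with pytest.raises(ValueError, match="fixed effects"):
            cm.choose_random_effect(F(["a"]), F(["b"]))

    def test_strong_signal_prefers_p(self):
        t = balanced_ultrametric(5)  # 32 tips
        species = sorted(t.tip_labels)
        Ct = t.vcv().reorder(species).matrix
        Ct /= np.max(np.diag(Ct))
        cov = tr.phylo_vcv(t)
        rng = np.random.default_rng(4)
        L = np.linalg.cholesky(Ct + 1e-9 * np.eye(32))
        picks = 0
        for _ in range(40):
            y = 2.0 * (L @ rng.normal(size=32)) + rng.normal(0, 0.2, 32)
            fp = cm.fit_pmm(y, np.ones((32, 1)), cov=cov, random="P", species=species)
            fnp = cm.fit_pmm(y, np.ones((32, 1)), random="NP", species=species)
            picks += cm.choose_random_effect(fp, fnp)[0] == "P"
        assert picks >= 38


class TestR2AndFDR:
    def test_equal_fits_give_zero(self):
        class F:
            n = 17
            loglik = -4.2
        assert cm.r2_lik(F(), F()) == 0.0

    def test_half_n_loglik_difference(self):
        class F:
            n = 20
            loglik = 0.0
        class G:
            n = 20
            loglik = -10.0
        assert cm.r2_lik(F(), G()) == pytest.approx(1 - math.exp(-1))

    def test_bounded_below_one(self):
        class F:
            n = 5
            loglik = 10.0
        class G:
            n = 5
            loglik = -10.0
        assert cm.r2_lik(F(), G()) < 1.0

    def test_non_nested_rejected(self):
        class F:
            n = 5
            loglik = -10.0
        class G:
            n = 5
            loglik = 0.0
        with pytest.raises(ValueError, match="nested|converge"):
            cm.r2_lik(F(), G())

    def test_by_hand_formula(self):
        adj = cm.by_adjust([0.01, 0.02, 0.03, 0.04])
        c4 = 1 + 1 / 2 + 1 / 3 + 1 / 4
        assert adj.min() == pytest.approx(0.01 * 4 * c4 / 1)  # = 0.08333

    def test_single_p_unchanged(self):
        assert cm.by_adjust([0.37])[0] == pytest.approx(0.37)

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = cm.by_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_reduces_to_bh_without_correction_factor(self):
        """BY with c(m)=1 is BH: cross-check via direct step-up evaluation."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 15))
            m = len(p)
            cm_factor = np.sum(1.0 / np.arange(1, m + 1))
            by = cm.by_adjust(p)
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(np.minimum(bh * cm_factor, 1.0), by, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            cm.by_adjust([0.1, 1.2])
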