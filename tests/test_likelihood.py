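import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats

import pathrates as pr
from pathrates.errors import DataError, FitError
from pathrates.likelihood import _model_cov_fn, _nll_and_grad

from conftest import quadrature_marginal_loglik


class TestMarginalLoglik:
    def test_unit_example_matches_quadrature(self):
        """m=1, V'=[1], y=0, alpha=beta=1: log Gamma(3/2) - log sqrt(2 pi)."""
        closed = pr.ig_marginal_loglik([[0.0]], [[1.0]], alpha=1.0, beta=1.0)
        assert closed == pytest.approx(-1.0397, abs=1e-4)
        quad = quadrature_marginal_loglik([0.0], [[1.0]], 1.0, 1.0)
        assert closed == pytest.approx(quad, abs=1e-10)

    def test_matches_quadrature_on_toy_contrasts(self, toy_tree):
        rng = np.random.default_rng(3)
        Vp = pr.contrast_covariance(pr.bm_covariance(toy_tree), "A").values
        for _ in range(10):
            y = rng.normal(size=2)
            a = rng.uniform(0.5, 10)
            b = rng.uniform(0.1, 10)
            closed = pr.ig_marginal_loglik(y[None, :], Vp, alpha=a, beta=b)
            assert closed == pytest.approx(
                quadrature_marginal_loglik(y, Vp, a, b), abs=1e-8
            )

    @given(
        log_c=st.floats(min_value=-3, max_value=3),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_scale_invariance(self, log_c, seed):
        """(V' -> cV', beta -> beta/c) leaves the marginal unchanged."""
        rng = np.random.default_rng(seed)
        c = 10.0**log_c
        Vp = np.array([[2.0, 1.0], [1.0, 4.0]])
        Y = rng.normal(size=(5, 2))
        base = pr.ig_marginal_loglik(Y, Vp, alpha=2.5, beta=1.7)
        scaled = pr.ig_marginal_loglik(Y, c * Vp, alpha=2.5, beta=1.7 / c)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_large_alpha_recovers_fixed_rate_gaussian(self, toy_tree):
        """One rate per gene is nested: alpha -> inf with beta = alpha*s
        approaches the fixed-rate Gaussian likelihood with rate s."""
        rng = np.random.default_rng(7)
        s = 1.7
        Vp = pr.contrast_covariance(pr.bm_covariance(toy_tree), "A").values
        Y = rng.normal(size=(20, 2))
        mixture = pr.ig_marginal_loglik(Y, Vp, alpha=1e6, beta=1e6 * s)
        gauss = stats.multivariate_normal(cov=s * Vp).logpdf(Y).sum()
        assert mixture == pytest.approx(gauss, abs=1e-3)

    def test_reference_invariance_at_fixed_params(self, yeast_tree):
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(
            rng.normal(size=(30, 4)), columns=list(yeast_tree.tip_names)
        )
        values = []
        for ref in yeast_tree.tip_names:
            Y = pr.make_contrasts(expr, ref, center=True)
            Vp = pr.contrast_covariance(pr.bm_covariance(yeast_tree), ref)
            values.append(pr.ig_marginal_loglik(Y, Vp, alpha=3.0, beta=2.0))
        assert np.ptp(values) < 1e-9

    def test_complement_shift_equivalence_at_fixed_params(self, toy_tree):
        """Shift (c, r) equals shift (complement, 1/r) after the global
        rescaling is moved into beta."""
        rng = np.random.default_rng(13)
        expr = pd.DataFrame(rng.normal(size=(25, 3)), columns=["A", "B", "C"])
        Y = pr.make_contrasts(expr, "A", center=True)
        r = 4.0
        V_c = pr.bm_covariance(toy_tree, pr.RateShiftSpec(("C",), r))
        V_ab = pr.bm_covariance(toy_tree, pr.RateShiftSpec(("A", "B"), 1 / r))
        ll_c = pr.ig_marginal_loglik(
            Y, pr.contrast_covariance(V_c, "A"), alpha=3.0, beta=2.0
        )
        # V_c(r) = r * V_ab(1/r), and (V' -> cV', beta -> c*beta) matches
        ll_ab = pr.ig_marginal_loglik(
            Y, pr.contrast_covariance(V_ab, "A"), alpha=3.0, beta=2.0 * r
        )
        assert ll_c == pytest.approx(ll_ab, abs=1e-9)


class TestMakeContrasts:
    def test_subtraction(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]], columns=["A", "B", "C"]
        )
        Y = pr.make_contrasts(expr, "A", center=False)
        assert Y.values == pytest.approx(np.array([[1.0, 2.0], [0.0, 0.0]]))
        assert Y.columns == ("B", "C")

    def test_centering_removes_column_means(self):
        expr = pd.DataFrame(
            [[0.0, 1.0, 2.0], [0.0, 3.0, 4.0]], columns=["A", "B", "C"]
        )
        Y = pr.make_contrasts(expr, "A", center=True)
        assert Y.values == pytest.approx(np.array([[-1.0, -1.0], [1.0, 1.0]]))
        assert np.abs(Y.values.mean(axis=0)).max() < 1e-12

    def test_incomplete_genes_dropped(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, np.nan], [2.0, 2.0, 2.0], [0.0, 1.0, 1.0]],
            columns=["A", "B", "C"],
            index=["g1", "g2", "g3"],
        )
        Y = pr.make_contrasts(expr, "A", center=False)
        assert Y.n_genes == 2
        assert Y.gene_ids == ("g2", "g3")

    def test_errors(self):
        with pytest.raises(DataError):
            pr.make_contrasts(pd.DataFrame({"A": [1.0, 2.0]}), "A")
        expr = pd.DataFrame([[1.0, 2.0]], columns=["A", "B"])
        with pytest.raises(DataError):
            pr.make_contrasts(expr, "A", center=True)  # single gene


class TestFitModel:
    @pytest.mark.parametrize(
        "spec",
        [
            pr.ModelSpec("shift", shift_clade=("par",)),
            pr.ModelSpec("ou"),
            pr.ModelSpec("equal-rates"),
        ],
        ids=["shift", "ou", "equal-rates"],
    )
    def test_analytic_gradient_matches_finite_differences(self, yeast_tree, spec):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.normal(size=(40, 4)), columns=list(yeast_tree.tip_names)
        )
        Y = pr.make_contrasts(expr, "cer")
        cov_fn = _model_cov_fn(yeast_tree, spec, "cer")
        x0 = np.log([2.0, 1.5, 3.0])[: 2 + (spec.family != "equal-rates")]
        _, grad = _nll_and_grad(x0, Y.values, cov_fn)
        num = optimize.approx_fprime(
            x0, lambda x: _nll_and_grad(x, Y.values, cov_fn)[0], 1e-7
        )
        assert grad == pytest.approx(num, rel=1e-4, abs=1e-4)

    def test_fit_dominates_generating_point(self, yeast_tree):
        rng = pr.replicate_rng(17, 0)
        rates = pr.draw_rates(3.0, 2.0, 60, rng)
        sim = pr.simulate_bm(yeast_tree, rates, rng=rng)
        Y = pr.make_contrasts(sim.expression, "cer")
        fit = pr.fit_model(Y, yeast_tree, pr.ModelSpec("equal-rates"))
        Vp = pr.contrast_covariance(pr.bm_covariance(yeast_tree), "cer")
        at_truth = pr.ig_marginal_loglik(Y, Vp, alpha=3.0, beta=2.0)
        assert fit.loglik >= at_truth - 1e-9
        assert fit.converged

    def test_recovers_generating_rate_distribution(self, yeast_tree):
        """The rate-distribution fit is consistent: alpha and beta land
        near the generating (3, 2) for large pathways, and the implied
        mean rate beta/(alpha - 1) is recovered already at 100 genes
        (where the shape itself is only weakly identified per gene)."""
        alphas, betas = [], []
        for rep in range(5):
            rng = pr.replicate_rng(23, rep)
            rates = pr.draw_rates(3.0, 2.0, 2000, rng)
            sim = pr.simulate_bm(yeast_tree, rates, rng=rng)
            Y = pr.make_contrasts(sim.expression, "cer")
            fit = pr.fit_model(Y, yeast_tree, pr.ModelSpec("equal-rates"))
            alphas.append(fit.params["alpha"])
            betas.append(fit.params["beta"])
        assert np.median(alphas) == pytest.approx(3.0, rel=0.2)
        assert np.median(betas) == pytest.approx(2.0, rel=0.2)

        mean_rates = []
        for rep in range(20):
            rng = pr.replicate_rng(24, rep)
            rates = pr.draw_rates(3.0, 2.0, 100, rng)
            sim = pr.simulate_bm(yeast_tree, rates, rng=rng)
            Y = pr.make_contrasts(sim.expression, "cer")
            fit = pr.fit_model(Y, yeast_tree, pr.ModelSpec("equal-rates"))
            mean_rates.append(fit.params["beta"] / (fit.params["alpha"] - 1))
        assert np.median(mean_rates) == pytest.approx(1.0, rel=0.25)

    def test_single_gene_rejected(self, yeast_tree):
        expr = pd.DataFrame(
            np.ones((1, 4)), columns=list(yeast_tree.tip_names)
        )
        Y = pr.make_contrasts(expr, "cer", center=False)
        with pytest.raises(FitError):
            pr.fit_model(Y, yeast_tree, pr.ModelSpec("equal-rates"))

    def test_degenerate_zero_column_rejected(self, yeast_tree):
        expr = pd.DataFrame(
            np.zeros((5, 4)), columns=list(yeast_tree.tip_names)
        )
        Y = pr.make_contrasts(expr, "cer", center=False)
        with pytest.raises(FitError):
            pr.fit_model(Y, yeast_tree, pr.ModelSpec("equal-rates"))


class TestCompareModels:
    @staticmethod
    def _fit(name_clade, loglik, k3=True, n=50):
        spec = (
            pr.ModelSpec("shift", shift_clade=name_clade)
            if k3
            else pr.ModelSpec("equal-rates")
        )
        return pr.FitResult(spec, {}, loglik, True, n)

    def test_equal_fits_split_evenly(self):
        comp = pr.compare_models([self._fit(("A",), -10), self._fit(("B",), -10)])
        assert comp.weights == pytest.approx([0.5, 0.5])

    def test_delta_aic_two(self):
        comp = pr.compare_models([self._fit(("A",), -10), self._fit(("B",), -11)])
        expected = np.array([1.0, np.exp(-1)]) / (1 + np.exp(-1))
        assert comp.weights == pytest.approx(expected, abs=1e-6)
        assert comp.best.spec.shift_clade == ("A",)

    def test_weights_sum_to_one(self):
        fits = [self._fit((c,), ll) for c, ll in zip("ABCD", [-5, -9, -2, -40])]
        comp = pr.compare_models(fits)
        assert comp.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tie_broken_by_smaller_k(self):
        er = self._fit(None, -10.0, k3=False)  # k=2, AIC = 24
        sh = self._fit(("A",), -9.0)  # k=3, AIC = 24
        comp = pr.compare_models([sh, er])
        assert comp.best.spec.family == "equal-rates"

    def test_mismatched_gene_counts_rejected(self):
        with pytest.raises(DataError):
            pr.compare_models([self._fit(("A",), -10, n=50), self._fit(("B",), -10, n=49)])


@pytest.fixture(scope="module")
def scan_inputs(yeast_tree):
    rng = pr.replicate_rng(29, 0)
    rates = pr.draw_rates(3.0, 2.0, 60, rng)
    sim = pr.simulate_bm(yeast_tree, rates, pr.RateShiftSpec(("par",), 5.0), rng)
    expr = sim.expression.copy()
    genes = list(expr.index)
    # 3 of the 12 genes of the undersized-after-filtering term lose a value
    expr.loc[genes[40:43], "mik"] = np.nan
    genesets = {
        "big": genes[:38],
        "small": genes[38:47][:9],
        "incomplete": genes[38:50],
    }
    return expr, genesets


class TestScanPathways:
    def test_shifted_pathway_detected_and_filters_applied(
        self, yeast_tree, scan_inputs
    ):
        expr, genesets = scan_inputs
        table = pr.scan_pathways(expr, genesets, yeast_tree, "cer", min_genes=10)
        assert list(table["term"]) == ["big"]  # 9-gene and 9-complete terms skipped
        row = table.iloc[0]
        assert row["n_genes"] == 38
        assert row["best_model"] == "par shift"
        assert row["parameter"] == pytest.approx(5.0, rel=0.6)
        weight_cols = [c for c in table.columns if c.startswith("w[")]
        assert len(weight_cols) == 7
        assert table[weight_cols].iloc[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_collection_rejected(self, yeast_tree, scan_inputs):
        expr, _ = scan_inputs
        with pytest.raises(DataError):
            pr.scan_pathways(expr, {}, yeast_tree, "cer")

    def test_no_term_passes_gives_empty_table(self, yeast_tree, scan_inputs):
        expr, _ = scan_inputs
        table = pr.scan_pathways(
            expr, {"tiny": list(expr.index[:3])}, yeast_tree, "cer"
        )
        assert table.empty


class TestNormalizedDivergence:
    def test_division_by_patristic_distance(self, yeast_tree):
        expr = pd.DataFrame(
            {"cer": [0.0, 0.0], "par": [0.4, -0.8], "mik": [0.0, 0.0], "bay": [1.0, -1.0]},
            index=["g1", "g2"],
        )
        nd = pr.normalized_divergence(expr, yeast_tree, "cer")
        assert nd["par"].tolist() == pytest.approx([0.4 / 0.25, -0.8 / 0.25])
        assert nd["bay"].tolist() == pytest.approx([1.0, -1.0])
        assert "cer" not in nd.columns

    def test_strong_constraint_narrows_most_divergent_species(self, yeast_tree):
        """Under phylogeny-wide OU, dividing log fold-changes by sequence
        branch length makes the most divergent species' distribution the
        narrowest."""
        rng = pr.replicate_rng(31, 0)
        rates = pr.draw_rates(3.0, 2.0, 4000, rng)
        sim = pr.simulate_ou(yeast_tree, rates, theta=10.0, rng=rng)
        nd = pr.normalized_divergence(sim.expression, yeast_tree, "cer")
        widths = nd.std(axis=0)
        assert widths["bay"] < widths["mik"] < widths["par"]
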