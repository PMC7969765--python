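"""Evidence integration: decorrelation, power transform, p-value combination."""

import numpy as np
import pytest
from scipy import stats as sps

from locusrisk.evidence import (
    BoxCoxFit,
    DegenerateDataError,
    boxcox_apply,
    boxcox_fit,
    compute_evidence,
    fisher_combine,
    fisher_combined_pvalue,
    gaussian_pvalues,
    hotelling_transform,
)
from locusrisk.datatypes import ValidationError

from conftest import make_bundle


class TestHotelling:
    def test_identical_rows_give_zeros(self):
        P = np.tile([1.0, 2.0, 3.0], (5, 1))
        _, out = hotelling_transform(P, n_components=1)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_collinear_data_auto_keeps_one_component(self, rng):
        x = rng.normal(size=20)
        P = np.column_stack([x, 2.0 * x])  # exact line
        model, out = hotelling_transform(P, "auto")
        assert model.n_components == 1
        assert out.shape == (20, 1)

    def test_component_variances_match_eigendecomposition(self, rng):
        P = rng.normal(size=(6, 3))
        model, out = hotelling_transform(P, "auto")
        # independent oracle: dense eigendecomposition of the sample covariance
        evals = np.sort(np.linalg.eigvalsh(np.cov(P, rowvar=False)))[::-1]
        np.testing.assert_allclose(out.var(axis=0, ddof=1),
                                   evals[: model.n_components], atol=1e-8)
        # off-diagonal sample covariances vanish
        c = np.cov(out, rowvar=False)
        np.testing.assert_allclose(c - np.diag(np.diag(c)), 0.0, atol=1e-8)

    def test_row_shift_invariance(self, rng):
        P = rng.normal(size=(15, 4))
        _, a = hotelling_transform(P, "auto")
        _, b = hotelling_transform(P + 13.7, "auto")
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_over_rank_request_rejected(self):
        P = np.tile([1.0, 2.0], (8, 1))  # zero variance
        with pytest.raises(ValidationError):
            hotelling_transform(P, n_components=2)


def _grid_beta_oracle(x, step=0.01):
    """Grid-search Box-Cox exponent from the closed-form profile likelihood."""
    mn = x.min()
    shifted = x + (0.0 if mn > 0 else 1.0 - mn)
    logx = np.log(shifted)
    betas = np.arange(-5.0, 5.0 + step, step)
    best, best_ll = None, -np.inf
    n = len(shifted)
    for b in betas:
        y = np.log(shifted) if b == 0 else (shifted**b - 1.0) / b
        ll = -n / 2.0 * np.log(y.var()) + (b - 1.0) * logx.sum()
        if ll > best_ll:
            best, best_ll = b, ll
    return best


class TestBoxCox:
    def test_lognormal_recovers_beta_zero(self, rng):
        x = np.exp(rng.normal(size=2000))
        fit = boxcox_fit(x)
        assert abs(fit.beta - 0.0) < 0.15
        assert abs(fit.beta - _grid_beta_oracle(x)) <= 0.01 + 1e-9

    def test_normal_data_recovers_beta_one(self, rng):
        x = rng.normal(loc=10.0, scale=1.0, size=2000)
        fit = boxcox_fit(x)
        assert abs(fit.beta - 1.0) < 0.2
        assert abs(fit.beta - _grid_beta_oracle(x)) <= 0.01 + 1e-9

    def test_shift_rule(self, rng):
        x = rng.normal(size=50)
        x[0] = -3.0
        fit = boxcox_fit(x)
        assert fit.shift == 4.0
        assert np.all(x + fit.shift >= 1.0)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateDataError):
            boxcox_fit(np.full(20, 2.0))

    @pytest.mark.parametrize(
        "beta,x_plus_c,expected",
        [(0.0, np.e, 1.0), (1.0, 5.0, 4.0), (2.0, 3.0, 4.0)],
    )
    def test_apply_closed_forms(self, beta, x_plus_c, expected):
        out = boxcox_apply(np.array([x_plus_c]), BoxCoxFit(shift=0.0, beta=beta))
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_apply_strictly_increasing(self, rng):
        x = np.sort(rng.uniform(0.1, 10.0, size=100))
        for beta in (-2.0, -0.5, 0.0, 0.5, 2.0):
            y = boxcox_apply(x, BoxCoxFit(shift=0.0, beta=beta))
            assert np.all(np.diff(y) > 0)

    def test_nonpositive_shifted_rejected(self):
        with pytest.raises(ValidationError):
            boxcox_apply(np.array([-1.0]), BoxCoxFit(shift=0.0, beta=1.0))


class TestGaussianPValues:
    def test_mean_value_maps_to_half(self):
        y = np.array([1.0, 2.0, 3.0])
        assert gaussian_pvalues(y)[1] == pytest.approx(0.5, abs=1e-12)

    def test_upper_tail_quantile(self, rng):
        # after standardization, the p of z = 1.959964 is ~0.025
        y = rng.normal(size=500)
        y = (y - y.mean()) / y.std(ddof=1)
        y[0] = 1.959964
        # re-standardize shifts slightly; check against the exact CDF oracle
        p = gaussian_pvalues(y)
        z0 = (y[0] - y.mean()) / y.std(ddof=1)
        assert p[0] == pytest.approx(sps.norm.sf(z0), abs=1e-12)
        assert sps.norm.sf(1.959964) == pytest.approx(0.025, abs=1e-6)

    def test_strictly_decreasing_in_value(self, rng):
        y = rng.normal(size=50)
        p = gaussian_pvalues(y)
        order = np.argsort(y)
        assert np.all(np.diff(p[order]) < 0)

    def test_mean_p_near_half_large_sample(self, rng):
        p = gaussian_pvalues(rng.normal(size=1000))
        assert abs(p.mean() - 0.5) < 0.05

    def test_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            gaussian_pvalues(np.ones(10))


class TestFisherCombine:
    def test_all_ones_zero_evidence(self):
        assert fisher_combine(np.array([1.0, 1.0]), np.array([1.0])) == 0.0

    def test_single_p_identity(self):
        for p in (0.9, 0.5, 0.01, 1e-8):
            assert fisher_combined_pvalue(np.array([p])) == pytest.approx(p, rel=1e-12)

    def test_two_p_chi_square_oracle(self):
        p = np.array([0.01, 0.05])
        T = -2 * np.log(p).sum()
        assert T == pytest.approx(15.2018, abs=1e-4)
        expected = sps.chi2.sf(T, df=4)
        assert fisher_combined_pvalue(p) == pytest.approx(expected, rel=1e-12)
        assert fisher_combine(p[:1], p[1:]) == pytest.approx(-np.log(expected), rel=1e-10)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValidationError):
            fisher_combined_pvalue(np.array([0.0, 0.5]))

    def test_monotone_in_each_p(self, rng):
        base = rng.uniform(0.05, 0.95, size=4)
        e0 = fisher_combine(base[:2], base[2:])
        for j in range(4):
            smaller = base.copy()
            smaller[j] *= 0.5
            assert fisher_combine(smaller[:2], smaller[2:]) >= e0


class TestComputeEvidence:
    def test_no_features_is_error(self):
        bundle = make_bundle(["A", "B"], np.empty((2, 0)), np.empty((2, 0)))
        with pytest.raises(ValidationError):
            compute_evidence(bundle)

    def test_dominant_gene_gets_max_evidence(self, rng):
        g = 20
        pv = rng.uniform(0.2, 1.0, size=(g, 2))
        pv[0] = 1e-6
        bundle = make_bundle([f"g{i}" for i in range(g)], pv, np.empty((g, 0)))
        scores = compute_evidence(bundle)
        assert max(scores.scores, key=scores.scores.get) == "g0"

    def test_matches_straightline_reimplementation(self, rng):
        """Full pipeline agrees with an inline, type-free recomputation.

        Agreement is limited by the exponent-search tolerance (1e-5), so the
        evidence comparison is at 1e-6.
        """
        g = 20
        pv = rng.uniform(size=(g, 2))
        cont = rng.normal(size=(g, 3))
        bundle = make_bundle([f"g{i}" for i in range(g)], pv, cont)
        scores = compute_evidence(bundle)

        # ---- inline oracle ----
        centered = cont - cont.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(cont, rowvar=False))
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        comps = []
        for k in range(3):
            v = evecs[:, k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            comps.append(centered @ v)
        comp_p = []
        for col in comps:
            shift = 0.0 if col.min() > 0 else 1.0 - col.min()
            shifted = col + shift

            def nll(b):
                y = np.log(shifted) if abs(b) < 1e-8 else (shifted**b - 1.0) / b
                n = len(y)
                return -(-n / 2.0 * np.log(y.var()) + (b - 1.0) * np.log(shifted).sum())

            # independent golden-section minimization
            a, b = -5.0, 5.0
            phi = (np.sqrt(5) - 1) / 2
            c, d = b - phi * (b - a), a + phi * (b - a)
            fc, fd = nll(c), nll(d)
            while b - a > 1e-5:
                if fc < fd:
                    b, d, fd = d, c, fc
                    c = b - phi * (b - a)
                    fc = nll(c)
                else:
                    a, c, fc = c, d, fd
                    d = a + phi * (b - a)
                    fd = nll(d)
            beta = (a + b) / 2
            y = np.log(shifted) if abs(beta) < 1e-8 else (shifted**beta - 1.0) / beta
            z = (y - y.mean()) / y.std(ddof=1)
            comp_p.append(np.clip(sps.norm.sf(z), 1e-300, 1.0))
        comp_p = np.column_stack(comp_p)
        for i, gene in enumerate(bundle.genes):
            allp = np.concatenate([comp_p[i], pv[i]])
            T = -2 * np.log(allp).sum()
            expected = -np.log(sps.chi2.sf(T, df=2 * allp.size))
            assert scores[gene] == pytest.approx(expected, abs=1e-6)
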