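"""REML machinery: closed-form oracles, recovery, BLUP vs Henderson system."""

from __future__ import annotations

import numpy as np
import pytest

from gremlkit.grm import compute_grm
from gremlkit.greml import (GREML, PhenotypeBlock, gblup_predict,
                            henderson_mme, observed_to_liability_h2,
                            residualize, wald_test)
from gremlkit.simulate import draw_frequencies, simulate_genotypes

from conftest import make_dataset


# ---------------------------------------------------------------------------
# residualize
# ---------------------------------------------------------------------------

def test_residualize_intercept_only_centers():
    y = np.array([1.0, 4.0, 7.0, 2.0])
    np.testing.assert_allclose(residualize(y, None), y - y.mean(), atol=1e-14)


def test_residualize_exact_span_gives_zero():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((30, 3))
    y = X @ np.array([1.0, -2.0, 0.5]) + 3.0
    assert np.abs(residualize(y, X)).max() < 1e-10


def test_residualize_matches_normal_equations():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((80, 4))
    y = rng.standard_normal(80)
    M = np.column_stack([np.ones(80), X])
    beta = np.linalg.solve(M.T @ M, M.T @ y)
    np.testing.assert_allclose(residualize(y, X), y - M @ beta, atol=1e-10)
    assert residualize(y, X).mean() == pytest.approx(0.0, abs=1e-14)


def test_residualize_drops_collinear_columns():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((40, 2))
    X = np.column_stack([X, X[:, 0] * 2.0])
    y = rng.standard_normal(40)
    with pytest.warns(UserWarning, match="collinear"):
        r = residualize(y, X)
    np.testing.assert_allclose(r, residualize(y, X[:, :2]), atol=1e-10)


# ---------------------------------------------------------------------------
# Wald test and liability transform
# ---------------------------------------------------------------------------

def test_wald_estimate_at_null_gives_one():
    assert wald_test(0.3, 0.1, 0.3, "two") == pytest.approx(1.0)


def test_wald_reproduces_printed_one_tail_p():
    # rg = 0.14 with SE 0.08 against 0, upper tail: 0.04 at two decimals
    assert round(wald_test(0.14, 0.08, 0.0, "upper"), 2) == 0.04


def test_wald_two_sided_matches_high_precision_cdf():
    from scipy.special import ndtr

    est, se, null = 0.47, 0.19, 1.0
    z = (est - null) / se
    expected = 2.0 * ndtr(-abs(z))
    assert wald_test(est, se, null, "two") == pytest.approx(expected, rel=1e-12)


def test_wald_invalid_se():
    with pytest.raises(ValueError):
        wald_test(1.0, 0.0)


def test_liability_transform_matches_symbolic_oracle():
    import sympy

    K = sympy.Rational(1, 100)
    P = sympy.Rational(1, 2)
    h2_obs = sympy.Rational(1, 5)
    t = sympy.sqrt(2) * sympy.erfinv(1 - 2 * K)
    phi = sympy.exp(-t**2 / 2) / sympy.sqrt(2 * sympy.pi)
    expected = h2_obs * K**2 * (1 - K) ** 2 / (P * (1 - P) * phi**2)
    got = observed_to_liability_h2(0.2, 0.01, 0.5)
    assert got == pytest.approx(float(sympy.N(expected, 30)), rel=1e-10)


def test_liability_transform_k_equals_p_reduces():
    import sympy

    K = sympy.Rational(1, 10)
    t = sympy.sqrt(2) * sympy.erfinv(1 - 2 * K)
    phi = sympy.exp(-t**2 / 2) / sympy.sqrt(2 * sympy.pi)
    # with K = P the factor reduces to K(1-K)/phi(t)^2 per unit h2_obs
    expected = float(sympy.N(K * (1 - K) / phi**2, 30))
    assert observed_to_liability_h2(1.0, 0.1, 0.1) == pytest.approx(expected, rel=1e-10)


def test_liability_transform_degenerate_inputs():
    assert observed_to_liability_h2(0.0, 0.01, 0.5) == 0.0
    with pytest.raises(ValueError):
        observed_to_liability_h2(0.2, 0.0, 0.5)
    with pytest.raises(ValueError):
        observed_to_liability_h2(0.2, 0.1, 1.0)


# ---------------------------------------------------------------------------
# REML: grid-search oracle and recovery
# ---------------------------------------------------------------------------

def _restricted_loglik_grid(G, y, sg_grid, se_grid):
    """Eigen-rotated restricted logL, evaluated on a (sg, se) grid."""
    lam, U = np.linalg.eigh(G)
    yt = U.T @ y
    xt = U.T @ np.ones(len(y))
    best, arg = -np.inf, (None, None)
    for sg in sg_grid:
        d = sg * lam[None, :] + se_grid[:, None]          # (n_se, n)
        logdet = np.sum(np.log(d), axis=1)
        xvx = np.sum(xt**2 / d, axis=1)
        yvy = np.sum(yt**2 / d, axis=1)
        yvx = np.sum(yt * xt / d, axis=1)
        ll = -0.5 * (logdet + np.log(xvx) + yvy - yvx**2 / xvx)
        k = int(np.argmax(ll))
        if ll[k] > best:
            best, arg = ll[k], (sg, se_grid[k])
    return best, arg


def _simulated_trait(n, m, h2, seed):
    freq = draw_frequencies(m, (0.1, 0.5), seed=seed + 100)
    d = simulate_genotypes(n, frequencies=freq, ld_block_size=1, seed=seed)
    rng = np.random.default_rng(seed + 1)
    b = rng.normal(0.0, np.sqrt(h2 / m), m)
    w = (d.calls - 2 * freq[:, None]) / np.sqrt(2 * freq * (1 - freq))[:, None]
    y = b @ w + rng.normal(0.0, np.sqrt(1 - h2), n)
    return d, y


@pytest.mark.parametrize("seed", [3, 5, 21])
def test_reml_matches_grid_search_oracle_n30(seed):
    d, y = _simulated_trait(30, 50, 0.5, seed=seed)
    G = compute_grm(d)
    res = GREML(G, [PhenotypeBlock("t", d.sample_ids, y)]).fit(tol=1e-8)
    grid = np.arange(1e-3, 2.0 * np.var(y), 1e-3)
    _, (sg_hat, se_hat) = _restricted_loglik_grid(G.values, y, grid, grid)
    assert res.params[0] == pytest.approx(sg_hat, abs=1.5e-3)
    assert res.params[1] == pytest.approx(se_hat, abs=1.5e-3)


def test_reml_recovers_h2_within_two_se():
    d, y = _simulated_trait(1000, 2000, 0.5, seed=23)
    G = compute_grm(d)
    res = GREML(G, [PhenotypeBlock("t", d.sample_ids, y)]).fit()
    h2, se = res.h2("t")
    assert abs(h2 - 0.5) < 2 * se


def test_reml_null_h2_not_significant():
    """With sigma_g = 0 truth, spurious heritability is rare.

    The one-sided Wald test at the boundary is conservative, so the
    exceedance over 200 seeded replicates stays well below 10%.
    """
    exceed = 0
    n_rep = 200
    for seed in range(n_rep):
        d, y = _simulated_trait(120, 200, 0.0, seed=1000 + seed)
        G = compute_grm(d)
        res = GREML(G, [PhenotypeBlock("t", d.sample_ids, y)]).fit()
        h2, se = res.h2("t")
        if se > 0 and wald_test(h2, se, 0.0, "upper") < 0.05:
            exceed += 1
    assert exceed / n_rep <= 0.10


def test_reml_gradient_scaled_step_small_at_optimum():
    d, y = _simulated_trait(200, 300, 0.4, seed=9)
    G = compute_grm(d)
    res = GREML(G, [PhenotypeBlock("t", d.sample_ids, y)]).fit(tol=1e-7)
    # natural-units Newton step at the reported optimum (AI^-1 grad)
    assert np.abs(res.natural_step).max() < 10 * 1e-6 * np.var(y)


def test_rg_invariant_to_phenotype_rescaling():
    d, y1 = _simulated_trait(300, 400, 0.4, seed=31)
    rng = np.random.default_rng(99)
    y2 = 0.6 * y1[::-1] + rng.standard_normal(300)
    G = compute_grm(d)
    half = 150
    ids = np.array(d.sample_ids)
    blocks = lambda ya, yb: [
        PhenotypeBlock("a", list(ids[:half]), ya[:half]),
        PhenotypeBlock("b", list(ids[half:]), yb[half:]),
    ]
    r1 = GREML(G, blocks(y1, y2)).fit(tol=1e-9)
    r2 = GREML(G, blocks(y1, 3.7 * y2)).fit(tol=1e-9)
    g1 = r1.genetic_correlation("a", "b")
    g2 = r2.genetic_correlation("a", "b")
    assert g1.raw_rg == pytest.approx(g2.raw_rg, abs=1e-8)


def test_genetic_correlation_edge_values():
    d, y = _simulated_trait(200, 300, 0.4, seed=51)
    G = compute_grm(d)
    ids = np.array(d.sample_ids)
    blocks = [PhenotypeBlock("a", list(ids[:100]), y[:100]),
              PhenotypeBlock("b", list(ids[100:]), y[100:])]
    res = GREML(G, blocks).fit()
    # direct formula checks on the fitted components
    k = res.model.T
    cov = res.params[k]
    expected = cov / np.sqrt(res.params[0] * res.params[1])
    assert res.genetic_correlation("a", "b").raw_rg == pytest.approx(expected)
    # synthetic components: zero covariance -> rg 0; equal -> rg 1
    res.params = res.params.copy()
    res.params[k] = 0.0
    assert res.genetic_correlation("a", "b").raw_rg == 0.0
    res.params[:2] = 1.0
    res.params[k] = 1.0
    assert res.genetic_correlation("a", "b").raw_rg == pytest.approx(1.0)


def test_disjoint_block_validation():
    d, y = _simulated_trait(40, 60, 0.3, seed=2)
    G = compute_grm(d)
    ids = d.sample_ids
    with pytest.raises(ValueError, match="more than one block"):
        GREML(G, [PhenotypeBlock("a", ids[:25], y[:25]),
                  PhenotypeBlock("b", ids[20:], y[20:])])
    with pytest.raises(ValueError, match="not in GRM"):
        GREML(G, [PhenotypeBlock("a", ["nope_1"], y[:1])])


# ---------------------------------------------------------------------------
# GBLUP vs the Henderson mixed-model equations
# ---------------------------------------------------------------------------

def _gblup_fixture(seed=77, n=50, m=500, h2=0.5):
    # GRM built against the true panel frequencies: in-sample centering
    # would make G exactly singular (G @ 1 = 0), which the Henderson oracle
    # cannot invert
    freq = draw_frequencies(m, (0.1, 0.5), seed=seed)
    d = simulate_genotypes(n, frequencies=freq, ld_block_size=1, seed=seed)
    rng = np.random.default_rng(seed + 1)
    b = rng.normal(0.0, np.sqrt(h2 / m), m)
    w = (d.calls - 2 * freq[:, None]) / np.sqrt(2 * freq * (1 - freq))[:, None]
    g_true = b @ w
    y = g_true + rng.normal(0.0, np.sqrt(1 - h2), n)
    return d, y, compute_grm(d, frequencies=freq)


def test_gblup_matches_henderson_mme():
    d, y, G = _gblup_fixture()
    ids = d.sample_ids
    obs, tgt = ids[:30], ids[30:]
    block = PhenotypeBlock("t", obs, y[:30])
    su2, se2 = 0.4, 0.6
    sol = gblup_predict((su2, se2), G, block, tgt)
    beta, u_all = henderson_mme(su2, se2, G.values, np.arange(30), y[:30],
                                np.ones((30, 1)))
    np.testing.assert_allclose(sol.u, u_all[30:], atol=1e-8)
    np.testing.assert_allclose(sol.fixed_effects, beta, atol=1e-8)
    # and the predictions track the best linear predictor closely
    assert np.corrcoef(sol.u, u_all[30:])[0, 1] > 0.95


def test_gblup_zero_genetic_variance_predicts_zero():
    d, y, G = _gblup_fixture()
    block = PhenotypeBlock("t", d.sample_ids[:30], y[:30])
    with pytest.warns(UserWarning, match="zero"):
        sol = gblup_predict((0.0, 1.0), G, block, d.sample_ids[30:])
    assert (sol.u == 0).all()


def test_gblup_duplicate_relatedness_gives_equal_prediction():
    d, y, G = _gblup_fixture(n=40)
    # make target 35 a relatedness clone of target 36
    V = G.values.copy()
    V[35, :] = V[36, :]
    V[:, 35] = V[:, 36]
    V[35, 35] = V[36, 36]
    G2 = type(G)(values=V, n_snps_used=G.n_snps_used, sample_ids=G.sample_ids)
    block = PhenotypeBlock("t", d.sample_ids[:30], y[:30])
    sol = gblup_predict((0.4, 0.6), G2, block, d.sample_ids[30:])
    assert sol.u[5] == pytest.approx(sol.u[6], abs=1e-12)
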