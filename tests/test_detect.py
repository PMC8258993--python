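import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.stats

from murkscreen import (
    call_murk_genes,
    detect_murk,
    fit_population_slope,
    fit_population_slopes,
    slope_increase_test,
)
from murkscreen.errors import InvalidParameterError

from .conftest import toy_layers


class TestSlopeFit:
    def test_exact_collinearity_gives_zero_se(self):
        fit = fit_population_slope(u=[0, 2, 4], s=[0, 1, 2])
        assert fit.slope == pytest.approx(2.0)
        assert fit.se_slope == pytest.approx(0.0, abs=1e-12)

    def test_three_point_slope_and_se(self):
        # OLS on (0,0),(1,1),(2,3): slope 1.5, se = sqrt((1/6)/1/2) = 0.28868
        fit = fit_population_slope(u=[0, 1, 3], s=[0, 1, 2])
        assert fit.slope == pytest.approx(1.5)
        assert fit.se_slope == pytest.approx(np.sqrt(1 / 12), abs=1e-10)

    def test_intercept_absorbs_shifts(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=30)
        u = 0.7 * s + rng.normal(size=30) * 0.1
        f1 = fit_population_slope(u, s)
        f2 = fit_population_slope(u + 5.0, s)
        assert f1.slope == pytest.approx(f2.slope)
        assert f1.se_slope == pytest.approx(f2.se_slope)

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=50)
        u = 1.2 * s + rng.normal(size=50)
        fit = fit_population_slope(u, s)
        ref = scipy.stats.linregress(s, u)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-12)
        assert fit.se_slope == pytest.approx(ref.stderr, rel=1e-10)

    def test_constant_spliced_gives_undefined_fit(self):
        fit = fit_population_slope(u=[1, 2, 3], s=[2, 2, 2])
        assert np.isnan(fit.slope) and np.isnan(fit.se_slope)

    def test_vectorized_fit_agrees_with_per_gene(self):
        rng = np.random.default_rng(4)
        S = rng.normal(size=(40, 5))
        U = S * 0.5 + rng.normal(size=(40, 5)) * 0.3
        layers = toy_layers(U, S, stage="imputed")
        pops = np.array(["P"] * 40, dtype=object)
        fits = fit_population_slopes(layers, ["P"], pops, min_cells=10)
        for j in range(5):
            ref = scipy.stats.linregress(S[:, j], U[:, j])
            row = fits.iloc[j]
            assert row.slope == pytest.approx(ref.slope, rel=1e-10)
            assert row.se_slope == pytest.approx(ref.stderr, rel=1e-8)


class TestSlopeIncreaseTest:
    def test_identical_fits_give_half(self):
        assert slope_increase_test(1.0, 0.1, 50, 1.0, 0.1, 50) == pytest.approx(0.5)

    def test_one_sidedness(self):
        p = slope_increase_test(0.5, 0.1, 50, 1.0, 0.1, 50)
        assert p > 0.5

    def test_matches_t_density_integration(self):
        # T = 1/sqrt(0.02) = 7.071, Welch df from (se^2=0.01, n-2=98) twice = 196
        p = slope_increase_test(2.0, 0.1, 100, 1.0, 0.1, 100)
        T = 1.0 / np.sqrt(0.02)
        df = 0.02**2 / (2 * 0.01**2 / 98)
        assert df == pytest.approx(196.0)
        tail, _ = scipy.integrate.quad(lambda x: scipy.stats.t.pdf(x, df), T, np.inf)
        assert p == pytest.approx(tail, rel=1e-6)

    def test_zero_se_conventions(self):
        assert slope_increase_test(1.0, 0.0, 10, 1.0, 0.0, 10) == 0.5
        assert slope_increase_test(2.0, 0.0, 10, 1.0, 0.0, 10) == 0.0
        assert slope_increase_test(0.5, 0.0, 10, 1.0, 0.0, 10) == 1.0

    def test_normal_approximation_option(self):
        p = slope_increase_test(2.0, 0.1, 100, 1.0, 0.1, 100, method="normal")
        assert p == pytest.approx(scipy.stats.norm.sf(1 / np.sqrt(0.02)), rel=1e-10)


def _fits_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "population", "slope", "se_slope", "n_cells", "mean_spliced"]
    )


class TestCallMurkGenes:
    def test_three_criteria_and_ranking(self):
        fits = _fits_frame([
            # g1: clear slope increase, max expression late, positive slope -> MURK
            ("g1", "E2", 0.1, 0.05, 100, 1.0), ("g1", "E3", 1.1, 0.05, 100, 3.0),
            # g2: bigger increase -> MURK, ranked first
            ("g2", "E2", 0.0, 0.05, 100, 1.0), ("g2", "E3", 2.0, 0.05, 100, 3.0),
            # g3: significant increase but late slope negative -> rejected
            ("g3", "E2", -3.0, 0.05, 100, 1.0), ("g3", "E3", -0.5, 0.05, 100, 3.0),
            # g4: increase but expression tie between populations -> rejected
            ("g4", "E2", 0.1, 0.05, 100, 2.0), ("g4", "E3", 1.1, 0.05, 100, 2.0),
        ])
        out = call_murk_genes(fits, "E2", "E3").set_index("gene_id")
        assert bool(out.loc["g1", "is_murk"]) and bool(out.loc["g2", "is_murk"])
        assert not out.loc["g3", "is_murk"]
        assert not out.loc["g4", "is_murk"] and not out.loc["g4", "passes_max_expression"]
        assert out.loc["g2", "rank"] == 1 and out.loc["g1", "rank"] == 2

    def test_undefined_fit_excluded(self):
        fits = _fits_frame([
            ("g1", "E2", np.nan, np.nan, 100, 1.0), ("g1", "E3", 1.0, 0.1, 100, 3.0),
            ("g2", "E2", 0.0, 0.1, 100, 1.0), ("g2", "E3", 1.0, 0.1, 100, 3.0),
        ])
        out = call_murk_genes(fits, "E2", "E3")
        assert list(out.gene_id) == ["g2"]

    def test_missing_population_raises(self):
        fits = _fits_frame([("g1", "E2", 0.0, 0.1, 100, 1.0)])
        with pytest.raises(InvalidParameterError):
            call_murk_genes(fits, "E2", "E3")

    def test_global_scaling_invariance(self, boosted_imputed):
        imputed, _, cells, _ = boosted_imputed
        d1 = detect_murk(imputed, cells, "Ery2", "Ery3")
        scaled = imputed.with_stage(imputed.U * 3.7, imputed.S * 3.7, "imputed")
        d2 = detect_murk(scaled, cells, "Ery2", "Ery3")
        np.testing.assert_allclose(d1.p_value, d2.p_value, rtol=1e-9)
        assert (d1.is_murk == d2.is_murk).all()


def test_detector_recovers_planted_genes(boosted_imputed):
    imputed, _, cells, genes = boosted_imputed
    dec = detect_murk(imputed, cells, "Ery2", "Ery3")
    truth = {g.gene_id: g.is_murk for g in genes}
    m = dec.gene_id.map(truth)
    sens = (dec.is_murk & m).sum() / m.sum()
    prec = (dec.is_murk & m).sum() / max(int(dec.is_murk.sum()), 1)
    assert sens >= 0.9 and prec >= 0.85
    # ranks are a permutation of 1..n_murk
    ranks = dec.loc[dec.is_murk, "rank"].to_numpy()
    assert sorted(ranks) == list(range(1, len(ranks) + 1))
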