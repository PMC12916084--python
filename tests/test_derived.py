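import numpy as np
import pytest

import lakegrowth as lg
from lakegrowth.mcmc import PosteriorDraws


def _growth_draws(n=500, seed=0, temp_effects=True, species="species_A"):
    """Hand-built hyperparameter draws for one species."""
    rng = np.random.default_rng(seed)
    names = []
    cols = []
    vals = {
        f"gamma0[alpha,{species}]": 2.0,
        f"gamma0[beta1,{species}]": 3.0,
        f"gamma0[amat,{species}]": 4.0,
        f"gamma0[beta2,{species}]": 1.0,
    }
    for k, v in vals.items():
        names.append(k)
        cols.append(np.full(n, v) + rng.normal(0, 0.05, n))
    for p in ("beta1", "amat", "beta2"):
        names.append(f"effect[{p},{species}]")
        if temp_effects:
            cols.append(rng.normal(0.4 if p == "beta1" else -0.3, 0.05, n))
        else:
            cols.append(np.zeros(n))
    arr = np.column_stack(cols)[None, :, :]
    return PosteriorDraws(names, arr, {"species": [species]})


def _longevity_draws(n=500, seed=1, slope=-0.5, species=("species_A",)):
    rng = np.random.default_rng(seed)
    names = ["intercept", "slope_T"]
    cols = [10.0 + rng.normal(0, 0.2, n), slope + rng.normal(0, 0.05, n)]
    for sp in species[1:]:
        names += [f"species[{sp}]", f"interaction[{sp}]"]
        cols += [rng.normal(2.0, 0.1, n), rng.normal(0.0, 0.05, n)]
    names += ["sigma_lake", "sigma_resid"]
    cols += [np.abs(rng.normal(1, 0.1, n)), np.abs(rng.normal(1, 0.1, n))]
    arr = np.column_stack(cols)[None, :, :]
    return PosteriorDraws(names, arr, {"species": list(species)})


class TestSizeAtMaturity:
    def test_degenerate_draws_arithmetic(self):
        g = _growth_draws(n=200, temp_effects=False)
        # strip jitter: force exact values
        g.array[..., :4] = [2.0, 3.0, 4.0, 1.0]
        lmat = lg.size_at_maturity_draws(g, "species_A", t_scaled=0.7)
        assert np.allclose(lmat, 2.0 + 3.0 * 4.0)

    def test_no_temperature_effect_means_no_regime_difference(self):
        g = _growth_draws(temp_effects=False)
        a = lg.size_at_maturity_draws(g, "species_A", -1.0)
        b = lg.size_at_maturity_draws(g, "species_A", 1.0)
        assert np.allclose(a, b)

    def test_uncertainty_propagation_inequality(self):
        # holding the change point at its posterior mean cannot inflate the
        # spread of the derived size
        g = _growth_draws(n=5000, seed=3)
        alpha = g.flat("gamma0[alpha,species_A]")
        beta1 = g.flat("gamma0[beta1,species_A]") + g.flat("effect[beta1,species_A]")
        amat = g.flat("gamma0[amat,species_A]") + g.flat("effect[amat,species_A]")
        full = lg.size_at_maturity_draws(g, "species_A", 1.0)
        fixed = alpha + beta1 * np.mean(amat)
        assert full.std() >= fixed.std() - 1e-6

    def test_extrapolation_warns(self):
        g = _growth_draws()
        with pytest.warns(UserWarning, match="extrapolation"):
            lg.size_at_maturity_draws(g, "species_A", 10.0)


class TestAmaxDraws:
    def test_zero_interaction_common_slope(self):
        ld = _longevity_draws(species=("species_A", "species_B"))
        ld.array[..., ld.names.index("interaction[species_B]")] = 0.0
        a = lg.amax_draws(ld, "species_A", 1.0) - lg.amax_draws(ld, "species_A", 0.0)
        b = lg.amax_draws(ld, "species_B", 1.0) - lg.amax_draws(ld, "species_B", 0.0)
        assert np.allclose(a, b)

    def test_negative_slope_median_decreasing_in_temperature(self):
        ld = _longevity_draws(slope=-0.5)
        med = [
            np.median(lg.amax_draws(ld, "species_A", t)) for t in (-1.0, 0.0, 1.0)
        ]
        assert med[0] > med[1] > med[2]


class TestGrowthCurves:
    def test_lmax_point_arithmetic(self):
        g = _growth_draws(n=400, temp_effects=False)
        g.array[..., :4] = [2.0, 3.0, 4.0, 1.0]
        ld = _longevity_draws(n=400, slope=0.0)
        ld.array[..., ld.names.index("intercept")] = 10.0
        ld.array[..., ld.names.index("slope_T")] = 0.0
        curve = lg.growth_curve_draws(g, ld, "species_A", 0.0, seed=0)
        # Lmat = 2 + 3*4 = 14; Lmax = 14 + 1 * (10 - 4) = 20
        assert curve.lmat["q50"] == pytest.approx(14.0, abs=1e-9)
        assert curve.lmax["q50"] == pytest.approx(20.0, abs=1e-9)
        assert curve.amax["q50"] == pytest.approx(10.0, abs=1e-9)

    def test_median_curve_nondecreasing_for_positive_slopes(self):
        g = _growth_draws(n=800, seed=5)
        ld = _longevity_draws(n=800, seed=6)
        curve = lg.growth_curve_draws(g, ld, "species_A", 0.0, seed=1).curve
        assert (np.diff(curve["q50"]) >= -1e-9).all()

    def test_band_orders_at_every_age(self):
        g = _growth_draws(n=800, seed=7)
        ld = _longevity_draws(n=800, seed=8)
        c = lg.growth_curve_draws(g, ld, "species_A", 0.5, seed=2).curve
        assert (c["q2.5"] <= c["q50"]).all() and (c["q50"] <= c["q97.5"]).all()

    def test_null_effects_make_regimes_coincide(self):
        g = _growth_draws(n=2000, temp_effects=False, seed=9)
        ld = _longevity_draws(n=2000, slope=0.0, seed=10)
        ld.array[..., ld.names.index("slope_T")] = 0.0
        cold = lg.growth_curve_draws(g, ld, "species_A", -1.5, seed=3)
        warm = lg.growth_curve_draws(g, ld, "species_A", 1.5, seed=3)
        m = min(len(cold.curve), len(warm.curve))
        assert np.allclose(
            cold.curve["q50"][:m], warm.curve["q50"][:m], atol=0.05
        )

    def test_lmat_identity_per_draw(self):
        # Lmat draws are exactly the biphasic mean evaluated at Amat
        g = _growth_draws(n=300, seed=11)
        th = lg.derived.species_params_draws(g, "species_A", 0.3)
        lmat = lg.size_at_maturity_draws(g, "species_A", 0.3)
        direct = lg.biphasic_mean(
            th["alpha"], th["beta1"], th["beta2"], th["amat"], th["amat"]
        )
        assert np.allclose(lmat, direct, atol=1e-12)

    def test_amax_floored_at_amat(self):
        g = _growth_draws(n=300, temp_effects=False, seed=12)
        ld = _longevity_draws(n=300, slope=0.0, seed=13)
        # force maximum age below the change point
        ld.array[..., ld.names.index("intercept")] = 1.0
        ld.array[..., ld.names.index("slope_T")] = 0.0
        curve = lg.growth_curve_draws(g, ld, "species_A", 0.0, seed=4)
        assert curve.frac_amax_floored == 1.0
        assert curve.amax["q50"] >= curve.curve["age"].iloc[0]
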