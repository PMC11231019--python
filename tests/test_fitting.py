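"""Nonlinear fitting: parameter recovery, the Kis >= Km constraint,
goodness-of-fit statistics and model selection."""

import numpy as np
import pytest

from badhkin import (
    ArrheniusParams,
    AssayDataset,
    AxisKind,
    PhProfileModel,
    PhProfileParams,
    RateLawModel,
    RateLawParams,
    eval_rate_law,
    fit_arrhenius,
    fit_ph_profile,
    fit_rate_law,
    gen_ph_dataset,
    gen_rate_dataset,
    gen_temperature_dataset,
    goodness_of_fit,
    select_ph_model,
)
from badhkin.constants import GAS_CONSTANT, celsius_to_kelvin
from badhkin.fitting import FitResult, rank_candidates
from badhkin.models import default_decay_segments
from badhkin.synthetic import NoiseSpec

S_GRID = np.linspace(0.25, 8.0, 12)


class TestGoodnessOfFit:
    def test_perfect_predictions(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        r2, adj_r2, red_chi2 = goodness_of_fit(y, y, None, 2)
        assert r2 == 1.0 and adj_r2 == 1.0 and red_chi2 == 0.0

    def test_hand_computed_four_point_example(self):
        # spreadsheet-style arithmetic: y = (2,4,6,8), yhat = (2.5,3.5,6.5,7.5)
        # SS_res = 4*0.25 = 1; mean y = 5; SS_tot = 9+1+1+9 = 20
        # r2 = 1 - 1/20 = 0.95; p = 1: adj = 1 - 0.05*3/2 = 0.925
        # red_chi2 = 1/(4-1) = 1/3
        y = [2.0, 4.0, 6.0, 8.0]
        yhat = [2.5, 3.5, 6.5, 7.5]
        r2, adj_r2, red_chi2 = goodness_of_fit(y, yhat, None, 1)
        assert r2 == pytest.approx(0.95, rel=1e-12)
        assert adj_r2 == pytest.approx(0.925, rel=1e-12)
        assert red_chi2 == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_sd_weights_enter_chi2(self):
        y = [2.0, 4.0, 6.0, 8.0]
        yhat = [2.5, 3.5, 6.5, 7.5]
        _, _, red_chi2 = goodness_of_fit(y, yhat, [0.5] * 4, 1)
        assert red_chi2 == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_extra_parameter_never_raises_adj_r2(self):
        rng = np.random.default_rng(42)
        y = rng.normal(5.0, 1.0, 10)
        yhat = y + rng.normal(0.0, 0.3, 10)
        for p in range(1, 7):
            _, adj_lo, _ = goodness_of_fit(y, yhat, None, p)
            _, adj_hi, _ = goodness_of_fit(y, yhat, None, p + 1)
            assert adj_hi <= adj_lo

    def test_degenerate_sstot_reported(self):
        with pytest.raises(ValueError, match="zero total sum of squares"):
            goodness_of_fit([3.0, 3.0, 3.0], [3.0, 3.1, 2.9], None, 1)


class TestRateLawFits:
    def test_noise_free_mm_si_recovery(self, balc_nad_params):
        ds = gen_rate_dataset(balc_nad_params, S_GRID)
        fr = fit_rate_law(ds, RateLawModel.MM_SI)
        assert fr.converged
        assert not fr.constraint_active
        assert fr.params.vmax == pytest.approx(410.0, rel=1e-3)
        assert fr.params.km == pytest.approx(3.6, rel=1e-3)
        assert fr.params.kis == pytest.approx(4.37, rel=1e-3)

    def test_noise_free_hill_si_recovery(self, nadp_hill_params):
        ds = gen_rate_dataset(nadp_hill_params, S_GRID)
        fr = fit_rate_law(ds, RateLawModel.HILL_SI)
        assert fr.params.hill_n == pytest.approx(2.44, rel=1e-3)
        assert fr.params.km == pytest.approx(2.39, rel=1e-3)

    def test_constraint_binds_when_generator_violates_it(self):
        gen = RateLawParams(RateLawModel.MM_SI, vmax=200.0, km=3.0, kis=1.5)
        ds = gen_rate_dataset(gen, S_GRID)
        fr = fit_rate_law(ds, RateLawModel.MM_SI, constrain_kis_ge_km=True)
        assert fr.constraint_active
        assert fr.params.km == fr.params.kis  # exact boundary solution
        # 2-D grid oracle over (km, kis) in the feasible half-plane: the best
        # feasible SSE must sit on the km = kis diagonal near the fitted km
        km_grid = np.linspace(1.0, 4.0, 61)
        best = (np.inf, None, None)
        y = np.asarray(ds.rate)
        for km in km_grid:
            for kis in km_grid[km_grid >= km]:
                # profile out vmax analytically (linear parameter)
                base = np.asarray(ds.x) / (km + np.asarray(ds.x)
                                           * (1 + np.asarray(ds.x) / kis))
                vmax = float(y @ base / (base @ base))
                sse = float(np.sum((y - vmax * base) ** 2))
                if sse < best[0]:
                    best = (sse, km, kis)
        assert best[1] == best[2]  # boundary optimum
        assert fr.params.km == pytest.approx(best[1], abs=0.05)

    def test_unconstrained_fit_recovers_kis_below_km(self):
        gen = RateLawParams(RateLawModel.MM_SI, vmax=200.0, km=3.0, kis=1.5)
        ds = gen_rate_dataset(gen, S_GRID)
        fr = fit_rate_law(ds, RateLawModel.MM_SI, constrain_kis_ge_km=False)
        assert fr.params.km == pytest.approx(3.0, rel=1e-3)
        assert fr.params.kis == pytest.approx(1.5, rel=1e-3)

    def test_constraint_inactive_iff_optimum_feasible(self, balc_nad_params):
        ds = gen_rate_dataset(balc_nad_params, S_GRID)
        fr = fit_rate_law(ds, RateLawModel.MM_SI, constrain_kis_ge_km=True)
        assert not fr.constraint_active
        assert fr.params.kis >= fr.params.km

    def test_nested_model_identity_on_mm_data(self):
        mm = RateLawParams(RateLawModel.MM, vmax=100.0, km=2.0)
        ds = gen_rate_dataset(mm, S_GRID)
        exact = fit_rate_law(ds, RateLawModel.MM)
        assert exact.params.vmax == pytest.approx(100.0, rel=1e-6)
        assert exact.params.km == pytest.approx(2.0, rel=1e-6)
        inflated = fit_rate_law(ds, RateLawModel.MM_SI)
        assert inflated.params.kis > 1e3 * inflated.params.km

    def test_insufficient_points_rejected(self):
        ds = AssayDataset(AxisKind.SUBSTRATE_MM, (1.0, 2.0, 3.0),
                          (10.0, 15.0, 17.0))
        with pytest.raises(ValueError, match="at least"):
            fit_rate_law(ds, RateLawModel.MM_SI)

    def test_wrong_axis_rejected(self, bell_params):
        ds = gen_ph_dataset(bell_params)
        with pytest.raises(ValueError, match="substrate-axis"):
            fit_rate_law(ds, RateLawModel.MM)

    @pytest.mark.parametrize("model_id", [RateLawModel.MM, RateLawModel.MM_SI,
                                          RateLawModel.HILL_SI])
    def test_zero_noise_recovery_over_random_draws(self, model_id):
        """Exact recovery (<=1e-3 relative) across 25 seeded random
        parameter draws within physiological ranges."""
        rng = np.random.default_rng(20240901)
        for _ in range(25):
            kwargs = {}
            km = float(rng.uniform(0.5, 5.0))
            if model_id in (RateLawModel.MM_SI, RateLawModel.HILL_SI):
                kwargs["kis"] = float(km * rng.uniform(1.2, 5.0))
            if model_id is RateLawModel.HILL_SI:
                kwargs["hill_n"] = float(rng.uniform(1.0, 3.0))
            gen = RateLawParams(model_id, vmax=float(rng.uniform(20, 400)),
                                km=km, **kwargs)
            ds = gen_rate_dataset(gen, S_GRID)
            fr = fit_rate_law(ds, model_id)
            assert fr.params.vmax == pytest.approx(gen.vmax, rel=1e-3)
            assert fr.params.km == pytest.approx(gen.km, rel=1e-3)
            if "kis" in kwargs:
                assert fr.params.kis == pytest.approx(gen.kis, rel=1e-3)
            if "hill_n" in kwargs:
                assert fr.params.hill_n == pytest.approx(gen.hill_n, rel=1e-3)

    def test_invariant_to_point_order(self, balc_nad_params):
        ds = gen_rate_dataset(balc_nad_params, S_GRID)
        perm = np.random.default_rng(3).permutation(len(ds))
        shuffled = AssayDataset(AxisKind.SUBSTRATE_MM,
                                tuple(np.asarray(ds.x)[perm]),
                                tuple(np.asarray(ds.rate)[perm]))
        a = fit_rate_law(ds, RateLawModel.MM_SI)
        b = fit_rate_law(shuffled, RateLawModel.MM_SI)
        assert b.params.km == pytest.approx(a.params.km, rel=1e-6)
        assert b.params.kis == pytest.approx(a.params.kis, rel=1e-6)

    def test_invariant_to_rate_rescaling(self, balc_nad_params):
        ds = gen_rate_dataset(balc_nad_params, S_GRID)
        scaled = AssayDataset(AxisKind.SUBSTRATE_MM, ds.x,
                              tuple(10.0 * r for r in ds.rate))
        a = fit_rate_law(ds, RateLawModel.MM_SI)
        b = fit_rate_law(scaled, RateLawModel.MM_SI)
        assert b.params.vmax == pytest.approx(10.0 * a.params.vmax, rel=1e-6)
        assert b.params.km == pytest.approx(a.params.km, rel=1e-6)
        assert b.params.kis == pytest.approx(a.params.kis, rel=1e-6)

    def test_multistart_reproducible_bit_for_bit(self, balc_nad_params):
        ds = gen_rate_dataset(balc_nad_params, S_GRID)
        a = fit_rate_law(ds, RateLawModel.MM_SI, seed=7)
        b = fit_rate_law(ds, RateLawModel.MM_SI, seed=7)
        assert a.params == b.params
        assert a.residuals == b.residuals


class TestPhProfileFits:
    def test_noise_free_bell_recovery(self, bell_params):
        ds = gen_ph_dataset(bell_params, ph_grid=np.linspace(4.5, 8.5, 9))
        fr = fit_ph_profile(ds, PhProfileModel.BELL)
        assert fr.params.vlim == pytest.approx(100.0, rel=1e-3)
        assert fr.params.pka == pytest.approx(5.5, abs=1e-3)
        assert fr.params.pkb == pytest.approx(7.0, abs=1e-3)
        assert not fr.boundary_pk

    def test_noise_free_plateau_recovery(self):
        gen = PhProfileParams(PhProfileModel.PLATEAU, vlim=100.0, pka=6.0,
                              pkb=7.5, vplateau=10.0)
        fr = fit_ph_profile(gen_ph_dataset(gen), PhProfileModel.PLATEAU)
        assert fr.params.vlim == pytest.approx(100.0, rel=1e-3)
        assert fr.params.vplateau == pytest.approx(10.0, rel=1e-2)

    def test_noise_free_bell_plateau_recovery(self):
        gen = PhProfileParams(PhProfileModel.BELL_PLATEAU, vlim=100.0,
                              pka=4.5, pkb=6.0, pkc=8.5, alpha=0.4)
        ds = gen_ph_dataset(gen, ph_grid=np.linspace(3.5, 9.5, 13))
        fr = fit_ph_profile(ds, PhProfileModel.BELL_PLATEAU)
        assert fr.params.alpha == pytest.approx(0.4, rel=1e-2)
        assert fr.params.pkc == pytest.approx(8.5, abs=1e-2)

    def test_monotone_data_flags_boundary_pk(self):
        ds = AssayDataset(AxisKind.PH, tuple(np.linspace(5.0, 9.0, 9)),
                          tuple(np.linspace(1.0, 100.0, 9)))
        fr = fit_ph_profile(ds, PhProfileModel.BELL)
        assert fr.boundary_pk
        assert fr.params.pkb > 9.0  # falling limb pushed beyond the data

    def test_noisy_replicate_pk_recovery(self, bell_params):
        """Median |pK error| over 100 seeded 5%-CV replicates stays within
        0.15 pH units — the package's own recovery tolerance."""
        errors = []
        grid = np.linspace(4.5, 8.5, 9)
        for seed in range(100):
            noisy = gen_ph_dataset(bell_params,
                                   noise=NoiseSpec(cv_or_sd=0.05, seed=seed),
                                   ph_grid=grid)
            fr = fit_ph_profile(noisy, PhProfileModel.BELL)
            errors.append(abs(fr.params.pka - 5.5))
            errors.append(abs(fr.params.pkb - 7.0))
        assert float(np.median(errors)) < 0.15

    def test_end_to_end_seeded_recovery(self, bell_params):
        noisy = gen_ph_dataset(bell_params,
                               noise=NoiseSpec(cv_or_sd=0.05, seed=7))
        fr = fit_ph_profile(noisy, PhProfileModel.BELL)
        assert fr.params.pka == pytest.approx(5.5, abs=0.2)
        assert fr.params.pkb == pytest.approx(7.0, abs=0.2)


class TestModelSelection:
    def test_bell_generated_data_selects_bell(self, bell_params):
        ds = gen_ph_dataset(bell_params, ph_grid=np.linspace(4.5, 8.5, 9))
        sel = select_ph_model(ds, [PhProfileModel.BELL, PhProfileModel.PLATEAU])
        assert sel.chosen == "BELL"
        assert sel.chosen in dict(sel.candidates)

    def test_plateau_generated_data_selects_plateau(self):
        gen = PhProfileParams(PhProfileModel.PLATEAU, vlim=100.0, pka=6.0,
                              pkb=7.5, vplateau=10.0)
        sel = select_ph_model(gen_ph_dataset(gen),
                              [PhProfileModel.BELL, PhProfileModel.PLATEAU])
        assert sel.chosen == "PLATEAU"

    def test_tie_breaks_prefer_fewer_parameters(self):
        def fake(n_params, adj_r2=0.9, red_chi2=1.0):
            p = PhProfileParams(PhProfileModel.BELL, vlim=1.0, pka=5.0, pkb=7.0)
            return FitResult(params=p, se={}, r2=0.95, adj_r2=adj_r2,
                             red_chi2=red_chi2, n_points=9, n_params=n_params,
                             converged=True, constraint_active=False,
                             residuals=())
        order = rank_candidates([("BIG", fake(5)), ("SMALL", fake(3))])
        assert order[0] == "SMALL"
        # lower red_chi2 wins before parameter count
        order = rank_candidates([("A", fake(3, red_chi2=2.0)),
                                 ("B", fake(5, red_chi2=1.0))])
        assert order[0] == "B"

    def test_single_candidate_rejected(self, bell_params):
        ds = gen_ph_dataset(bell_params)
        with pytest.raises(ValueError, match="two candidate"):
            select_ph_model(ds, [PhProfileModel.BELL])


class TestArrheniusFits:
    T_GRID = [10.0, 15.0, 20.0, 25.0, 30.0]

    def test_noise_free_recovery(self, arrhenius_params, decay_segments):
        ds = gen_temperature_dataset(arrhenius_params, decay_segments,
                                     self.T_GRID)
        fr = fit_arrhenius(ds)
        assert fr.params.ea == pytest.approx(25.8, rel=1e-3)

    def test_full_curve_uses_only_ascending_limb(self, arrhenius_params,
                                                 decay_segments):
        ds = gen_temperature_dataset(arrhenius_params, decay_segments,
                                     list(range(10, 76, 5)))
        fr = fit_arrhenius(ds)
        assert fr.params.ea == pytest.approx(25.8, rel=1e-3)
        assert fr.n_points == 5  # points at 10..30 degC

    def test_matches_log_linear_oracle_at_zero_noise(self, arrhenius_params,
                                                     decay_segments):
        ds = gen_temperature_dataset(arrhenius_params, decay_segments,
                                     self.T_GRID)
        t_k = celsius_to_kelvin(np.asarray(ds.x))
        slope, _ = np.polyfit(1.0 / t_k, np.log(np.asarray(ds.rate)), 1)
        ea_oracle = -slope * GAS_CONSTANT / 1000.0
        fr = fit_arrhenius(ds)
        assert fr.params.ea == pytest.approx(ea_oracle, rel=1e-6)

    def test_flat_profile_recovers_zero_ea(self):
        arr = ArrheniusParams(prefactor=5.0, ea=0.0)
        seg = default_decay_segments(arr)
        ds = gen_temperature_dataset(arr, seg, self.T_GRID)
        fr = fit_arrhenius(ds)
        assert abs(fr.params.ea) < 1e-6

    def test_too_few_ascending_points_rejected(self):
        ds = AssayDataset(AxisKind.TEMPERATURE_C, (10.0, 20.0, 30.0, 40.0),
                          (5.0, 10.0, 20.0, 1.0))
        with pytest.raises(ValueError, match="ascending"):
            fit_arrhenius(ds, ascending_limit_c=15.0)
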