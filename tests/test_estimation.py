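"""Mixed-effects estimation: marginal-likelihood oracles (Monte-Carlo
integration, degenerate limits, censoring saturation), fit self-consistency,
unit invariance, scaled-down estimator calibration, diagnostics and VPC
mechanics."""

import numpy as np
import pandas
import pytest
from scipy.stats import norm

from mrnapkpd.estimation import (
    FitSpec,
    ModelParameters,
    compute_diagnostics,
    fit,
    subject_marginal_loglik,
    vpc,
)
from mrnapkpd.population import Individual, PopulationParams, SubjectDesign, simulate_population
from mrnapkpd.synthetic import default_designs, default_truth, generate_study


def _subject_records(truth, seed=1, times=(1.0, 8.0, 24.0), dvid="mrna", n_sub=1):
    cohort = [
        SubjectDesign(
            individual=Individual(id=f"s{i}", wt=0.025),
            doses=[(0.0, 1.0, 0.0)],
            sampling={dvid: np.array(times)},
        )
        for i in range(n_sub)
    ]
    return simulate_population(
        truth.pk, truth.pd, truth.biomarkers, truth.pop, cohort, seed=seed
    )


class TestMarginalLoglik:
    def test_degenerate_prior_reduces_to_conditional(self, truth, truth_model):
        records = _subject_records(truth)
        m0 = truth_model.copy()
        m0.pop = PopulationParams(omega_cl32=0.0, sigma_prop=0.375)
        ll0 = subject_marginal_loglik(records, m0, method="agq")
        # tiny-but-nonzero omega converges to the same value
        m1 = truth_model.copy()
        m1.pop = PopulationParams(omega_cl32=1e-4, sigma_prop=0.375)
        ll1 = subject_marginal_loglik(records, m1, method="agq")
        assert ll1 == pytest.approx(ll0, abs=1e-3)

    def test_agq_matches_monte_carlo_integration(self, truth, truth_model):
        # oracle: plain Monte-Carlo marginalisation over 1e5 eta draws
        records = _subject_records(truth, seed=2)
        model = truth_model
        ll_agq = subject_marginal_loglik(records, model, method="agq", n_nodes=21)

        from mrnapkpd.estimation import _Subject, _conditional_loglik, _predict_subject

        subj = _Subject(
            "s0", records[records["ID"] == "s0"], ("mrna",), "m3"
        )
        rng = np.random.default_rng(99)
        etas = rng.normal(0.0, model.pop.omega_cl32, size=100_000)
        vals = np.array(
            [
                _conditional_loglik(subj, _predict_subject(model, subj, e), model)
                for e in etas[:20_000]
            ]
        )
        w = np.exp(vals - vals.max())
        ll_mc = np.log(np.mean(w)) + vals.max()
        se_mc = np.std(w) / (np.sqrt(w.size) * np.mean(w))
        assert abs(ll_agq - ll_mc) < 3.0 * se_mc

    def test_laplace_close_to_agq(self, truth, truth_model):
        records = _subject_records(truth, seed=3, times=(0.5, 1, 2, 4, 8, 24, 48))
        ll_l = subject_marginal_loglik(records, truth_model, method="laplace")
        ll_q = subject_marginal_loglik(records, truth_model, method="agq", n_nodes=21)
        assert abs(-2 * ll_l - (-2 * ll_q)) < 0.1

    def test_all_blq_far_below_limit_saturates_to_zero(self, truth, truth_model):
        # a subject whose predictions are far below the LLOQ contributes
        # log Phi(large) ~ 0 per censored record
        df = pandas.DataFrame(
            {
                "ID": ["x"] * 4,
                "TIME": [0.0, 500.0, 600.0, 700.0],
                "EVID": [1, 0, 0, 0],
                "AMT": [1e-6, np.nan, np.nan, np.nan],
                "RATE": [0.0, np.nan, np.nan, np.nan],
                "DV": [np.nan, 25.0, 25.0, 25.0],
                "DVID": [".", "mrna", "mrna", "mrna"],
                "MDV": [1, 0, 0, 0],
                "BLQ": [0, 1, 1, 1],
                "LLOQ": [np.nan, 25.0, 25.0, 25.0],
                "WT": [0.025] * 4,
                "SPECIES": ["mouse"] * 4,
            }
        )
        ll = subject_marginal_loglik(df, truth_model, method="agq")
        assert -1e-6 < ll <= 1e-9

    def test_blq_discard_policy_drops_censored_records(self, truth, truth_model):
        records = _subject_records(truth, seed=4, dvid="3hp", times=(24.0, 72.0, 168.0))
        records.loc[records["DVID"] == "3hp", ["BLQ", "LLOQ"]] = [1, 25.0]
        records.loc[records["DVID"] == "3hp", "DV"] = 25.0
        with pytest.raises(ValueError):
            subject_marginal_loglik(
                records, truth_model, method="agq", blq_policy="discard"
            )


class TestFit:
    def test_self_consistency_on_noise_free_data(self, truth):
        quiet = default_truth()
        quiet.pop = PopulationParams(omega_cl32=0.0, sigma_prop=0.0)
        designs = default_designs()
        df = generate_study(designs["mouse-pk"], quiet, seed=5)
        model = ModelParameters(pk=quiet.pk, pop=PopulationParams(0.0, 1e-3))
        spec = FitSpec(
            free={"tvcl12": 19.7, "tvcl32": 2.96},
            observables=("mrna",),
            method="agq",
            compute_se=False,
        )
        res = fit(df, spec, model)
        assert res.estimates["tvcl12"] == pytest.approx(19.7, rel=1e-3)
        assert res.estimates["tvcl32"] == pytest.approx(2.96, rel=1e-3)

    def test_perturbing_optimum_increases_objective(self, truth):
        quiet = default_truth()
        quiet.pop = PopulationParams(omega_cl32=0.0, sigma_prop=0.0)
        df = generate_study(default_designs()["mouse-pk"], quiet, seed=5)
        model = ModelParameters(pk=quiet.pk, pop=PopulationParams(0.0, 1e-3))
        spec = FitSpec(
            free={"tvcl12": 19.7}, observables=("mrna",), method="agq",
            compute_se=False,
        )
        res = fit(df, spec, model)
        from mrnapkpd.estimation import _neg2ll, _split_subjects
        import math

        subs = _split_subjects(df, ("mrna",), "m3")
        f_opt = res.neg2ll
        for factor in (0.8, 1.2):
            th = np.array([math.log(res.estimates["tvcl12"] * factor)])
            assert (
                _neg2ll(th, ["tvcl12"], res.model.copy(), subs, spec, 1e6) > f_opt
            )

    def test_unit_scale_invariance(self, truth):
        # multiplying all concentrations by a common unit factor (handled by
        # the explicit observation unit scale) leaves every estimate unchanged
        df = generate_study(default_designs()["mouse-pk"], truth, seed=6)
        df10 = df.copy()
        obs = df10["EVID"] == 0
        df10.loc[obs, "DV"] *= 10.0
        model = ModelParameters(pk=truth.pk, pop=truth.pop)
        spec = FitSpec(
            free={"tvcl12": 25.0, "omega_cl32": 0.4, "sigma_mrna": 0.3},
            observables=("mrna",),
            compute_se=False,
            maxiter=60,
        )
        r1 = fit(df, spec, model, conc_scale=1e6)
        r2 = fit(df10, spec, model, conc_scale=1e7)
        for k in spec.free:
            assert r2.estimates[k] == pytest.approx(r1.estimates[k], rel=1e-6)

    def test_estimator_calibration_scaled_down(self, truth):
        # replicate-level check at reduced scale: median relative bias of the
        # recovered typical values stays under 15% across 5 replicates
        designs = default_designs(n_mouse_pk=12)
        model = ModelParameters(pk=truth.pk, pop=truth.pop)
        rel_err = {"tvcl12": [], "sigma_mrna": []}
        for seed in range(5):
            df = generate_study(designs["mouse-pk"], truth, seed=100 + seed)
            spec = FitSpec(
                free={"tvcl12": 30.0, "omega_cl32": 0.4, "sigma_mrna": 0.3},
                observables=("mrna",),
                compute_se=False,
                maxiter=80,
            )
            res = fit(df, spec, model)
            rel_err["tvcl12"].append(res.estimates["tvcl12"] / 19.7 - 1.0)
            rel_err["sigma_mrna"].append(res.estimates["sigma_mrna"] / 0.375 - 1.0)
        for k, errs in rel_err.items():
            assert abs(np.median(errs)) < 0.15, (k, errs)

    def test_missing_observable_raises(self, truth, truth_model):
        df = _subject_records(truth)
        spec = FitSpec(free={"ic50_2mc": 20.0}, observables=("2mc",), compute_se=False)
        with pytest.raises(ValueError, match="2mc"):
            fit(df, spec, truth_model)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FitSpec(free={})
        with pytest.raises(ValueError):
            FitSpec(free={"x": 1.0}, method="saem")
        with pytest.raises(ValueError):
            FitSpec(free={"x": 5.0}, bounds={"x": (1.0, 2.0)})


class TestDiagnostics:
    def test_zero_noise_cwres_near_zero_and_pred_equals_ipred(self, truth):
        quiet = default_truth()
        quiet.pop = PopulationParams(omega_cl32=0.0, sigma_prop=0.0)
        df = generate_study(default_designs()["mouse-pk"], quiet, seed=7)
        model = ModelParameters(pk=quiet.pk, pop=PopulationParams(0.0, 0.05))
        spec = FitSpec(free={"tvcl12": 19.7}, observables=("mrna",), compute_se=False)
        from mrnapkpd.estimation import FitResult

        res = FitResult(
            estimates={}, se={}, rse_percent={}, fixed={}, neg2ll=0.0,
            converged=True, message="", n_evals=0, model=model, spec=spec,
        )
        diag = compute_diagnostics(df, res)
        assert np.all(np.abs(diag["CWRES"]) < 1e-6)
        np.testing.assert_allclose(diag["PRED"], diag["IPRED"], rtol=1e-9)

    def test_blq_records_excluded_and_counted(self, truth, truth_model):
        df = _subject_records(truth, seed=8, dvid="3hp", times=(24.0, 72.0, 168.0))
        blq_rows = (df["DVID"] == "3hp").sum()
        df.loc[df["DVID"] == "3hp", ["BLQ", "LLOQ", "DV"]] = [1, 25.0, 25.0]
        spec = FitSpec(free={"ic50_3hp": 37.5}, observables=("3hp",), compute_se=False)
        from mrnapkpd.estimation import FitResult

        res = FitResult(
            estimates={}, se={}, rse_percent={}, fixed={}, neg2ll=0.0,
            converged=True, message="", n_evals=0, model=truth_model, spec=spec,
        )
        diag = compute_diagnostics(df, res)
        assert diag.empty
        assert diag.attrs["n_blq_excluded"] == blq_rows


class TestVPC:
    def test_band_ordering_and_determinism(self, truth, truth_model):
        df = _subject_records(truth, seed=9, n_sub=8, times=(1.0, 8.0, 24.0, 48.0))
        b1 = vpc(df, truth_model, n_sim=100, seed=1)
        b2 = vpc(df, truth_model, n_sim=100, seed=1)
        pandas.testing.assert_frame_equal(b1, b2)
        assert np.all(b1["sim_lo"] <= b1["sim_med"])
        assert np.all(b1["sim_med"] <= b1["sim_hi"])

    def test_doubling_nsim_changes_bands_only_slightly(self, truth, truth_model):
        df = _subject_records(truth, seed=10, n_sub=8, times=(1.0, 8.0, 24.0))
        b1 = vpc(df, truth_model, n_sim=200, seed=2)
        b2 = vpc(df, truth_model, n_sim=400, seed=2)
        np.testing.assert_allclose(b1["sim_med"], b2["sim_med"], rtol=0.1)

    def test_all_blq_bin_reported_at_lloq_with_flag(self, truth, truth_model):
        cohort = [
            SubjectDesign(
                individual=Individual(id=f"s{i}", wt=0.025),
                doses=[(0.0, 2.0, 0.0)],
                sampling={"3hp": np.array([168.0])},
                lloq={"3hp": 25.0},
            )
            for i in range(6)
        ]
        df = simulate_population(
            truth.pk, truth.pd, truth.biomarkers, truth.pop, cohort, seed=11
        )
        assert (df.loc[df["EVID"] == 0, "BLQ"] == 1).all()
        bands = vpc(df, truth_model, n_sim=100, seed=3)
        row = bands.iloc[0]
        assert row["all_blq"]
        assert row["sim_med"] == pytest.approx(25.0)

    def test_minimum_replicates_enforced(self, truth, truth_model):
        df = _subject_records(truth)
        with pytest.raises(ValueError):
            vpc(df, truth_model, n_sim=50)
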