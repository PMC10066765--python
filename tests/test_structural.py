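"""Structural model: allometry, disposition ODEs, protein turnover,
biomarker statics — each operation checked against an independent oracle
(direct arithmetic, matrix assembly, matrix exponential, eigenvalues,
log-linear regression of simulated decay)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from mrnapkpd.structural import (
    BiomarkerParams,
    DoseEvent,
    PDParams,
    PKParams,
    allometric_scale,
    amenable_fraction,
    biomarker_level,
    pk_derivatives,
    pk_matrix,
    protein_terminal_halflife,
    simulate_pk,
    simulate_pkpd,
)


@pytest.fixture(scope="module")
def pk():
    return PKParams(
        tvcl12=19.7, tvcl23=0.215, tvcl32=2.96, tvcl20=0.136,
        tvv=2.67, tvv2=0.961, cl_alpha=0.631, cl_beta=1.10,
    )


class TestAllometry:
    def test_identity_at_reference_weight(self, pk):
        sc = allometric_scale(pk, pk.wt_ref)
        assert sc.cl12 == pk.tvcl12
        assert sc.cl23 == pk.tvcl23
        assert sc.cl32 == pk.tvcl32
        assert sc.cl20 == pk.tvcl20
        assert sc.v == pk.tvv and sc.v2 == pk.tvv2

    def test_power_law_oracle_70kg(self, pk):
        # independent one-line arithmetic for each scaled parameter
        sc = allometric_scale(pk, 70.0)
        assert sc.cl12 == pytest.approx(19.7 * 70.0**0.631, rel=1e-12)
        assert sc.cl32 == pytest.approx(2.96 * 70.0**0.631, rel=1e-12)
        assert sc.cl23 == pytest.approx(0.215 * 70.0**1.10, rel=1e-12)
        assert sc.cl20 == pytest.approx(0.136 * 70.0**1.10, rel=1e-12)
        assert sc.v == pytest.approx(2.67 * 70.0, rel=1e-12)
        assert sc.v2 == pytest.approx(0.961 * 70.0, rel=1e-12)

    def test_zero_exponents_degenerate_to_typical(self, pk):
        flat = PKParams(
            tvcl12=pk.tvcl12, tvcl23=pk.tvcl23, tvcl32=pk.tvcl32,
            tvcl20=pk.tvcl20, tvv=pk.tvv, tvv2=pk.tvv2,
            cl_alpha=0.0, cl_beta=0.0, v_exponent=0.0,
        )
        for wt in (0.02, 1.0, 70.0):
            sc = allometric_scale(flat, wt)
            assert (sc.cl12, sc.cl23, sc.v) == (pk.tvcl12, pk.tvcl23, pk.tvv)

    def test_derived_rates_are_clearance_over_volume(self, pk):
        sc = allometric_scale(pk, 3.0)
        assert sc.k12 == pytest.approx(sc.cl12 / sc.v)
        assert sc.k23 == pytest.approx(sc.cl23 / sc.v2)
        assert sc.k32 == pytest.approx(sc.cl32 / sc.v)
        assert sc.k20 == pytest.approx(sc.cl20 / sc.v2)

    def test_nonpositive_weight_rejected_naming_subject(self, pk):
        with pytest.raises(ValueError, match="monkey-007"):
            allometric_scale(pk, -1.0, subject="monkey-007")


class TestPKDerivatives:
    def test_zero_state_zero_derivative(self, pk):
        sc = allometric_scale(pk, 1.0)
        assert np.all(pk_derivatives(np.zeros(3), 0.0, sc) == 0.0)

    def test_conservation_without_elimination(self, pk):
        no_elim = PKParams(
            tvcl12=pk.tvcl12, tvcl23=pk.tvcl23, tvcl32=pk.tvcl32,
            tvcl20=1e-30, tvv=pk.tvv, tvv2=pk.tvv2,
        )
        sc = allometric_scale(no_elim, 1.0)
        state = np.array([0.3, 1.2, 0.7])
        d = pk_derivatives(state, 5.0, sc, infusion_rate=0.25)
        assert d.sum() == pytest.approx(0.25, abs=1e-12)

    def test_matches_independently_assembled_matrix(self, pk, rng):
        # oracle: assemble A directly from the rate list, row by row
        sc = allometric_scale(pk, 0.5)
        k12, k23, k32, k20 = sc.k12, sc.k23, sc.k32, sc.k20
        A = np.array(
            [[-k12, 0, 0], [k12, -(k23 + k20), k32], [0, k23, -k32]]
        )
        for _ in range(5):
            state = rng.uniform(0, 2, size=3)
            np.testing.assert_allclose(
                pk_derivatives(state, 0.0, sc), A @ state, rtol=1e-12
            )


class TestSimulatePK:
    def test_matches_matrix_exponential_oracle(self, pk):
        wt = 0.025
        doses = [DoseEvent(0.0, 2.0 * wt)]
        times = np.linspace(0.0, 48.0, 97)
        conc = simulate_pk(pk, wt, doses, times)
        sc = allometric_scale(pk, wt)
        A = pk_matrix(sc)
        x0 = np.array([2.0 * wt, 0.0, 0.0])
        ref = np.array([(expm(A * t) @ x0)[2] for t in times]) / sc.v * 1e6
        mask = ref > 1e-9 * ref.max()
        np.testing.assert_allclose(conc[mask], ref[mask], rtol=1e-6)

    def test_closed_form_route_matches_ode_route(self, pk):
        wt = 3.0
        doses = [DoseEvent(0.0, 3.0, 1.0), DoseEvent(336.0, 3.0, 1.0)]
        times = np.linspace(0.0, 480.0, 100)
        c1 = simulate_pk(pk, wt, doses, times, method="lsoda", rtol=1e-10, atol=1e-12)
        c2 = simulate_pk(pk, wt, doses, times, method="closed_form")
        # compare above the ODE solver's absolute-tolerance floor
        mask = c2 > 1e-4 * c2.max()
        np.testing.assert_allclose(c1[mask], c2[mask], rtol=1e-6)

    def test_delayed_cmax_in_observed_compartment(self, pk):
        times = np.linspace(0.0, 48.0, 200)
        conc = simulate_pk(pk, 0.025, [DoseEvent(0.0, 0.05)], times)
        assert conc[0] == pytest.approx(0.0, abs=1e-9)
        assert times[np.argmax(conc)] > 0.0

    def test_dose_linearity(self, pk):
        times = np.array([0.5, 2.0, 8.0, 24.0])
        c1 = simulate_pk(pk, 0.025, [DoseEvent(0.0, 0.025)], times)
        c2 = simulate_pk(pk, 0.025, [DoseEvent(0.0, 0.050)], times)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-7)

    def test_unsorted_times_rejected(self, pk):
        with pytest.raises(ValueError, match="sorted"):
            simulate_pk(pk, 1.0, [DoseEvent(0.0, 1.0)], np.array([2.0, 1.0]))


@pytest.fixture(scope="module")
def pd_params():
    return PDParams(ke0=0.5, ksyn_slope=0.14, kdeg=0.0359, kq=0.00474)


class TestSimulatePKPD:
    def test_no_synthesis_no_protein(self, pk, pd_params):
        silent = PDParams(ke0=0.5, ksyn_slope=0.0, kdeg=0.0359, kq=0.00474)
        times = np.linspace(0.0, 500.0, 50)
        out = simulate_pkpd(pk, silent, 0.025, [DoseEvent(0.0, 0.05)], times)
        assert np.all(out["p_total"] == 0.0)

    def test_protein_scales_linearly_with_synthesis_gain(self, pk, pd_params):
        times = np.linspace(0.0, 1000.0, 60)
        doses = [DoseEvent(0.0, 0.05)]
        p1 = simulate_pkpd(pk, pd_params, 0.025, doses, times)["p_total"]
        double = PDParams(
            ke0=pd_params.ke0, ksyn_slope=2 * pd_params.ksyn_slope,
            kdeg=pd_params.kdeg, kq=pd_params.kq,
        )
        p2 = simulate_pkpd(pk, double, 0.025, doses, times)["p_total"]
        mask = p1 > 1e-9 * p1.max()
        np.testing.assert_allclose(p2[mask], 2.0 * p1[mask], rtol=1e-7)

    def test_terminal_slope_matches_protein_eigenvalue(self, pk, pd_params):
        # oracle: slowest eigenvalue of the 2x2 protein subsystem
        M = np.array(
            [
                [-(pd_params.kdeg + pd_params.kq), pd_params.kq],
                [pd_params.kq, -pd_params.kq],
            ]
        )
        lam_slow = max(np.linalg.eigvals(M).real)
        times = np.linspace(0.0, 6000.0, 400)
        out = simulate_pkpd(pk, pd_params, 0.025, [DoseEvent(0.0, 0.05)], times)
        tail = times > 3500.0  # mRNA long gone; terminal protein phase
        slope = np.polyfit(times[tail], np.log(out["p_total"][tail]), 1)[0]
        assert slope == pytest.approx(lam_slow, rel=1e-3)


class TestProteinHalflife:
    def test_decoupled_pools(self):
        pd = PDParams(ke0=1.0, ksyn_slope=0.1, kdeg=0.01, kq=0.0)
        assert protein_terminal_halflife(pd) == pytest.approx(np.log(2) / 0.01)

    def test_matches_simulated_decay(self, pk, pd_params):
        # oracle: log-linear regression of a long simulated decay tail
        hl = protein_terminal_halflife(pd_params)
        times = np.linspace(0.0, 3000.0, 500)
        out = simulate_pkpd(
            pk, pd_params, 0.025, [DoseEvent(0.0, 0.05)], times, method="closed_form"
        )
        # fast protein mode is ~e^-37 down by 1000 h; tail is purely terminal
        tail = times > 1500.0
        slope = np.polyfit(times[tail], np.log(out["p_total"][tail]), 1)[0]
        assert np.log(2.0) / -slope == pytest.approx(hl, rel=1e-3)

    def test_invalid_kdeg_rejected(self):
        pd = PDParams(ke0=1.0, ksyn_slope=0.1, kdeg=0.01, kq=0.0)
        object.__setattr__(pd, "kdeg", 0.0)
        with pytest.raises(ValueError):
            protein_terminal_halflife(pd)


@pytest.fixture(scope="module")
def bp():
    return BiomarkerParams(name="2mc", e0=7.26, base=12.74, ic50=21.0)


class TestBiomarkerStatics:
    def test_characteristic_points(self, bp):
        assert biomarker_level(0.0, bp) == pytest.approx(bp.e0 + bp.base)
        half = bp.e0 + bp.base * (1.0 - bp.imax / 2.0)
        assert biomarker_level(bp.ic50, bp) == pytest.approx(half, rel=1e-12)
        assert biomarker_level(1e9, bp) == pytest.approx(
            bp.e0 + bp.base * (1.0 - bp.imax), rel=1e-6
        )

    @settings(deadline=None, max_examples=60)
    @given(
        p=st.lists(st.floats(0.0, 1e4), min_size=2, max_size=6),
        e0=st.floats(0.0, 50.0),
        base=st.floats(0.1, 200.0),
        ic50=st.floats(0.1, 500.0),
        imax=st.floats(0.01, 1.0),
        gamma=st.floats(0.2, 4.0),
    )
    def test_monotone_nonincreasing_in_protein(self, p, e0, base, ic50, imax, gamma):
        bp = BiomarkerParams(
            name="x", e0=e0, base=base, ic50=ic50, imax=imax, gamma=gamma
        )
        levels = biomarker_level(np.sort(np.asarray(p)), bp)
        assert np.all(np.diff(levels) <= 1e-12)

    def test_amenable_fraction_cases(self, bp):
        assert amenable_fraction(bp) == pytest.approx(12.74 / 20.0)
        full = BiomarkerParams(name="x", e0=0.0, base=5.0, ic50=1.0)
        assert amenable_fraction(full) == 1.0
        sym = BiomarkerParams(name="x", e0=3.0, base=3.0, ic50=1.0)
        assert amenable_fraction(sym) == 0.5

    def test_negative_protein_rejected(self, bp):
        with pytest.raises(ValueError):
            biomarker_level(-1.0, bp)


class TestValidation:
    def test_dose_event_contracts(self):
        with pytest.raises(ValueError):
            DoseEvent(-1.0, 1.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 0.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 1.0, duration=-0.5)

    def test_pk_params_positivity(self):
        with pytest.raises(ValueError):
            PKParams(tvcl12=-1, tvcl23=1, tvcl32=1, tvcl20=1, tvv=1, tvv2=1)

    def test_biomarker_params_contracts(self):
        with pytest.raises(ValueError):
            BiomarkerParams(name="x", e0=0.0, base=0.0, ic50=1.0)
        with pytest.raises(ValueError):
            BiomarkerParams(name="x", e0=0.0, base=1.0, ic50=1.0, imax=1.2)


class TestMassBalance:
    def test_total_amount_equals_dose_without_elimination(self, pk):
        no_elim = PKParams(
            tvcl12=pk.tvcl12, tvcl23=pk.tvcl23, tvcl32=pk.tvcl32,
            tvcl20=1e-30, tvv=pk.tvv, tvv2=pk.tvv2,
        )
        from mrnapkpd.structural import _simulate_linear, pk_matrix

        sc = allometric_scale(no_elim, 1.0)
        doses = [DoseEvent(0.0, 1.0), DoseEvent(24.0, 0.5, 2.0)]
        times = np.linspace(0.0, 96.0, 49)
        states = _simulate_linear(pk_matrix(sc), np.zeros(3), doses, times, "lsoda")
        total = states.sum(axis=1)
        expected = np.where(
            times < 24.0, 1.0, np.where(times < 26.0, 1.0 + 0.5 * (times - 24) / 2.0, 1.5)
        )
        np.testing.assert_allclose(total, expected, rtol=1e-6, atol=1e-9)
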