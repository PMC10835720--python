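"""ITC: displacement bookkeeping, mass action, forward model, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import copigkit as ck
from copigkit.itc import _species_two_site
from copigkit.reference import itc_reference, itc_schedules


@pytest.fixture
def schedule():
    # the strong-binder assay: 200 uM pigment cell, 250 uM copigment syringe
    return ck.InjectionSchedule(syringe_conc=250e-6, cell_conc=200e-6)


class TestSchedule:
    def test_rejects_nonpositive_fields(self):
        with pytest.raises(ValueError):
            ck.InjectionSchedule(syringe_conc=0.0, cell_conc=1e-4)

    def test_rejects_overfull_cell(self):
        with pytest.raises(ValueError, match="exceeds"):
            ck.InjectionSchedule(
                syringe_conc=1e-3, cell_conc=1e-4,
                injection_volume=20e-6, n_injections=19,
            )

    def test_json_round_trip(self, schedule, tmp_path):
        p = tmp_path / "sched.json"
        schedule.to_json(p)
        assert ck.InjectionSchedule.from_json(p) == schedule


class TestConcentrations:
    def test_before_titration(self, schedule):
        assert ck.concentrations_after(schedule, 0) == (schedule.cell_conc, 0.0)

    def test_vanishing_injection_volume_limit(self):
        s = ck.InjectionSchedule(
            syringe_conc=250e-6, cell_conc=200e-6, injection_volume=1e-15
        )
        Mt, Lt = ck.concentrations_after(s, 19)
        assert Mt == pytest.approx(200e-6, rel=1e-8)
        assert Lt == pytest.approx(0.0, abs=1e-12)

    def test_matches_effective_volume_mole_ledger(self, schedule):
        """Independent algebraic oracle: all injected titrant moles in an
        effective volume V0 + dV_cum/2; an equal overflow share of titrate
        removed at its initial concentration."""
        V0 = schedule.cell_volume
        for i in (1, 7, 19):
            dVc = i * schedule.injection_volume
            Veff = V0 + dVc / 2.0
            lt_oracle = schedule.syringe_conc * dVc / Veff
            mt_oracle = schedule.cell_conc * (V0 - dVc / 2.0) / Veff
            Mt, Lt = ck.concentrations_after(schedule, i)
            assert Mt == pytest.approx(mt_oracle, rel=1e-10)
            assert Lt == pytest.approx(lt_oracle, rel=1e-10)

    def test_monotone_in_expected_directions(self, schedule):
        pairs = [ck.concentrations_after(schedule, i) for i in range(20)]
        Mt = [p[0] for p in pairs]
        Lt = [p[1] for p in pairs]
        assert all(a > b for a, b in zip(Mt, Mt[1:]))
        assert all(a < b for a, b in zip(Lt, Lt[1:]))

    def test_index_out_of_range(self, schedule):
        with pytest.raises(ValueError):
            ck.concentrations_after(schedule, 20)


class TestBoundFraction:
    def test_no_ligand(self):
        assert ck.bound_fraction(1e4, 1e-4, 0.0) == 0.0

    def test_tight_binding_stoichiometric_limit(self):
        ml = ck.bound_fraction(1e12, 2e-4, 1e-4)
        assert ml == pytest.approx(1e-4, rel=1e-5)

    def test_equimolar_closed_form_vs_fixed_point_oracle(self):
        K, Mt, Lt = 1e4, 1e-4, 1e-4
        ml = ck.bound_fraction(K, Mt, Lt)
        assert ml == pytest.approx(3.8197e-5, rel=1e-4)
        # independent fixed-point iteration on mass action
        x = 0.0
        for _ in range(2000):
            x = Lt * K * (Mt - x) / (1.0 + K * (Mt - x))
        assert ml == pytest.approx(x, abs=1e-12)

    @given(
        logK=st.floats(min_value=1, max_value=9),
        mt=st.floats(min_value=1e-6, max_value=1e-2),
        lt=st.floats(min_value=0.0, max_value=1e-2),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_physical_bounds_and_mass_action_residual(self, logK, mt, lt):
        K = 10.0**logK
        ml = ck.bound_fraction(K, mt, lt)
        assert 0.0 <= ml <= min(mt, lt) + 1e-18
        resid = K * (mt - ml) * (lt - ml) - ml
        # closed form loses ~eps*(K(mt+lt)+1)*max(mt,lt) to cancellation
        scale = (K * (mt + lt) + 1.0) * max(mt, lt)
        assert abs(resid) <= 1e-10 * scale + 1e-15


class TestForwardModel:
    def test_athermal_binding_is_all_zero(self, schedule):
        t = ck.simulate_thermogram(schedule, K=1e4, dH=0.0)
        np.testing.assert_array_equal(t.heats, 0.0)

    def test_first_injection_saturation_limit(self, schedule):
        # with K enormous and the cell pigment in excess, all injected
        # ligand binds: q1 ~ dH * (dV * Lsyr)
        t = ck.simulate_thermogram(schedule, K=1e12, dH=-3000.0)
        expected = -3000.0 * schedule.injection_volume * schedule.syringe_conc
        assert t.heats[0] == pytest.approx(expected, rel=1e-3)

    def test_heats_decay_past_equivalence(self):
        # past saturation each aliquot finds less free pigment to bind
        s = ck.InjectionSchedule(syringe_conc=5e-3, cell_conc=2e-4)
        t = ck.simulate_thermogram(s, K=1e4, dH=-3000.0)
        past = t.heats[t.molar_ratio > 1.5]
        assert np.all(np.diff(np.abs(past)) < 0)

    def test_energy_bookkeeping_conservation(self, schedule):
        K, dH = 1e4, -3000.0
        t = ck.simulate_thermogram(schedule, K=K, dH=dH)
        V0, dV = schedule.cell_volume, schedule.injection_volume
        ml = [0.0] + [
            ck.bound_fraction(K, *ck.concentrations_after(schedule, i))
            for i in range(1, schedule.n_injections + 1)
        ]
        total = V0 * dH * ml[-1] + sum(
            dV * dH * (ml[i] + ml[i - 1]) / 2.0
            for i in range(1, schedule.n_injections + 1)
        )
        assert t.heats.sum() == pytest.approx(total, rel=1e-9)

    def test_two_site_species_satisfy_mass_action(self):
        K1, K2, Mt, Lt = 1e5, 1e3, 2e-4, 5e-4
        ml, ml2 = _species_two_site(K1, K2, Mt, Lt)
        M = Mt - ml - ml2
        L = Lt - ml - 2 * ml2
        assert ml == pytest.approx(K1 * M * L, rel=1e-8)
        assert ml2 == pytest.approx(K2 * ml * L, rel=1e-8)

    def test_two_site_reduces_to_one_site_when_second_step_off(self, schedule):
        a = ck.simulate_thermogram(schedule, K=1e4, dH=-3000.0)
        b = ck.simulate_thermogram(schedule, K=1e4, dH=-3000.0, K2=1e-12, dH2=0.0)
        np.testing.assert_allclose(a.heats, b.heats, rtol=1e-6)


class TestBlank:
    def test_zero_blank_is_identity(self, schedule):
        t = ck.simulate_thermogram(schedule, K=1e4, dH=-3000.0)
        blank = ck.Thermogram(np.zeros(len(t)), t.molar_ratio)
        np.testing.assert_array_equal(ck.subtract_blank(t, blank).heats, t.heats)

    def test_sample_equal_to_blank_gives_zero(self, schedule):
        t = ck.simulate_thermogram(schedule, K=1e4, dH=-3000.0)
        np.testing.assert_array_equal(ck.subtract_blank(t, t).heats, 0.0)

    def test_constant_dilution_heat_removed(self, schedule):
        t = ck.simulate_thermogram(schedule, K=1e4, dH=-3000.0)
        dil = 0.5e-6  # 0.5 ucal dilution heat per injection
        spiked = ck.Thermogram(t.heats + dil, t.molar_ratio)
        blank = ck.Thermogram(np.full(len(t), dil), t.molar_ratio)
        np.testing.assert_allclose(
            ck.subtract_blank(spiked, blank).heats, t.heats, atol=1e-18
        )

    def test_length_mismatch_rejected(self, schedule):
        t = ck.simulate_thermogram(schedule, K=1e4, dH=-3000.0)
        short = ck.Thermogram(t.heats[:-1], t.molar_ratio[:-1])
        with pytest.raises(ValueError, match="length"):
            ck.subtract_blank(t, short)


class TestFit:
    def test_noiseless_round_trip(self, schedule):
        t = ck.simulate_thermogram(schedule, K=1e4, dH=-3000.0, n=1.0)
        r = ck.fit_binding(t, schedule)
        assert r.K == pytest.approx(1e4, rel=1e-3)
        assert r.dH == pytest.approx(-3000.0, rel=1e-3)
        assert r.n == pytest.approx(1.0, rel=1e-3)

    @pytest.mark.parametrize("K,M0", [(1e2, 1e-2), (1e4, 1e-4), (1e6, 1e-5), (1e8, 1e-6)])
    def test_round_trip_across_affinity_decades(self, K, M0):
        # schedules scaled to keep c = K*n*M0 in a fittable range
        s = ck.InjectionSchedule(syringe_conc=12.5 * M0, cell_conc=M0)
        t = ck.simulate_thermogram(s, K=K, dH=-3000.0, n=1.0)
        r = ck.fit_binding(t, s)
        assert r.K == pytest.approx(K, rel=1e-3)
        assert r.dH == pytest.approx(-3000.0, rel=1e-3)
        assert r.n == pytest.approx(1.0, rel=1e-3)
        assert not r.flags

    def test_two_site_round_trip(self):
        s = ck.InjectionSchedule(syringe_conc=2.5e-3, cell_conc=2e-4)
        t = ck.simulate_thermogram(s, K=1e5, dH=-3000.0, K2=1e3, dH2=-1500.0)
        r = ck.fit_binding(
            t, s, model="sequential_two_site",
            init={"logK": 5.3, "dH": -2700.0, "logK2": 2.8, "dH2": -1300.0},
        )
        assert r.K == pytest.approx(1e5, rel=1e-3)
        assert r.K2 == pytest.approx(1e3, rel=1e-3)
        assert r.dH == pytest.approx(-3000.0, rel=1e-3)
        assert r.dH2 == pytest.approx(-1500.0, rel=1e-3)

    def test_all_zero_thermogram_uninformative(self, schedule):
        t = ck.Thermogram(np.zeros(19), ck.molar_ratios(schedule))
        with pytest.raises(ck.UninformativeTitrationError, match="uninformative"):
            ck.fit_binding(t, schedule)

    def test_too_few_injections_rejected(self):
        s = ck.InjectionSchedule(syringe_conc=250e-6, cell_conc=200e-6, n_injections=4)
        t = ck.simulate_thermogram(s, K=1e4, dH=-3000.0)
        with pytest.raises(ck.UninformativeTitrationError, match="5"):
            ck.fit_binding(t, s)

    def test_result_thermodynamic_identities(self, schedule):
        t = ck.simulate_thermogram(schedule, K=1e4, dH=-3000.0)
        r = ck.fit_binding(t, schedule)
        assert r.dG == pytest.approx(-ck.R_CAL * r.temperature * math.log(r.K), rel=1e-6)
        assert r.minus_TdS == r.dG - r.dH

    def test_low_information_flagged_not_spuriously_precise(self):
        # c = K*M0 = 0.001: the isotherm is a featureless line
        s = ck.InjectionSchedule(syringe_conc=1.25e-3, cell_conc=1e-4)
        t = ck.simulate_thermogram(s, K=10.0, dH=-3000.0)
        r = ck.fit_binding(t, s)
        assert any("low information" in f or "uninformative" in f for f in r.flags)

    def test_reported_stderr_present_for_noisy_fit(self, schedule):
        rec = ck.ThermogramRecipe(
            true_K=1e4, true_dH=-3000.0, schedule=schedule, noise_sd=0.01, seed=11
        )
        t, _ = ck.make_thermogram(rec)
        r = ck.fit_binding(t, schedule)
        assert r.std_errors.get("K", 0) > 0


class TestThermodynamics:
    @pytest.mark.parametrize(
        "K,expected_dG",
        [(2.01e3, -4.50e3), (8.40e17, -2.44e4)],  # epicatechin 1:1 / quercetin 1:2
    )
    def test_minus_RT_lnK_reproduces_reported_dG(self, K, expected_dG):
        dG, _ = ck.derive_thermodynamics(K, -100.0, 298.0)
        # agreement at three significant figures
        assert dG == pytest.approx(expected_dG, rel=5e-3)

    def test_unit_equilibrium_constant(self):
        dG, mTdS = ck.derive_thermodynamics(1.0, -500.0, 310.0)
        assert dG == 0.0 and mTdS == 500.0

    def test_rejects_nonpositive_K(self):
        with pytest.raises(ValueError):
            ck.derive_thermodynamics(0.0, -100.0, 298.0)

    def test_reported_table_identity_dH_plus_minusTdS(self, itc_table):
        """ΔH + (−TΔS) reproduces the printed ΔG at printed precision
        (3 significant figures) for >= 9 of 10 interactions; the catechin
        1:1 row is off by one last-digit rounding unit."""
        ok = 0
        for label, row in itc_table.iterrows():
            recomputed = row.dH + row.minus_TdS
            # one unit in the third significant figure of the printed value
            exponent = math.floor(math.log10(abs(row.dG)))
            unit = 10.0 ** (exponent - 2)
            assert abs(recomputed - row.dG) <= unit + 1e-9, label
            if abs(recomputed - row.dG) <= unit / 2.0:
                ok += 1
        assert ok >= 9

    def test_affinity_ordering_of_first_ratio_interactions(self, itc_table):
        first = ["Mv3G_QG", "Mv3G_CA", "Mv3G_E", "Mv3G_GA", "Mv3G_C"]
        Ks = [itc_table.loc[l, "K"] for l in first]
        assert Ks == sorted(Ks, reverse=True)  # QG > CA > E > GA > C


class TestForceClassification:
    @pytest.mark.parametrize(
        "dH,mTdS,expected",
        [
            (2.74e2, -1.06e4, ck.ForceClass.HYDROPHOBIC),  # caffeic acid 1:2
            (-2.65e3, -3.19e2, ck.ForceClass.BOTH),  # catechin 1:1
            (-1.0, 1.0, ck.ForceClass.HYDROGEN_BONDING),
        ],
    )
    def test_sign_quadrants(self, dH, mTdS, expected):
        assert ck.classify_forces(dH, mTdS) is expected

    def test_zero_indeterminate(self):
        with pytest.raises(ValueError, match="indeterminate"):
            ck.classify_forces(0.0, -1.0)

    def test_non_spontaneous_quadrant_not_assigned(self):
        with pytest.raises(ValueError, match="non-spontaneous"):
            ck.classify_forces(1.0, 1.0)

    def test_reported_interactions_classification(self, itc_table):
        classes = {
            label: ck.classify_forces(row.dH, row.minus_TdS)
            for label, row in itc_table.iterrows()
        }
        assert classes.pop("Mv3G_CA2") is ck.ForceClass.HYDROPHOBIC
        assert all(c is ck.ForceClass.BOTH for c in classes.values())


def test_thermogram_csv_round_trip(tmp_path):
    sched = itc_schedules()["E"]
    t = ck.simulate_thermogram(sched, K=2.01e3, dH=-256.0)
    p = tmp_path / "thermo.csv"
    t.to_csv(p)
    back = ck.Thermogram.from_csv(p, schedule=sched)
    np.testing.assert_allclose(back.heats, t.heats)
    np.testing.assert_allclose(back.molar_ratio, t.molar_ratio)
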