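import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phenflux as pf
from phenflux.domain import ConfigError, DegenerateEnrichmentError
from phenflux.wholebody import SteelePair


MEAL = pf.MealSpec(26.0, 0.05, 8190.0)


def pair(t1=0, t2=10, C1=55.0, C2=60.0, E1=0.060, E2=0.055):
    return SteelePair(t1, t2, C1, C2, E1, E2)


class TestSteeleRa:
    def test_steady_state_is_dilution_form(self):
        p = pair(C1=70, C2=70, E1=0.05, E2=0.05)
        assert pf.steele_ra(0.07, 0.19, p) == pytest.approx(1.4, rel=1e-12)

    def test_nonsteady_hand_value(self):
        # (0.07 - 0.19*57.5*(-0.0005)) / 0.0575 = 1.31239...
        expected = (0.07 + 0.19 * 57.5 * 0.0005) / 0.0575
        assert pf.steele_ra(0.07, 0.19, pair()) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(1.3124, abs=5e-5)

    def test_zero_enrichment_degenerate(self):
        with pytest.raises(DegenerateEnrichmentError):
            pf.steele_ra(0.07, 0.19, pair(E1=0.0, E2=0.0))

    def test_reversed_grid_rejected(self):
        with pytest.raises(pf.domain.GridError):
            SteelePair(10, 0, 55, 55, 0.05, 0.05)

    def test_baseline_pair_midpoint(self):
        assert SteelePair(-60, -30, 55, 55, 0.05, 0.05).midpoint == -45


class TestSteeleRd:
    def test_steady_state_equals_ra(self):
        p = pair(C1=70, C2=70)
        ra = pf.steele_ra(0.07, 0.19, p)
        assert pf.steele_rd(ra, 0.19, p) == ra

    def test_rising_pool_lowers_rd(self):
        assert pf.steele_rd(1.3124, 0.19, pair()) == pytest.approx(
            1.2174, abs=5e-5
        )

    def test_falling_pool_raises_rd(self):
        p = pair(C1=60, C2=55)
        assert pf.steele_rd(1.4, 0.19, p) == pytest.approx(1.495, abs=5e-5)


class TestOralRa:
    def test_no_meal_label_means_zero(self):
        p = pair(E1=0.0, E2=0.0, C1=70, C2=70)
        assert pf.oral_ra(1.8, 0.19, p, MEAL) == 0.0

    def test_corrected_hand_value(self):
        # (1.80*0.011 + 0.19*70*0.0002) / 0.05 = 0.4492
        p = SteelePair(0, 10, 70, 70, 0.010, 0.012)
        expected = (1.80 * 0.011 + 0.19 * 70 * 0.0002) / 0.05
        assert pf.oral_ra(1.80, 0.19, p, MEAL) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.4492, abs=5e-5)

    def test_modes_agree_at_steady_state(self):
        p = SteelePair(0, 10, 70, 70, 0.0125, 0.0125)
        for mode in ("corrected", "printed"):
            assert pf.oral_ra(1.8, 0.19, p, MEAL, mode=mode) == pytest.approx(
                0.45, rel=1e-12
            )

    def test_printed_mode_drops_concentration_factor(self):
        p = SteelePair(0, 10, 70, 70, 0.010, 0.012)
        printed = pf.oral_ra(1.80, 0.19, p, MEAL, mode="printed")
        assert printed == pytest.approx(
            (1.80 * 0.011 + 0.19 * 0.0002) / 0.05, rel=1e-12
        )

    def test_bad_mode(self):
        with pytest.raises(ConfigError):
            pf.oral_ra(1.8, 0.19, pair(), MEAL, mode="wrong")


class TestEndogenousRa:
    def test_simple(self):
        assert pf.endogenous_ra(1.80, 0.45) == pytest.approx(1.35)

    def test_subtract_tracer(self):
        assert pf.endogenous_ra(
            1.80, 0.45, F=0.07, mode="subtract_tracer"
        ) == pytest.approx(1.28)

    def test_fasting_limit(self):
        assert pf.endogenous_ra(1.4, 0.0) == 1.4

    def test_negative_clipped(self):
        assert pf.endogenous_ra(0.4, 0.5) == 0.0


class TestHydroxylation:
    def test_zero_when_no_labeled_tyrosine(self):
        assert pf.hydroxylation_rate(0.55, 0.0, (0.05, 0.06)) == 0.0

    def test_hand_value(self):
        assert pf.hydroxylation_rate(0.55, 0.004, (0.055, 0.055)) == (
            pytest.approx(0.55 * 0.004 / 0.055, rel=1e-12)
        )
        assert 0.55 * 0.004 / 0.055 == pytest.approx(0.04, rel=1e-9)

    @given(factor=st.floats(0.1, 10))
    def test_ratio_invariance(self, factor):
        base = pf.hydroxylation_rate(0.55, 0.004, (0.05, 0.06))
        scaled = pf.hydroxylation_rate(
            0.55, 0.004 * factor, (0.05 * factor, 0.06 * factor)
        )
        assert scaled == pytest.approx(base, rel=1e-9)


class TestProteinMath:
    def test_synthesis_is_rd_minus_hydroxylation(self):
        assert pf.protein_synthesis_rate(1.2174, 0.04) == pytest.approx(1.1774)
        assert pf.protein_synthesis_rate(1.2, 0.0) == 1.2
        assert pf.protein_synthesis_rate(0.03, 0.04) == pytest.approx(-0.01)

    def test_grams_per_day_unit_fixture(self):
        assert pf.to_grams_per_day(273.0 / 1440.0) == pytest.approx(
            1.0, rel=1e-12
        )
        assert pf.to_grams_per_day(1.1774) == pytest.approx(
            1.1774 * 1440 / 273, rel=1e-12
        )
        assert 1.1774 * 1440 / 273 == pytest.approx(6.2105, abs=5e-5)
        assert pf.to_grams_per_day(0.0) == 0.0

    @given(a=st.floats(-2, 2), b=st.floats(-2, 2))
    def test_grams_per_day_linear(self, a, b):
        assert pf.to_grams_per_day(a + b) == pytest.approx(
            pf.to_grams_per_day(a) + pf.to_grams_per_day(b), abs=1e-12
        )

    def test_net_gain(self):
        assert pf.net_protein_gain(6.21, 6.75) == pytest.approx(-0.54)
        assert pf.net_protein_gain(5.0, 5.0) == 0.0


class TestSplanchnic:
    def _subject(self, lm=60.0):
        return pf.SubjectProfile("x", "healthy_weight", lm + 20, lm)

    def test_constant_oral_ra(self):
        # 0.40 μmol/kgLM/min for 360 min vs 180 μmol/kgLM ingested -> 80%
        s = self._subject(60.0)
        meal = pf.MealSpec(26.0, 0.05, 180.0 * 60.0)
        t = np.array([0.0, 100.0, 360.0])
        res = pf.splanchnic_appearance_percent(t, np.full(3, 0.40), meal, s)
        assert res.appearance_percent == pytest.approx(80.0, rel=1e-12)
        assert res.first_pass_percent == pytest.approx(20.0, rel=1e-12)

    def test_zero_oral_ra(self):
        s = self._subject()
        meal = pf.MealSpec(26.0, 0.05, 8190.0)
        res = pf.splanchnic_appearance_percent(
            np.array([0.0, 360.0]), np.zeros(2), meal, s
        )
        assert res.appearance_percent == 0.0

    def test_auc_equal_to_ingested_is_100(self):
        s = self._subject(50.0)
        meal = pf.MealSpec(26.0, 0.05, 50.0 * 360.0)  # AUC 360 per kg LM
        res = pf.splanchnic_appearance_percent(
            np.array([0.0, 360.0]), np.ones(2), meal, s
        )
        assert res.appearance_percent == pytest.approx(100.0, rel=1e-12)


class TestSteadyStateProperty:
    @given(
        F=st.floats(0.01, 0.2),
        E=st.floats(0.01, 0.3),
        C=st.floats(20, 200),
        dt=st.floats(1, 120),
    )
    def test_constant_enrichment_closed_form(self, F, E, C, dt):
        p = SteelePair(0.0, dt, C, C, E, E)
        ra = pf.steele_ra(F, 0.19, p)
        assert ra == pytest.approx(F / E, rel=1e-12)
        assert pf.steele_rd(ra, 0.19, p) == pytest.approx(ra, rel=1e-12)


class TestPipeline:
    def test_recovers_steady_state_everywhere(self, subject):
        """Constant enrichment and concentration -> every midpoint F/E."""
        times = [-150, -60, -30, 10, 20, 30]
        phe = {"d8": 0.046, "d7": 0.004, "d5": 0.01}
        tyr = {"d2": 0.04, "d7": 0.003, "d6": 0.001}
        samples = []
        for t in times:
            is_bg = t == -150
            samples.append(pf.PlasmaSample(
                float(t), "artery", "phenylalanine", 55.0,
                {k: (0.0 if is_bg else v) for k, v in phe.items()},
            ))
            samples.append(pf.PlasmaSample(
                float(t), "artery", "tyrosine", 47.0,
                {k: (0.0 if is_bg else v) for k, v in tyr.items()},
            ))
        series = pf.PlasmaSeries("s01", "saline", "artery", samples)
        lm = subject.lean_mass
        protocols = {
            "phe_d8": pf.TracerProtocol("phe_d8", 3.0, 0.07, 30.0, 0.07 * lm / 30.0),
            "tyr_d2": pf.TracerProtocol("tyr_d2", 2.3, 0.04, 24.0, 0.04 * lm / 24.0),
        }
        res = pf.wholebody_pipeline(series, protocols, MEAL, subject)
        assert res.midpoint_times.tolist() == [-45.0, -10.0, 15.0, 25.0]
        np.testing.assert_allclose(res.ra_total, 0.07 / 0.05, rtol=1e-12)
        np.testing.assert_allclose(res.rd_total, res.ra_total, rtol=1e-12)
        # constant D5 -> oral Ra = Ra_total * E5 / r at every midpoint
        np.testing.assert_allclose(
            res.ra_oral, (0.07 / 0.05) * 0.01 / MEAL.d5_to_tracee_ratio_r,
            rtol=1e-12,
        )
        res.validate()

    def test_missing_sample_pairs_across_gap(self, noisefree_config):
        """Dropping the 90-min sample yields the (60, 120) pair, midpoint 90."""
        ds = pf.simulate_subject(noisefree_config, 1, group="healthy_weight")
        kept = [s for s in ds.arterial.samples if s.time != 90.0]
        series = pf.PlasmaSeries("s", "saline", "artery", kept)
        res = pf.wholebody_pipeline(series, ds.protocols, ds.meal, ds.subject)
        assert 90.0 in res.midpoint_times  # midpoint of the (60, 120) pair
        assert 75.0 not in res.midpoint_times  # (60, 90) no longer exists
        assert 105.0 not in res.midpoint_times  # nor (90, 120)


class TestIdentity:
    @given(
        ra=st.floats(0.5, 3.0),
        frac=st.floats(0.0, 0.99),
        F=st.floats(0.0, 0.2),
        mode=st.sampled_from(["simple", "subtract_tracer"]),
    )
    def test_total_splits_exactly(self, ra, frac, F, mode):
        oral = ra * frac if mode == "simple" else max(ra - F, 0) * frac
        endo = pf.endogenous_ra(ra, oral, F=F, mode=mode)
        extra = F if mode == "subtract_tracer" else 0.0
        assert endo + oral + extra == pytest.approx(ra, rel=1e-15)
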