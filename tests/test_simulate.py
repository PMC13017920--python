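import dataclasses

import numpy as np
import pytest

import phenflux as pf
from phenflux.domain import ConfigError


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = pf.default_scenario(seed=42, n_per_group=1, visits=("saline",))
        a = pf.simulate_subject(cfg, 0, group="obesity")
        b = pf.simulate_subject(cfg, 0, group="obesity")
        assert a.subject == b.subject
        for sa, sb in zip(a.arterial.samples, b.arterial.samples):
            assert sa == sb
        np.testing.assert_array_equal(a.flow.flow, b.flow.flow)
        np.testing.assert_array_equal(a.truth.ra_endo, b.truth.ra_endo)

    def test_different_seeds_differ(self):
        a = pf.simulate_subject(pf.default_scenario(seed=1), 0)
        b = pf.simulate_subject(pf.default_scenario(seed=2), 0)
        assert a.subject.body_weight != b.subject.body_weight

    def test_subject_body_shared_across_visits(self):
        cfg = pf.default_scenario(seed=5)
        a = pf.simulate_subject(cfg, 3, group="obesity", visit="saline")
        b = pf.simulate_subject(cfg, 3, group="obesity", visit="il6r_ab")
        assert a.subject.body_weight == b.subject.body_weight
        assert a.subject.lean_mass == b.subject.lean_mass


class TestPhysiology:
    def test_seed_required(self):
        with pytest.raises((ConfigError, TypeError)):
            pf.ScenarioConfig(seed=None)

    def test_conservation_all_channels(self, noisefree_dataset):
        for channel, (infused, pool, cleared) in (
            noisefree_dataset.truth.conservation.items()
        ):
            assert abs(infused - pool - cleared) / infused < 1e-6, channel

    def test_plateau_matches_dilution_closed_form(self, noisefree_config):
        """No meal, no suppression: arterial TTRs plateau at F/Ra."""
        groups = {
            k: dataclasses.replace(
                v, meal_systemic_fraction=1e-12, suppression_depth=0.0,
                suppression_depth_sd=0.0,
            )
            for k, v in noisefree_config.groups.items()
        }
        cfg = dataclasses.replace(noisefree_config, groups=groups)
        ds = pf.simulate_subject(cfg, 0, group="healthy_weight")
        art = pf.background_correct(ds.arterial)
        _, e8 = art.channel_series("phe_d8d7")
        _, e2 = art.channel_series("tyr_d2")
        ra_phe = ds.truth.ra_endo[-1]
        ra_tyr = ds.truth.ra_tyr_inflow[-1]
        assert e8[-1] == pytest.approx(0.07 / ra_phe, rel=1e-9)
        assert e2[-1] == pytest.approx(0.04 / ra_tyr, rel=1e-9)

    def test_meal_label_plateau_ratio(self, noisefree_config):
        """At the absorption peak region the D5 TTR tracks
        r * Ra_oral / inflow (quasi-steady approximation)."""
        ds = pf.simulate_subject(noisefree_config, 2, group="healthy_weight")
        art = pf.background_correct(ds.arterial)
        t, e5 = art.channel_series("phe_d5")
        tr = ds.truth
        i = np.argmax(e5)
        expected = (
            ds.meal.d5_to_tracee_ratio_r
            * np.interp(t[i], tr.time, tr.ra_oral / tr.inflow())
        )
        assert e5[i] == pytest.approx(expected, rel=0.25)

    def test_fasting_only_net_loss(self, noisefree_config):
        """Without a meal the body is in net protein loss at all midpoints."""
        groups = {
            k: dataclasses.replace(
                v, meal_systemic_fraction=1e-12, suppression_depth=0.0,
                suppression_depth_sd=0.0,
            )
            for k, v in noisefree_config.groups.items()
        }
        cfg = dataclasses.replace(noisefree_config, groups=groups)
        ds = pf.simulate_subject(cfg, 0, group="healthy_weight")
        res = pf.wholebody_pipeline(
            ds.arterial, ds.protocols, ds.meal, ds.subject
        )
        assert np.all(res.net_gain_g_day < 0)
        assert np.all(ds.truth.net_gain_g_day < 0)


class TestRecovery:
    def test_dense_grid_within_two_percent_of_peak(self, noisefree_config):
        dense = (-150,) + tuple(range(-60, 361))
        cfg = dataclasses.replace(noisefree_config, sampling_times=dense)
        ds = pf.simulate_subject(cfg, 0, group="healthy_weight")
        res = pf.wholebody_pipeline(
            ds.arterial, ds.protocols, ds.meal, ds.subject
        )
        truth = ds.truth
        true_inflow = np.interp(res.midpoint_times, truth.time, truth.inflow())
        err = np.abs(res.ra_total - true_inflow) / truth.inflow().max()
        assert err.max() < 0.02

    def test_study_grid_within_ten_percent_mid_window(self, noisefree_dataset):
        ds = noisefree_dataset
        res = pf.wholebody_pipeline(
            ds.arterial, ds.protocols, ds.meal, ds.subject
        )
        truth = ds.truth
        true_inflow = np.interp(res.midpoint_times, truth.time, truth.inflow())
        err = np.abs(res.ra_total - true_inflow) / truth.inflow().max()
        window = (res.midpoint_times >= 15) & (res.midpoint_times <= 270)
        assert err[window].max() < 0.10

    def test_splanchnic_appearance_near_truth(self, noisefree_dataset):
        """AUC of recovered oral Ra ~ systemic fraction of ingested phe."""
        ds = noisefree_dataset
        res = pf.wholebody_pipeline(
            ds.arterial, ds.protocols, ds.meal, ds.subject
        )
        sp = pf.splanchnic_appearance_percent(
            res.midpoint_times, res.ra_oral, ds.meal, ds.subject
        )
        # truth: 85% systemic fraction x gamma mass within 0-360 min
        assert sp.appearance_percent == pytest.approx(85.0, abs=8.0)

    def test_injected_group_effect_single_replicate(self):
        """20% blunted proteolysis suppression -> higher postprandial
        endogenous Ra and lower net gain in that group (one cohort)."""
        base = pf.default_scenario(seed=0).groups["healthy_weight"]
        groups = {
            "healthy_weight": base,
            "obesity": dataclasses.replace(
                base,
                body_weight_mean=111.8, body_weight_sd=12.1,
                lean_fraction_mean=0.61, lean_fraction_sd=0.04,
                suppression_depth=base.suppression_depth * 0.8,
            ),
        }
        cfg = pf.ScenarioConfig(seed=99, groups=groups, visits=("saline",),
                                n_per_group=12)
        stats = {}
        for grp in groups:
            endo, gain = [], []
            for i in range(cfg.n_per_group):
                ds = pf.simulate_subject(cfg, i, group=grp)
                res = pf.wholebody_pipeline(
                    ds.arterial, ds.protocols, ds.meal, ds.subject
                )
                resp = pf.postprandial_response(res)
                endo.append(resp["endo_change_rel"])
                gain.append(resp["net_gain_iauc"])
            stats[grp] = (np.mean(endo), np.mean(gain))
        assert stats["obesity"][0] > stats["healthy_weight"][0]
        assert stats["obesity"][1] < stats["healthy_weight"][1]


class TestCohort:
    def test_smoke_cohort_runs_quickly(self):
        cfg = pf.default_scenario(seed=8, n_per_group=2)
        datasets = pf.simulate_cohort(cfg)
        # 2 groups x 2 subjects x 2 visits
        assert len(datasets) == 8
        ids = {(d.subject.subject_id, d.visit) for d in datasets}
        assert len(ids) == 8
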