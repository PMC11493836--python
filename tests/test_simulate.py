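"""Synthetic acquisition: trace synthesis, study designs, cohort model."""

import numpy as np
import pandas as pd
import pytest

from gslmrm import simulate as sim
from gslmrm.simulate import (
    STANDARD_MIX,
    AcquisitionModel,
    SamplePlan,
    default_cohort_model,
    make_calibration_series,
    make_cohort,
    make_qc_series,
    make_stability_series,
    simulate_chromatograms,
)

NOISELESS = AcquisitionModel(
    baseline=0.0, noise_sigma=0.0, noise_proportional=0.0, amplitude_cv=0.0,
    rt_jitter_sd_min=0.0,
)


def plan(amounts, seed=0, **kw):
    return SamplePlan(sample_id="S1", group="calibrator", amounts=amounts, seed=seed, **kw)


class TestTraceSynthesis:
    def test_zero_amount_zero_noise_gives_zero_trace(self, default_panel):
        ch = simulate_chromatograms(
            default_panel[:5], plan({}, is_spike=0.0), NOISELESS
        )
        assert (ch["intensity"] == 0).all()

    def test_noise_free_area_matches_closed_form(self, default_panel):
        """Trapezoid area over the synthetic peak recovers amount x
        response to within discretization error (<0.5%)."""
        t = default_panel[0]
        amount = 100.0
        ch = simulate_chromatograms(
            default_panel, plan({t.species_id: amount}), NOISELESS
        )
        g = ch[ch.transition_id == t.transition_id]
        area = np.trapezoid(g["intensity"], g["time_min"])
        expected = amount * NOISELESS.response_for(t.class_name)
        assert area == pytest.approx(expected, rel=5e-3)

    def test_points_confined_to_scheduled_windows(self, default_panel):
        ch = simulate_chromatograms(default_panel, plan({}))
        bytrans = {t.transition_id: t.window for t in default_panel}
        for tid, g in ch.groupby("transition_id"):
            lo, hi = bytrans[tid]
            assert g["time_min"].min() >= lo - 1e-9
            assert g["time_min"].max() <= hi + 1e-9

    def test_seed_contract_same_locations_different_noise(self, default_panel):
        sub = default_panel[:3]
        amounts = {sub[0].species_id: 500.0}
        a = simulate_chromatograms(sub, plan(amounts, seed=1))
        b = simulate_chromatograms(sub, plan(amounts, seed=2))
        assert not np.allclose(a["intensity"], b["intensity"])
        # peak location (argmax time) identical: jitter keyed to identity
        ga = a[a.transition_id == sub[0].transition_id]
        gb = b[b.transition_id == sub[0].transition_id]
        assert (
            ga["time_min"].iloc[ga["intensity"].argmax()]
            == gb["time_min"].iloc[gb["intensity"].argmax()]
        )

    def test_identical_seed_bit_identical(self, default_panel):
        p = plan({default_panel[0].species_id: 50.0}, seed=7)
        a = simulate_chromatograms(default_panel[:4], p)
        b = simulate_chromatograms(default_panel[:4], p)
        pd.testing.assert_frame_equal(a, b)

    def test_species_absent_from_panel_rejected(self, default_panel):
        with pytest.raises(KeyError, match="GX"):
            simulate_chromatograms(default_panel[:2], plan({"GX d36:1": 1.0}))

    def test_linearity_by_construction(self, default_panel):
        """Noise-free areas vs amounts: r^2 = 1 and slope = response x
        matrix factor x extraction efficiency."""
        t = default_panel[0]
        mf, ee = 0.8, 0.95
        amounts = [10.0, 50.0, 250.0, 1000.0]
        areas = []
        for a in amounts:
            ch = simulate_chromatograms(
                [t],
                plan({t.species_id: a}, matrix_factor=mf, extraction_efficiency=ee),
                NOISELESS,
            )
            areas.append(np.trapezoid(ch["intensity"], ch["time_min"]))
        slope, intercept = np.polyfit(amounts, areas, 1)
        r = np.corrcoef(amounts, areas)[0, 1]
        assert r**2 > 1 - 1e-9
        assert slope == pytest.approx(
            NOISELESS.response_for(t.class_name) * mf * ee, rel=5e-3
        )

    def test_emg_shape_conserves_area(self, default_panel):
        acq = AcquisitionModel(
            peak_shape="emg", emg_tau_s=3.0, baseline=0.0, noise_sigma=0.0,
            noise_proportional=0.0, amplitude_cv=0.0, rt_jitter_sd_min=0.0,
        )
        t = default_panel[0]
        ch = simulate_chromatograms([t], plan({t.species_id: 100.0}), acq)
        area = np.trapezoid(ch["intensity"], ch["time_min"])
        assert area == pytest.approx(100.0 * acq.response_for(t.class_name), rel=2e-2)


class TestStudyDesigns:
    def test_calibration_series_default_seven_levels(self):
        plans = make_calibration_series()
        assert len(plans) == 7
        levels = sorted({p.amounts["GM3 d36:1"] for p in plans}, reverse=True)
        assert levels[0] == pytest.approx(5000.0)
        for a, b in zip(levels, levels[1:]):
            assert a / b == pytest.approx(4.0)
        assert all(set(p.amounts) == set(STANDARD_MIX) for p in plans)

    def test_calibration_replicates_distinct_seeds(self):
        plans = make_calibration_series(replicates=3)
        assert len(plans) == 21
        assert len({p.seed for p in plans}) == 21

    def test_empty_level_list_rejected(self):
        with pytest.raises(ValueError):
            make_calibration_series(levels=[])
        with pytest.raises(ValueError):
            make_calibration_series(levels=[0.0, 10.0])

    def test_qc_series_levels_and_counts(self):
        plans = make_qc_series(replicates=5, days=5)
        assert len(plans) == 50
        lows = [p for p in plans if p.group == "qc_low"]
        assert len(lows) == 25
        assert all(v == 50.0 for p in lows for v in p.amounts.values())

    def test_stability_no_decay_full_recovery(self):
        plans = make_stability_series("room", [0, 1, 3, 7], decay_rate_per_day=0.0)
        base = plans[0].amounts
        for p in plans:
            assert p.amounts == base

    def test_stability_first_order_decay(self):
        rate = -np.log(0.8) / 7.0
        plans = make_stability_series("room", [7], decay_rate_per_day=rate)
        day7 = next(p for p in plans if p.storage_days == 7)
        base = next(p for p in plans if p.storage_days == 0)
        sid = next(iter(base.amounts))
        assert day7.amounts[sid] / base.amounts[sid] == pytest.approx(0.8)

    def test_freeze_thaw_compound_loss(self):
        plans = make_stability_series(
            "freeze_thaw", [4], per_cycle_loss=0.02
        )
        c4 = next(p for p in plans if p.freeze_thaw_cycles == 4)
        base = next(p for p in plans if p.freeze_thaw_cycles == 0)
        sid = next(iter(base.amounts))
        assert c4.amounts[sid] / base.amounts[sid] == pytest.approx(0.98**4)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            make_stability_series("microwave", [1])


class TestCohortModel:
    def test_default_cohort_is_39_samples(self):
        plans, truth = make_cohort(default_cohort_model(), seed=0)
        assert len(plans) == 39
        assert (truth["group"] == "control").sum() == 36
        assert (truth["group"] == "tay_sachs").sum() == 2
        assert (truth["group"] == "sandhoff").sum() == 1

    def test_null_multipliers_identical_in_law(self):
        model = default_cohort_model()
        model.patient_fold = {}
        model.sandhoff_extra = {}
        assert model.fold_for("GM2", "tay_sachs") == 1.0
        assert model.fold_for("GA2", "sandhoff") == 1.0

    def test_gm2_fold_recovered_at_large_n(self):
        """Monte-Carlo: expected patient/control mean ratio ~ 10."""
        model = default_cohort_model()
        rng = np.random.default_rng(11)
        mu, sg = model.class_lognorm["GM2"]
        ctrl = rng.lognormal(mu, sg, 2000)
        pat = rng.lognormal(mu, sg, 2000) * model.fold_for("GM2", "tay_sachs")
        assert pat.mean() / ctrl.mean() == pytest.approx(10.0, rel=0.06)

    def test_sandhoff_only_ga2_elevation(self):
        model = default_cohort_model()
        assert model.fold_for("GA2", "sandhoff") == pytest.approx(2.4)
        assert model.fold_for("GA2", "tay_sachs") == 1.0
        assert model.fold_for("GA2", "control") == 1.0

    def test_fixture_faithfulness_of_control_means(self, cohort_table):
        """Across 10 seeds, simulated control class means stay within
        2 SE (n=36) of the packaged-cohort class means."""
        model = default_cohort_model()
        ctrl = cohort_table[cohort_table["group"] == "control"]
        sums = {}
        for seed in range(10):
            _, truth = make_cohort(model, seed=seed)
            tc = truth[truth["group"] == "control"]
            for cname in ("GM3", "GM2", "GM1", "GD3", "GD2", "GD1", "GT1"):
                sums.setdefault(cname, []).append(tc[f"{cname} d36:1"].mean())
        for cname, means in sums.items():
            col = ctrl[f"{cname} d36:1"]
            se = col.std(ddof=1) / np.sqrt(len(col))
            assert abs(np.mean(means) - col.mean()) < 2 * se, cname

    def test_truth_table_matches_plans(self):
        plans, truth = make_cohort(default_cohort_model(), seed=3)
        row = truth[truth.sample_id == plans[0].sample_id].iloc[0]
        for sid, amt in plans[0].amounts.items():
            assert row[sid] == pytest.approx(amt)


def test_plan_validation():
    with pytest.raises(ValueError):
        SamplePlan("s", "control", amounts={"GM3 d36:1": -1.0})
    with pytest.raises(ValueError):
        SamplePlan("s", "control", matrix_factor=0.0)
    with pytest.raises(ValueError):
        SamplePlan("s", "control", extraction_efficiency=1.5)
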