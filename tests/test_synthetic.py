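"""Generators: cohort structure, questionnaires, signals, ground truth."""

import numpy as np
import pytest
from scipy import stats as sps

import qeegnorm as q
from qeegnorm.exceptions import SpecError
from qeegnorm.normdb import score_cohort
from qeegnorm.synthetic import MDD_GROUP_SIZES

GROUPS = ("20-30", "31-40", "41-50", "51-60", "61-70")


class TestCohortStructure:
    def test_healthy_preset_counts(self):
        records, subjects, _ = q.generate_cohort(q.hc_spec(), seed=1)
        assert len(records) == 260
        by_group = {}
        for r in records:
            by_group.setdefault(q.assign_age_group(r.age), []).append(r)
        assert [len(by_group[g]) for g in GROUPS] == [84, 47, 55, 49, 25]
        sexes = [s.sex for s in subjects]
        assert sexes.count("F") == sexes.count("M") == 130

    def test_patient_preset_counts(self):
        records, subjects, _ = q.generate_cohort(q.mdd_spec(), seed=1)
        assert len(records) == 221
        sexes = [s.sex for s in subjects]
        assert (sexes.count("F"), sexes.count("M")) == (163, 58)
        assert sum(nf + nm for nf, nm in MDD_GROUP_SIZES.values()) == 221

    def test_same_seed_reproduces_cohort(self):
        a = q.generate_cohort(q.hc_spec(), seed=9)
        b = q.generate_cohort(q.hc_spec(), seed=9)
        assert [r.power for r in a[0]] == [r.power for r in b[0]]
        assert [s.__dict__ for s in a[1]] == [s.__dict__ for s in b[1]]

    def test_negative_group_size_rejected(self):
        with pytest.raises(SpecError):
            q.CohortSpec(group_sizes={"20-30": (-1, 5)})

    def test_powers_positive_and_truth_consistent(self):
        records, _, truth = q.generate_cohort(q.hc_spec(), seed=2)
        assert all(v > 0 for r in records for v in r.power.values())
        # truth mean follows baseline x age-trend multiplier
        base_mean, base_sd = q.synthetic.DEFAULT_BASELINE["delta"]
        row = truth.loc[("61-70", "Cz", "delta")]
        assert row["mean"] == pytest.approx(base_mean * 0.92)
        assert row["sd"] == pytest.approx(base_sd * 0.92)


class TestQuestionnaires:
    def test_healthy_scores_respect_screen(self):
        _, subjects, _ = q.generate_cohort(q.hc_spec(), seed=3)
        assert all(s.bdi_ii < 14 and s.bai < 8 for s in subjects)
        assert all(q.screen_subject(s, "HC")[0] for s in subjects)

    def test_patient_scores_respect_screen(self):
        _, subjects, _ = q.generate_cohort(q.mdd_spec(), seed=3)
        assert all(s.bdi_ii > 14 and s.bai > 8 for s in subjects)
        assert all(q.screen_subject(s, "MDD")[0] for s in subjects)

    def test_healthy_depression_mean_matches_truncated_normal(self):
        # oracle: screening truncates N(4.23, 3.52^2) to [0, 14), which
        # shifts the population mean upward; compare against that mean
        _, subjects, _ = q.generate_cohort(q.hc_spec(), seed=4)
        scores = np.array([s.bdi_ii for s in subjects])
        mu, sd = 4.23, 3.52
        a, b = (0 - mu) / sd, (14 - mu) / sd
        expected = sps.truncnorm.mean(a, b, loc=mu, scale=sd)
        # 3 standard errors plus a margin for integer rounding
        assert abs(scores.mean() - expected) < 3 * sd / np.sqrt(260) + 0.2


class TestRecovery:
    def test_norms_recover_cell_means_within_ci(self):
        # round-trip: build_norms vs the generator's ground truth
        records, _, truth = q.generate_cohort(q.hc_spec(), seed=5)
        db = q.build_norms(records)
        sizes = {"20-30": 84, "31-40": 47, "41-50": 55,
                 "51-60": 49, "61-70": 25}
        hits = total = 0
        for (group, electrode, band), row in truth.iterrows():
            mean_hat, _, n = db.cell(group, electrode, band)
            assert n == sizes[group]
            half_width = 1.96 * row["sd"] / np.sqrt(n)
            hits += abs(mean_hat - row["mean"]) <= half_width
            total += 1
        assert hits / total >= 0.93

    def test_null_effect_cohorts_exchangeable(self):
        hc, _, _ = q.generate_cohort(q.hc_spec(), seed=6)
        null_mdd, _, _ = q.generate_cohort(
            q.mdd_spec(delta={}), seed=7)
        cells = list(hc[0].power)
        p_values = []
        for cell in cells:
            a = [r.power[cell] for r in hc if q.assign_age_group(r.age)
                 == "20-30"]
            b = [r.power[cell] for r in null_mdd
                 if q.assign_age_group(r.age) == "20-30"]
            p_values.append(sps.ttest_ind(a, b, equal_var=False).pvalue)
        # ~5% false positives expected over 95 cells
        assert np.mean(np.asarray(p_values) < 0.05) < 0.13

    def test_injected_effect_recovered_by_mean_z(self):
        hc, _, _ = q.generate_cohort(q.hc_spec(), seed=8)
        mdd, _, _ = q.generate_cohort(q.mdd_spec(), seed=9)
        z = score_cohort(mdd, q.build_norms(hc))
        mean_z = z[("Fz", "high-beta")].mean()
        assert mean_z == pytest.approx(1.73, abs=2 / np.sqrt(221) + 0.15)


class TestSignals:
    def test_alpha_only_target_recovered(self):
        spec = q.SignalSpec(duration_seconds=60.0,
                            band_targets={"alpha": 200.0})
        rec = q.generate_signal(spec, seed=10)
        segs = q.CleanSegmentSet(rec.subject_id, rec.sampling_rate,
                                 [(0, rec.n_samples)])
        bp = q.band_power(rec, segs)
        assert bp.power[("Cz", "alpha")] == pytest.approx(200.0, rel=0.05)
        assert bp.power[("Cz", "delta")] < 0.02 * 200.0

    def test_default_targets_calibrated_within_five_percent(self):
        spec = q.SignalSpec(duration_seconds=60.0)
        rec = q.generate_signal(spec, seed=11)
        segs = q.CleanSegmentSet(rec.subject_id, rec.sampling_rate,
                                 [(0, rec.n_samples)])
        bp = q.band_power(rec, segs)
        for band, target in spec.band_targets.items():
            assert bp.power[("Pz", band)] == pytest.approx(target, rel=0.05)

    def test_silent_when_no_targets(self):
        spec = q.SignalSpec(duration_seconds=30.0, band_targets={})
        rec = q.generate_signal(spec, seed=12)
        assert np.abs(rec.data).max() == 0.0

    def test_blink_rejects_exactly_its_window(self):
        spec = q.SignalSpec(duration_seconds=100.0, artifacts=[
            q.ArtifactEvent(time_seconds=30.0, kind="blink",
                            amplitude=400.0)])
        rec = q.generate_signal(spec, seed=13)
        segs = q.reject_artifacts(rec)
        assert segs.total_clean_seconds == pytest.approx(80.0)
        dropped = [(s, e) for s, e in [(0, rec.n_samples)]]
        for start, end in segs.segments:
            assert not (start < 30 * 256 < end)

    def test_blink_confined_to_frontal_channels(self):
        spec = q.SignalSpec(duration_seconds=40.0, band_targets={},
                            artifacts=[q.ArtifactEvent(30.0, "blink")])
        rec = q.generate_signal(spec, seed=14)
        fp1 = rec.channels.index("Fp1")
        o1 = rec.channels.index("O1")
        assert np.abs(rec.data[fp1]).max() > 100
        assert np.abs(rec.data[o1]).max() == 0.0

    def test_movement_hits_all_channels(self):
        spec = q.SignalSpec(duration_seconds=40.0, band_targets={},
                            artifacts=[q.ArtifactEvent(20.0, "movement",
                                                       amplitude=300.0)])
        rec = q.generate_signal(spec, seed=15)
        assert (np.abs(rec.data).max(axis=1) > 100).all()

    def test_deterministic_per_seed(self):
        spec = q.SignalSpec(duration_seconds=10.0)
        a = q.generate_signal(spec, seed=16)
        b = q.generate_signal(spec, seed=16)
        np.testing.assert_array_equal(a.data, b.data)

    def test_sub_nyquist_spec_rejected(self):
        with pytest.raises(SpecError):
            q.SignalSpec(sampling_rate=40.0)


class TestTidyFrames:
    def test_powers_frame_round_trip(self, small_cohort):
        records, _, _ = small_cohort
        frame = q.powers_to_frame(records)
        assert set(frame.columns) == {"subject_id", "age", "sex", "group",
                                      "electrode", "band", "power_uv2"}
        back = q.powers_from_frame(frame)
        assert [r.power for r in back] == [r.power for r in records]
        assert [r.age for r in back] == [r.age for r in records]
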