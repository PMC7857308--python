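"""Synthetic gait laboratory: subjects, deformations, trials, ground truth."""

import numpy as np
import pytest

from gaitload import kinematics as kin
from gaitload.synth import (GaitCondition, MarkerNoise, default_conditions,
                            generate_standing_trial, generate_subject,
                            generate_trial)


class TestSubjects:
    def test_demographic_bmi(self, subject):
        assert subject.spec.bmi == pytest.approx(30.41, abs=0.005)

    def test_identity_deformation_reproduces_template(self, template,
                                                      identity_subject):
        for seg, bone in template.bones.items():
            tgt = identity_subject.bones[seg]
            np.testing.assert_allclose(tgt.mesh.vertices, bone.mesh.vertices,
                                       atol=1e-12)
            for name, p in bone.landmarks.items():
                np.testing.assert_allclose(tgt.landmarks[name], p, atol=1e-12)

    def test_segment_lengths_match_deformed_joint_distances(self, subject):
        """Recorded true lengths equal joint-to-joint distances of the
        deformed geometry to machine precision."""
        d = subject.deformations["thigh_r"]
        lms = subject.template.bones["thigh_r"].landmarks
        thigh = np.linalg.norm(d.true_map(lms["hip_center"])
                               - d.true_map(lms["knee_center"]))
        assert abs(thigh - subject.spec.true_segment_lengths["thigh"]) < 1e-9

    def test_deterministic_for_fixed_seed(self, template):
        a = generate_subject(42, {"mass": 80, "height": 170}, template=template)
        b = generate_subject(42, {"mass": 80, "height": 170}, template=template)
        np.testing.assert_array_equal(a.bones["shank_r"].mesh.vertices,
                                      b.bones["shank_r"].mesh.vertices)
        assert a.spec.true_segment_lengths == b.spec.true_segment_lengths

    def test_rejects_nonphysiological_demographics(self, template):
        with pytest.raises(ValueError, match="mass and height"):
            generate_subject(1, {"mass": -5, "height": 170}, template=template)

    def test_landmarks_near_surface(self, subject):
        """Every named landmark lies within 5 cm of the bone mesh (interior
        reference points such as joint centers sit inside the bone)."""
        for seg, bone in subject.bones.items():
            assert bone.max_landmark_surface_distance() < 0.05, seg


class TestConditions:
    def test_condition_invariants(self):
        conds = default_conditions()
        assert set(conds) == {"shod", "insole_0", "insole_5", "insole_10",
                              "toe_in", "toe_out", "wide"}
        for c in ("shod", "toe_in", "toe_out", "wide"):
            assert conds[c].wedge_angle == 0
        for c in ("insole_0", "insole_5", "insole_10"):
            assert conds[c].foot_progression_offset == 0
            assert conds[c].step_width_offset == 0
        assert conds["toe_in"].foot_progression_offset < 0

    def test_invalid_conditions_rejected(self):
        with pytest.raises(ValueError):
            GaitCondition("toe_in", wedge_angle=5, foot_progression_offset=-10)
        with pytest.raises(ValueError):
            GaitCondition("insole_5", wedge_angle=5, step_width_offset=0.1)


class TestTrials:
    def test_zero_noise_markers_equal_forward_kinematics(self, subject):
        trial = generate_trial(subject, GaitCondition("shod"),
                               noise=MarkerNoise.none(), seed=3)
        km = kin.KinematicModel.from_model(subject.true_model)
        _, mk = kin.forward_kinematics(km, trial.ground_truth["q"])
        for m in trial.markers:
            np.testing.assert_allclose(trial.markers[m], mk[m], atol=1e-12)

    def test_toe_out_progression_angle(self, subject):
        """Foot progression measured from heel/toe markers shifts by the
        configured offset within half a degree."""
        def progression(trial):
            t0, t1 = trial.events["heel_strike"], trial.events["toe_off"]
            rate = trial.marker_rate
            sl = slice(int(t0 * rate) + 8, int(t1 * rate) - 8)
            v = trial.markers["RTOE"][sl] - trial.markers["RHEE"][sl]
            return np.degrees(np.arctan2(v[:, 1], v[:, 0])).mean()

        shod = generate_trial(subject, GaitCondition("shod"),
                              noise=MarkerNoise.none(), seed=4)
        toe_out = generate_trial(subject,
                                 GaitCondition("toe_out",
                                               foot_progression_offset=10.0),
                                 noise=MarkerNoise.none(), seed=4)
        # tested leg is right: positive (outward) progression rotates toes
        # laterally, i.e. toward -y; the marker angle decreases by the offset
        assert progression(toe_out) - progression(shod) == pytest.approx(-10.0,
                                                                         abs=0.5)

    def test_zero_wedge_insole_equals_shod_grf(self, subject):
        shod = generate_trial(subject, GaitCondition("shod"), seed=5)
        ins0 = generate_trial(subject, GaitCondition("insole_0"), seed=5)
        for plate in shod.grf:
            np.testing.assert_array_equal(shod.grf[plate]["force"],
                                          ins0.grf[plate]["force"])
            np.testing.assert_array_equal(shod.grf[plate]["cop"],
                                          ins0.grf[plate]["cop"])

    def test_wedge_shifts_cop_laterally(self, subject):
        shod = generate_trial(subject, GaitCondition("shod"),
                              noise=MarkerNoise.none(), seed=5)
        ins10 = generate_trial(subject, GaitCondition("insole_10", wedge_angle=10),
                               noise=MarkerNoise.none(), seed=5)
        fz = shod.grf["plate2"]["force"][:, 2]
        mask = fz > 100
        dy = (ins10.grf["plate2"]["cop"][mask, 1]
              - shod.grf["plate2"]["cop"][mask, 1])
        # right tested leg: lateral is -y; 2 mm/deg * 10 deg = 2 cm
        assert np.allclose(dy, -0.02, atol=1e-3)

    def test_vertical_grf_nonnegative_and_impulse(self, subject):
        """Each plate records one contact; the two single-stance vertical
        impulses together approximate body weight x one stride time (the
        double-support overlap is not modeled: documented 10% tolerance)."""
        trial = generate_trial(subject, GaitCondition("shod"), seed=6,
                               duration=2.2)
        bw = subject.spec.body_weight
        assert (trial.grf["plate2"]["force"][:, 2] >= 0).all()
        stride = trial.ground_truth["stride_time"]
        impulse = sum(np.trapezoid(trial.grf[p]["force"][:, 2],
                                   dx=1.0 / trial.force_rate)
                      for p in trial.grf)
        assert impulse == pytest.approx(bw * stride, rel=0.10)

    def test_too_short_duration_rejected(self, subject):
        with pytest.raises(ValueError, match="too short"):
            generate_trial(subject, GaitCondition("shod"), duration=0.5)

    def test_trial_determinism(self, subject):
        a = generate_trial(subject, GaitCondition("wide", step_width_offset=0.08),
                           seed=11)
        b = generate_trial(subject, GaitCondition("wide", step_width_offset=0.08),
                           seed=11)
        for m in a.markers:
            np.testing.assert_array_equal(a.markers[m], b.markers[m])


class TestStandingTrial:
    def test_zero_noise_constant(self, clean_standing):
        for m, tr in clean_standing.markers.items():
            assert np.ptp(tr, axis=0).max() == 0.0

    def test_determinism(self, subject):
        a = generate_standing_trial(subject, seed=9)
        b = generate_standing_trial(subject, seed=9)
        for m in a.markers:
            np.testing.assert_array_equal(a.markers[m], b.markers[m])

    def test_marker_noise_statistics(self, subject):
        """Per-marker temporal SD within 20% of the requested sigma."""
        trial = generate_standing_trial(subject, seed=10, duration=3.0,
                                        noise=MarkerNoise(white_std=0.002,
                                                          sta_amplitude=0.0))
        sds = np.array([trial.markers[m].std(axis=0).mean()
                        for m in trial.markers])
        assert np.all(np.abs(sds - 0.002) < 0.2 * 0.002)
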