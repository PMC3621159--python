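"""Virtual-subject generator: determinism, trends, measurement emulation."""

import numpy as np
import pytest

from cvsid.features import extract_setpoints
from cvsid.synth import (SepsisTrajectoryConfig, generate_dataset,
                         sample_baseline, septic_trajectory, write_dataset)


@pytest.fixture(scope="module")
def subject():
    return sample_baseline(1)


@pytest.fixture(scope="module")
def single_timepoint(subject):
    return generate_dataset(subject,
                            SepsisTrajectoryConfig(n_timepoints=1),
                            noise=False, seed=1)


class TestBaselineSampling:
    def test_deterministic_for_fixed_seed(self, subject):
        again = sample_baseline(1)
        assert again.baseline.to_dict() == subject.baseline.to_dict()

    def test_distinct_seeds_differ(self, subject):
        other = sample_baseline(2)
        assert other.baseline.to_dict() != subject.baseline.to_dict()

    def test_physiological_screen(self):
        for seed in (3, 4, 5):
            s = sample_baseline(seed)
            assert 50.0 <= s.screen["MAP"] <= 130.0
            assert 20.0 <= s.screen["SV"] <= 60.0


class TestSepticTrajectory:
    def test_zero_drop_keeps_baseline(self, subject):
        cfg = SepsisTrajectoryConfig(r_sys_drop_fraction=0.0,
                                     r_pul_rise_fraction=0.0,
                                     hr_rise_fraction=0.0)
        traj = septic_trajectory(subject, cfg)
        for p in traj:
            assert p.R_sys == pytest.approx(subject.baseline.R_sys)
            assert p.R_pul == pytest.approx(subject.baseline.R_pul)

    def test_configured_drop_reached_at_two_hours(self, subject):
        traj = septic_trajectory(subject, SepsisTrajectoryConfig())
        t120 = traj[4]  # T0, T30, T60, T90, T120
        assert t120.R_sys == pytest.approx(0.58 * subject.baseline.R_sys,
                                           rel=1e-9)
        assert t120.R_pul == pytest.approx(1.5 * subject.baseline.R_pul,
                                           rel=1e-9)

    def test_responder_relaxes_back_toward_baseline(self, subject):
        traj = septic_trajectory(subject,
                                 SepsisTrajectoryConfig(responder=True))
        r = [p.R_sys for p in traj]
        assert r[-1] >= min(r)
        assert r[-1] > 0.75 * subject.baseline.R_sys

    def test_heart_rate_rises(self, subject):
        traj = septic_trajectory(subject, SepsisTrajectoryConfig())
        assert traj[-1].heart_rate > traj[0].heart_rate

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SepsisTrajectoryConfig(r_sys_drop_fraction=1.2)


class TestGenerateDataset:
    def test_noiseless_round_trip(self, single_timepoint):
        sp = single_timepoint.setpoints[0]
        truth = single_timepoint.truth_outputs[0]
        assert sp.MAP == pytest.approx(truth["MAP"], rel=5e-3)
        # the extractor smooths before the amplitude read-off, the stored
        # truth uses the raw trace: a small definitional gap remains
        assert sp.SV == pytest.approx(truth["SV"], rel=3e-2)
        assert sp.GEDV == pytest.approx(truth["LVEDV"] + truth["RVEDV"],
                                        rel=5e-3)

    def test_deterministic_output_files(self, subject, tmp_path):
        cfg = SepsisTrajectoryConfig(n_timepoints=1)
        for d in ("a", "b"):
            ds = generate_dataset(subject, cfg, beats=2, noise=True, seed=7)
            write_dataset(ds, tmp_path / d)
        f_a = (tmp_path / "a" / "waveforms_T0.csv").read_bytes()
        f_b = (tmp_path / "b" / "waveforms_T0.csv").read_bytes()
        assert f_a == f_b
        t_a = (tmp_path / "a" / "truth.json").read_bytes()
        assert t_a == (tmp_path / "b" / "truth.json").read_bytes()

    def test_noise_perturbs_but_preserves_truth(self, subject,
                                                single_timepoint):
        cfg = SepsisTrajectoryConfig(n_timepoints=1)
        noisy = generate_dataset(subject, cfg, noise=True, seed=11)
        clean_sp = single_timepoint.setpoints[0]
        assert noisy.setpoints[0].MAP != clean_sp.MAP
        assert noisy.truth_outputs[0]["MAP"] == pytest.approx(
            single_timepoint.truth_outputs[0]["MAP"])

    def test_rv_underestimation_scales_measured_amplitude_only(self, subject):
        cfg_full = SepsisTrajectoryConfig(n_timepoints=1)
        cfg_half = SepsisTrajectoryConfig(n_timepoints=1,
                                          rv_underestimation=0.5)
        full = generate_dataset(subject, cfg_full, noise=False, seed=1)
        half = generate_dataset(subject, cfg_half, noise=False, seed=1)
        amp_full = float(np.ptp(full.waveforms[0]["V_rv"]))
        amp_half = float(np.ptp(half.waveforms[0]["V_rv"]))
        assert amp_half == pytest.approx(0.5 * amp_full, rel=1e-9)
        assert half.truth_outputs[0]["RVEDV"] == pytest.approx(
            full.truth_outputs[0]["RVEDV"])

    def test_nine_timepoint_labels(self, subject):
        cfg = SepsisTrajectoryConfig()
        assert cfg.labels() == ["T0", "T30", "T60", "T90", "T120", "T150",
                                "T180", "T210", "T240"]
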