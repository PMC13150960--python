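"""The synthetic cohort generator: hypnograms, night synthesis, loss, cohorts."""

import numpy as np
import pytest

from patchsleep.containers import ArtifactMask, Hypnogram
from patchsleep.io_formats import read_hypnogram, read_manifest
from patchsleep.preprocess import quality_gate
from patchsleep.spectral import BANDS, band_power, relative_band_power, welch_psd
from patchsleep.synthetic import (CohortSpec, HypnogramParams, StageParams,
                                  default_hypnogram_params, default_stage_params,
                                  emulate_data_loss, generate_hypnogram, make_cohort,
                                  spec_from_yaml, spec_to_yaml, synthesize_night)

from conftest import make_recording


class TestGenerateHypnogram:
    def test_starts_awake_and_is_deterministic(self):
        a = generate_hypnogram(default_hypnogram_params(), 960, seed=1)
        b = generate_hypnogram(default_hypnogram_params(), 960, seed=1)
        assert a.stages[0] == "W"
        assert a.stages == b.stages
        assert a.n_epochs == 960

    def test_n3_fraction_near_dwell_expectation(self):
        # Monte-Carlo expectation (100 seeds at these defaults): N3 ~18% of TST
        hyp = generate_hypnogram(default_hypnogram_params(), 960, seed=1)
        sleep = [s for s in hyp.stages if s != "W"]
        n3_pct = 100.0 * sleep.count("N3") / len(sleep)
        assert abs(n3_pct - 18.0) <= 5.0

    def test_all_wake_parameterization(self):
        params = HypnogramParams(wake_latency_mean=1e6)
        hyp = generate_hypnogram(params, 10, seed=0)
        assert hyp.stages == ["W"] * 10

    @pytest.mark.parametrize("seed", range(5))
    def test_full_cycle_present_in_90_minutes(self, seed):
        hyp = generate_hypnogram(default_hypnogram_params(), 180, seed=seed)
        assert "N3" in hyp.stages and "REM" in hyp.stages

    def test_nonpositive_epochs_rejected(self):
        with pytest.raises(ValueError):
            generate_hypnogram(default_hypnogram_params(), 0, seed=0)


class TestSynthesizeNight:
    def test_spindle_counts_and_band_power(self):
        """All-N2, 2 spindles/min, 10 min: the event log is Poisson-consistent
        and the sigma band carries more power than an events-off rendering."""
        hyp = Hypnogram(["N2"] * 20)
        on = {"N2": StageParams(stage="N2", background_amp=12.0,
                                spindle_rate=2.0, spindle_amp=15.0)}
        off = {"N2": StageParams(stage="N2", background_amp=12.0,
                                 spindle_rate=2.0, spindle_amp=0.0)}
        rec_on, truth = synthesize_night(hyp, on, fs=100.0, seed=5)
        rec_off, _ = synthesize_night(hyp, off, fs=100.0, seed=5)
        n = len(truth.spindle_events)
        assert abs(n - 20) <= 3 * np.sqrt(20)  # Poisson(20) within 3 sigma
        p_on = band_power(welch_psd(rec_on.channel("EEG Ch1"), 100.0), 12.0, 16.0)
        p_off = band_power(welch_psd(rec_off.channel("EEG Ch1"), 100.0), 12.0, 16.0)
        assert p_on > p_off

    def test_zero_amplitude_equals_background_rendering(self):
        hyp = Hypnogram(["N2"] * 4 + ["N3"] * 4)
        params = {
            "N2": StageParams(stage="N2", spindle_rate=3.0, spindle_amp=0.0,
                              so_rate=1.0, so_amp=0.0),
            "N3": StageParams(stage="N3", so_rate=5.0, so_amp=0.0),
        }
        bg = {
            "N2": StageParams(stage="N2", spindle_rate=3.0, spindle_amp=0.0,
                              so_rate=1.0, so_amp=0.0),
            "N3": StageParams(stage="N3", so_rate=5.0, so_amp=0.0),
        }
        a, truth = synthesize_night(hyp, params, fs=100.0, seed=9)
        b, _ = synthesize_night(hyp, bg, fs=100.0, seed=9)
        assert np.array_equal(a.samples, b.samples)
        assert truth.so_events == [] and truth.spindle_events == []

    def test_dense_so_train_logged(self):
        hyp = Hypnogram(["N3"] * 20)  # 10 min
        params = {"N3": StageParams(stage="N3", background_amp=20.0,
                                    so_rate=5.0, so_amp=150.0)}
        _, truth = synthesize_night(hyp, params, fs=100.0, seed=2)
        assert len(truth.so_events) >= 40

    def test_unknown_stage_label_named(self):
        hyp = Hypnogram(["N2"])
        with pytest.raises(KeyError, match="N2"):
            synthesize_night(hyp, {"W": StageParams(stage="W")}, seed=0)

    def test_determinism(self):
        hyp = Hypnogram(["N2"] * 4)
        params = default_stage_params()
        a, _ = synthesize_night(hyp, params, fs=100.0, seed=3)
        b, _ = synthesize_night(hyp, params, fs=100.0, seed=3)
        assert np.array_equal(a.samples, b.samples)

    def test_background_band_fractions_stable_across_seeds(self):
        """Background-only renderings share relative band powers within ±0.05."""
        hyp = Hypnogram(["N2"] * 4)
        params = {"N2": StageParams(stage="N2", background_amp=12.0)}
        fractions = {k: [] for k in BANDS}
        for seed in range(20):
            rec, _ = synthesize_night(hyp, params, fs=100.0, seed=seed)
            rel = relative_band_power(welch_psd(rec.channel("EEG Ch1"), 100.0))
            for k, v in rel.items():
                fractions[k].append(v)
        for k, vals in fractions.items():
            assert np.ptp(vals) < 0.1  # ±0.05 about the per-band center

    def test_event_energy_exceeds_local_background(self, rng):
        """Band-passed energy at an injected spindle's time beats the night median."""
        from patchsleep.preprocess import bandpass_array

        hyp = Hypnogram(["N2"] * 20)
        params = {"N2": StageParams(stage="N2", background_amp=12.0,
                                    spindle_rate=2.5, spindle_amp=30.0)}
        rec, truth = synthesize_night(hyp, params, fs=100.0, seed=13)
        filt = bandpass_array(rec.channel("EEG Ch1"), 100.0, 12.0, 16.0)
        power = filt**2
        med = np.median(power)
        checked = 0
        for (t0, d0, _) in truth.spindle_events[:50]:
            a, b = int(t0 * 100), int((t0 + d0) * 100)
            assert power[a:b].mean() > med
            checked += 1
        assert checked > 10


class TestEmulateDataLoss:
    def test_usable_identity(self):
        rec = make_recording(duration_s=60.0)
        out, spans = emulate_data_loss(rec, "usable", seed=0)
        assert out is rec and spans == []

    def test_not_worn_empty(self):
        out, _ = emulate_data_loss(make_recording(), "not_worn", seed=0)
        assert out.n_samples == 0

    def test_bluetooth_truncates_below_gate(self):
        rec = make_recording(duration_s=8 * 3600.0, fs=2.0, seed=1)
        out, _ = emulate_data_loss(rec, "bluetooth", seed=1)
        assert out.duration_s < 5 * 3600.0

    @pytest.mark.parametrize("seed", range(20))
    def test_adhesion_loss_fails_quality_gate(self, seed):
        rec = make_recording(duration_s=8 * 3600.0, fs=2.0, seed=seed)
        out, spans = emulate_data_loss(rec, "poor_reference_adhesion", seed=seed)
        keep, reason = quality_gate(out)
        assert not keep and reason == "short_recording"
        assert spans  # corrupted spans reported

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="disposition"):
            emulate_data_loss(make_recording(), "solar_flare", seed=0)


class TestMakeCohort:
    @staticmethod
    def _tiny_spec(**kw):
        defaults = dict(n_per_group=2, nights_per_participant=2, epochs_per_night=4,
                        fs=100.0, seed=7,
                        loss_probs={"usable": 1.0, "not_worn": 0.0,
                                    "poor_reference_adhesion": 0.0, "bluetooth": 0.0})
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_counts_and_all_usable(self, tmp_path):
        manifest = make_cohort(self._tiny_spec(), tmp_path)
        assert len(manifest) == 8
        assert (manifest["disposition"] == "usable").all()
        assert len(list(tmp_path.glob("*.edf"))) == 8
        assert len(list(tmp_path.glob("*.truth.csv"))) == 8
        hyp = read_hypnogram(tmp_path / manifest.iloc[0]["hypnogram_path"])
        assert hyp.n_epochs == 4

    def test_degenerate_loss_probability(self, tmp_path):
        spec = self._tiny_spec(
            loss_probs={"usable": 0.0, "not_worn": 0.0,
                        "poor_reference_adhesion": 1.0, "bluetooth": 0.0}
        )
        manifest = make_cohort(spec, tmp_path)
        assert (manifest["disposition"] == "poor_reference_adhesion").all()

    def test_manifest_byte_identical_across_runs(self, tmp_path):
        make_cohort(self._tiny_spec(), tmp_path / "a")
        make_cohort(self._tiny_spec(), tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
               (tmp_path / "b" / "manifest.csv").read_bytes()

    def test_manifest_readable_and_valid(self, tmp_path):
        make_cohort(self._tiny_spec(), tmp_path)
        df = read_manifest(tmp_path / "manifest.csv")
        assert df["participant_id"].nunique() == 4

    def test_invalid_loss_probs_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            CohortSpec(loss_probs={"usable": 0.5, "not_worn": 0.0,
                                   "poor_reference_adhesion": 0.0, "bluetooth": 0.0})

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = self._tiny_spec()
        spec_to_yaml(spec, tmp_path / "spec.yaml")
        back = spec_from_yaml(tmp_path / "spec.yaml")
        assert back == spec
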