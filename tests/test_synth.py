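"""Synthetic-session generator: designs, populations, traces, kernels."""

import numpy as np
import pandas as pd
import pytest

from axonspace import preprocess, synth
from axonspace.geometry import ArrayGeometry, Position, angular_distance, default_array
from axonspace.synth import AxonSpec, SessionConfig, TuningSpec


class TestStimLog:
    def test_block_randomized_balance(self):
        cfg = SessionConfig(n_reps=3, seed=0)
        log = synth.generate_stim_log(cfg)
        for m in cfg.modalities:
            counts = (
                log[log.modality == m]
                .groupby(["azimuth_deg", "elevation_deg"])
                .size()
            )
            assert len(counts) == 39
            assert (counts == 3).all()
        assert np.all(np.diff(log.onset_time_s) > 0)

    def test_blocks_are_permutations(self):
        cfg = SessionConfig(n_reps=4, modalities=("auditory",), seed=3)
        log = synth.generate_stim_log(cfg)
        n_pos = cfg.geometry.n_positions
        for b in range(4):
            block = log.iloc[b * n_pos : (b + 1) * n_pos]
            assert (
                block.groupby(["azimuth_deg", "elevation_deg"]).size() == 1
            ).all()

    def test_degenerate_design(self):
        cfg = SessionConfig(
            geometry=ArrayGeometry((0.0,), (0.0,)),
            n_reps=1,
            modalities=("auditory",),
        )
        assert len(synth.generate_stim_log(cfg)) == 1

    def test_determinism(self):
        cfg = SessionConfig(n_reps=2, seed=11)
        pd.testing.assert_frame_equal(
            synth.generate_stim_log(cfg), synth.generate_stim_log(cfg)
        )


class TestPopulation:
    def test_direct_construction(self):
        specs, table = synth.generate_population(
            10, tuning_mixture={"gaussian": 1.0}, width_range=(30, 30), seed=0
        )
        assert len(specs) == 10
        assert all(s.tuning.kind == "gaussian" for s in specs)
        assert (table.width_deg == 30).all()

    def test_mixture_proportions_binomial(self):
        mix = {"gaussian": 0.5, "flat_responsive": 0.3, "nonresponsive": 0.2}
        _, table = synth.generate_population(1000, tuning_mixture=mix, seed=1)
        for kind, p in mix.items():
            n = (table.kind == kind).sum()
            sd = np.sqrt(1000 * p * (1 - p))
            assert abs(n - 1000 * p) < 3 * sd

    def test_determinism(self):
        a = synth.generate_population(20, seed=5)[1]
        b = synth.generate_population(20, seed=5)[1]
        pd.testing.assert_frame_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_population(0)


class TestTraces:
    def test_nonresponsive_axon_null(self):
        cfg = SessionConfig(modalities=("auditory",), n_reps=5, seed=4)
        log = synth.generate_stim_log(cfg)
        spec = [AxonSpec(axon_id=0, tuning=TuningSpec("nonresponsive", amplitude=0.0))]
        traces, _ = synth.simulate_traces(log, spec, cfg)
        tensor = preprocess.segment_and_dff(traces, log)
        resp = preprocess.trial_response(tensor)
        n = resp.size
        assert abs(resp.mean()) < 3 * cfg.noise_sd / np.sqrt(n)

    def test_tuned_axon_peaks_at_center(self):
        cfg = SessionConfig(
            modalities=("auditory",), n_reps=3, noise_sd=0.0, gain_sigma=0.0,
            isi_s=6.0, seed=5,  # long ISI isolates trials from indicator carry-over
        )
        log = synth.generate_stim_log(cfg)
        spec = [
            AxonSpec(
                axon_id=0,
                tuning=TuningSpec("gaussian", Position(40.0, 0.0), 25.0, 0.5),
            )
        ]
        traces, _ = synth.simulate_traces(log, spec, cfg)
        tensor = preprocess.segment_and_dff(traces, log)
        resp = preprocess.trial_response(tensor)[0]
        means = (
            pd.DataFrame(
                {"r": resp, "az": log.azimuth_deg, "el": log.elevation_deg}
            )
            .groupby(["az", "el"])["r"]
            .mean()
        )
        assert means.idxmax() == (40.0, 0.0)

    def test_within_axon_correlation_calibration(self):
        # 2 boutons sharing a latent at target r = 0.6 over 780 trials
        cfg = SessionConfig(modalities=("auditory",), n_reps=20, seed=6)
        rng = np.random.default_rng(6)
        log = synth.generate_stim_log(cfg, rng=rng)
        spec = [
            AxonSpec(
                axon_id=0,
                tuning=TuningSpec("gaussian", Position(40, 0), 30.0, 0.5),
                n_boutons=2,
                within_axon_corr=0.6,
            )
        ]
        traces, _ = synth.simulate_traces(log, spec, cfg, rng=rng)
        tensor = preprocess.segment_and_dff(traces, log)
        resp = preprocess.trial_response(tensor)
        assert resp.shape[1] == 780
        r = np.corrcoef(resp)[0, 1]
        assert 0.45 <= r <= 0.75

    def test_deconvolution_inverts_kernel(self):
        cfg = SessionConfig(
            modalities=("auditory",), n_reps=2, noise_sd=0.0, seed=7
        )
        log = synth.generate_stim_log(cfg)
        spec = [
            AxonSpec(
                axon_id=0, tuning=TuningSpec("gaussian", Position(0, 0), 30.0, 0.5)
            )
        ]
        traces, _ = synth.simulate_traces(log, spec, cfg)
        dff = traces.F / cfg.baseline_f - 1.0
        recovered = synth.deconvolve(dff, cfg.kernel_gamma)
        assert np.max(np.abs(recovered - traces.events)) < 1e-6

    def test_monotone_falloff_with_distance(self):
        cfg = SessionConfig(
            modalities=("auditory",), n_reps=2, noise_sd=0.0, gain_sigma=0.0, seed=8
        )
        log = synth.generate_stim_log(cfg)
        center = Position(40.0, 0.0)
        spec = [AxonSpec(axon_id=0, tuning=TuningSpec("gaussian", center, 30.0, 0.5))]
        traces, _ = synth.simulate_traces(log, spec, cfg)
        tensor = preprocess.segment_and_dff(traces, log)
        resp = preprocess.trial_response(tensor)[0]
        d = np.array(
            [
                angular_distance(center, Position(a, e))
                for a, e in zip(log.azimuth_deg, log.elevation_deg)
            ]
        )
        slope = np.polyfit(d, resp, 1)[0]
        assert slope < 0

    def test_determinism(self):
        cfg = SessionConfig(modalities=("auditory",), n_reps=2, seed=9)
        log = synth.generate_stim_log(cfg)
        spec, _ = synth.generate_population(5, seed=9)
        t1, _ = synth.simulate_traces(log, spec, cfg)
        t2, _ = synth.simulate_traces(log, spec, cfg)
        np.testing.assert_array_equal(t1.F, t2.F)


class TestV1Population:
    def test_population_map_peaks_at_rf_center(self):
        cfg = SessionConfig(
            modalities=("visual",), n_reps=4, noise_sd=0.01, gain_sigma=0.0, seed=10
        )
        traces, log, truth = synth.simulate_v1_population(
            Position(50, 0), rf_width=20, center_jitter=0.0, n_neurons=10,
            config=cfg, seed=10,
        )
        tensor = preprocess.segment_and_dff(traces, log)
        resp = preprocess.trial_response(tensor).mean(axis=0)
        df = pd.DataFrame(
            {"r": resp, "az": log.azimuth_deg, "el": log.elevation_deg}
        )
        assert df.groupby(["az", "el"])["r"].mean().idxmax() == (50.0, 0.0)

    def test_jitter_averages_out(self):
        _, _, truth = synth.simulate_v1_population(
            Position(50, 0), center_jitter=5.0, n_neurons=50, seed=11
        )
        assert abs(truth.rois.center_az.mean() - 50.0) < 2.0
        assert abs(truth.rois.center_el.mean() - 0.0) < 2.0


class TestAVSession:
    def test_condition_repetitions(self):
        _, log, _ = synth.simulate_av_session(seed=12)
        counts = log.groupby(
            ["condition", "led_az_deg", "offset_az_deg", "offset_el_deg"],
            dropna=False,
        ).size()
        assert (counts == 7).all()

    def test_unit_gain_is_null(self):
        traces, log, truth = synth.simulate_av_session(av_gain=1.0, seed=13)
        tensor = preprocess.segment_and_dff(traces, log)
        resp = preprocess.trial_response(tensor, (0.0, 1.0 + 1 / 6))
        v = resp[:, log.condition == "V"].mean()
        av = resp[:, log.condition == "AV"].mean()
        assert abs(av - v) < 0.05 * v

    def test_gain_recovered(self):
        traces, log, truth = synth.simulate_av_session(av_gain=1.5, seed=14)
        tensor = preprocess.segment_and_dff(traces, log)
        resp = preprocess.trial_response(tensor, (0.0, 1.0 + 1 / 6))
        keep = log.offset_el_deg.isna() | (log.offset_el_deg == 0)
        v = resp[:, (log.condition == "V").to_numpy()].mean()
        av = resp[:, ((log.condition == "AV") & keep).to_numpy()].mean()
        assert 1.4 <= av / v <= 1.6


def test_kernel_attenuation_matches_rendered_response():
    """Window-mean of a rendered noise-free unit response equals the
    closed-form discrete-kernel attenuation factor."""
    cfg = SessionConfig(
        modalities=("auditory",),
        geometry=ArrayGeometry((0.0,), (0.0,)),
        n_reps=2,
        noise_sd=0.0,
        gain_sigma=0.0,
        isi_s=20.0,  # isolate trials so no carry-over
        seed=15,
    )
    log = synth.generate_stim_log(cfg)
    spec = [AxonSpec(axon_id=0, tuning=TuningSpec("flat_responsive", amplitude=1.0))]
    traces, _ = synth.simulate_traces(log, spec, cfg)
    tensor = preprocess.segment_and_dff(traces, log)
    resp = preprocess.trial_response(tensor)
    kappa = synth.kernel_attenuation(cfg)
    assert np.allclose(resp, kappa, atol=1e-6)
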