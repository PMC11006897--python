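"""Synthetic two-photon sessions with known ground truth.

The generator emulates the statistical structure of calcium-imaging
recordings from axonal boutons and somata during free-field speaker/LED
stimulation: block-randomized interleaved auditory/visual stimulus
sequences, Gaussian spatial tuning of varying width (plus flat-responsive
and nonresponsive units), multiple boutons per axon sharing a trial-level
latent signal with a controllable within-axon Pearson correlation, a slow
mono-exponential indicator kernel sampled at ~6 Hz, and additive white
noise. Every generator is bit-reproducible given its seed.

Signal model, per trial t and axon a:

    latent_a(t) = amplitude_a * G(position_t; center_a, width_a) * gain_a(t)

where ``G`` is an unnormalized Gaussian falloff in the (azimuth, elevation)
degree plane and ``gain`` a lognormal trial gain. Each bouton adds
independent trial noise calibrated in closed form so the expected
bouton-bouton Pearson correlation across trials equals the axon's
``within_axon_corr``: with v = Var(latent) and w the noise variance,
corr = v / (v + w), hence w = v (1 - r) / r.

Trial signals are placed as boxcars over the stimulus window in a
deconvolved-event trace s[n] and passed through the normalized first-order
indicator filter

    c[n] = g c[n-1] + (1 - g) s[n],     g = exp(-1 / (frame_rate * tau)),

so a sustained boxcar of height h converges to fluorescence amplitude h and
:func:`deconvolve` inverts the filter exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import STIM_LOG_COLUMNS, GroundTruth, RoiTraces
from .geometry import ArrayGeometry, Position, default_array

__all__ = [
    "TuningSpec",
    "AxonSpec",
    "SessionConfig",
    "generate_stim_log",
    "generate_population",
    "simulate_traces",
    "simulate_v1_population",
    "simulate_av_session",
    "deconvolve",
    "kernel_attenuation",
    "frame_noise_for_snr",
    "make_tuned_session",
    "make_clustering_session",
]

TUNING_KINDS = ("gaussian", "flat_responsive", "nonresponsive")


@dataclass(frozen=True)
class TuningSpec:
    """Spatial tuning of one unit.

    kind : 'gaussian' (Gaussian falloff around ``center`` with s.d.
        ``width`` degrees), 'flat_responsive' (equal response at every
        position) or 'nonresponsive' (amplitude treated as zero).
    amplitude : peak response in ΔF/F units.
    """

    kind: str
    center: Position = Position(0.0, 0.0)
    width: float = 30.0
    amplitude: float = 0.5
    modality: str = "auditory"

    def __post_init__(self) -> None:
        if self.kind not in TUNING_KINDS:
            raise ValueError(f"unknown tuning kind {self.kind!r}")
        if self.kind == "gaussian" and self.width <= 0:
            raise ValueError("gaussian tuning requires width > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def response_at(self, azimuth: float, elevation: float) -> float:
        if self.kind == "nonresponsive":
            return 0.0
        if self.kind == "flat_responsive":
            return self.amplitude
        d2 = (azimuth - self.center.azimuth) ** 2 + (
            elevation - self.center.elevation
        ) ** 2
        return self.amplitude * math.exp(-d2 / (2.0 * self.width**2))


@dataclass(frozen=True)
class AxonSpec:
    axon_id: int
    tuning: TuningSpec
    n_boutons: int = 1
    within_axon_corr: float = 0.6

    def __post_init__(self) -> None:
        if self.n_boutons < 1:
            raise ValueError("n_boutons must be >= 1")
        if not 0.0 <= self.within_axon_corr <= 1.0:
            raise ValueError("within_axon_corr must be in [0, 1]")


@dataclass(frozen=True)
class SessionConfig:
    """Acquisition and stimulus-timing parameters of a synthetic session.

    Defaults follow the recorded sessions: 20 repetitions per trial type,
    1 s stimuli separated by 2 s offset-to-onset gaps, ~6 Hz frame rate,
    and a slow indicator with 1 s mono-exponential decay.
    """

    geometry: ArrayGeometry = field(default_factory=default_array)
    n_reps: int = 20
    modalities: tuple[str, ...] = ("auditory", "visual")
    frame_rate: float = 6.0
    stim_duration_s: float = 1.0
    isi_s: float = 2.0
    indicator_tau_s: float = 1.0
    noise_sd: float = 0.05
    gain_sigma: float = 0.25
    baseline_f: float = 1.0
    start_pad_s: float = 3.0
    end_pad_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def kernel_gamma(self) -> float:
        return math.exp(-1.0 / (self.frame_rate * self.indicator_tau_s))


# ---------------------------------------------------------------------------
# Stimulus sequence
# ---------------------------------------------------------------------------


def generate_stim_log(config: SessionConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Block-randomized interleaved stimulus sequence.

    Within each of ``n_reps`` blocks every grid position of each modality
    appears exactly once; the randomization sequences of the modalities are
    independent, and their trials alternate. Onsets are spaced
    ``stim_duration_s + isi_s`` apart starting at ``start_pad_s``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pts = config.geometry.position_array()
    n_pos = pts.shape[0]
    # per-modality block-randomized position order
    orders = {
        m: np.concatenate(
            [rng.permutation(n_pos) for _ in range(config.n_reps)]
        )
        for m in config.modalities
    }
    rows = []
    period = config.stim_duration_s + config.isi_s
    n_total = n_pos * config.n_reps * len(config.modalities)
    for t in range(n_total):
        m = config.modalities[t % len(config.modalities)]
        pos_i = orders[m][t // len(config.modalities)]
        onset = config.start_pad_s + t * period
        rows.append(
            {
                "trial": t,
                "onset_time_s": onset,
                "onset_frame": int(math.ceil(onset * config.frame_rate - 1e-9)),
                "modality": m,
                "azimuth_deg": pts[pos_i, 0],
                "elevation_deg": pts[pos_i, 1],
                "intensity": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=STIM_LOG_COLUMNS)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------


def generate_population(
    n_axons: int,
    boutons_per_axon: int | tuple[int, int] = (2, 4),
    tuning_mixture: Optional[dict[str, float]] = None,
    width_range: tuple[float, float] = (15.0, 60.0),
    amplitude_range: tuple[float, float] = (0.3, 0.8),
    within_axon_corr: float = 0.6,
    geometry: Optional[ArrayGeometry] = None,
    modality: str = "auditory",
    seed: int = 0,
) -> tuple[list[AxonSpec], pd.DataFrame]:
    """Draw a reproducible axon population.

    ``tuning_mixture`` gives proportions over tuning kinds (default
    0.5 gaussian / 0.3 flat_responsive / 0.2 nonresponsive); gaussian
    centers are uniform over the geometry's az/el bounding box, widths and
    amplitudes uniform over the stated ranges. Returns the specs plus a
    per-axon ground-truth table.
    """
    if n_axons < 1:
        raise ValueError("n_axons must be >= 1")
    mixture = tuning_mixture or {
        "gaussian": 0.5,
        "flat_responsive": 0.3,
        "nonresponsive": 0.2,
    }
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise ValueError("tuning_mixture proportions must sum to 1")
    geometry = geometry or default_array()
    rng = np.random.default_rng(seed)
    kinds = rng.choice(
        list(mixture.keys()), size=n_axons, p=list(mixture.values())
    )
    az_lo, az_hi = min(geometry.azimuths), max(geometry.azimuths)
    el_lo, el_hi = min(geometry.elevations), max(geometry.elevations)
    specs: list[AxonSpec] = []
    rows = []
    for a in range(n_axons):
        if isinstance(boutons_per_axon, int):
            nb = boutons_per_axon
        else:
            nb = int(rng.integers(boutons_per_axon[0], boutons_per_axon[1] + 1))
        center = Position(
            float(rng.uniform(az_lo, az_hi)), float(rng.uniform(el_lo, el_hi))
        )
        amp = 0.0 if kinds[a] == "nonresponsive" else float(
            rng.uniform(*amplitude_range)
        )
        tuning = TuningSpec(
            kind=str(kinds[a]),
            center=center,
            width=float(rng.uniform(*width_range)),
            amplitude=amp,
            modality=modality,
        )
        specs.append(
            AxonSpec(
                axon_id=a,
                tuning=tuning,
                n_boutons=nb,
                within_axon_corr=within_axon_corr,
            )
        )
        rows.append(
            {
                "axon_id": a,
                "kind": tuning.kind,
                "center_az": center.azimuth,
                "center_el": center.elevation,
                "width_deg": tuning.width,
                "amplitude": amp,
                "modality": modality,
                "n_boutons": nb,
                "within_axon_corr": within_axon_corr,
            }
        )
    return specs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------


def _indicator_filter(signal: np.ndarray, gamma: float) -> np.ndarray:
    """Normalized first-order (mono-exponential) indicator filter."""
    out = np.empty_like(signal, dtype=float)
    acc = np.zeros(signal.shape[:-1], dtype=float)
    g1 = 1.0 - gamma
    for n in range(signal.shape[-1]):
        acc = gamma * acc + g1 * signal[..., n]
        out[..., n] = acc
    return out


def deconvolve(fluo: np.ndarray, gamma: float) -> np.ndarray:
    """Exact inverse of the first-order indicator filter."""
    fluo = np.asarray(fluo, dtype=float)
    prev = np.concatenate(
        [np.zeros(fluo.shape[:-1] + (1,)), fluo[..., :-1]], axis=-1
    )
    return (fluo - gamma * prev) / (1.0 - gamma)


def _stim_frames(onset_frame: int, config: SessionConfig) -> slice:
    n = max(1, int(round(config.stim_duration_s * config.frame_rate)))
    return slice(onset_frame, onset_frame + n)


def _n_frames(log: pd.DataFrame, config: SessionConfig) -> int:
    last = float(log["onset_time_s"].iloc[-1]) + config.stim_duration_s
    return int(math.ceil((last + config.end_pad_s) * config.frame_rate))


def simulate_traces(
    stim_log: pd.DataFrame,
    population: Sequence[AxonSpec],
    config: SessionConfig,
    rng: Optional[np.random.Generator] = None,
    with_neuropil: bool = False,
    mouse_ids: Optional[Sequence[str]] = None,
) -> tuple[RoiTraces, GroundTruth]:
    """Render a bouton population into fluorescence and event traces.

    Returns ``RoiTraces`` with F, an exactly-invertible fluorescence signal
    (white frame noise added after the indicator filter), and the
    pre-kernel deconvolved-event traces; plus the per-ROI ground truth.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_frames = _n_frames(stim_log, config)
    az = stim_log["azimuth_deg"].to_numpy(float)
    el = stim_log["elevation_deg"].to_numpy(float)
    mod = stim_log["modality"].to_numpy()
    onset_frames = stim_log["onset_frame"].to_numpy(int)
    n_trials = len(stim_log)

    n_rois = sum(a.n_boutons for a in population)
    events = np.zeros((n_rois, n_frames))
    rows = []
    roi = 0
    for axon in population:
        tun = axon.tuning
        base = np.array(
            [
                tun.response_at(az[t], el[t]) if mod[t] == tun.modality else 0.0
                for t in range(n_trials)
            ]
        )
        gains = (
            rng.lognormal(mean=-config.gain_sigma**2 / 2.0, sigma=config.gain_sigma, size=n_trials)
            if config.gain_sigma > 0
            else np.ones(n_trials)
        )
        latent = base * gains
        v = float(np.var(latent))
        r = min(max(axon.within_axon_corr, 1e-2), 1.0)
        # the shared-latent/private-noise split only applies to multi-bouton
        # axons; a single bouton carries the latent exactly
        w_sd = (
            math.sqrt(v * (1.0 - r) / r) if (v > 0 and axon.n_boutons > 1) else 0.0
        )
        for _ in range(axon.n_boutons):
            resp = latent + (
                rng.normal(0.0, w_sd, size=n_trials) if w_sd > 0 else 0.0
            )
            for t in range(n_trials):
                if resp[t] != 0.0:
                    events[roi, _stim_frames(onset_frames[t], config)] += resp[t]
            rows.append(
                {
                    "roi_id": f"roi{roi:04d}",
                    "axon_id": axon.axon_id,
                    "kind": tun.kind,
                    "center_az": tun.center.azimuth,
                    "center_el": tun.center.elevation,
                    "width_deg": tun.width,
                    "amplitude": tun.amplitude,
                    "modality": tun.modality,
                    "responsive": tun.kind != "nonresponsive" and tun.amplitude > 0,
                }
            )
            roi += 1

    conv = _indicator_filter(events, config.kernel_gamma)
    F = config.baseline_f * (1.0 + conv)
    if config.noise_sd > 0:
        F = F + rng.normal(0.0, config.noise_sd * config.baseline_f, size=F.shape)
    Fneu = None
    if with_neuropil:
        # weak shared neuropil signal at 80% of the cellular baseline
        shared = conv.mean(axis=0, keepdims=True)
        Fneu = 0.8 * config.baseline_f * (1.0 + 0.3 * shared)
        Fneu = np.broadcast_to(Fneu, F.shape).copy()
        if config.noise_sd > 0:
            Fneu += rng.normal(0.0, 0.3 * config.noise_sd, size=F.shape)

    rois = pd.DataFrame(rows)
    if mouse_ids is not None:
        rois["mouse_id"] = list(mouse_ids)
    traces = RoiTraces(
        F=F,
        Fneu=Fneu,
        events=events,
        frame_rate=config.frame_rate,
        roi_ids=list(rois["roi_id"]),
    )
    axon_rows = pd.DataFrame(
        [
            {
                "axon_id": a.axon_id,
                "kind": a.tuning.kind,
                "center_az": a.tuning.center.azimuth,
                "center_el": a.tuning.center.elevation,
                "width_deg": a.tuning.width,
                "amplitude": a.tuning.amplitude,
                "n_boutons": a.n_boutons,
                "within_axon_corr": a.within_axon_corr,
            }
            for a in population
        ]
    )
    return traces, GroundTruth(rois=rois, axons=axon_rows)


# ---------------------------------------------------------------------------
# Kernel bookkeeping and SNR calibration
# ---------------------------------------------------------------------------


def kernel_attenuation(
    config: SessionConfig, window: tuple[float, float] = (0.2, 1.8)
) -> float:
    """Window-mean of the indicator-filtered unit boxcar.

    The trial response of a unit-amplitude stimulus is not 1 but this
    factor, because the slow indicator integrates the boxcar and the
    response window extends past stimulus offset. Computed by exact
    enumeration of the discrete filter.
    """
    pad = int(math.ceil(5 * config.frame_rate * config.indicator_tau_s)) + 8
    onset = pad
    n = onset + pad
    s = np.zeros(n)
    s[_stim_frames(onset, config)] = 1.0
    c = _indicator_filter(s[None, :], config.kernel_gamma)[0]
    k = np.arange(n) - onset
    t = k / config.frame_rate
    mask = (t >= window[0]) & (t < window[1])
    return float(c[mask].mean())


def frame_noise_for_snr(
    config: SessionConfig,
    amplitude: float,
    snr: float,
    response_window: tuple[float, float] = (0.2, 1.8),
    baseline_window: tuple[float, float] = (-1.0, 0.0),
) -> float:
    """Frame-noise s.d. giving a target trial-response SNR.

    SNR is defined at the trial-response level: the window-mean ΔF/F at the
    tuning peak (kernel attenuation included) divided by the s.d. of the
    window-mean under white frame noise, accounting for baseline
    subtraction.
    """
    kappa = kernel_attenuation(config, response_window)
    n_resp = max(
        1,
        int(
            np.sum(
                (np.arange(0, 1000) / config.frame_rate >= response_window[0])
                & (np.arange(0, 1000) / config.frame_rate < response_window[1])
            )
        ),
    )
    n_base = max(
        1, int(round((baseline_window[1] - baseline_window[0]) * config.frame_rate))
    )
    per_trial_factor = math.sqrt(1.0 / n_resp + 1.0 / n_base)
    return kappa * amplitude / (snr * per_trial_factor)


# ---------------------------------------------------------------------------
# V1 somata and audiovisual sessions
# ---------------------------------------------------------------------------


def simulate_v1_population(
    rf_center: Position,
    rf_width: float = 20.0,
    center_jitter: float = 5.0,
    n_neurons: int = 50,
    config: Optional[SessionConfig] = None,
    amplitude: float = 0.5,
    seed: int = 0,
) -> tuple[RoiTraces, pd.DataFrame, GroundTruth]:
    """Simulate V1 somata with similar 2D Gaussian visual RFs.

    Each neuron's RF center is the population center plus isotropic normal
    jitter (s.d. ``center_jitter`` degrees). Neuropil traces are included so
    the somatic inclusion filters can be exercised. Returns (traces,
    stimulus log, ground truth) with the true population RF in
    ``ground_truth.extra``.
    """
    config = config or SessionConfig(modalities=("visual",), seed=seed)
    rng = np.random.default_rng(seed)
    log = generate_stim_log(config, rng=rng)
    specs = []
    for i in range(n_neurons):
        c = Position(
            float(np.clip(rf_center.azimuth + rng.normal(0, center_jitter), -180, 180)),
            float(np.clip(rf_center.elevation + rng.normal(0, center_jitter), -90, 90)),
        )
        specs.append(
            AxonSpec(
                axon_id=i,
                tuning=TuningSpec(
                    kind="gaussian",
                    center=c,
                    width=rf_width,
                    amplitude=amplitude,
                    modality="visual",
                ),
                n_boutons=1,
                within_axon_corr=1.0,
            )
        )
    traces, truth = simulate_traces(log, specs, config, rng=rng, with_neuropil=True)
    truth.extra["rf_center"] = (rf_center.azimuth, rf_center.elevation)
    truth.extra["rf_width"] = rf_width
    return traces, log, truth


AV_SPEAKER_OFFSETS = ((-40.0, 0.0), (-20.0, 0.0), (0.0, 0.0), (20.0, 0.0), (40.0, 0.0))
AV_ELEVATION_OFFSETS = ((0.0, -20.0), (0.0, 20.0))


def simulate_av_session(
    rf_center: Position = Position(45.0, 0.0),
    speaker_offsets: tuple[tuple[float, float], ...] = AV_SPEAKER_OFFSETS,
    loudness_levels: tuple[float, ...] = (85.0,),
    brightness_levels: tuple[float, ...] = (11.4,),
    av_gain: float = 1.5,
    config: Optional[SessionConfig] = None,
    n_neurons: int = 40,
    n_mice: int = 5,
    n_reps: int = 7,
    v_amplitude: float = 0.5,
    a_amplitude: float = 0.08,
    rf_width: float = 20.0,
    include_elevation_speakers: bool = True,
    n_leds: int = 2,
    seed: int = 0,
) -> tuple[RoiTraces, pd.DataFrame, GroundTruth]:
    """Simulate an audiovisual V1 somata session.

    Conditions: V (LED flash at one of ``n_leds`` adjacent LEDs inside the
    population RF), A (sound from a speaker at an azimuth/elevation offset
    from the target LED), and AV (both). By construction the visual
    response follows each neuron's RF, the auditory response is a small
    offset-independent baseline, and the AV response is the V response
    scaled by ``av_gain`` independent of speaker offset — the generative
    null for the offset analyses. Each condition combination is repeated
    ``n_reps`` times (7 in the recorded design). Defaults differ from the
    RF-mapping design: the inter-stimulus interval is 5 s (the pacing
    implied by the recorded AV session durations) and the indicator decay
    is 0.4 s, emulating the fast indicator used for the somatic AV
    recordings, so fluorescence from one trial has fully decayed before
    the next.
    """
    config = config or SessionConfig(isi_s=5.0, indicator_tau_s=0.4, seed=seed)
    rng = np.random.default_rng(seed)
    offsets = list(speaker_offsets) + (
        list(AV_ELEVATION_OFFSETS) if include_elevation_speakers else []
    )
    led_az = [rf_center.azimuth + 10.0 * k for k in range(n_leds)]

    combos: list[dict] = []
    for b in brightness_levels:
        for led in led_az:
            combos.append(
                {"condition": "V", "led_az_deg": led, "offset_az_deg": np.nan,
                 "offset_el_deg": np.nan, "loudness_db": np.nan, "brightness_cdm2": b}
            )
    for l in loudness_levels:
        for oaz, oel in offsets:
            combos.append(
                {"condition": "A", "led_az_deg": np.nan, "offset_az_deg": oaz,
                 "offset_el_deg": oel, "loudness_db": l, "brightness_cdm2": np.nan}
            )
    for b in brightness_levels:
        for l in loudness_levels:
            for led in led_az:
                for oaz, oel in offsets:
                    combos.append(
                        {"condition": "AV", "led_az_deg": led, "offset_az_deg": oaz,
                         "offset_el_deg": oel, "loudness_db": l, "brightness_cdm2": b}
                    )
    trial_specs = combos * n_reps
    order = rng.permutation(len(trial_specs))
    period = config.stim_duration_s + config.isi_s
    rows = []
    for t, idx in enumerate(order):
        spec = dict(trial_specs[idx])
        onset = config.start_pad_s + t * period
        spec.update(
            trial=t,
            onset_time_s=onset,
            onset_frame=int(math.ceil(onset * config.frame_rate - 1e-9)),
            modality="av",
            azimuth_deg=spec["offset_az_deg"],
            elevation_deg=spec["offset_el_deg"],
            intensity=spec["loudness_db"],
        )
        rows.append(spec)
    log = pd.DataFrame(rows)

    # neuron RFs jittered around the population center
    centers = [
        (
            rf_center.azimuth + rng.normal(0, 4.0),
            rf_center.elevation + rng.normal(0, 4.0),
        )
        for _ in range(n_neurons)
    ]
    mouse_ids = [f"mouse{m % n_mice}" for m in range(n_neurons)]

    n_frames = _n_frames(log, config)
    events = np.zeros((n_neurons, n_frames))
    cond = log["condition"].to_numpy()
    led_col = log["led_az_deg"].to_numpy(float)
    onset_frames = log["onset_frame"].to_numpy(int)
    for i, (caz, cel) in enumerate(centers):
        for t in range(len(log)):
            if cond[t] == "A":
                resp = a_amplitude
            else:
                d2 = (led_col[t] - caz) ** 2 + (0.0 - cel) ** 2
                v = v_amplitude * math.exp(-d2 / (2.0 * rf_width**2))
                resp = v * (av_gain if cond[t] == "AV" else 1.0)
            resp *= float(
                rng.lognormal(-config.gain_sigma**2 / 2, config.gain_sigma)
                if config.gain_sigma > 0
                else 1.0
            )
            if resp != 0.0:
                events[i, _stim_frames(onset_frames[t], config)] += resp
    conv = _indicator_filter(events, config.kernel_gamma)
    F = config.baseline_f * (1.0 + conv)
    if config.noise_sd > 0:
        F = F + rng.normal(0.0, config.noise_sd * config.baseline_f, size=F.shape)
    shared = conv.mean(axis=0, keepdims=True)
    Fneu = 0.8 * config.baseline_f * (1.0 + 0.3 * shared)
    Fneu = np.broadcast_to(Fneu, F.shape).copy()
    Fneu += rng.normal(0.0, 0.3 * config.noise_sd, size=F.shape)

    roi_ids = [f"cell{i:04d}" for i in range(n_neurons)]
    rois = pd.DataFrame(
        {
            "roi_id": roi_ids,
            "axon_id": np.arange(n_neurons),
            "kind": "gaussian",
            "center_az": [c[0] for c in centers],
            "center_el": [c[1] for c in centers],
            "width_deg": rf_width,
            "amplitude": v_amplitude,
            "modality": "visual",
            "responsive": True,
            "mouse_id": mouse_ids,
        }
    )
    truth = GroundTruth(rois=rois)
    truth.extra.update(
        rf_center=(rf_center.azimuth, rf_center.elevation),
        av_gain=av_gain,
        a_amplitude=a_amplitude,
    )
    traces = RoiTraces(
        F=F, Fneu=Fneu, events=events, frame_rate=config.frame_rate, roi_ids=roi_ids
    )
    return traces, log, truth


# ---------------------------------------------------------------------------
# Benchmark session helpers
# ---------------------------------------------------------------------------


def make_tuned_session(
    n_axons: int = 50,
    width: float = 30.0,
    snr: float = 3.0,
    n_reps: int = 20,
    geometry: Optional[ArrayGeometry] = None,
    boutons_per_axon: int = 1,
    amplitude: float = 0.5,
    kind: str = "gaussian",
    centers_on_grid: bool = True,
    seed: int = 0,
) -> tuple[RoiTraces, pd.DataFrame, GroundTruth, SessionConfig]:
    """Auditory-only benchmark session of Gaussian-tuned (or flat) axons.

    Frame noise is set from the target trial-response SNR via
    :func:`frame_noise_for_snr`; the lognormal trial gain is disabled so
    SNR is governed by the frame noise alone.
    """
    geometry = geometry or default_array()
    base_cfg = SessionConfig(
        geometry=geometry, n_reps=n_reps, modalities=("auditory",), seed=seed,
        gain_sigma=0.0,
    )
    noise_sd = frame_noise_for_snr(base_cfg, amplitude, snr)
    config = replace(base_cfg, noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    log = generate_stim_log(config, rng=rng)
    pts = geometry.position_array()
    specs = []
    for a in range(n_axons):
        if centers_on_grid:
            caz, cel = pts[rng.integers(pts.shape[0])]
        else:
            caz = rng.uniform(min(geometry.azimuths), max(geometry.azimuths))
            cel = rng.uniform(min(geometry.elevations), max(geometry.elevations))
        specs.append(
            AxonSpec(
                axon_id=a,
                tuning=TuningSpec(
                    kind=kind,
                    center=Position(float(caz), float(cel)),
                    width=width,
                    amplitude=amplitude,
                    modality="auditory",
                ),
                n_boutons=boutons_per_axon,
                within_axon_corr=0.6,
            )
        )
    traces, truth = simulate_traces(log, specs, config, rng=rng)
    return traces, log, truth, config


def make_clustering_session(
    n_axons: int = 20,
    boutons_per_axon: int = 3,
    within_axon_corr: float = 0.6,
    n_reps: int = 10,
    geometry: Optional[ArrayGeometry] = None,
    seed: int = 0,
) -> tuple[RoiTraces, pd.DataFrame, GroundTruth, SessionConfig]:
    """Benchmark for axon clustering: correlated boutons, independent axons.

    Axons carry narrow Gaussian tuning with scattered centers plus a
    strong lognormal trial gain, so different axons respond on largely
    disjoint trial sets (cross-axon trace correlation ~ 0) while boutons
    of one axon share their latent at the requested Pearson correlation.
    """
    geometry = geometry or default_array()
    config = SessionConfig(
        geometry=geometry,
        n_reps=n_reps,
        modalities=("auditory",),
        gain_sigma=0.6,
        noise_sd=0.03,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    log = generate_stim_log(config, rng=rng)
    pts = geometry.position_array()
    # candidate centers >= 20 deg apart so tuning overlap stays below the
    # clustering threshold between different axons
    az = np.asarray(geometry.azimuths)
    keep = np.isin(pts[:, 0], az[::2])
    candidates = pts[keep]
    if n_axons > candidates.shape[0]:
        raise ValueError("clustering benchmark needs fewer axons than spaced centers")
    centers = candidates[rng.choice(candidates.shape[0], size=n_axons, replace=False)]
    specs = [
        AxonSpec(
            axon_id=a,
            tuning=TuningSpec(
                kind="gaussian",
                center=Position(float(centers[a, 0]), float(centers[a, 1])),
                width=8.0,
                amplitude=0.5,
            ),
            n_boutons=boutons_per_axon,
            within_axon_corr=within_axon_corr,
        )
        for a in range(n_axons)
    ]
    traces, truth = simulate_traces(log, specs, config, rng=rng)
    return traces, log, truth, config
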