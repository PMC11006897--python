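"""Trace preprocessing: neuropil correction, ΔF/F, trial alignment, and
responsiveness/inclusion filters.

Conventions
-----------
* ΔF/F = (F − F0) / F0 with F0 the mean fluorescence over the trial's
  baseline window (default the 1 s immediately preceding stimulus onset).
* The onset frame is the first frame whose start time is >= the stimulus
  onset; all windows are half-open [start, end) in seconds relative to
  onset, and a frame belongs to a window when its start time does.
* Because F0 is the baseline-window mean, the per-trial mean ΔF/F over the
  baseline window is identically zero; the paired responsiveness tests
  therefore reduce to tests of the response values against zero.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RoiTraces, TrialTensor, validate_stim_log

__all__ = [
    "neuropil_correct",
    "segment_and_dff",
    "trial_response",
    "baseline_response",
    "select_responsive_boutons",
    "select_somata",
]

NEUROPIL_COEFF = 0.7
RESPONSE_WINDOW_BOUTONS = (0.2, 1.8)
BASELINE_WINDOW = (-1.0, 0.0)


def neuropil_correct(traces: RoiTraces, coefficient: float = NEUROPIL_COEFF) -> RoiTraces:
    """Subtract a scaled neuropil signal: F <- F − coefficient × Fneu."""
    if traces.Fneu is None:
        raise ValueError("neuropil correction requires Fneu traces")
    return RoiTraces(
        F=traces.F - coefficient * traces.Fneu,
        Fneu=traces.Fneu,
        events=traces.events,
        frame_rate=traces.frame_rate,
        roi_ids=list(traces.roi_ids),
    )


def _segment(
    signal: np.ndarray,
    onset_frames: np.ndarray,
    pre_frames: int,
    post_frames: int,
) -> np.ndarray:
    """Cut (roi x frame) into (roi x trial x within-trial frame)."""
    n_frames = signal.shape[1]
    idx = onset_frames[:, None] + np.arange(-pre_frames, post_frames)[None, :]
    if idx.min() < 0 or idx.max() >= n_frames:
        raise ValueError("trial windows fall outside the recorded frames")
    return signal[:, idx]


def segment_and_dff(
    traces: RoiTraces,
    log: pd.DataFrame,
    pre_s: float = 1.0,
    post_s: float = 3.0,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    use_events: bool = False,
) -> TrialTensor:
    """Trial-align traces and convert to ΔF/F.

    With ``use_events`` the deconvolved-event traces are aligned instead
    and returned as-is (no F0 normalization), for event-rate analyses.
    """
    validate_stim_log(log)
    fr = traces.frame_rate
    pre_frames = int(round(pre_s * fr))
    post_frames = int(round(post_s * fr))
    onset_frames = log["onset_frame"].to_numpy(int)
    frame_offsets = np.arange(-pre_frames, post_frames)

    if use_events:
        if traces.events is None:
            raise ValueError("no deconvolved event traces in this session")
        seg = _segment(traces.events, onset_frames, pre_frames, post_frames)
        return TrialTensor(
            dff=seg,
            frame_offsets=frame_offsets,
            frame_rate=fr,
            roi_ids=list(traces.roi_ids),
            trials=log.reset_index(drop=True),
            baseline_window=baseline_window,
        )

    seg = _segment(traces.F, onset_frames, pre_frames, post_frames)
    t = frame_offsets / fr
    base_mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not base_mask.any():
        raise ValueError("empty baseline window at this frame rate")
    f0 = seg[:, :, base_mask].mean(axis=2, keepdims=True)
    if np.any(f0 <= 0):
        raise ValueError("non-positive baseline fluorescence F0")
    return TrialTensor(
        dff=(seg - f0) / f0,
        frame_offsets=frame_offsets,
        frame_rate=fr,
        roi_ids=list(traces.roi_ids),
        trials=log.reset_index(drop=True),
        baseline_window=baseline_window,
    )


def trial_response(
    tensor: TrialTensor, window: tuple[float, float] = RESPONSE_WINDOW_BOUTONS
) -> np.ndarray:
    """Time-mean ΔF/F over a window: (n_roi, n_trial) scalar responses."""
    mask = tensor.window_mask(window)
    if not mask.any():
        raise ValueError(f"window {window} contains no frames at {tensor.frame_rate} Hz")
    return tensor.dff[:, :, mask].mean(axis=2)


def baseline_response(tensor: TrialTensor) -> np.ndarray:
    """Per-trial baseline-window means (zero by ΔF/F construction)."""
    return tensor.dff[:, :, tensor.window_mask(tensor.baseline_window)].mean(axis=2)


def _position_labels(trials: pd.DataFrame) -> np.ndarray:
    """Integer trial-type labels from (modality, azimuth, elevation)."""
    key = (
        trials["modality"].astype(str)
        + "|"
        + trials["azimuth_deg"].astype(str)
        + "|"
        + trials["elevation_deg"].astype(str)
    )
    _, labels = np.unique(key.to_numpy(), return_inverse=True)
    return labels


def select_responsive_boutons(
    tensor: TrialTensor,
    alpha: float = 0.01,
    amp_thresh: float = 0.15,
    method: str = "wilcoxon",
    window: tuple[float, float] = RESPONSE_WINDOW_BOUTONS,
    amp_on: str = "mean",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Responsiveness filter for bouton ROIs.

    For each ROI the stimulus position with the strongest median response
    is found; the ROI is responsive iff the paired two-sided Wilcoxon
    signed-rank test of that position's responses against the matched
    baseline rejects at ``alpha`` and the response amplitude (mean by
    default, median with ``amp_on='median'``) exceeds ``amp_thresh`` ΔF/F.
    ``method='bootstrap'`` instead requires the strongest median response
    to exceed the 95th percentile of a baseline-resampling null (baseline
    frames resampled within trials), plus the same amplitude gate.

    Returns (responsive mask, best-position label per ROI).
    """
    responses = trial_response(tensor, window)
    labels = _position_labels(tensor.trials)
    uniq = np.unique(labels)
    if any((labels == u).sum() < 2 for u in uniq):
        raise ValueError("responsiveness filter needs >= 2 trials per position")
    n_roi = responses.shape[0]
    mask = np.zeros(n_roi, dtype=bool)
    best = np.zeros(n_roi, dtype=int)
    rng = np.random.default_rng(seed)
    base_frames = tensor.dff[:, :, tensor.window_mask(tensor.baseline_window)]
    for i in range(n_roi):
        medians = np.array([np.median(responses[i, labels == u]) for u in uniq])
        b = int(np.argmax(medians))
        best[i] = uniq[b]
        sel = labels == uniq[b]
        vals = responses[i, sel]
        amp = float(np.mean(vals) if amp_on == "mean" else np.median(vals))
        if amp <= amp_thresh:
            continue
        if method == "wilcoxon":
            # matched baseline means are identically 0 -> signed-rank vs 0
            diffs = vals[vals != 0]
            if diffs.size < 2:
                continue
            p = stats.wilcoxon(diffs, alternative="two-sided").pvalue
            mask[i] = p < alpha
        elif method == "bootstrap":
            bf = base_frames[i, sel, :]  # trials x baseline frames
            nt, nf = bf.shape
            boot = np.empty(n_boot)
            for k in range(n_boot):
                draw = bf[np.arange(nt)[:, None], rng.integers(0, nf, size=(nt, nf))]
                boot[k] = np.median(draw.mean(axis=1))
            mask[i] = medians[b] > np.quantile(boot, 0.95)
        else:
            raise ValueError(f"unknown method {method!r}")
    return mask, best


def select_somata(
    traces: RoiTraces,
    tensor: TrialTensor,
    neuropil_margin: float = 0.03,
    p_thresh: float = 0.05,
    amp_thresh: float = 0.05,
    window: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Inclusion filter for somatic recordings.

    A neuron is kept iff (1) its mean trial-baseline raw fluorescence
    exceeds the surrounding neuropil's by more than ``neuropil_margin``
    (3%), and (2) its best trial type elicits a significant response
    (paired t-test of response vs. matched baseline, p < 0.05) with mean
    response amplitude > ``amp_thresh`` ΔF/F.
    """
    if traces.Fneu is None:
        raise ValueError("somatic selection requires Fneu traces")
    fr = traces.frame_rate
    onset_frames = tensor.trials["onset_frame"].to_numpy(int)
    t = tensor.frame_offsets / fr
    base_mask = (t >= tensor.baseline_window[0]) & (t < tensor.baseline_window[1])
    pre = int(-tensor.frame_offsets[0])
    post = int(tensor.frame_offsets[-1] + 1)
    segF = _segment(traces.F, onset_frames, pre, post)
    segN = _segment(traces.Fneu, onset_frames, pre, post)
    baseF = segF[:, :, base_mask].mean(axis=(1, 2))
    baseN = segN[:, :, base_mask].mean(axis=(1, 2))
    bright = baseF > (1.0 + neuropil_margin) * baseN

    if window is None:
        # somatic window: 1st frame after onset to 1st frame after offset
        window = (0.0, 1.0 + 1.0 / fr)
    responses = trial_response(tensor, window)
    labels = _position_labels(tensor.trials)
    uniq = np.unique(labels)
    responsive = np.zeros(traces.n_rois, dtype=bool)
    for i in range(traces.n_rois):
        means = np.array([responses[i, labels == u].mean() for u in uniq])
        b = int(np.argmax(means))
        vals = responses[i, labels == uniq[b]]
        if means[b] <= amp_thresh or vals.size < 2:
            continue
        p = stats.ttest_1samp(vals, 0.0).pvalue  # matched baselines are 0
        responsive[i] = p < p_thresh
    return bright & responsive
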