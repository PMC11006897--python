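"""In-memory containers shared across the pipeline stages.

Fluorescence is stored as plain ROI x frame numpy arrays; trial metadata as
pandas DataFrames. The stimulus log is a DataFrame with the columns listed
in :data:`STIM_LOG_COLUMNS`; one row per presented stimulus, onsets strictly
increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

STIM_LOG_COLUMNS = [
    "trial",
    "onset_time_s",
    "onset_frame",
    "modality",
    "azimuth_deg",
    "elevation_deg",
    "intensity",
]


@dataclass
class RoiTraces:
    """Raw fluorescence traces for one session.

    F : (n_roi, n_frames) fluorescence
    Fneu : optional neuropil traces, same shape
    events : optional deconvolved-event traces, same shape (pre-kernel signal)
    """

    F: np.ndarray
    frame_rate: float
    roi_ids: list[str]
    Fneu: Optional[np.ndarray] = None
    events: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be 2-D (roi x frame)")
        if len(self.roi_ids) != self.F.shape[0]:
            raise ValueError("roi_ids length must match F rows")
        for name in ("Fneu", "events"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).shape != self.F.shape:
                raise ValueError(f"{name} shape must match F")

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


@dataclass
class TrialTensor:
    """Trial-aligned ΔF/F: ROI x trial x within-trial frame.

    ``frame_offsets`` gives each within-trial frame's index relative to the
    onset frame (frame 0 is the first post-onset frame); frame k starts at
    time k / frame_rate relative to stimulus onset. Windows are half-open
    [start, end) in seconds relative to onset.
    """

    dff: np.ndarray
    frame_offsets: np.ndarray
    frame_rate: float
    roi_ids: list[str]
    trials: pd.DataFrame
    baseline_window: tuple[float, float] = (-1.0, 0.0)
    response_window: tuple[float, float] = (0.2, 1.8)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 3:
            raise ValueError("dff must be 3-D (roi x trial x frame)")
        if self.dff.shape[1] != len(self.trials):
            raise ValueError("trial axis must match trials table")
        if self.dff.shape[2] != len(self.frame_offsets):
            raise ValueError("frame axis must match frame_offsets")
        if self.baseline_window[1] > 0:
            raise ValueError("baseline window must precede onset")

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]

    @property
    def n_trials(self) -> int:
        return self.dff.shape[1]

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask over within-trial frames with start time in [a, b)."""
        t = self.frame_offsets / self.frame_rate
        return (t >= window[0]) & (t < window[1])


@dataclass
class GroundTruth:
    """True generative parameters of a synthetic session.

    ``rois`` has one row per ROI (roi_id, axon_id, kind, center_az,
    center_el, width_deg, amplitude, modality, responsive, ...);
    ``axons`` one row per axon. ``extra`` carries session-level truths such
    as the V1 population RF center.
    """

    rois: pd.DataFrame
    axons: pd.DataFrame = field(default_factory=pd.DataFrame)
    extra: dict = field(default_factory=dict)


def validate_stim_log(log: pd.DataFrame) -> None:
    missing = [c for c in STIM_LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"stimulus log missing columns: {missing}")
    onsets = log["onset_time_s"].to_numpy()
    if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
        raise ValueError("stimulus onsets must be strictly increasing")
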