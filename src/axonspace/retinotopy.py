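"""V1 population receptive-field fitting and retinotopic-alignment tests.

The population visual RF is obtained by averaging baseline-subtracted,
repetition-averaged responses over the field of view into a map R(az, el)
and fitting an elliptical 2D Gaussian (amplitude, center, two widths,
orientation, offset) by bounded least squares. The retinotopic-alignment
question — do axonal auditory preferences follow V1 retinotopy? — is
tested by regressing session best azimuths on session RF azimuth centers
(residual-bootstrap CIs) and by binning decoding error by the distance
between the stimulus azimuth and the RF azimuth center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import TrialTensor
from .geometry import ArrayGeometry, Position
from . import decoder as _decoder
from .preprocess import trial_response
from .tuning import position_indices, response_map

__all__ = [
    "RFFit",
    "population_rf",
    "fit_gaussian_2d",
    "retinotopy_regression",
    "error_vs_rf_distance",
    "error_vs_retinotopic_position",
]


@dataclass
class RFFit:
    center: Position
    widths: tuple[float, float]
    orientation_deg: float
    amplitude: float
    offset: float
    residual_norm: float
    converged: bool = True
    reliable: bool = True


def _gauss2d(coords, amp, x0, y0, sx, sy, theta, offset):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    xr = (x - x0) * ct + (y - y0) * st
    yr = -(x - x0) * st + (y - y0) * ct
    return offset + amp * np.exp(-(xr**2 / (2 * sx**2) + yr**2 / (2 * sy**2)))


def fit_gaussian_2d(
    az: np.ndarray, el: np.ndarray, values: np.ndarray, geometry: ArrayGeometry
) -> RFFit:
    """Bounded least-squares elliptical 2D Gaussian fit of a response map.

    Initialized at the map's response-weighted centroid with range-based
    widths; restarted from the map peak if the first optimization fails.
    The center is bounded to the geometry span ± 20°. A fit whose
    amplitude is indistinguishable from zero relative to the map spread is
    flagged unreliable.
    """
    az = np.asarray(az, float).ravel()
    el = np.asarray(el, float).ravel()
    v = np.asarray(values, float).ravel()
    az_lo, az_hi = min(geometry.azimuths) - 20.0, max(geometry.azimuths) + 20.0
    el_lo, el_hi = min(geometry.elevations) - 20.0, max(geometry.elevations) + 20.0
    vpos = np.clip(v - v.min(), 0, None)
    wsum = vpos.sum()
    if wsum > 0:
        cx, cy = float((az * vpos).sum() / wsum), float((el * vpos).sum() / wsum)
    else:
        cx, cy = float(az.mean()), float(el.mean())
    span_az = max(az.max() - az.min(), 10.0)
    span_el = max(el.max() - el.min(), 10.0)
    inits = [
        (v.max() - v.min(), cx, cy, span_az / 4, span_el / 4, 0.0, v.min()),
        (v.max() - v.min(), az[np.argmax(v)], el[np.argmax(v)], span_az / 3,
         span_el / 3, 0.0, float(np.median(v))),
    ]
    bounds = (
        [-np.inf, az_lo, el_lo, 1.0, 1.0, -np.pi / 2, -np.inf],
        [np.inf, az_hi, el_hi, 4 * span_az, 4 * span_el, np.pi / 2, np.inf],
    )
    best = None
    for p0 in inits:
        try:
            popt, _ = optimize.curve_fit(
                _gauss2d, (az, el), v, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(v - _gauss2d((az, el), *popt)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return RFFit(
            center=Position(cx, cy), widths=(np.nan, np.nan),
            orientation_deg=np.nan, amplitude=np.nan, offset=np.nan,
            residual_norm=np.inf, converged=False, reliable=False,
        )
    popt, resid = best
    amp, x0, y0, sx, sy, theta, off = popt
    # a fit is only trusted when the amplitude clearly exceeds the
    # residual noise level; pure-noise maps overfit small bumps
    resid_sd = resid / math.sqrt(max(v.size, 1))
    reliable = float(np.std(v)) > 0 and abs(amp) > 5.0 * resid_sd
    return RFFit(
        center=Position(float(x0), float(y0)),
        widths=(float(sx), float(sy)),
        orientation_deg=float(np.degrees(theta)),
        amplitude=float(amp),
        offset=float(off),
        residual_norm=resid,
        converged=True,
        reliable=bool(reliable),
    )


def population_rf(
    tensor: TrialTensor,
    geometry: ArrayGeometry,
    window: Optional[tuple[float, float]] = None,
    modality: str = "visual",
) -> tuple[RFFit, np.ndarray]:
    """Population RF: field-of-view mean response map + 2D Gaussian fit.

    ΔF/F is already baseline-subtracted per trial; responses are
    time-averaged over the stimulus window (first frame after onset to
    first frame after offset by default), averaged across repetitions and
    neurons, and fitted. Returns the fit and the (n_positions,) map.
    """
    if window is None:
        window = (0.0, 1.0 + 1.0 / tensor.frame_rate)
    sel = tensor.trials["modality"].to_numpy() == modality
    if not sel.any():
        raise ValueError(f"no {modality!r} trials in this tensor")
    sub = tensor.trials.loc[sel].reset_index(drop=True)
    responses = trial_response(tensor, window)[:, sel]
    pos_idx = position_indices(sub, geometry)
    maps = response_map(responses, pos_idx, geometry.n_positions)
    fov_map = maps.mean(axis=0)
    pts = geometry.position_array()
    fit = fit_gaussian_2d(pts[:, 0], pts[:, 1], fov_map, geometry)
    return fit, fov_map


def retinotopy_regression(
    rf_centers: Sequence[float],
    best_azimuths: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """OLS of session best azimuth on V1 RF azimuth center, with
    residual-bootstrap 95% CIs on slope and intercept."""
    x = np.asarray(rf_centers, float)
    y = np.asarray(best_azimuths, float)
    if x.size < 3:
        raise ValueError("regression needs >= 3 sessions")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all RF centers equal")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    resid = y - yhat
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        yb = yhat + rng.choice(resid, size=resid.size, replace=True)
        boots[b] = np.polyfit(x, yb, 1)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "slope_ci": (
            float(np.quantile(boots[:, 0], 0.025)),
            float(np.quantile(boots[:, 0], 0.975)),
        ),
        "intercept_ci": (
            float(np.quantile(boots[:, 1], 0.025)),
            float(np.quantile(boots[:, 1], 0.975)),
        ),
    }


def error_vs_rf_distance(
    decode_results: pd.DataFrame,
    rf_center_az: float,
    bin_width: float = 10.0,
    shuffle_results: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Decoding error binned by |stimulus azimuth − RF azimuth center|.

    Bins are ``bin_width``-degree wide; empty bins are reported as NaN,
    never as zero. With shuffle results the per-bin shuffle-subtracted
    error is added.
    """
    d = np.abs(decode_results["true_az"].to_numpy() - rf_center_az)
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    idx = np.clip(np.digitize(d, edges) - 1, 0, edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        sel = idx == b
        row = {
            "bin_lo": edges[b],
            "bin_hi": edges[b + 1],
            "n_trials": int(sel.sum()),
            "mean_error_deg": float(decode_results["error_deg"].to_numpy()[sel].mean())
            if sel.any()
            else np.nan,
        }
        if shuffle_results is not None:
            ds = np.abs(shuffle_results["true_az"].to_numpy() - rf_center_az)
            sel_s = np.clip(np.digitize(ds, edges) - 1, 0, edges.size - 2) == b
            shuf = (
                float(shuffle_results["error_deg"].to_numpy()[sel_s].mean())
                if sel_s.any()
                else np.nan
            )
            row["shuffle_error_deg"] = shuf
            row["shuffle_subtracted_deg"] = row["mean_error_deg"] - shuf
        rows.append(row)
    return pd.DataFrame(rows)


def error_vs_retinotopic_position(
    sessions: Sequence[dict],
    n_min: Optional[int] = None,
    n_draws: int = 10,
    window_deg: float = 20.0,
    step_deg: float = 5.0,
    seed: int = 0,
    **decode_kwargs,
) -> pd.DataFrame:
    """Moving-average decoding error along the V1 azimuth map.

    Each session dict supplies ``responses`` (axon x trial), ``pos_idx``,
    ``geometry``, and ``rf_az`` (the session's RF azimuth center). Every
    session is subsampled to the common minimal axon count (``n_min``
    draws without replacement, ``n_draws`` times, errors averaged) to
    remove the session-size confound, then session errors are averaged in
    a ``window_deg`` window stepped by ``step_deg`` along RF azimuth.
    """
    if len(sessions) < 2:
        raise ValueError("needs >= 2 sessions")
    pools = [np.atleast_2d(s["responses"]).shape[0] for s in sessions]
    n_min = min(pools) if n_min is None else n_min
    if n_min > min(pools):
        raise ValueError("n_min exceeds the smallest session's axon pool")
    rng = np.random.default_rng(seed)
    sess_err = []
    sess_az = []
    for s in sessions:
        resp = np.atleast_2d(s["responses"])
        errs = []
        for _ in range(n_draws):
            sub = rng.choice(resp.shape[0], size=n_min, replace=False)
            _, summary = _decoder.crossval_decode(
                resp[sub], s["pos_idx"], s["geometry"],
                seed=int(rng.integers(2**31)), enforce_min_axons=False,
                **decode_kwargs,
            )
            errs.append(summary["mean_error_deg"])
        sess_err.append(float(np.mean(errs)))
        sess_az.append(float(s["rf_az"]))
    sess_err = np.asarray(sess_err)
    sess_az = np.asarray(sess_az)
    centers = np.arange(sess_az.min(), sess_az.max() + step_deg / 2, step_deg)
    rows = []
    for c in centers:
        sel = np.abs(sess_az - c) <= window_deg / 2
        rows.append(
            {
                "rf_az_center": float(c),
                "mean_error_deg": float(sess_err[sel].mean()) if sel.any() else np.nan,
                "n_sessions": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
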