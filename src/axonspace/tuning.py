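"""Per-bouton spatial statistics.

The central quantity is the spatial modulation index (SMI) of a response
map r_1..r_n (mean response at each of the n stimulus positions, grand
mean R):

    SMI = sum_i (r_i - R)^2 / sum_i r_i^2

i.e. the fraction of the map's energy not explained by its spatial mean:
0 for a perfectly uniform map, and (n-1)/n for a one-hot map (the
single-location limit). SMI is invariant to multiplicative scaling of the
map and increases under mean-preserving concentration.

Reliability, best azimuth, and distance-tuning curves all follow the same
resampling scheme: trials of each position are randomly split in half,
tuning maps computed per half, and the half-map Pearson correlation
(threshold 0.3) defines reliable boutons; the loop is repeated (100
iterations by default) to give means and percentile 95% CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TrialTensor
from .geometry import ArrayGeometry, angular_distance, virtual_isotropic_arrays

__all__ = [
    "position_indices",
    "response_map",
    "smi",
    "population_smi",
    "split_half_reliability",
    "best_azimuth_session",
    "distance_tuning_curves",
    "azimuth_elevation_fractions",
    "classify_onset_offset",
    "frequency_tuning",
]

RELIABILITY_THRESHOLD = 0.3
N_RESAMPLE = 100


def position_indices(trials: pd.DataFrame, geometry: ArrayGeometry) -> np.ndarray:
    """Map each trial to its geometry position index."""
    az = np.asarray(geometry.azimuths)
    el = np.asarray(geometry.elevations)
    ia = np.searchsorted(az, trials["azimuth_deg"].to_numpy(float))
    ie = np.searchsorted(el, trials["elevation_deg"].to_numpy(float))
    ia = np.clip(ia, 0, az.size - 1)
    ie = np.clip(ie, 0, el.size - 1)
    ok = np.isclose(az[ia], trials["azimuth_deg"]) & np.isclose(
        el[ie], trials["elevation_deg"]
    )
    if not ok.all():
        raise ValueError("trials contain positions outside the geometry")
    return ie * az.size + ia


def response_map(responses: np.ndarray, pos_idx: np.ndarray, n_positions: int) -> np.ndarray:
    """Mean response per position: (n_roi, n_positions)."""
    responses = np.atleast_2d(responses)
    counts = np.bincount(pos_idx, minlength=n_positions)
    if np.any(counts == 0):
        raise ValueError("every position needs at least one trial")
    sums = np.zeros((responses.shape[0], n_positions))
    for p in range(n_positions):
        sums[:, p] = responses[:, pos_idx == p].sum(axis=1)
    return sums / counts


def smi(map_r: np.ndarray, rectify: bool = False) -> float:
    """Spatial modulation index of one response map.

    Noise-driven negative entries are used as-is by default; ``rectify``
    clips them at zero first.
    """
    r = np.asarray(map_r, dtype=float).ravel()
    if rectify:
        r = np.clip(r, 0.0, None)
    denom = float(np.sum(r**2))
    if denom == 0.0:
        raise ValueError("SMI undefined for an all-zero response map")
    return float(np.sum((r - r.mean()) ** 2) / denom)


def population_smi(maps: np.ndarray) -> float:
    """SMI of the position-wise mean map across ROIs."""
    maps = np.atleast_2d(maps)
    if maps.shape[0] == 0:
        raise ValueError("population SMI needs at least one map")
    return smi(maps.mean(axis=0))


def _split_half_once(
    responses: np.ndarray, pos_idx: np.ndarray, n_positions: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random within-position half-split -> two (n_roi, n_pos) maps."""
    h1 = np.zeros(pos_idx.size, dtype=bool)
    for p in range(n_positions):
        idx = np.flatnonzero(pos_idx == p)
        if idx.size < 2:
            raise ValueError("split-half needs >= 2 trials per position")
        perm = rng.permutation(idx)
        h1[perm[: idx.size // 2]] = True
    m1 = response_map(responses[:, h1], pos_idx[h1], n_positions)
    m2 = response_map(responses[:, ~h1], pos_idx[~h1], n_positions)
    return m1, m2


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    return np.where(denom > 0, r, 0.0)


def split_half_reliability(
    responses: np.ndarray,
    pos_idx: np.ndarray,
    n_positions: int,
    r_thresh: float = RELIABILITY_THRESHOLD,
    n_iter: int = N_RESAMPLE,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean split-half tuning-map correlation per ROI and reliability mask."""
    rng = np.random.default_rng(seed)
    responses = np.atleast_2d(responses)
    rs = np.zeros((n_iter, responses.shape[0]))
    for k in range(n_iter):
        m1, m2 = _split_half_once(responses, pos_idx, n_positions, rng)
        rs[k] = _rowwise_pearson(m1, m2)
    mean_r = rs.mean(axis=0)
    return mean_r, mean_r > r_thresh


def _azimuth_marginal(maps: np.ndarray, geometry: ArrayGeometry) -> np.ndarray:
    """Average maps across elevations -> (n_roi, n_azimuths)."""
    n_az = len(geometry.azimuths)
    n_el = len(geometry.elevations)
    return maps.reshape(maps.shape[0], n_el, n_az).mean(axis=1)


def best_azimuth(
    responses: np.ndarray, pos_idx: np.ndarray, geometry: ArrayGeometry
) -> np.ndarray:
    """Per-ROI best azimuth (degrees), elevations averaged out."""
    maps = response_map(np.atleast_2d(responses), pos_idx, geometry.n_positions)
    marg = _azimuth_marginal(maps, geometry)
    return np.asarray(geometry.azimuths)[np.argmax(marg, axis=1)]


def best_azimuth_session(
    responses: np.ndarray,
    pos_idx: np.ndarray,
    geometry: ArrayGeometry,
    min_reliable: int = 10,
    r_thresh: float = RELIABILITY_THRESHOLD,
    n_iter: int = N_RESAMPLE,
    seed: int = 0,
) -> dict:
    """Session-level best azimuth: the median best azimuth across reliable
    boutons, resampled over random split-halves.

    Within each iteration reliability is re-derived from a fresh half-split
    (r > 0.3) while each bouton's best azimuth comes from all trials. The
    session is excluded when fewer than ``min_reliable`` boutons are
    reliable on the mean criterion; the returned dict reports this.
    """
    rng = np.random.default_rng(seed)
    responses = np.atleast_2d(responses)
    ba = best_azimuth(responses, pos_idx, geometry)
    medians = []
    reliable_counts = []
    for _ in range(n_iter):
        m1, m2 = _split_half_once(responses, pos_idx, geometry.n_positions, rng)
        rel = _rowwise_pearson(m1, m2) > r_thresh
        reliable_counts.append(int(rel.sum()))
        if rel.any():
            medians.append(float(np.median(ba[rel])))
    mean_reliable = float(np.mean(reliable_counts))
    excluded = mean_reliable < min_reliable
    if not medians:
        return {"excluded": True, "n_reliable": mean_reliable}
    med = np.asarray(medians)
    return {
        "excluded": excluded,
        "n_reliable": mean_reliable,
        "best_azimuth": float(np.mean(med)),
        "median": float(np.median(med)),
        "ci": (float(np.quantile(med, 0.025)), float(np.quantile(med, 0.975))),
        "per_roi_best_azimuth": ba,
    }


def distance_tuning_curves(
    responses: np.ndarray,
    pos_idx: np.ndarray,
    geometry: ArrayGeometry,
    r_thresh: float = RELIABILITY_THRESHOLD,
    n_iter: int = N_RESAMPLE,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized response vs. distance from the preferred position.

    Per iteration: preferred position per reliable bouton from one random
    half; the other half's map normalized to its value at that position;
    values pooled by angular distance from the preferred position. Returns
    distance, mean, and 95% CI columns.
    """
    rng = np.random.default_rng(seed)
    responses = np.atleast_2d(responses)
    pts = geometry.position_array()
    dmat = np.hypot(
        pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
    )
    dist_round = np.round(dmat, 1)
    per_iter: list[dict[float, float]] = []
    for _ in range(n_iter):
        m1, m2 = _split_half_once(responses, pos_idx, geometry.n_positions, rng)
        rel = _rowwise_pearson(m1, m2) > r_thresh
        if not rel.any():
            continue
        pooled: dict[float, list[float]] = {}
        for i in np.flatnonzero(rel):
            pref = int(np.argmax(m1[i]))
            ref = m2[i, pref]
            if abs(ref) < 1e-12:
                continue
            norm = m2[i] / ref
            for p in range(geometry.n_positions):
                pooled.setdefault(float(dist_round[pref, p]), []).append(norm[p])
        per_iter.append({d: float(np.mean(v)) for d, v in pooled.items()})
    if not per_iter:
        raise ValueError("no reliable boutons for distance tuning curves")
    dists = sorted({d for it in per_iter for d in it})
    rows = []
    for d in dists:
        vals = np.array([it[d] for it in per_iter if d in it])
        rows.append(
            {
                "distance_deg": d,
                "mean": vals.mean(),
                "ci_lo": np.quantile(vals, 0.025),
                "ci_hi": np.quantile(vals, 0.975),
                "n_iter": vals.size,
            }
        )
    return pd.DataFrame(rows)


def _balanced_two_way_anova(
    y: np.ndarray, a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized balanced fixed-effects two-way ANOVA.

    y: (n_roi, n_obs); a, b: factor level indices per observation; every
    (a, b) cell must hold the same number of observations. Returns p-values
    (n_roi,) for factor A, factor B, and the interaction.
    """
    A = int(a.max()) + 1
    B = int(b.max()) + 1
    cell = a * B + b
    counts = np.bincount(cell, minlength=A * B)
    if counts.min() < 2 or counts.min() != counts.max():
        raise ValueError("two-way ANOVA requires a balanced design with >= 2 per cell")
    n = counts[0]
    n_roi = y.shape[0]
    cell_means = np.stack(
        [y[:, cell == c].mean(axis=1) for c in range(A * B)], axis=1
    ).reshape(n_roi, A, B)
    grand = cell_means.mean(axis=(1, 2))
    a_means = cell_means.mean(axis=2)
    b_means = cell_means.mean(axis=1)
    ss_a = n * B * ((a_means - grand[:, None]) ** 2).sum(axis=1)
    ss_b = n * A * ((b_means - grand[:, None]) ** 2).sum(axis=1)
    inter = (
        cell_means
        - a_means[:, :, None]
        - b_means[:, None, :]
        + grand[:, None, None]
    )
    ss_ab = n * (inter**2).sum(axis=(1, 2))
    resid = y - cell_means.reshape(n_roi, A * B)[:, cell]
    ss_e = (resid**2).sum(axis=1)
    df_a, df_b = A - 1, B - 1
    df_ab = df_a * df_b
    df_e = A * B * (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ms_e = ss_e / df_e
        f_a = (ss_a / df_a) / ms_e
        f_b = (ss_b / df_b) / ms_e
        f_ab = (ss_ab / df_ab) / ms_e
    return (
        stats.f.sf(f_a, df_a, df_e),
        stats.f.sf(f_b, df_b, df_e),
        stats.f.sf(f_ab, df_ab, df_e),
    )


def azimuth_elevation_fractions(
    responses: np.ndarray,
    pos_idx: np.ndarray,
    geometry: ArrayGeometry,
    alpha: float = 0.05,
) -> dict:
    """Fractions of boutons modulated by azimuth, elevation, or their
    interaction, on isotropic virtual sub-arrays.

    The anisotropic grid is downsampled to every 40° x 40° 3 x 3 virtual
    array; a two-way fixed-effects ANOVA (azimuth x elevation) is run per
    bouton on each, and the significant fractions are averaged across the
    virtual arrays.
    """
    responses = np.atleast_2d(responses)
    subs = virtual_isotropic_arrays(geometry)
    pts = geometry.position_array()
    fracs = {"azimuth": [], "elevation": [], "interaction": []}
    for sub in subs:
        keep = np.isin(pts[pos_idx, 0], sub.azimuths) & np.isin(
            pts[pos_idx, 1], sub.elevations
        )
        sub_idx = pos_idx[keep]
        a = np.searchsorted(np.asarray(sub.azimuths), pts[sub_idx, 0])
        b = np.searchsorted(np.asarray(sub.elevations), pts[sub_idx, 1])
        p_a, p_b, p_ab = _balanced_two_way_anova(responses[:, keep], a, b)
        fracs["azimuth"].append(np.mean(p_a < alpha))
        fracs["elevation"].append(np.mean(p_b < alpha))
        fracs["interaction"].append(np.mean(p_ab < alpha))
    return {k: float(np.mean(v)) for k, v in fracs.items()}


def classify_onset_offset(
    event_tensor: TrialTensor,
    alpha: float = 0.01,
    stim_duration_s: float = 1.0,
) -> np.ndarray:
    """Classify boutons as onset, offset, or neither from deconvolved
    event rates.

    The best position is taken from the median deconvolved activity over
    stimulus onset to 1 s past offset. At that position, onset boutons show
    event rates during the stimulus significantly above the 1 s baseline
    (two-sided Wilcoxon signed-rank, alpha = 0.01); offset boutons show
    post-offset rates above baseline while the stimulus window does not
    differ from baseline.
    """
    base_w = (-1.0, 0.0)
    stim_w = (0.0, stim_duration_s)
    post_w = (stim_duration_s, stim_duration_s + 1.0)
    full_w = (0.0, stim_duration_s + 1.0)
    rates = {
        name: event_tensor.dff[:, :, event_tensor.window_mask(w)].mean(axis=2)
        for name, w in {"base": base_w, "stim": stim_w, "post": post_w, "full": full_w}.items()
    }
    labels = None
    from .preprocess import _position_labels

    labels = _position_labels(event_tensor.trials)
    uniq = np.unique(labels)
    out = np.full(event_tensor.n_rois, "none", dtype=object)
    for i in range(event_tensor.n_rois):
        med = np.array([np.median(rates["full"][i, labels == u]) for u in uniq])
        sel = labels == uniq[int(np.argmax(med))]

        def _p(x: np.ndarray, y: np.ndarray) -> float:
            d = x - y
            d = d[d != 0]
            if d.size < 2:
                return 1.0
            return float(stats.wilcoxon(d, alternative="two-sided").pvalue)

        p_stim = _p(rates["stim"][i, sel], rates["base"][i, sel])
        stim_up = rates["stim"][i, sel].mean() > rates["base"][i, sel].mean()
        if p_stim < alpha and stim_up:
            out[i] = "onset"
            continue
        p_post = _p(rates["post"][i, sel], rates["base"][i, sel])
        post_up = rates["post"][i, sel].mean() > rates["base"][i, sel].mean()
        if p_post < alpha and post_up and p_stim >= alpha:
            out[i] = "offset"
    return np.asarray(out, dtype=str)


def frequency_tuning(
    responses: np.ndarray,
    freq_labels: np.ndarray,
    alpha_responsive: float = 0.01,
    amp_thresh: float = 0.1,
    alpha_tuned: float = 0.05,
) -> pd.DataFrame:
    """Pure-tone responsiveness and frequency tuning.

    Tone-responsive: the best frequency's responses differ from the matched
    baseline (paired t-test, alpha = 0.01; baselines are zero by ΔF/F
    construction) and the mean response exceeds 0.1 ΔF/F. Frequency-tuned:
    additionally modulated across frequencies (one-way repeated-measures
    ANOVA over repetitions, alpha = 0.05). Returns per-ROI flags, the best
    frequency, and the curve normalized to the best response.
    """
    responses = np.atleast_2d(responses)
    freq_labels = np.asarray(freq_labels)
    freqs = np.unique(freq_labels)
    if freqs.size < 2:
        raise ValueError("frequency tuning needs >= 2 frequencies")
    counts = np.array([(freq_labels == f).sum() for f in freqs])
    if counts.min() != counts.max():
        raise ValueError("repeated-measures ANOVA requires equal repetitions per frequency")
    n_rep = counts[0]
    # repetition index within frequency, pairing repetitions across levels
    by_freq = np.stack(
        [responses[:, freq_labels == f] for f in freqs], axis=1
    )  # (n_roi, n_freq, n_rep)
    rows = []
    for i in range(responses.shape[0]):
        means = by_freq[i].mean(axis=1)
        b = int(np.argmax(means))
        vals = by_freq[i, b]
        p_best = float(stats.ttest_1samp(vals, 0.0).pvalue) if n_rep > 1 else 1.0
        responsive = p_best < alpha_responsive and means[b] > amp_thresh
        tuned = False
        if responsive:
            # one-way RM ANOVA: subjects = repetitions, within factor = frequency
            data = by_freq[i]  # (n_freq, n_rep)
            subj_mean = data.mean(axis=0)
            freq_mean = data.mean(axis=1)
            grand = data.mean()
            ss_freq = n_rep * ((freq_mean - grand) ** 2).sum()
            ss_err = (
                (data - freq_mean[:, None] - subj_mean[None, :] + grand) ** 2
            ).sum()
            df_f = freqs.size - 1
            df_e = df_f * (n_rep - 1)
            if ss_err > 0 and df_e > 0:
                f_stat = (ss_freq / df_f) / (ss_err / df_e)
                tuned = float(stats.f.sf(f_stat, df_f, df_e)) < alpha_tuned
            else:
                tuned = ss_freq > 0
        norm = means / means[b] if means[b] != 0 else means
        rows.append(
            {
                "roi": i,
                "tone_responsive": bool(responsive),
                "frequency_tuned": bool(tuned),
                "best_frequency": freqs[b],
                "curve": norm,
            }
        )
    return pd.DataFrame(rows)
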