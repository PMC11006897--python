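"""Audiovisual modulation of V1 somata.

Three questions, asked of sessions where an LED inside the population RF
is flashed alone (V), a speaker at an azimuth offset from the LED plays
alone (A), or both play together (AV): (1) does concurrent sound enhance
visual responses (AV vs. V)?  (2) does the enhancement depend on the
speaker-LED offset?  (3) can the speaker offset be decoded from the
somatic population at all?  Analyses aggregate neuron -> mouse: for each
cell the LED eliciting the maximum visual response is selected, speakers
non-congruent in elevation are excluded, responses are averaged across
intensity levels (unless stratified), and the mouse is the
repeated-measures subject.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ArrayGeometry
from . import decoder as _decoder

__all__ = ["av_enhancement", "modulation_vs_offset", "decode_offset_from_somata"]


def _best_led(responses: np.ndarray, trials: pd.DataFrame) -> np.ndarray:
    """Per-neuron LED (azimuth) eliciting the maximal mean V response."""
    v = trials["condition"].to_numpy() == "V"
    leds = np.unique(trials.loc[v, "led_az_deg"].to_numpy(float))
    means = np.stack(
        [
            responses[:, v & (trials["led_az_deg"].to_numpy(float) == led)].mean(axis=1)
            for led in leds
        ],
        axis=1,
    )
    return leds[np.argmax(means, axis=1)]


def _azimuth_congruent(trials: pd.DataFrame) -> np.ndarray:
    """Trials whose speaker (if any) is congruent in elevation."""
    oel = trials["offset_el_deg"].to_numpy(float)
    return np.isnan(oel) | (oel == 0.0)


def av_enhancement(
    responses: np.ndarray,
    trials: pd.DataFrame,
    mouse_ids: Sequence[str],
) -> tuple[pd.DataFrame, Optional[dict]]:
    """Per-neuron AV − V and AV/V, and the mouse-level paired test.

    V and AV means use each neuron's best LED, averaged across intensity
    levels and azimuth-congruent speaker offsets. The population statistic
    is a two-sided paired t-test of AV vs. V across mouse means; it is
    refused (None) with fewer than two mice.
    """
    responses = np.atleast_2d(responses)
    mouse_ids = np.asarray(mouse_ids)
    keep = _azimuth_congruent(trials)
    cond = trials["condition"].to_numpy()
    led = trials["led_az_deg"].to_numpy(float)
    best = _best_led(responses, trials)
    rows = []
    for i in range(responses.shape[0]):
        sel_v = keep & (cond == "V") & (led == best[i])
        sel_av = keep & (cond == "AV") & (led == best[i])
        v_mean = responses[i, sel_v].mean()
        av_mean = responses[i, sel_av].mean()
        rows.append(
            {
                "neuron": i,
                "mouse_id": mouse_ids[i],
                "best_led_az": best[i],
                "v_mean": v_mean,
                "av_mean": av_mean,
                "av_minus_v": av_mean - v_mean,
                "av_over_v": av_mean / v_mean if v_mean != 0 else np.nan,
            }
        )
    per_neuron = pd.DataFrame(rows)
    by_mouse = per_neuron.groupby("mouse_id")[["v_mean", "av_mean"]].mean()
    if len(by_mouse) < 2:
        return per_neuron, None
    t = stats.ttest_rel(by_mouse["av_mean"], by_mouse["v_mean"])
    pop = {
        "n_mice": len(by_mouse),
        "t": float(t.statistic),
        "p": float(t.pvalue),
        "mean_av_minus_v": float((by_mouse["av_mean"] - by_mouse["v_mean"]).mean()),
        "mean_av_over_v": float((by_mouse["av_mean"] / by_mouse["v_mean"]).mean()),
    }
    return per_neuron, pop


def modulation_vs_offset(
    responses: np.ndarray,
    trials: pd.DataFrame,
    mouse_ids: Sequence[str],
    stratify_intensity: bool = False,
) -> dict:
    """Condition means per speaker offset and the repeated-measures ANOVA.

    Elevation-non-congruent speakers are excluded. Neuron responses (best
    LED for AV/V, all speakers for A) are averaged within mouse; the
    repeated-measures ANOVA on mouse means tests the offset effect, with
    brightness and loudness as additional within factors when
    ``stratify_intensity`` is set and multiple levels exist.
    """
    from statsmodels.stats.anova import AnovaRM

    responses = np.atleast_2d(responses)
    mouse_ids = np.asarray(mouse_ids)
    keep = _azimuth_congruent(trials)
    cond = trials["condition"].to_numpy()
    led = trials["led_az_deg"].to_numpy(float)
    oaz = trials["offset_az_deg"].to_numpy(float)
    best = _best_led(responses, trials)
    offsets = np.unique(oaz[keep & (cond == "AV")])

    long_rows = []
    for i in range(responses.shape[0]):
        sel_v = keep & (cond == "V") & (led == best[i])
        v_mean = responses[i, sel_v].mean()
        for off in offsets:
            sel_av = keep & (cond == "AV") & (led == best[i]) & (oaz == off)
            sel_a = keep & (cond == "A") & (oaz == off)
            if stratify_intensity:
                for (b, l), grp in trials.loc[sel_av].groupby(
                    ["brightness_cdm2", "loudness_db"]
                ):
                    long_rows.append(
                        {
                            "neuron": i, "mouse_id": mouse_ids[i], "offset": off,
                            "brightness": b, "loudness": l,
                            "av": responses[i, grp.index].mean(),
                            "a": np.nan, "av_over_v": np.nan,
                        }
                    )
            else:
                long_rows.append(
                    {
                        "neuron": i, "mouse_id": mouse_ids[i], "offset": off,
                        "av": responses[i, sel_av].mean(),
                        "a": responses[i, sel_a].mean(),
                        "av_over_v": responses[i, sel_av].mean() / v_mean
                        if v_mean != 0 else np.nan,
                    }
                )
    long = pd.DataFrame(long_rows)
    group_cols = ["mouse_id", "offset"] + (
        ["brightness", "loudness"] if stratify_intensity else []
    )
    mouse_means = long.groupby(group_cols, as_index=False)["av"].mean()
    within = ["offset"] + (
        ["brightness", "loudness"] if stratify_intensity else []
    )
    within = [
        w for w in within if mouse_means[w].nunique() > 1
    ]
    anova = AnovaRM(
        mouse_means, depvar="av", subject="mouse_id", within=within
    ).fit()
    table = anova.anova_table.reset_index().rename(columns={"index": "effect"})
    offset_p = float(
        table.loc[table["effect"].str.lower() == "offset", "Pr > F"].iloc[0]
    )
    per_offset = long.groupby("offset", as_index=False)[
        [c for c in ("av", "a", "av_over_v") if c in long]
    ].mean()
    return {
        "per_offset": per_offset,
        "mouse_means": mouse_means,
        "anova": table,
        "offset_p": offset_p,
    }


def decode_offset_from_somata(
    responses: np.ndarray,
    trials: pd.DataFrame,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Decode the speaker offset from somatic responses, A and AV trials
    separately, with leave-one-out cross-validation and a label-permutation
    shuffle null (100 permutations). All neurons are included."""
    responses = np.atleast_2d(responses)
    keep = _azimuth_congruent(trials)
    cond = trials["condition"].to_numpy()
    oaz = trials["offset_az_deg"].to_numpy(float)
    rng = np.random.default_rng(seed)
    out = {}
    for c in ("A", "AV"):
        sel = keep & (cond == c)
        offsets = np.unique(oaz[sel])
        geom = ArrayGeometry(azimuths=tuple(offsets), elevations=(0.0,))
        labels = np.searchsorted(offsets, oaz[sel])
        resp = responses[:, sel]
        results, summary = _decoder.loo_decode(resp, labels, geom)
        shuf = np.empty(n_shuffles)
        for s in range(n_shuffles):
            perm = rng.permutation(labels.size)
            _, ssum = _decoder.loo_decode(resp, labels[perm], geom)
            shuf[s] = ssum["mean_error_deg"]
        out[c] = {
            "results": results,
            "mean_error_deg": summary["mean_error_deg"],
            "shuffle_errors": shuf,
            "chance_interval": (
                float(np.quantile(shuf, 0.025)),
                float(np.quantile(shuf, 0.975)),
            ),
        }
    return out
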