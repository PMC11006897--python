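"""Naive-Bayes maximum-likelihood decoding of stimulus position.

Each axon's trial response to stimulus position s is modeled as a normal
distribution with training mean R_{i,s} and training standard deviation
sigma_{i,s}. Assuming conditional independence across axons given the
stimulus, the population log-likelihood of a response vector n is

    log P(n | s) = sum_i log N(n_i; R_{i,s}, sigma_{i,s})

and the decoded position is the maximum-likelihood estimate
s_hat = argmax_s log P(n | s). The stimulus prior is uniform and the
evidence term constant in s, so both cancel in the argmax and are not
stored. Decoding error is the Euclidean distance, in the degree plane,
between the true and decoded positions.

Cross-validation is 5-fold, stratified by position so every fold trains on
every position; every trial is decoded exactly once. The shuffle null
permutes position labels across trials and repeats the full CV decode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .geometry import ArrayGeometry

__all__ = [
    "GaussianResponseModel",
    "fit_model",
    "log_likelihood",
    "decode_trial",
    "crossval_decode",
    "shuffle_null",
    "error_vs_n_axons",
    "loo_decode",
]

SIGMA_FLOOR = 1e-3
MIN_AXONS = 10


@dataclass
class GaussianResponseModel:
    """Per-axon, per-position response mean and s.d. (sigma floored)."""

    means: np.ndarray  # (n_axons, n_positions)
    sds: np.ndarray  # (n_axons, n_positions)
    sigma_floor: float = SIGMA_FLOOR

    @property
    def n_axons(self) -> int:
        return self.means.shape[0]

    @property
    def n_positions(self) -> int:
        return self.means.shape[1]


def fit_model(
    responses: np.ndarray,
    pos_idx: np.ndarray,
    n_positions: int,
    sigma_floor: float = SIGMA_FLOOR,
) -> GaussianResponseModel:
    """Training means and (n−1)-denominator s.d.s per axon and position."""
    responses = np.atleast_2d(responses)
    means = np.empty((responses.shape[0], n_positions))
    sds = np.empty_like(means)
    for p in range(n_positions):
        sel = pos_idx == p
        if sel.sum() < 2:
            raise ValueError(f"position {p} has fewer than 2 training trials")
        means[:, p] = responses[:, sel].mean(axis=1)
        sds[:, p] = responses[:, sel].std(axis=1, ddof=1)
    sds = np.maximum(sds, sigma_floor)
    return GaussianResponseModel(means=means, sds=sds, sigma_floor=sigma_floor)


def _ll_matrix(model: GaussianResponseModel, responses: np.ndarray) -> np.ndarray:
    """(n_trials, n_positions) log-likelihoods, normal density summed over
    axons: -((r - R)^2 / (2 sigma^2)) - log(sigma) - log(2 pi)/2."""
    r = responses[:, :, None]  # axon x trial x 1
    mu = model.means[:, None, :]
    sd = model.sds[:, None, :]
    z = (r - mu) / sd
    return (-0.5 * z**2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)).sum(axis=0)


def log_likelihood(model: GaussianResponseModel, response_vector: np.ndarray) -> np.ndarray:
    """log P(n | s) for every position s (no prior, no evidence term)."""
    r = np.asarray(response_vector, dtype=float)
    if r.shape != (model.n_axons,):
        raise ValueError(
            f"response vector length {r.shape} != {model.n_axons} axons"
        )
    return _ll_matrix(model, r[:, None])[0]


def decode_trial(
    model: GaussianResponseModel,
    response_vector: np.ndarray,
    tie_rng: Optional[np.random.Generator] = None,
) -> tuple[int, np.ndarray]:
    """Maximum-likelihood position index; exact ties broken uniformly."""
    ll = log_likelihood(model, response_vector)
    winners = np.flatnonzero(ll == ll.max())
    if winners.size == 1 or tie_rng is None:
        return int(winners[0]), ll
    return int(tie_rng.choice(winners)), ll


def _errors_frame(
    true_idx: np.ndarray,
    decoded_idx: np.ndarray,
    fold: np.ndarray,
    geometry: ArrayGeometry,
) -> pd.DataFrame:
    pts = geometry.position_array()
    err = np.hypot(
        pts[true_idx, 0] - pts[decoded_idx, 0],
        pts[true_idx, 1] - pts[decoded_idx, 1],
    )
    return pd.DataFrame(
        {
            "true_pos": true_idx,
            "decoded_pos": decoded_idx,
            "true_az": pts[true_idx, 0],
            "true_el": pts[true_idx, 1],
            "decoded_az": pts[decoded_idx, 0],
            "decoded_el": pts[decoded_idx, 1],
            "error_deg": err,
            "fold": fold,
        }
    )


def mean_error_by_position(results: pd.DataFrame) -> float:
    """Errors averaged within position, then across positions."""
    return float(results.groupby("true_pos")["error_deg"].mean().mean())


def crossval_decode(
    responses: np.ndarray,
    pos_idx: np.ndarray,
    geometry: ArrayGeometry,
    k: int = 5,
    seed: int = 0,
    min_axons: int = MIN_AXONS,
    sigma_floor: float = SIGMA_FLOOR,
    enforce_min_axons: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """k-fold cross-validated decoding of every trial.

    Folds are stratified by position; each trial is decoded exactly once
    from a model trained on the remaining folds. Sessions with
    ``min_axons`` or fewer axons are rejected (the recorded-session gate),
    unless ``enforce_min_axons`` is disabled for small benchmarks.
    """
    responses = np.atleast_2d(responses)
    n_axons, n_trials = responses.shape
    if enforce_min_axons and n_axons <= min_axons:
        raise ValueError(
            f"session yields {n_axons} axons; decoder requires more than {min_axons}"
        )
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
    true_idx = np.asarray(pos_idx, dtype=int)
    decoded = np.empty(n_trials, dtype=int)
    fold_id = np.empty(n_trials, dtype=int)
    for f, (train, test) in enumerate(skf.split(responses.T, true_idx)):
        model = fit_model(
            responses[:, train], true_idx[train], geometry.n_positions, sigma_floor
        )
        ll = _ll_matrix(model, responses[:, test])
        best = np.argmax(ll, axis=1)
        ties = ll == ll.max(axis=1, keepdims=True)
        for row in np.flatnonzero(ties.sum(axis=1) > 1):
            best[row] = rng.choice(np.flatnonzero(ties[row]))
        decoded[test] = best
        fold_id[test] = f
    results = _errors_frame(true_idx, decoded, fold_id, geometry)
    summary = {
        "mean_error_deg": mean_error_by_position(results),
        "n_axons": n_axons,
        "n_trials": n_trials,
        "k": k,
    }
    return results, summary


def shuffle_null(
    responses: np.ndarray,
    pos_idx: np.ndarray,
    geometry: ArrayGeometry,
    k: int = 5,
    n_shuffles: int = 100,
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Mean decoding errors after permuting trial position labels."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(len(pos_idx))
        _, summary = crossval_decode(
            responses,
            np.asarray(pos_idx)[perm],
            geometry,
            k=k,
            seed=int(rng.integers(2**31)),
            **kwargs,
        )
        out[s] = summary["mean_error_deg"]
    return out


def error_vs_n_axons(
    responses: np.ndarray,
    pos_idx: np.ndarray,
    geometry: ArrayGeometry,
    n_grid: Sequence[int],
    n_iter: int = 100,
    k: int = 5,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Decoding error vs. number of axons, subsampled without replacement.

    For each population size, axons are drawn without replacement (to keep
    the independence assumption intact), the full CV decode is run, and
    the draw is repeated ``n_iter`` times for the mean and percentile 95%
    CI. The fold assignment is held fixed across draws so that the full
    pool yields a zero-width interval.
    """
    responses = np.atleast_2d(responses)
    pool = responses.shape[0]
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31))
    rows = []
    for n in n_grid:
        if n > pool:
            raise ValueError(f"cannot draw {n} axons from a pool of {pool}")
        errs = np.empty(n_iter)
        for it in range(n_iter):
            sub = np.sort(rng.choice(pool, size=n, replace=False))
            # the >10-axon gate applies to sessions, not subsample draws
            _, summary = crossval_decode(
                responses[sub], pos_idx, geometry, k=k, seed=fold_seed,
                enforce_min_axons=False, **kwargs
            )
            errs[it] = summary["mean_error_deg"]
        rows.append(
            {
                "n_axons": n,
                "mean_error_deg": errs.mean(),
                "ci_lo": np.quantile(errs, 0.025),
                "ci_hi": np.quantile(errs, 0.975),
            }
        )
    return pd.DataFrame(rows)


def loo_decode(
    responses: np.ndarray,
    pos_idx: np.ndarray,
    geometry: ArrayGeometry,
    sigma_floor: float = SIGMA_FLOOR,
) -> tuple[pd.DataFrame, dict]:
    """Leave-one-out cross-validated decoding (somatic sessions).

    Deterministic given the data: fold t trains on every trial but t.
    Requires at least 3 trials per position so the training s.d. is
    defined in every fold.
    """
    responses = np.atleast_2d(responses)
    true_idx = np.asarray(pos_idx, dtype=int)
    counts = np.bincount(true_idx, minlength=geometry.n_positions)
    if counts.min() < 3:
        raise ValueError("leave-one-out decoding needs >= 3 trials per position")
    n_trials = responses.shape[1]
    decoded = np.empty(n_trials, dtype=int)
    for t in range(n_trials):
        train = np.ones(n_trials, dtype=bool)
        train[t] = False
        model = fit_model(
            responses[:, train], true_idx[train], geometry.n_positions, sigma_floor
        )
        decoded[t], _ = decode_trial(model, responses[:, t])
    results = _errors_frame(true_idx, decoded, np.arange(n_trials), geometry)
    summary = {
        "mean_error_deg": mean_error_by_position(results),
        "n_axons": responses.shape[0],
        "n_trials": n_trials,
        "k": n_trials,
    }
    return results, summary
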