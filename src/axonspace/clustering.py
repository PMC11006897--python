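"""Correlation-based grouping of bouton ROIs into putative axons.

Boutons of one axon share presynaptic activity, so their ΔF/F traces are
highly correlated; a Bayesian population decoder that treats every bouton
as independent would otherwise double-count evidence. Pairs of ROIs whose
full-trace Pearson correlation reaches the threshold (0.3, established
from anatomically verified same-axon bouton pairs) are agglomerated in
random order: the first drawn pair seeds a cluster, and each subsequent
pair joins an existing cluster when at least one of its ROIs correlates at
threshold with at least one current member (or already belongs to it),
otherwise it seeds a new cluster. ROIs in no qualifying pair remain
singletons. Each cluster's activity is represented by the member with the
largest mean ΔF/F, not an average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AxonAssignment", "cluster_axons", "cluster_activity"]

R_THRESHOLD = 0.3


@dataclass
class AxonAssignment:
    """Partition of ROIs into putative axons.

    roi_to_cluster : cluster id per ROI index
    representatives : per cluster, the member ROI with largest mean ΔF/F
    members : per cluster, sorted member ROI indices
    """

    roi_to_cluster: np.ndarray
    representatives: list[int]
    members: list[list[int]]
    zero_variance_rois: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.members)


def cluster_axons(
    dff: np.ndarray, r_thresh: float = R_THRESHOLD, seed: int = 0
) -> AxonAssignment:
    """Group ROIs whose trace correlation reaches ``r_thresh``.

    ``dff`` is (n_roi, n_frames) full-session ΔF/F (trial-response
    matrices work identically). The paper's order-dependent agglomeration
    is preserved; ``seed`` controls the random pair order, and a pair whose
    ROIs match two different clusters joins the one matched by its
    first-drawn ROI. Zero-variance traces (undefined correlation) are
    treated as below threshold and reported.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    n = dff.shape[0]
    if n == 0:
        raise ValueError("need at least one ROI")
    sd = dff.std(axis=1)
    zero_var = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(dff) if n > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=-np.inf)
    above = corr >= r_thresh
    np.fill_diagonal(above, False)

    rng = np.random.default_rng(seed)
    pairs = np.argwhere(np.triu(above, k=1))
    order = rng.permutation(len(pairs))

    cluster_of = -np.ones(n, dtype=int)
    members: list[list[int]] = []
    for k in order:
        i, j = int(pairs[k, 0]), int(pairs[k, 1])
        if rng.random() < 0.5:  # pair orientation is arbitrary
            i, j = j, i
        target = -1
        for roi in (i, j):
            if cluster_of[roi] >= 0:
                target = cluster_of[roi]
                break
            hit = next(
                (
                    c
                    for c, mem in enumerate(members)
                    if any(above[roi, m] for m in mem)
                ),
                -1,
            )
            if hit >= 0:
                target = hit
                break
        if target < 0:
            target = len(members)
            members.append([])
        for roi in (i, j):
            if cluster_of[roi] < 0:
                cluster_of[roi] = target
                members[target].append(roi)
    for roi in range(n):
        if cluster_of[roi] < 0:
            cluster_of[roi] = len(members)
            members.append([roi])

    mean_dff = dff.mean(axis=1)
    reps = [int(mem[int(np.argmax(mean_dff[mem]))]) for mem in members]
    return AxonAssignment(
        roi_to_cluster=cluster_of,
        representatives=reps,
        members=[sorted(m) for m in members],
        zero_variance_rois=[int(z) for z in zero_var],
    )


def cluster_activity(assignment: AxonAssignment, responses: np.ndarray) -> np.ndarray:
    """Axon x trial responses: each cluster contributes its representative
    ROI's rows (largest mean ΔF/F member), not a member average."""
    responses = np.atleast_2d(responses)
    if responses.shape[0] <= max(assignment.representatives):
        raise ValueError("responses do not cover all representative ROIs")
    return responses[assignment.representatives]
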