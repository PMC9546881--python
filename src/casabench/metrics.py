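"""Evaluation metrics: OSPA, assignment precision/recall, CLEAR-MOT.

OSPA (optimal subpattern assignment) is a true metric between point sets
combining a localization term (optimally assigned, cutoff-saturated
distances) and a cardinality term penalizing unmatched points at the
cutoff ``c``.  Precision/recall count true positives under a one-to-one
optimal assignment with a distance cutoff.  CLEAR-MOT evaluates tracks
against ground truth with persistent frame-to-frame correspondences:
MOTP is the mean matched distance and MOTA = 1 − (FP̄ + M̄ + MMĒ) with
rates normalized by the total number of ground-truth objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["OSPAResult", "MOTReport", "ospa", "match_and_pr", "clear_mot"]

_BIG = 1e12


@dataclass(frozen=True)
class OSPAResult:
    """OSPA distance with its localization and cardinality components."""

    total: float
    localization: float
    cardinality: float
    c: float
    p: float


@dataclass(frozen=True)
class MOTReport:
    """CLEAR-MOT evaluation: MOTP (px) and the normalized error rates.

    ``fp_rate``, ``miss_rate`` and ``mismatch_rate`` are per-object
    per-frame rates (counts divided by the total number of ground-truth
    objects over all frames); MOTA = 1 − their sum, exactly.
    """

    motp: float
    fp_rate: float
    miss_rate: float
    mismatch_rate: float
    n_truth: int
    n_matches: int
    n_fp: int
    n_miss: int
    n_mismatch: int
    distance_sum: float
    cutoff: float

    @property
    def mota(self) -> float:
        return 1.0 - (self.fp_rate + self.miss_rate + self.mismatch_rate)

    @classmethod
    def from_rates(cls, fp_rate: float, miss_rate: float, mismatch_rate: float,
                   motp: float = float("nan"), cutoff: float = 5.0) -> "MOTReport":
        """Build a report directly from published normalized rates."""
        return cls(motp, fp_rate, miss_rate, mismatch_rate,
                   0, 0, 0, 0, 0, float("nan"), cutoff)


def _as_points(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.size == 0:
        return np.empty((0, 2))
    return a.reshape(len(a), -1)


def ospa(X, Y, c: float = 20.0, p: float = 2.0) -> OSPAResult:
    """Optimal subpattern assignment distance between two point sets.

    With m = |X| <= n = |Y| (sets swapped otherwise):
    total = ((1/n)·(min over assignments Σ d_c^p + c^p·(n−m)))^(1/p),
    d_c = min(d, c).  Empty vs empty is 0 by convention.
    """
    if c <= 0 or p < 1:
        raise ValueError("require c > 0 and p >= 1")
    X, Y = _as_points(X), _as_points(Y)
    if len(X) > len(Y):
        X, Y = Y, X
    m, n = len(X), len(Y)
    if n == 0:
        return OSPAResult(0.0, 0.0, 0.0, c, p)
    if m == 0:
        return OSPAResult(c, 0.0, c, c, p)
    d = np.minimum(cdist(X, Y), c)
    rows, cols = linear_sum_assignment(d**p)
    loc_pp = float((d[rows, cols] ** p).sum())
    card_pp = c**p * (n - m)
    total = ((loc_pp + card_pp) / n) ** (1.0 / p)
    return OSPAResult(total, (loc_pp / n) ** (1.0 / p), (card_pp / n) ** (1.0 / p), c, p)


def match_and_pr(truth, detections, cutoff: float = 20.0):
    """Optimal one-to-one matching under a cutoff; returns (precision, recall,
    matching) with matching a list of (truth_index, detection_index) pairs.

    precision = TP / #detections and recall = TP / #truth; with no
    detections, precision is 1 if the truth is also empty and 0 otherwise
    (and symmetrically for recall), so failure points stay well defined.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    t, d = _as_points(truth), _as_points(detections)
    if len(d) == 0 and len(t) == 0:
        return 1.0, 1.0, []
    if len(d) == 0:
        return 0.0, 0.0, []
    if len(t) == 0:
        return 0.0, 1.0, []
    dist = cdist(t, d)
    cost = np.where(dist <= cutoff, dist, _BIG)
    rows, cols = linear_sum_assignment(cost)
    matching = [(int(i), int(j)) for i, j in zip(rows, cols) if dist[i, j] <= cutoff]
    tp = len(matching)
    return tp / len(d), tp / len(t), matching


def clear_mot(truth: pd.DataFrame, tracks, c_T: float = 5.0) -> MOTReport:
    """CLEAR-MOT evaluation of a track set against a ground-truth table.

    ``truth`` has columns frame, cell_id, x, y; ``tracks`` is a TrackSet or
    a table with columns track_id, frame, x, y.  Correspondences persist
    across frames while the pair stays within ``c_T``; remaining objects
    are matched per frame by optimal assignment under ``c_T``.  A truth
    object re-matched to a different track counts one identity mismatch.
    """
    if hasattr(tracks, "to_frame"):
        tracks = tracks.to_frame()
    truth_by_frame = {int(f): g for f, g in truth.groupby("frame")}
    tracks_by_frame = ({int(f): g for f, g in tracks.groupby("frame")}
                       if len(tracks) else {})
    frames = sorted(set(truth_by_frame) | set(tracks_by_frame))

    corr: dict[int, int] = {}       # gt id -> track id
    last_track: dict[int, int] = {}  # gt id -> last matched track id (for MME)
    n_truth = n_matches = n_fp = n_miss = n_mme = 0
    dist_sum = 0.0

    for f in frames:
        gt = truth_by_frame.get(f)
        tr = tracks_by_frame.get(f)
        gt_ids = gt["cell_id"].to_numpy(dtype=int) if gt is not None else np.array([], int)
        gt_xy = gt[["x", "y"]].to_numpy(dtype=float) if gt is not None else np.empty((0, 2))
        tr_ids = tr["track_id"].to_numpy(dtype=int) if tr is not None else np.array([], int)
        tr_xy = tr[["x", "y"]].to_numpy(dtype=float) if tr is not None else np.empty((0, 2))
        n_truth += len(gt_ids)
        gt_pos = {g: i for i, g in enumerate(gt_ids)}
        tr_pos = {h: i for i, h in enumerate(tr_ids)}

        matched_gt: dict[int, int] = {}
        # 1. persist previous correspondences still within the cutoff
        for g, h in list(corr.items()):
            if g in gt_pos and h in tr_pos:
                d = float(np.linalg.norm(gt_xy[gt_pos[g]] - tr_xy[tr_pos[h]]))
                if d <= c_T:
                    matched_gt[g] = h
                    dist_sum += d
        # 2. optimal assignment for the rest
        free_g = [g for g in gt_ids if g not in matched_gt]
        used_h = set(matched_gt.values())
        free_h = [h for h in tr_ids if h not in used_h]
        if free_g and free_h:
            d = cdist(gt_xy[[gt_pos[g] for g in free_g]],
                      tr_xy[[tr_pos[h] for h in free_h]])
            cost = np.where(d <= c_T, d, _BIG)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if d[i, j] <= c_T:
                    g, h = free_g[i], free_h[j]
                    matched_gt[g] = h
                    dist_sum += float(d[i, j])
                    if g in last_track and last_track[g] != h:
                        n_mme += 1
        n_matches += len(matched_gt)
        n_miss += len(gt_ids) - len(matched_gt)
        n_fp += len(tr_ids) - len(matched_gt)
        corr = dict(matched_gt)
        last_track.update(matched_gt)

    if n_truth == 0:
        raise ValueError("ground truth is empty; CLEAR-MOT is undefined")
    motp = dist_sum / n_matches if n_matches else float("nan")
    return MOTReport(
        motp=motp,
        fp_rate=n_fp / n_truth,
        miss_rate=n_miss / n_truth,
        mismatch_rate=n_mme / n_truth,
        n_truth=n_truth,
        n_matches=n_matches,
        n_fp=n_fp,
        n_miss=n_miss,
        n_mismatch=n_mme,
        distance_sum=dist_sum,
        cutoff=c_T,
    )
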