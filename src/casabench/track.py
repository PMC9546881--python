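"""Multi-target tracking over per-frame detections.

Four classical data-association strategies share a constant-velocity Kalman
filter: nearest neighbor (NN, per-track greedy), global nearest neighbor
(GNN, Hungarian one-to-one assignment), the probabilistic data association
filter (PDAF, per-track weighting of all gated detections), and the joint
PDAF (JPDAF, exhaustive feasible-event enumeration over clusters of tracks
sharing gated detections).

State is (x, y, vx, vy) with white-acceleration process noise; measurements
are detection centroids.  Tracks confirm after two consecutive
associations and die after three consecutive misses; tentative tracks are
excluded from the evaluation output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["KalmanConfig", "Track", "TrackSet", "kalman_cv_step", "track",
           "TRACKERS"]

TRACKERS = ("nn", "gnn", "pdaf", "jpdaf")

TRACK_COLUMNS = ["track_id", "frame", "x", "y"]


@dataclass(frozen=True)
class KalmanConfig:
    """Shared tracker configuration.

    ``T`` frame period (s); ``process_noise`` white-acceleration intensity
    (px²/s³); ``measurement_std`` detection noise (px); ``gate`` association
    radius (px); ``P_D`` detection probability; ``clutter_density`` false
    alarms per px²; confirmation after ``confirm_hits`` consecutive
    associations, deletion after ``delete_misses`` consecutive misses.
    """

    T: float = 1.0 / 15.0
    process_noise: float = 600.0  # matches the swim modes' maneuver scale
    measurement_std: float = 1.0
    gate: float = 20.0
    P_D: float = 0.99             # measured detection rate of isolated cells
    clutter_density: float = 1e-6
    confirm_hits: int = 2
    delete_misses: int = 3
    init_speed_std: float = 50.0  # of the order of the cells' swim speed
    merge_distance: float = 2.0
    # extra innovation std (px) added in quadrature when computing association
    # probabilities in PDAF/JPDAF (not in the state update); absorbs maneuver
    # model mismatch (Brownian jumps, ribbon turning points) that would
    # otherwise starve tracks of association probability
    pdaf_innovation_inflation: float = 4.0
    jpdaf_max_cluster: int = 8
    jpdaf_max_events: int = 20000

    def __post_init__(self) -> None:
        if min(self.T, self.process_noise, self.measurement_std, self.gate,
               self.clutter_density, self.init_speed_std) <= 0:
            raise ValueError("Kalman parameters must be positive")
        if not 0 < self.P_D <= 1:
            raise ValueError("P_D must be in (0, 1]")

    def matrices(self):
        t = self.T
        f = np.array([[1, 0, t, 0], [0, 1, 0, t], [0, 0, 1, 0], [0, 0, 0, 1]], float)
        qb = self.process_noise * np.array([[t**3 / 3, t**2 / 2], [t**2 / 2, t]])
        q = np.zeros((4, 4))
        q[np.ix_([0, 2], [0, 2])] = qb
        q[np.ix_([1, 3], [1, 3])] = qb
        h = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], float)
        r = self.measurement_std**2 * np.eye(2)
        return f, q, h, r


@dataclass
class KalmanState:
    x: np.ndarray  # (4,) state mean
    P: np.ndarray  # (4, 4) covariance


@dataclass
class Track:
    """One target hypothesis with its filtered trajectory."""

    id: int
    state: KalmanState
    status: str = "tentative"  # tentative | confirmed | dead
    consecutive_hits: int = 1
    consecutive_misses: int = 0
    history: list = field(default_factory=list)  # (frame, x, y) while confirmed


@dataclass
class TrackSet:
    """All tracks produced by one tracker run."""

    tracks: list

    def to_frame(self) -> pd.DataFrame:
        rows = [(t.id, f, x, y) for t in self.tracks for f, x, y in t.history]
        return pd.DataFrame(rows, columns=TRACK_COLUMNS)

    @property
    def confirmed(self) -> list:
        return [t for t in self.tracks if t.history]


def _new_track(tid: int, z: np.ndarray, cfg: KalmanConfig) -> Track:
    x = np.array([z[0], z[1], 0.0, 0.0])
    p = np.diag([cfg.measurement_std**2, cfg.measurement_std**2,
                 cfg.init_speed_std**2, cfg.init_speed_std**2])
    return Track(tid, KalmanState(x, p))


def _predict(st: KalmanState, f: np.ndarray, q: np.ndarray) -> None:
    st.x = f @ st.x
    st.P = f @ st.P @ f.T + q


def _innovation_cov(st: KalmanState, h: np.ndarray, r: np.ndarray) -> np.ndarray:
    return h @ st.P @ h.T + r


def _update(st: KalmanState, z: np.ndarray, h: np.ndarray, r: np.ndarray) -> None:
    s = _innovation_cov(st, h, r)
    k = st.P @ h.T @ np.linalg.inv(s)
    st.x = st.x + k @ (z - h @ st.x)
    ikh = np.eye(4) - k @ h
    # Joseph form keeps the covariance symmetric positive definite
    st.P = ikh @ st.P @ ikh.T + k @ r @ k.T


def kalman_cv_step(state: KalmanState, detection, cfg: KalmanConfig) -> KalmanState:
    """One constant-velocity predict/update cycle.

    ``detection`` is an (x, y) measurement or None; detections outside the
    gate (Euclidean, around the predicted position) are treated as misses.
    """
    f, q, h, r = cfg.matrices()
    if not np.all(np.linalg.eigvalsh((state.P + state.P.T) / 2) > 0):
        raise ValueError("state covariance must be symmetric positive definite")
    _predict(state, f, q)
    if detection is not None:
        z = np.asarray(detection, dtype=float)
        if np.linalg.norm(z - h @ state.x) <= cfg.gate:
            _update(state, z, h, r)
    return state


def _gaussian_like(nu: np.ndarray, s: np.ndarray) -> float:
    det = np.linalg.det(s)
    inv = np.linalg.inv(s)
    return math.exp(-0.5 * float(nu @ inv @ nu)) / (2 * math.pi * math.sqrt(det))


def _pdaf_update(tr: Track, dets: np.ndarray, betas: np.ndarray, beta0: float,
                 h: np.ndarray, r: np.ndarray) -> None:
    """PDAF measurement update with association probabilities ``betas``.

    The association probabilities may come from an inflated-likelihood model
    (see ``KalmanConfig.pdaf_innovation_inflation``); the state update uses
    the filter's own innovation covariance so a confidently associated
    measurement is weighted exactly as in the plain Kalman update.
    """
    st = tr.state
    s = _innovation_cov(st, h, r)
    k = st.P @ h.T @ np.linalg.inv(s)
    nus = dets - (h @ st.x)[None, :]
    nu = (betas[:, None] * nus).sum(axis=0)
    st.x = st.x + k @ nu
    pc = st.P - k @ s @ k.T
    spread = (betas[:, None, None] * (nus[:, :, None] @ nus[:, None, :])).sum(axis=0)
    ptilde = k @ (spread - np.outer(nu, nu)) @ k.T
    st.P = beta0 * st.P + (1 - beta0) * pc + ptilde


def _enumerate_events(track_gates: list[list[int]]):
    """Yield feasible joint events as tuples of detection indices (-1 = miss)."""

    def rec(i, used, current):
        if i == len(track_gates):
            yield tuple(current)
            return
        yield from rec(i + 1, used, current + [-1])
        for j in track_gates[i]:
            if j not in used:
                yield from rec(i + 1, used | {j}, current + [j])

    yield from rec(0, frozenset(), [])


def _count_events(track_gates: list[list[int]], cap: int) -> int:
    n = 0
    for _ in _enumerate_events(track_gates):
        n += 1
        if n > cap:
            return n
    return n


def track(detections: pd.DataFrame, algo: str, cfg: KalmanConfig | None = None,
          frames: range | None = None) -> TrackSet:
    """Run a multi-target tracker over a detection table.

    ``detections`` must have columns frame, x, y (ordered or orderable by
    frame).  Returns the closed track set; only frames where a track was
    confirmed appear in its history.
    """
    if algo not in TRACKERS:
        raise ValueError(f"unknown tracker {algo!r}; choose from {TRACKERS}")
    if cfg is None:
        cfg = KalmanConfig()
    f_m, q_m, h_m, r_m = cfg.matrices()

    if len(detections) and frames is None:
        frames = range(int(detections["frame"].min()), int(detections["frame"].max()) + 1)
    elif frames is None:
        return TrackSet([])
    by_frame = {int(f): g[["x", "y"]].to_numpy(dtype=float)
                for f, g in detections.groupby("frame")}

    tracks: list[Track] = []
    dead: list[Track] = []
    next_id = 0

    for fr in frames:
        dets = by_frame.get(fr, np.empty((0, 2)))
        active = [t for t in tracks if t.status != "dead"]
        for t in active:
            _predict(t.state, f_m, q_m)
        preds = np.array([t.state.x[:2] for t in active]).reshape(-1, 2)

        if len(active) and len(dets):
            dist = np.linalg.norm(preds[:, None, :] - dets[None, :, :], axis=2)
            gated = dist <= cfg.gate
        else:
            dist = np.zeros((len(active), len(dets)))
            gated = np.zeros((len(active), len(dets)), dtype=bool)

        assigned_det = set()
        hit = [False] * len(active)

        if algo == "nn":
            for i, t in enumerate(active):
                cands = [j for j in np.argsort(dist[i]) if gated[i, j]
                         and j not in assigned_det]
                if cands:
                    j = cands[0]
                    _update(t.state, dets[j], h_m, r_m)
                    assigned_det.add(j)
                    hit[i] = True
        elif algo == "gnn":
            if gated.any():
                big = 1e9
                cost = np.where(gated, dist, big)
                rows, cols = linear_sum_assignment(cost)
                for i, j in zip(rows, cols):
                    if gated[i, j]:
                        _update(active[i].state, dets[j], h_m, r_m)
                        assigned_det.add(j)
                        hit[i] = True
        elif algo == "pdaf":
            det_assoc = np.zeros(len(dets))
            for i, t in enumerate(active):
                js = np.flatnonzero(gated[i])
                if len(js) == 0:
                    continue
                s = (_innovation_cov(t.state, h_m, r_m)
                     + cfg.pdaf_innovation_inflation**2 * np.eye(2))
                liks = np.array([_gaussian_like(dets[j] - h_m @ t.state.x, s)
                                 for j in js])
                l_ratio = cfg.P_D * liks / cfg.clutter_density
                b = 1.0 - cfg.P_D * 0.997
                denom = b + l_ratio.sum()
                betas = l_ratio / denom
                beta0 = b / denom
                _pdaf_update(t, dets[js], betas, beta0, h_m, r_m)
                # for track management, count as a miss when the no-association
                # hypothesis dominates (prunes tracks fed only by neighbors)
                hit[i] = beta0 < 0.5
                det_assoc[js] += betas
            # spawn only from weakly associated detections
            assigned_det = set(np.flatnonzero(det_assoc >= 0.3).tolist())
        else:  # jpdaf
            assigned_det, hit = _jpdaf_frame(active, dets, gated, dist, cfg,
                                             h_m, r_m)

        # merge coalesced duplicates: two tracks on one target starve each
        # other in the probabilistic filters; keep the older of the pair.
        # Requires similar velocities so crossing targets are not merged.
        if cfg.merge_distance > 0 and len(active) > 1:
            pos = np.array([t.state.x[:2] for t in active])
            vel = np.array([t.state.x[2:] for t in active])
            dd = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            dv = np.linalg.norm(vel[:, None] - vel[None, :], axis=2)
            for i in range(len(active)):
                for j in range(i + 1, len(active)):
                    if dd[i, j] < cfg.merge_distance and dv[i, j] < 15.0:
                        a, b = ((i, j) if active[i].consecutive_hits
                                >= active[j].consecutive_hits else (j, i))
                        if active[b].status != "dead":
                            active[b].status = "dead"

        # track management
        for i, t in enumerate(active):
            if t.status == "dead":  # merged away this frame
                continue
            if hit[i]:
                t.consecutive_hits += 1
                t.consecutive_misses = 0
                if t.status == "tentative" and t.consecutive_hits >= cfg.confirm_hits:
                    t.status = "confirmed"
            else:
                t.consecutive_misses += 1
                t.consecutive_hits = 0
                if t.status == "tentative" or t.consecutive_misses >= cfg.delete_misses:
                    t.status = "dead"
            if t.status == "confirmed":
                t.history.append((fr, float(t.state.x[0]), float(t.state.x[1])))

        tracks = [t for t in tracks if t.status != "dead" or not _drop(dead, t)]
        for j in range(len(dets)):
            if j not in assigned_det:
                tr = _new_track(next_id, dets[j], cfg)
                next_id += 1
                tracks.append(tr)

    dead.extend(t for t in tracks if t not in dead)
    return TrackSet(dead)


def _drop(dead: list, t: Track) -> bool:
    dead.append(t)
    return True


def _jpdaf_frame(active, dets, gated, dist, cfg, h_m, r_m):
    """Joint probabilistic association for one frame (cluster-wise)."""
    det_assoc = np.zeros(len(dets))
    hit = [False] * len(active)
    if not gated.any():
        return set(), hit

    # connected clusters of tracks sharing gated detections
    n_tr = len(active)
    parent = list(range(n_tr))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    det_owner: dict[int, int] = {}
    for i in range(n_tr):
        for j in np.flatnonzero(gated[i]):
            if j in det_owner:
                ra, rb = find(i), find(det_owner[j])
                parent[ra] = rb
            else:
                det_owner[j] = i
    clusters: dict[int, list[int]] = {}
    for i in range(n_tr):
        if gated[i].any():
            clusters.setdefault(find(i), []).append(i)

    for members in clusters.values():
        det_ids = sorted({j for i in members for j in np.flatnonzero(gated[i])})
        track_gates = [[det_ids.index(j) for j in np.flatnonzero(gated[i])]
                       for i in members]
        use_exact = len(members) <= cfg.jpdaf_max_cluster and _count_events(
            track_gates, cfg.jpdaf_max_events) <= cfg.jpdaf_max_events
        if not use_exact:
            # approximation: optimal hard assignment within the cluster
            sub = dist[np.ix_(members, det_ids)]
            sub = np.where(gated[np.ix_(members, det_ids)], sub, 1e9)
            rows, cols = linear_sum_assignment(sub)
            for a, b in zip(rows, cols):
                if sub[a, b] < 1e9:
                    i = members[a]
                    _update(active[i].state, dets[det_ids[b]], h_m, r_m)
                    hit[i] = True
                    det_assoc[det_ids[b]] = 1.0
            continue

        liks = np.zeros((len(members), len(det_ids)))
        for a, i in enumerate(members):
            s = (_innovation_cov(active[i].state, h_m, r_m)
                 + cfg.pdaf_innovation_inflation**2 * np.eye(2))
            for b in track_gates[a]:
                nu = dets[det_ids[b]] - h_m @ active[i].state.x
                liks[a, b] = _gaussian_like(nu, s)
        beta = np.zeros((len(members), len(det_ids)))
        total = 0.0
        for event in _enumerate_events(track_gates):
            w = 1.0
            for a, b in enumerate(event):
                if b == -1:
                    w *= 1.0 - cfg.P_D
                else:
                    w *= cfg.P_D * liks[a, b] / cfg.clutter_density
            total += w
            for a, b in enumerate(event):
                if b != -1:
                    beta[a, b] += w
        if total <= 0:
            continue
        beta /= total
        for a, i in enumerate(members):
            bsum = beta[a].sum()
            if bsum <= 1e-12:
                continue
            js = track_gates[a]
            _pdaf_update(active[i], dets[[det_ids[b] for b in js]],
                         beta[a, js], 1.0 - bsum, h_m, r_m)
            hit[i] = bsum > 0.5
            for b in js:
                det_assoc[det_ids[b]] += beta[a, b]
    return set(np.flatnonzero(det_assoc >= 0.3).tolist()), hit
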