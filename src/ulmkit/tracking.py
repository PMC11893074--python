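"""Kalman/graph microbubble tracking across consecutive frames.

Detections in adjacent frames are paired by minimising a total cost of
``1/p``, where ``p`` is the pairing probability under a linear
constant-velocity Kalman model (Gaussian innovation likelihood normalized
to 1 at zero innovation, so ``p = exp(-d^2/2)`` for Mahalanobis distance
``d``).  The per-frame pairing is solved globally on an augmented cost
matrix that also offers every track a "death" and every detection a
"birth" option.  Tracks shorter than 3 frames are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from ulmkit.core import DegenerateInputError, Localization, Track

__all__ = [
    "KalmanState",
    "TrackingParams",
    "AssignmentProblem",
    "kalman_predict",
    "kalman_update",
    "pairing_probability",
    "build_assignment_problem",
    "solve_assignment",
    "link_tracks",
]

#: large-but-finite cost for forbidden assignments
FORBIDDEN_COST = 1e9

_H = np.array([[1.0, 0.0, 0.0, 0.0],
               [0.0, 1.0, 0.0, 0.0]])


@dataclass
class KalmanState:
    """Constant-velocity state (x, y, vx, vy) in um and um/s."""

    mean: np.ndarray  # (4,)
    cov: np.ndarray  # (4, 4)
    frame: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (4,) or self.cov.shape != (4, 4):
            raise ValueError("state must be (4,) with (4, 4) covariance")
        if not np.allclose(self.cov, self.cov.T, atol=1e-6):
            raise ValueError("covariance must be symmetric")

    @property
    def position(self) -> np.ndarray:
        return self.mean[:2]

    @property
    def velocity(self) -> np.ndarray:
        return self.mean[2:]


@dataclass(frozen=True)
class TrackingParams:
    """Tuning knobs for the tracker (all config-exposed)."""

    accel_std_mm_s2: float = 1.0  # white-noise-acceleration magnitude
    meas_sigma_um: float = 4.0  # localization noise, per axis
    init_speed_std_um_s: float = 5000.0  # new-track velocity uncertainty
    gate_mahalanobis: float = 3.0
    min_track_length: int = 3


def _transition(dt: float) -> np.ndarray:
    F = np.eye(4)
    F[0, 2] = dt
    F[1, 3] = dt
    return F


def _process_noise(dt: float, accel_std_um_s2: float) -> np.ndarray:
    """Continuous white-noise-acceleration Q, independent per axis."""
    q = accel_std_um_s2**2
    q11 = q * dt**4 / 4.0
    q12 = q * dt**3 / 2.0
    q22 = q * dt**2
    Q = np.zeros((4, 4))
    Q[0, 0] = Q[1, 1] = q11
    Q[0, 2] = Q[2, 0] = Q[1, 3] = Q[3, 1] = q12
    Q[2, 2] = Q[3, 3] = q22
    return Q


def kalman_predict(state: KalmanState, dt: float,
                   accel_std_mm_s2: float = 1.0) -> KalmanState:
    """Propagate the constant-velocity model by ``dt`` seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    F = _transition(dt)
    Q = _process_noise(dt, accel_std_mm_s2 * 1000.0)
    return KalmanState(F @ state.mean, F @ state.cov @ F.T + Q,
                       frame=state.frame + 1)


def kalman_update(state: KalmanState, measurement_um: np.ndarray,
                  meas_sigma_um: float = 4.0) -> KalmanState:
    """Standard Kalman measurement update with position-only observation."""
    z = np.asarray(measurement_um, dtype=float)
    R = np.eye(2) * meas_sigma_um**2
    S = _H @ state.cov @ _H.T + R
    K = state.cov @ _H.T @ np.linalg.inv(S)
    mean = state.mean + K @ (z - _H @ state.mean)
    cov = (np.eye(4) - K @ _H) @ state.cov
    cov = 0.5 * (cov + cov.T)
    return KalmanState(mean, cov, frame=state.frame)


def _innovation_stats(predicted: KalmanState, position_um: np.ndarray,
                      meas_sigma_um: float) -> tuple[float, np.ndarray]:
    nu = np.asarray(position_um, float) - predicted.position
    S = _H @ predicted.cov @ _H.T + np.eye(2) * meas_sigma_um**2
    det = np.linalg.det(S)
    if not np.isfinite(det) or det <= 0:
        raise DegenerateInputError("singular innovation covariance")
    d2 = float(nu @ np.linalg.solve(S, nu))
    return d2, S


def pairing_probability(predicted: KalmanState, detection: Localization,
                        meas_sigma_um: float = 4.0) -> float:
    """Normalized Gaussian pairing probability ``p = exp(-d^2/2)``.

    ``d`` is the Mahalanobis distance of the innovation under the
    predicted state; ``p`` is 1 at zero innovation and the pairing cost is
    ``1/p``.
    """
    d2, _ = _innovation_stats(predicted, detection.position, meas_sigma_um)
    return float(np.exp(-0.5 * d2))


@dataclass
class AssignmentProblem:
    """Augmented square cost matrix (tracks + births) x (detections + deaths)."""

    cost: np.ndarray
    n_tracks: int
    n_detections: int

    def __post_init__(self) -> None:
        n = self.n_tracks + self.n_detections
        self.cost = np.asarray(self.cost, dtype=float)
        if self.cost.shape != (n, n):
            raise ValueError("augmented cost matrix must be square (n+m)")
        if not np.all(np.isfinite(self.cost)):
            raise ValueError("costs must be finite")


def build_assignment_problem(
    pair_costs: np.ndarray,
    birth_cost: float,
    death_cost: float,
) -> AssignmentProblem:
    """Augment an n x m pairing-cost matrix with birth/death options."""
    pair_costs = np.atleast_2d(np.asarray(pair_costs, dtype=float))
    n, m = pair_costs.shape
    cost = np.full((n + m, n + m), FORBIDDEN_COST)
    cost[:n, :m] = pair_costs
    cost[n:, m:] = 0.0  # slack block: free complements
    for i in range(n):
        cost[i, m + i] = death_cost
    for j in range(m):
        cost[n + j, j] = birth_cost
    return AssignmentProblem(cost, n, m)


def solve_assignment(
    problem: AssignmentProblem,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Globally minimum-cost assignment on the augmented matrix.

    Returns ``(pairs, dead_tracks, born_detections)`` where pairs are
    (track_index, detection_index) tuples.
    """
    rows, cols = linear_sum_assignment(problem.cost)
    n, m = problem.n_tracks, problem.n_detections
    pairs: list[tuple[int, int]] = []
    dead: list[int] = []
    born: list[int] = []
    for r, c in zip(rows, cols):
        if r < n and c < m:
            pairs.append((int(r), int(c)))
        elif r < n:
            dead.append(int(r))
        elif c < m:
            born.append(int(c))
    return sorted(pairs), sorted(dead), sorted(born)


class _ActiveTrack:
    __slots__ = ("track_id", "state", "history")

    def __init__(self, track_id: int, state: KalmanState,
                 first: Localization) -> None:
        self.track_id = track_id
        self.state = state
        self.history: list[Localization] = [first]


def _new_state(loc: Localization, params: TrackingParams,
               frame: int) -> KalmanState:
    mean = np.array([loc.x_um, loc.y_um, 0.0, 0.0])
    cov = np.diag([
        params.meas_sigma_um**2,
        params.meas_sigma_um**2,
        params.init_speed_std_um_s**2,
        params.init_speed_std_um_s**2,
    ])
    return KalmanState(mean, cov, frame=frame)


def _finalize(history: list[Localization], track_id: int,
              frame_rate_hz: float) -> Track:
    n = len(history)
    x = np.array([h.x_um for h in history])
    y = np.array([h.y_um for h in history])
    frames = np.array([h.frame for h in history])
    scores = np.array([h.score for h in history])
    if n >= 2:
        vx = np.diff(x) * frame_rate_hz
        vy = np.diff(y) * frame_rate_hz
        vx = np.append(vx, vx[-1])
        vy = np.append(vy, vy[-1])
    else:
        vx = np.zeros(1)
        vy = np.zeros(1)
    return Track(track_id, frames, x, y, vx, vy, scores)


def link_tracks(
    localizations: list[list[Localization]],
    frame_rate_hz: float,
    params: TrackingParams | None = None,
) -> list[Track]:
    """Assemble tracks by per-frame-pair global assignment.

    New tracks start with zero velocity and inflated velocity covariance;
    matched tracks receive a Kalman update; per-step velocities are raw
    displacements times the frame rate.  Tracks shorter than
    ``params.min_track_length`` localizations are dropped.
    """
    params = params or TrackingParams()
    if len(localizations) < 2:
        return []
    dt = 1.0 / frame_rate_hz
    gate2 = params.gate_mahalanobis**2
    # a pairing at the gate radius should tie with death + birth
    birth_cost = death_cost = 0.5 * float(np.exp(0.5 * gate2))

    active: list[_ActiveTrack] = []
    finished: list[tuple[int, list[Localization]]] = []
    next_id = 0
    for loc in localizations[0]:
        active.append(_ActiveTrack(next_id, _new_state(loc, params, 0), loc))
        next_id += 1

    for t in range(1, len(localizations)):
        dets = localizations[t]
        predictions = [
            kalman_predict(tr.state, dt, params.accel_std_mm_s2)
            for tr in active
        ]
        n, m = len(active), len(dets)
        if n == 0 and m == 0:
            continue
        pair_costs = np.full((n, m), FORBIDDEN_COST)
        for i, pred in enumerate(predictions):
            for j, det in enumerate(dets):
                d2, _ = _innovation_stats(pred, det.position,
                                          params.meas_sigma_um)
                if d2 <= gate2:
                    pair_costs[i, j] = float(np.exp(0.5 * d2))  # 1/p
        problem = build_assignment_problem(
            pair_costs if n and m else np.zeros((n, m)),
            birth_cost, death_cost,
        ) if (n or m) else None
        if problem is None:
            continue
        pairs, dead, born = solve_assignment(problem)

        survivors: list[_ActiveTrack] = []
        for i, j in pairs:
            tr = active[i]
            tr.state = kalman_update(predictions[i], dets[j].position,
                                     params.meas_sigma_um)
            tr.history.append(dets[j])
            survivors.append(tr)
        for i in dead:
            finished.append((active[i].track_id, active[i].history))
        for j in born:
            loc = dets[j]
            survivors.append(
                _ActiveTrack(next_id, _new_state(loc, params, t), loc)
            )
            next_id += 1
        active = sorted(survivors, key=lambda tr: tr.track_id)

    for tr in active:
        finished.append((tr.track_id, tr.history))

    tracks = [
        _finalize(history, tid, frame_rate_hz)
        for tid, history in sorted(finished)
        if len(history) >= params.min_track_length
    ]
    return tracks
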