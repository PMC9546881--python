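"""Kinematic models for the four sperm swimming modes.

Circular swimmers follow a sinusoid-modulated circular path; linear-mean
swimmers progress along a straight line while rolling side to side on a
ribbon-shaped path; hyperactive cells perform driftless Brownian motion;
immotile cells are frozen snapshots.  Flagella for the propulsive modes use
Dresdner-style travelling-wave curves with position-dependent beating
amplitudes; hyperactive and immotile flagella trail the recent head path.

All positions are in pixels, time in seconds, with the image convention of
x rightward and y downward.  Tail curves always contain exactly ``M``
points and the tail root is re-anchored exactly at the head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CircularParams",
    "LinearParams",
    "HyperactiveParams",
    "CellState",
    "TransitionModel",
    "MODES",
    "circular_head",
    "circular_tail",
    "ribbon_constant",
    "linear_head",
    "linear_tail",
    "hyperactive_head",
    "trailing_tail",
    "immotile_state",
    "step_mode",
    "jitter_position",
]

MODES = ("circular", "linear", "hyperactive", "immotile")


def ribbon_constant(A_har: float) -> float:
    """Correction constant A_c = 1 / max over θ of (sin θ + A_har·sin 3θ).

    Scales the ribbon's vertical sinusoid pair so its peak excursion is
    exactly r_h/2 regardless of the third-harmonic ratio.
    """
    if A_har < 0:
        raise ValueError("A_har must be >= 0")
    if A_har == 0:
        return 1.0
    theta = np.linspace(0.0, 2 * np.pi, 1 << 16, endpoint=False)
    vals = np.sin(theta) + A_har * np.sin(3 * theta)
    i = int(np.argmax(vals))
    fine = np.linspace(theta[i] - 2e-4, theta[i] + 2e-4, 4001)
    m = float(np.max(np.sin(fine) + A_har * np.sin(3 * fine)))
    return 1.0 / m


@dataclass(frozen=True)
class CircularParams:
    """Circular swim: radius ``r_c``, modulation amplitude ``a`` and frequency
    ``f_s`` (Hz), circular rate ``f_c`` (cycles/s), center offsets, tail
    wavelength ``lambda_`` and ``M`` tail points with amplitude profile
    b(k) = a·(alpha·lambda·k/M + beta)."""

    r_c: float = 80.0
    a: float = 3.0
    f_s: float = 4.0
    f_c: float = 50.0 / 360.0
    C_xc: float = 0.0
    C_yc: float = 0.0
    lambda_: float = 40.0
    M: int = 200
    alpha: float = 0.02
    beta: float = 0.8
    phase: float = 0.0        # initial angle on the circle (rad)
    beat_phase: float = 0.0   # initial phase of the modulating sinusoid (rad)

    def __post_init__(self) -> None:
        if self.r_c <= 0 or self.lambda_ <= 0 or self.M < 2:
            raise ValueError("require r_c > 0, lambda > 0, M >= 2")

    @staticmethod
    def deg_per_s(omega_deg: float) -> float:
        """Convert a circular rate printed in degrees/s to cycles/s."""
        return omega_deg / 360.0


@dataclass(frozen=True)
class LinearParams:
    """Linear mean swim: speed ``V`` along heading ``theta_r`` plus a ribbon
    offset of width ``r_h``, height ``r_v`` at rate ``f_l`` (Hz) with
    third-harmonic ratio ``A_har``; tail shaping via sigmoid b1, decaying
    exponential b2 and correction profile b3."""

    V: float = 50.0
    theta_r: float = 0.0
    f_l: float = 3.0
    r_h: float = 12.0
    r_v: float = 8.0
    A_har: float = 0.1
    C_xL: float = 0.0
    C_yL: float = 0.0
    lambda_: float = 40.0
    M: int = 200
    alpha: float = 22.0
    beta: float = -2.0
    gamma1: float = 5.0
    gamma2: float = 1.5
    phase: float = 0.0  # initial ribbon phase (rad)
    A_c: float = field(init=False)

    def __post_init__(self) -> None:
        if self.V < 0:
            raise ValueError("V must be >= 0")
        object.__setattr__(self, "A_c", ribbon_constant(self.A_har))


@dataclass(frozen=True)
class HyperactiveParams:
    """Driftless Brownian motion with diffusion ``sigma_b`` (px/√s) sampled at
    frame period ``T``; the tail trails the last n = ceil(0.2 s / T) head
    positions."""

    mu: tuple[float, float] = (0.0, 0.0)
    sigma_b: float = 10.0
    T: float = 1.0 / 15.0
    M: int = 200

    def __post_init__(self) -> None:
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")
        if self.T <= 0:
            raise ValueError("frame period T must be positive")

    @property
    def n(self) -> int:
        return max(1, math.ceil(0.2 / self.T))


@dataclass
class CellState:
    """Mutable per-cell simulation state.

    ``t0`` is the scene time at which the current mode started; the
    closed-form modes are evaluated at local time t − t0.
    """

    id: int
    mode: str
    head: tuple[float, float]
    tail: np.ndarray
    params: object
    head_history: list = field(default_factory=list)
    intensity_factor: float = 1.0
    rng: np.random.Generator | None = None
    heading: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic 4x4 matrix over MODES, evaluated once per ``period`` s."""

    matrix: np.ndarray
    period: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4 over the four modes")
        if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be nonnegative and sum to 1")
        object.__setattr__(self, "matrix", m)


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _tail_k(M: int) -> np.ndarray:
    # M samples spanning the full index range [0, M]
    return np.linspace(0.0, M, M)


# ---------------------------------------------------------------------------
# circular swim


def circular_head(t: float, p: CircularParams) -> tuple[float, float]:
    """Head position on the sinusoid-modulated circular path at time t."""
    r = p.r_c + p.a * math.sin(2 * math.pi * p.f_s * t + p.beat_phase)
    th = 2 * math.pi * p.f_c * t + p.phase
    return (r * math.cos(th) + p.C_xc, r * math.sin(th) + p.C_yc)


def circular_heading(t: float, p: CircularParams) -> float:
    """Instantaneous direction of movement (analytic tangent of the path)."""
    ws = 2 * math.pi * p.f_s
    wc = 2 * math.pi * p.f_c
    r = p.r_c + p.a * math.sin(ws * t + p.beat_phase)
    dr = p.a * ws * math.cos(ws * t + p.beat_phase)
    th = wc * t + p.phase
    dx = dr * math.cos(th) - r * wc * math.sin(th)
    dy = dr * math.sin(th) + r * wc * math.cos(th)
    return math.atan2(dy, dx)


def circular_tail(t: float, head: tuple[float, float], p: CircularParams) -> np.ndarray:
    """Tail polyline (M, 2) of a circular swimmer.

    The local travelling wave x(k) = b(k)·sin(2π(k/M − f_s t)) over the axis
    y(k) = −λk/M is rotated to match the instantaneous direction of movement
    and translated to the head, with the root re-anchored on the head.
    """
    k = _tail_k(p.M)
    b = p.a * (p.alpha * p.lambda_ * k / p.M + p.beta)
    x_t = b * np.sin(2 * np.pi * (k / p.M - p.f_s * t) - p.beat_phase)
    y_t = -p.lambda_ * k / p.M
    x_t = x_t - x_t[0]  # re-anchor the root at the head
    theta = circular_heading(t, p) - math.pi / 2.0  # local tail axis is -y
    local = np.column_stack([x_t, y_t]) @ _rot(theta).T
    return local + np.asarray(head, dtype=float)


# ---------------------------------------------------------------------------
# linear mean swim


def _ribbon_offset(t: float, p: LinearParams) -> tuple[float, float]:
    ph = 2 * math.pi * p.f_l * t + p.phase
    px = (p.r_v / 2.0) * math.sin(2 * ph)
    py = (p.r_h * p.A_c / 2.0) * (math.sin(ph) + p.A_har * math.sin(3 * ph))
    return px, py


def linear_head(t: float, p: LinearParams) -> tuple[float, float]:
    """Straight-line center plus the heading-rotated ribbon offset."""
    cx = p.V * math.cos(p.theta_r) * t + p.C_xL
    cy = p.V * math.sin(p.theta_r) * t + p.C_yL
    off = _rot(p.theta_r) @ np.asarray(_ribbon_offset(t, p))
    return (cx + off[0], cy + off[1])


def linear_tail(t: float, head: tuple[float, float], p: LinearParams) -> np.ndarray:
    """Tail polyline (M, 2) of a linear-mean swimmer.

    Travelling-wave oscillations shaped by the sigmoid b1 (horizontal) and
    exponential b2 (vertical) profiles are laid along the −x axis, vertically
    corrected by b3 to track the ribbon, rotated by the heading and attached
    to the head with the root re-anchored on it.
    """
    k = _tail_k(p.M)
    u = k / p.M
    ph = 2 * math.pi * p.f_l * t + p.phase
    b1 = 1.0 / (1.0 + np.exp(p.alpha * u + p.beta))
    b2 = np.exp(-p.gamma1 * u)
    b3 = 1.0 - np.exp(-p.gamma2 * u)
    x_t = (p.r_v / 2.0) * np.sin(4 * np.pi * u + 2 * ph)
    y_t = (p.r_h / 2.0) * np.sin(2 * np.pi * u + ph)
    x_lm = b1 * x_t - p.lambda_ * u
    p_y = _ribbon_offset(t, p)[1]
    y_lm2 = b2 * y_t - (p_y - y_t[0]) * b3
    local = np.column_stack([x_lm, y_lm2])
    local -= local[0]  # re-anchor the root at the head
    return local @ _rot(p.theta_r).T + np.asarray(head, dtype=float)


# ---------------------------------------------------------------------------
# hyperactive / immotile


def hyperactive_head(prev: tuple[float, float], p: HyperactiveParams,
                     rng: np.random.Generator) -> tuple[float, float]:
    """One Brownian step: prev + μ·T + σ_b·W(T), W(T) ~ N(0, T) per axis."""
    step = p.sigma_b * rng.normal(0.0, math.sqrt(p.T), size=2)
    return (prev[0] + p.mu[0] * p.T + step[0], prev[1] + p.mu[1] * p.T + step[1])


def trailing_tail(history, n: int, M: int) -> np.ndarray:
    """Tail as the recent head path, resampled by arc length to M points.

    Linear interpolation through the last min(n+1, available) head positions
    (newest end at the head); a single-point or zero-length history yields M
    coincident points.
    """
    pts = np.asarray(list(history)[-(n + 1):], dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("history must be non-empty")
    pts = pts[::-1]  # newest first, so the tail starts at the head
    if len(pts) == 1:
        return np.repeat(pts, M, axis=0)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        return np.repeat(pts[:1], M, axis=0)
    q = np.linspace(0.0, s[-1], M)
    return np.column_stack([np.interp(q, s, pts[:, 0]), np.interp(q, s, pts[:, 1])])


def immotile_state(initial: CellState, t: float) -> CellState:
    """Frozen snapshot: head and tail identical to the initial state for all t."""
    return initial


# ---------------------------------------------------------------------------
# scene-level features


def step_mode(state: CellState, tm: TransitionModel, rng: np.random.Generator,
              param_factory=None, t: float | None = None) -> CellState:
    """Resample the cell's swim mode from its transition row (one evaluation).

    On a transition the new mode is initialized at the current head position
    with the current heading preserved; ``param_factory(mode, state, rng)``
    supplies the new mode's parameter block (defaults to
    :func:`continue_params`).  Mutates and returns ``state``.
    """
    row = tm.matrix[MODES.index(state.mode)]
    new_mode = MODES[int(rng.choice(4, p=row))]
    if new_mode == state.mode:
        return state
    if param_factory is None:
        param_factory = continue_params
    now = state.t0 if t is None else t
    state.mode = new_mode
    state.params = param_factory(new_mode, state, rng)
    state.t0 = now
    state.head_history = [state.head]
    if new_mode == "immotile":
        pass  # head and tail stay frozen as they are
    return state


def continue_params(mode: str, state: CellState, rng: np.random.Generator):
    """Default parameter block continuing at the cell's position and heading."""
    x, y = state.head
    h = state.heading
    if mode == "circular":
        phase = h - math.pi / 2.0  # heading is tangent of a CCW circle
        p = CircularParams()
        return CircularParams(
            r_c=p.r_c, a=p.a, f_s=p.f_s, f_c=p.f_c,
            C_xc=x - p.r_c * math.cos(phase), C_yc=y - p.r_c * math.sin(phase),
            lambda_=p.lambda_, M=p.M, phase=phase,
        )
    if mode == "linear":
        return LinearParams(theta_r=h, C_xL=x, C_yL=y)
    if mode == "hyperactive":
        return HyperactiveParams()
    if mode == "immotile":
        return None
    raise ValueError(f"unknown mode {mode!r}")


def jitter_position(pos: tuple[float, float], sigma_j: float,
                    rng: np.random.Generator) -> tuple[float, float]:
    """Add independent zero-mean Gaussian positional noise (std sigma_j) per axis.

    The jittered position is what gets rendered and recorded as ground truth;
    the underlying kinematic state is untouched.
    """
    if sigma_j < 0:
        raise ValueError("sigma_j must be >= 0")
    if sigma_j == 0:
        return pos
    d = rng.normal(0.0, sigma_j, size=2)
    return (pos[0] + d[0], pos[1] + d[1])
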