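"""Multi-cell scene simulation: video frames plus exact ground truth.

A :class:`SimulationConfig` declares the frame geometry, the cell census
(fixed per-mode counts and/or cells drawn from per-mode probabilities),
appearance and kinematic defaults, and the optional realism features:
per-frame positional jitter, per-cell intensity factors, swim-mode
transitions, and additive frame noise.  :func:`simulate` advances every
cell's kinematic state at the frame rate, renders each frame through the
PSF pipeline, and emits one ground-truth row per in-frame cell per frame.
Everything is bit-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import swim
from .psf import AppearanceParams, _KernelBank, render_cells
from .swim import (CellState, CircularParams, HyperactiveParams, LinearParams,
                   TransitionModel, trailing_tail)

__all__ = [
    "SimulationConfig",
    "simulate",
    "add_frame_noise",
    "write_artifacts",
    "read_artifacts",
    "TRUTH_COLUMNS",
    "ArtifactError",
]

TRUTH_COLUMNS = ["frame", "cell_id", "x", "y", "mode"]

#: Table-style noise variance printed on a normalized [0, 1] intensity scale
#: is converted to the 0-255 gray scale by multiplying with 255².
NORMALIZED_TO_GRAY_VARIANCE = 255.0**2


class ArtifactError(ValueError):
    """Malformed simulation artifact (frames or truth table)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulated semen video.

    ``mode_counts`` fixes exact per-mode cell counts; ``n_random_cells``
    additional cells draw their mode from ``mode_probs``.  Kinematic
    magnitudes come from the per-mode template parameter blocks; each cell
    gets its own random start position, heading/phase and swim direction.
    ``noise_variance`` is on the 0-255 gray scale (gray²).
    """

    frame_size: int = 250
    fps: float = 15.0
    duration: float = 1.0
    mode_counts: dict = field(default_factory=dict)
    n_random_cells: int = 0
    mode_probs: dict = field(default_factory=lambda: {
        "circular": 0.25, "linear": 0.25, "hyperactive": 0.25, "immotile": 0.25})
    appearance: AppearanceParams = field(default_factory=AppearanceParams)
    circular: CircularParams = field(default_factory=CircularParams)
    linear: LinearParams = field(default_factory=LinearParams)
    hyperactive: HyperactiveParams = field(default_factory=HyperactiveParams)
    noise_variance: float = 0.0
    jitter_sigma: float = 0.0
    intensity_range: tuple[float, float] = (1.0, 1.0)
    transitions: TransitionModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration <= 0 or self.frame_size < 1:
            raise ValueError("require fps > 0, duration > 0, frame_size >= 1")
        if self.n_random_cells < 0 or any(v < 0 for v in self.mode_counts.values()):
            raise ValueError("cell counts must be >= 0")
        for m in self.mode_counts:
            if m not in swim.MODES:
                raise ValueError(f"unknown mode {m!r}")
        if self.n_random_cells:
            p = sum(self.mode_probs.values())
            if not math.isclose(p, 1.0, abs_tol=1e-9):
                raise ValueError("mode_probs must sum to 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def n_cells(self) -> int:
        return sum(self.mode_counts.values()) + self.n_random_cells

    @classmethod
    def detection_fixture(cls, *, duration: float = 2.0,
                          seed: int | None = None) -> "SimulationConfig":
        """Reference sample for segmentation/localization testing.

        250x250 frames, 10 cells of which 3 are non-moving (immotile); the 7
        movers are drawn 50/50 between linear-mean and circular swimming.
        The scene's own noise variance 8.22e-6 is on the normalized scale.
        """
        return cls(
            frame_size=250, fps=15.0, duration=duration,
            mode_counts={"immotile": 3},
            n_random_cells=7,
            mode_probs={"circular": 0.5, "linear": 0.5,
                        "hyperactive": 0.0, "immotile": 0.0},
            appearance=AppearanceParams(sigma_head=(1.86, 2.86)),
            noise_variance=8.22e-6 * NORMALIZED_TO_GRAY_VARIANCE,
            seed=seed,
        )

    @classmethod
    def tracking_scenario(cls, n_cells: int, *, duration: float = 10.0,
                          seed: int | None = None) -> "SimulationConfig":
        """Tracking-assessment scenario: 500x500 px, 15 FPS, equal-probability
        assignment of the four swim modes, no frame noise."""
        return cls(
            frame_size=500, fps=15.0, duration=duration,
            n_random_cells=n_cells,
            seed=seed,
        )


def _init_cell(cid: int, mode: str, cfg: SimulationConfig,
               rng: np.random.Generator) -> CellState:
    n = cfg.frame_size
    start = rng.uniform(0.0, n - 1.0, size=2)  # uniform over pixel centers
    lo, hi = cfg.intensity_range
    intensity = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    if mode == "circular":
        tpl = cfg.circular
        direction = 1.0 if rng.random() < 0.5 else -1.0
        p = replace(tpl, f_c=direction * abs(tpl.f_c),
                    phase=float(rng.uniform(0, 2 * math.pi)),
                    beat_phase=float(rng.uniform(0, 2 * math.pi)),
                    C_xc=0.0, C_yc=0.0)
        h0 = swim.circular_head(0.0, p)
        p = replace(p, C_xc=start[0] - h0[0], C_yc=start[1] - h0[1])
        head = swim.circular_head(0.0, p)
        tail = swim.circular_tail(0.0, head, p)
        heading = swim.circular_heading(0.0, p)
    elif mode == "linear":
        tpl = cfg.linear
        theta = float(rng.uniform(0, 2 * math.pi))
        p = replace(tpl, theta_r=theta, phase=float(rng.uniform(0, 2 * math.pi)),
                    C_xL=0.0, C_yL=0.0)
        h0 = swim.linear_head(0.0, p)
        p = replace(p, C_xL=start[0] - h0[0], C_yL=start[1] - h0[1])
        head = swim.linear_head(0.0, p)
        tail = swim.linear_tail(0.0, head, p)
        heading = theta
    elif mode == "hyperactive":
        p = replace(cfg.hyperactive, T=1.0 / cfg.fps)
        head = tuple(start)
        tail = trailing_tail([head], p.n, p.M)
        heading = float(rng.uniform(0, 2 * math.pi))
    elif mode == "immotile":
        # frozen snapshot of a hyperactive-style flagellum: the pre-history
        # runs backwards in time from the (fixed) head position
        p = replace(cfg.hyperactive, T=1.0 / cfg.fps)
        past = [tuple(start)]
        for _ in range(p.n):
            past.append(swim.hyperactive_head(past[-1], p, rng))
        head = tuple(start)
        tail = trailing_tail(past[::-1], p.n, p.M)  # newest (head) last
        heading = float(rng.uniform(0, 2 * math.pi))
        p = None
    else:  # pragma: no cover
        raise ValueError(mode)
    return CellState(id=cid, mode=mode, head=tuple(map(float, head)), tail=tail,
                     params=p, head_history=[tuple(map(float, head))],
                     intensity_factor=intensity, rng=rng, heading=heading)


def _advance_cell(cell: CellState, t: float, fps: float) -> None:
    """Advance one cell's kinematic state to scene time t (one frame step)."""
    tl = t - cell.t0
    if cell.mode == "circular":
        head = swim.circular_head(tl, cell.params)
        cell.tail = swim.circular_tail(tl, head, cell.params)
        cell.heading = swim.circular_heading(tl, cell.params)
        cell.head = head
    elif cell.mode == "linear":
        head = swim.linear_head(tl, cell.params)
        cell.tail = swim.linear_tail(tl, head, cell.params)
        cell.heading = cell.params.theta_r
        cell.head = head
    elif cell.mode == "hyperactive":
        if tl > 0:
            prev = cell.head
            cell.head = swim.hyperactive_head(prev, cell.params, cell.rng)
            dx, dy = cell.head[0] - prev[0], cell.head[1] - prev[1]
            if dx or dy:
                cell.heading = math.atan2(dy, dx)
        cell.head_history.append(cell.head)
        cell.tail = trailing_tail(cell.head_history, cell.params.n, cell.params.M)
        return
    elif cell.mode == "immotile":
        return
    cell.head_history.append(cell.head)
    n_keep = max(2, math.ceil(0.2 * fps)) + 1
    if len(cell.head_history) > n_keep:
        del cell.head_history[:-n_keep]


def simulate(config: SimulationConfig,
             seed: int | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a video: (frames uint8 array (T, N, N), ground-truth table).

    Truth rows record the rendered (jittered) head position of every cell
    whose head lies inside the frame, one row per cell per frame.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    scene_seed, noise_seed, *cell_seeds = ss.spawn(2 + config.n_cells)
    rng = np.random.default_rng(scene_seed)
    noise_rng = np.random.default_rng(noise_seed)

    modes: list[str] = []
    for m in swim.MODES:
        modes += [m] * config.mode_counts.get(m, 0)
    if config.n_random_cells:
        probs = [config.mode_probs.get(m, 0.0) for m in swim.MODES]
        drawn = rng.choice(len(swim.MODES), size=config.n_random_cells, p=probs)
        modes += [swim.MODES[i] for i in drawn]

    cells = [_init_cell(cid, m, config, np.random.default_rng(cs))
             for cid, (m, cs) in enumerate(zip(modes, cell_seeds))]

    def _transition_params(mode: str, state: CellState, cell_rng):
        # continue at the cell's position/heading using the scene's templates
        x, y = state.head
        h = state.heading
        if mode == "circular":
            tpl = config.circular
            phase = h - math.pi / 2.0
            return replace(tpl, phase=phase, beat_phase=0.0,
                           C_xc=x - tpl.r_c * math.cos(phase),
                           C_yc=y - tpl.r_c * math.sin(phase))
        if mode == "linear":
            return replace(config.linear, theta_r=h, phase=0.0, C_xL=x, C_yL=y)
        if mode == "hyperactive":
            return replace(config.hyperactive, T=1.0 / config.fps)
        return None  # immotile: frozen as-is

    bank = _KernelBank(config.appearance)
    n_px = config.frame_size
    frames = np.empty((config.n_frames, n_px, n_px), dtype=np.uint8)
    rows = []
    check_every = max(1, math.ceil(config.fps))
    for f in range(config.n_frames):
        t = f / config.fps
        if config.transitions is not None and f > 0 and f % check_every == 0:
            for c in cells:
                swim.step_mode(c, config.transitions, c.rng,
                               param_factory=_transition_params, t=t)
        if f > 0:
            for c in cells:
                _advance_cell(c, t, config.fps)

        heads, tails, weights = [], [], []
        for c in cells:
            hx, hy = swim.jitter_position(c.head, config.jitter_sigma, c.rng)
            dx, dy = hx - c.head[0], hy - c.head[1]
            heads.append((hx, hy))
            tails.append(c.tail + np.array([dx, dy]))
            weights.append(c.intensity_factor)
            if -0.5 <= hx < n_px - 0.5 and -0.5 <= hy < n_px - 0.5:
                rows.append((f, c.id, hx, hy, c.mode))
        frame = render_cells(heads, tails, weights, n_px, config.appearance, bank)
        if config.noise_variance > 0:
            frame = add_frame_noise(frame, config.noise_variance, noise_rng)
        frames[f] = frame

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return frames, truth


def add_frame_noise(frame: np.ndarray, variance: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Additive zero-mean Gaussian pixel noise (gray² variance on 0-255 scale),
    clipped to [0, 255] and re-quantized to 8 bits."""
    if variance < 0:
        raise ValueError("noise variance must be >= 0")
    if variance == 0:
        return frame
    noisy = frame.astype(float) + rng.normal(0.0, math.sqrt(variance), frame.shape)
    return np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# artifact I/O


def write_artifacts(frames: np.ndarray, truth: pd.DataFrame, path,
                    avi: bool = False) -> None:
    """Write frames (multi-page TIFF) and truth (CSV) into directory ``path``.

    Round-trips losslessly with :func:`read_artifacts`.  ``avi=True``
    additionally exports a viewing copy (requires an ffmpeg-enabled imageio).
    """
    import pathlib

    import tifffile

    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ArtifactError("refusing to write an empty or non-3D frame stack")
    p = pathlib.Path(path)
    p.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(p / "frames.tif", frames.astype(np.uint8))
    out = truth.copy()
    missing = [c for c in TRUTH_COLUMNS if c not in out.columns]
    if missing:
        raise ArtifactError(f"truth table missing columns: {missing}")
    out[TRUTH_COLUMNS].to_csv(p / "truth.csv", index=False,
                              float_format="%.6f")
    if avi:
        import imageio
        imageio.mimwrite(p / "video.avi", list(frames), fps=15)


def read_artifacts(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read back a (frames, truth) pair written by :func:`write_artifacts`."""
    import pathlib

    import tifffile

    p = pathlib.Path(path)
    frames = tifffile.imread(p / "frames.tif")
    if frames.ndim == 2:
        frames = frames[None]
    truth = read_truth(p / "truth.csv")
    return frames, truth


def read_truth(csv_path) -> pd.DataFrame:
    """Parse a ground-truth CSV, validating the header and row types."""
    truth = pd.read_csv(csv_path)
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ArtifactError(f"{csv_path}: missing columns {missing}")
    try:
        truth["frame"] = truth["frame"].astype(int)
        truth["cell_id"] = truth["cell_id"].astype(int)
        truth["x"] = truth["x"].astype(float)
        truth["y"] = truth["y"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ArtifactError(f"{csv_path}: malformed values ({exc})") from exc
    return truth[TRUTH_COLUMNS]
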