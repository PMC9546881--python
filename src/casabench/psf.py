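"""Point-spread-function rendering of sperm cells.

A simulated cell is drawn from two point sets: the head position (one point)
and the flagellum polyline (``M`` points).  Three PSF kernels turn those
points into the grayscale structures seen in phase-contrast-like semen
images:

* ``f1`` — an anisotropic Gaussian; convolved with the head point and
  complemented it produces the dark oval head center.
* ``f2`` — the positive part of the Laplacian of an anisotropic Gaussian;
  it produces the bright "horseshoe" halo of the head membrane.
* ``f3`` — the positive part of an isotropic Laplacian of Gaussian; it
  turns the tail polyline into a thin bright ridge of uniform calibre.

The pipeline mirrors a five-stage process: head center (complement against
a uniform background ``B_L``), membrane halo, head merge, flagellum ridge,
and the final additive composition clipped to 8-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "PSFKernel",
    "AppearanceParams",
    "rasterize_points",
    "make_gaussian_psf",
    "make_halo_psf",
    "make_ridge_psf",
    "calibrate_gain",
    "render_head_center",
    "render_membrane",
    "render_flagellum",
    "compose_sperm_image",
    "render_cells",
]

POINT_VALUE = 255.0  # gray level marking a rasterized point


@dataclass(frozen=True)
class PSFKernel:
    """Discrete 2-D point-spread weight grid on a square odd-sided support."""

    weights: np.ndarray
    half_width: int
    sigmas: tuple[float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        side = 2 * self.half_width + 1
        if w.shape != (side, side):
            raise ValueError(f"kernel must be {side}x{side}, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("kernel weights must be finite")
        object.__setattr__(self, "weights", w)

    @property
    def max_weight(self) -> float:
        return float(self.weights.max())


@dataclass(frozen=True)
class AppearanceParams:
    """Appearance of a rendered cell.

    Sigmas are in pixels; peaks and background are gray levels on [0, 255].
    Defaults follow the reference sample: head Gaussian (1.86, 2.86) px,
    membrane halo (2.79, 4.29) px, flagellum ridge 1.5 px, peaks 255/51/13
    over a uniform background of 204 (80% of 255).
    """

    sigma_head: tuple[float, float] = (1.86, 2.86)
    sigma_membrane: tuple[float, float] = (2.79, 4.29)
    sigma_flagellum: float = 1.5
    kernel_half_width: int = 12
    head_peak: float = 255.0
    membrane_peak: float = 51.0
    flagellum_peak: float = 13.0
    background: float = 204.0

    def __post_init__(self) -> None:
        for s in (*self.sigma_head, *self.sigma_membrane, self.sigma_flagellum):
            if s <= 0:
                raise ValueError("all sigmas must be positive")
        for v in (self.head_peak, self.membrane_peak, self.flagellum_peak, self.background):
            if not 0 <= v <= 255:
                raise ValueError("peaks and background must lie in [0, 255]")


def rasterize_points(points, frame_size: int) -> np.ndarray:
    """Rasterize continuous positions into an N x N buffer.

    Each in-frame point sets the nearest-integer pixel to 255 (half-up
    rounding); out-of-frame points are silently dropped; collisions merge.
    Coordinates are (x, y) with origin at the top-left pixel, x rightward,
    y downward; the buffer is indexed [y, x].
    """
    if frame_size < 1:
        raise ValueError("frame_size must be >= 1")
    buf = np.zeros((frame_size, frame_size), dtype=float)
    pts = np.asarray(list(points), dtype=float).reshape(-1, 2)
    if pts.size == 0:
        return buf
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in point set")
    ij = np.floor(pts + 0.5).astype(int)  # round half up
    inside = (ij[:, 0] >= 0) & (ij[:, 0] < frame_size) & (ij[:, 1] >= 0) & (ij[:, 1] < frame_size)
    ij = ij[inside]
    buf[ij[:, 1], ij[:, 0]] = POINT_VALUE
    return buf


def _grid(half_width: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(-half_width, half_width + 1, dtype=float)
    return np.meshgrid(r, r)  # x varies along columns, y along rows


def make_gaussian_psf(sigmas: tuple[float, float], half_width: int = 12) -> PSFKernel:
    """Anisotropic Gaussian PSF: (1/2πσxσy)·exp(−[(x/σx)² + (y/σy)²]/2)."""
    sx, sy = sigmas
    if sx <= 0 or sy <= 0:
        raise ValueError("sigmas must be positive")
    x, y = _grid(half_width)
    w = np.exp(-((x / sx) ** 2 + (y / sy) ** 2) / 2.0) / (2.0 * np.pi * sx * sy)
    return PSFKernel(w, half_width, (sx, sy))


def _gaussian_laplacian(sx: float, sy: float, half_width: int) -> np.ndarray:
    # Analytic ∇²G of the anisotropic Gaussian above:
    # ∂²G/∂x² = G·(x²/σx⁴ − 1/σx²), likewise in y.
    x, y = _grid(half_width)
    g = np.exp(-((x / sx) ** 2 + (y / sy) ** 2) / 2.0) / (2.0 * np.pi * sx * sy)
    return g * ((x**2 / sx**4 - 1.0 / sx**2) + (y**2 / sy**4 - 1.0 / sy**2))


def make_halo_psf(sigmas: tuple[float, float], half_width: int = 12) -> PSFKernel:
    """Clipped Laplacian-of-Gaussian halo PSF: max(0, ∇²G)."""
    sx, sy = sigmas
    if sx <= 0 or sy <= 0:
        raise ValueError("sigmas must be positive")
    w = np.maximum(0.0, _gaussian_laplacian(sx, sy, half_width))
    return PSFKernel(w, half_width, (sx, sy))


def make_ridge_psf(sigma: float, half_width: int = 12) -> PSFKernel:
    """Isotropic clipped Laplacian-of-Gaussian ridge PSF (σx = σy = σ_f).

    The positive-part clipping makes a convolved 1-px curve render as a
    single bright band instead of the double ridge of the raw LoG.
    """
    return make_halo_psf((sigma, sigma), half_width)


def calibrate_gain(psf: PSFKernel, target_peak: float) -> float:
    """Gain making a single unit point's convolved response peak at target.

    The gain is a fixed calibration constant computed once from the
    single-point response (the kernel maximum), not a per-frame normalizer,
    so overlapping cells superpose additively.
    """
    m = psf.max_weight
    if m <= 0:
        raise ValueError("kernel has no positive response; cannot calibrate")
    return float(target_peak) / m


def _convolve(mask: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # zero-padded convolution, output cropped to the input frame; all kernels
    # here are non-negative, so clip the FFT round-off below zero
    return np.maximum(0.0, fftconvolve(mask, kernel, mode="same"))


def _point_mask(buffer: np.ndarray) -> np.ndarray:
    """Unit-valued mask from a 255-valued rasterized buffer."""
    return np.asarray(buffer, dtype=float) / POINT_VALUE


def render_head_center(head_points: np.ndarray, psf_f1: PSFKernel,
                       params: AppearanceParams) -> np.ndarray:
    """Dark head-center buffer I5 on the uniform background.

    I3 = gain1·(I1 * f1) peaks at ``head_peak`` per isolated head; I4 is its
    complement; I5 = max(0, I4 − (255 − B_L)) re-inserts the background, so
    far-field pixels equal B_L and an isolated head's darkest pixel equals
    max(0, 255 − head_peak − (255 − B_L)).
    """
    gain = calibrate_gain(psf_f1, params.head_peak)
    i3 = gain * _convolve(_point_mask(head_points), psf_f1.weights)
    i4 = 255.0 - i3
    return np.maximum(0.0, i4 - (255.0 - params.background))


def render_membrane(head_points: np.ndarray, psf_f2: PSFKernel,
                    params: AppearanceParams) -> np.ndarray:
    """Additive halo buffer I6; an isolated head's halo peaks at membrane_peak."""
    gain = calibrate_gain(psf_f2, params.membrane_peak)
    return gain * _convolve(_point_mask(head_points), psf_f2.weights)


def render_flagellum(tail_points: np.ndarray, psf_f3: PSFKernel,
                     params: AppearanceParams) -> np.ndarray:
    """Additive ridge buffer I8; each isolated tail's ridge peaks at flagellum_peak.

    Unlike the head kernels (whose input is a single point), the tail is a
    polyline whose per-point responses superpose, so the flagellum gain is
    calibrated per connected tail component: each isolated tail is scaled to
    peak exactly at ``flagellum_peak``.  Gains are per-tail constants, not a
    per-frame normalization, so distinct cells remain additive and local.
    """
    from scipy import ndimage

    mask = _point_mask(tail_points)
    out = np.zeros_like(mask)
    if not mask.any():
        return out
    # group rasterized tail pixels into connected components (8-connectivity)
    labels, n = ndimage.label(mask > 0, structure=np.ones((3, 3), dtype=int))
    for lab in range(1, n + 1):
        comp = mask * (labels == lab)
        resp = _convolve(comp, psf_f3.weights)
        peak = resp.max()
        if peak > 0:
            out += resp * (params.flagellum_peak / peak)
    return out


def compose_sperm_image(i5: np.ndarray, i6: np.ndarray, i8: np.ndarray) -> np.ndarray:
    """Final 8-bit frame I9 = clip(I5 + I6 + I8, 0, 255), quantized."""
    if not (i5.shape == i6.shape == i8.shape):
        raise ValueError("buffer dimensions must match")
    i9 = np.clip(i5 + i6 + i8, 0.0, 255.0)
    return np.floor(i9 + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# fast multi-cell frame rendering used by the scene simulator


@dataclass
class _KernelBank:
    """Pre-calibrated kernels for one appearance configuration."""

    params: AppearanceParams
    f1: PSFKernel = field(init=False)
    f2: PSFKernel = field(init=False)
    f3: PSFKernel = field(init=False)
    head_kernel: np.ndarray = field(init=False)      # gain1·f1
    membrane_kernel: np.ndarray = field(init=False)  # gain2·f2

    def __post_init__(self) -> None:
        p = self.params
        hw = p.kernel_half_width
        self.f1 = make_gaussian_psf(p.sigma_head, hw)
        self.f2 = make_halo_psf(p.sigma_membrane, hw)
        self.f3 = make_ridge_psf(p.sigma_flagellum, hw)
        self.head_kernel = calibrate_gain(self.f1, p.head_peak) * self.f1.weights
        self.membrane_kernel = calibrate_gain(self.f2, p.membrane_peak) * self.f2.weights


def render_cells(heads, tails, intensity, frame_size: int,
                 params: AppearanceParams, bank: _KernelBank | None = None) -> np.ndarray:
    """Render a full frame from per-cell heads, tail polylines and intensities.

    ``heads`` is (n, 2) float (x, y); ``tails`` a sequence of (M, 2) arrays;
    ``intensity`` per-cell factors in (0, 1] scaling each cell's deviation
    from the background.  Equivalent to the staged per-buffer pipeline for
    unit intensity, but runs a constant number of frame-sized convolutions:
    per-cell gains are folded into the rasterized point weights (the
    convolution is linear in its input).  Per-tail ridge gains are measured
    on a first unweighted tail convolution restricted to each tail's
    neighborhood.
    """
    if bank is None:
        bank = _KernelBank(params)
    n_px = frame_size
    hw = params.kernel_half_width
    heads = np.asarray(heads, dtype=float).reshape(-1, 2)
    intensity = np.asarray(intensity, dtype=float).reshape(-1)

    head_w = np.zeros((n_px, n_px))
    for (x, y), w in zip(heads, intensity):
        i, j = int(np.floor(y + 0.5)), int(np.floor(x + 0.5))
        if 0 <= i < n_px and 0 <= j < n_px:
            head_w[i, j] += w

    # tails: binary mask per cell with bounding boxes for local gain lookup
    tail_mask = np.zeros((n_px, n_px))
    boxes = []
    tail_pixels = []
    for tail in tails:
        if tail is None or len(tail) == 0:
            boxes.append(None)
            tail_pixels.append(None)
            continue
        ij = np.floor(np.asarray(tail, dtype=float) + 0.5).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < n_px) & (ij[:, 1] >= 0) & (ij[:, 1] < n_px)
        ij = np.unique(ij[keep], axis=0)
        if len(ij) == 0:
            boxes.append(None)
            tail_pixels.append(None)
            continue
        tail_mask[ij[:, 1], ij[:, 0]] = 1.0
        boxes.append((ij[:, 1].min(), ij[:, 1].max(), ij[:, 0].min(), ij[:, 0].max()))
        tail_pixels.append(ij)

    if head_w.any():
        deficit = _convolve(head_w, bank.head_kernel)
        membrane = _convolve(head_w, bank.membrane_kernel)
    else:
        deficit = membrane = np.zeros((n_px, n_px))

    if tail_mask.any():
        resp = _convolve(tail_mask, bank.f3.weights)
        tail_w = np.zeros((n_px, n_px))
        for ij, box, w in zip(tail_pixels, boxes, intensity):
            if ij is None:
                continue
            i0, i1, j0, j1 = box
            local = resp[max(0, i0 - hw):i1 + hw + 1, max(0, j0 - hw):j1 + hw + 1]
            peak = local.max()
            if peak > 0:
                tail_w[ij[:, 1], ij[:, 0]] = w * params.flagellum_peak / peak
        flag = _convolve(tail_w, bank.f3.weights) if tail_w.any() else np.zeros((n_px, n_px))
    else:
        flag = np.zeros((n_px, n_px))

    i5 = np.maximum(0.0, params.background - deficit)
    return compose_sperm_image(i5, membrane, flag)
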