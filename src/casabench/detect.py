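"""Sperm-cell detection: segmentation + localization algorithms.

Five detectors are benchmarked: four static per-frame methods (Otsu
thresholding, Bradley adaptive thresholding, spot-enhancement, Sobel edge
detection) and one motion detector (per-pixel mixture-of-Gaussians
background subtraction).  Cells are dark heads on a light background, so
the static methods threshold the complemented frame; every binary mask is
morphologically cleaned (closing / dilation / erosion with a small disk),
small components are dropped, and the remaining blob centroids are emitted
as detections with their pixel areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import sobel, threshold_otsu
from skimage.morphology import disk

__all__ = [
    "DetectorParams",
    "STATIC_METHODS",
    "ALGORITHMS",
    "detect_static",
    "detect_gmm",
    "detect_video",
    "MixtureBackgroundModel",
]

STATIC_METHODS = ("otsu", "adaptive", "spot", "edge")
ALGORITHMS = STATIC_METHODS + ("gmm",)

DETECTION_COLUMNS = ["frame", "x", "y", "area"]


@dataclass(frozen=True)
class DetectorParams:
    """Shared detector configuration.

    ``sensitivity`` is the adaptive-threshold sensitivity in (0, 1] (higher
    admits more foreground).  The mixture background model uses
    ``gmm_modes`` Gaussians per pixel, ``gmm_training_frames`` frames of
    burn-in, learning rate ``gmm_learning_rate`` and cumulative-weight
    ``gmm_background_ratio``.  Masks are cleaned with a disk of
    ``morph_radius`` px and components below ``min_area`` px² are dropped.
    The spot filter defaults its bandwidth to the head-appearance sigmas.
    """

    sensitivity: float = 0.8
    gmm_training_frames: int = 20
    gmm_modes: int = 3
    gmm_learning_rate: float = 0.005
    gmm_background_ratio: float = 0.7
    morph_radius: int = 2
    min_area: int = 4
    adaptive_window: int = 11  # ~ one head diameter; cell-scale, not frame-scale
    spot_sigmas: tuple[float, float] = (1.86, 2.86)

    def __post_init__(self) -> None:
        if not 0 < self.sensitivity <= 1:
            raise ValueError("sensitivity must be in (0, 1]")
        for v in (self.gmm_training_frames, self.gmm_modes, self.morph_radius,
                  self.min_area):
            if v <= 0:
                raise ValueError("detector parameters must be positive")


def _clean_and_centroids(mask: np.ndarray, params: DetectorParams,
                         order: str = "cde") -> list[tuple[float, float, int]]:
    """Morphological cleaning then blob centroids as (x, y, area).

    ``order`` spells the operator sequence: c=closing, d=dilation, e=erosion.
    """
    se = disk(params.morph_radius).astype(bool)
    ops = {"c": lambda m: ndimage.binary_closing(m, structure=se),
           "d": lambda m: ndimage.binary_dilation(m, structure=se),
           "e": lambda m: ndimage.binary_erosion(m, structure=se)}
    for o in order:
        mask = ops[o](mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    centroids = ndimage.center_of_mass(mask, labels, index=range(1, n + 1))
    out = []
    for (cy, cx), area in zip(centroids, areas):
        if area >= params.min_area:
            out.append((float(cx), float(cy), int(area)))
    return out


def _bradley_mask(inv: np.ndarray, params: DetectorParams) -> np.ndarray:
    """Bradley-style adaptive threshold on the complemented frame.

    The local mean over a square window (default 11 px, about one head
    diameter) forms a per-pixel threshold T = μ + (1 − s)·(255 − μ): the
    local mean plus a (1 − sensitivity) fraction of the remaining dynamic
    range.  Sensitivity 1 admits everything above the local mean; lower
    values demand a proportionally larger excess.
    """
    local_mean = ndimage.uniform_filter(inv, size=params.adaptive_window,
                                        mode="reflect")
    thr = local_mean + (1.0 - params.sensitivity) * (255.0 - local_mean)
    return inv > thr


def _spot_response(inv: np.ndarray, params: DetectorParams) -> np.ndarray:
    """Blob-enhancing matched filter at the head scale.

    A negated Laplacian-of-Gaussian with sigmas matched to the head
    appearance; the kernel is zero-mean, so the uniform background maps to
    (approximately) zero and head-sized bright blobs in the complemented
    frame map to strong positive responses.  Negative responses are clipped
    before thresholding.
    """
    from scipy.signal import fftconvolve

    from .psf import _gaussian_laplacian

    sx, sy = params.spot_sigmas
    kernel = -_gaussian_laplacian(sx, sy, half_width=12)
    kernel -= kernel.mean()
    # spot-enhanced image: original plus the blob-matched band-pass response
    return inv + fftconvolve(inv, kernel, mode="same")


def detect_static(frame: np.ndarray, method: str,
                  params: DetectorParams | None = None) -> pd.DataFrame:
    """Detect cells in one 8-bit grayscale frame with a static method.

    Returns a table with columns x, y (blob centroid, px) and area (px²).
    Degenerate frames (near-zero gray-level variance) yield no detections
    rather than an arbitrary global threshold.
    """
    if params is None:
        params = DetectorParams()
    if method not in STATIC_METHODS:
        raise ValueError(f"unknown static method {method!r}; choose from {STATIC_METHODS}")
    img = np.asarray(frame, dtype=float)
    inv = 255.0 - img  # cells are dark-on-light: work on the complement
    order = "cde"
    if img.std() < 1e-3:
        rows = []
    elif method == "otsu":
        rows = _clean_and_centroids(inv > threshold_otsu(inv), params, order)
    elif method == "adaptive":
        rows = _clean_and_centroids(_bradley_mask(inv, params), params, order)
    elif method == "spot":
        resp = _spot_response(inv, params)
        rows = _clean_and_centroids(resp > threshold_otsu(resp), params, order)
    else:  # edge
        med = ndimage.median_filter(img, size=3)
        grad = sobel(med)
        mask = grad > threshold_otsu(grad)
        mask = ndimage.binary_fill_holes(mask)
        rows = _clean_and_centroids(mask, params, "dce")
    return pd.DataFrame(rows, columns=["x", "y", "area"])


class MixtureBackgroundModel:
    """Per-pixel mixture-of-Gaussians background model (Stauffer-Grimson).

    Each pixel keeps K weighted Gaussians over gray level.  A pixel matches
    a component within ``MATCH_SIGMA2`` squared standard deviations (default
    16, i.e. a 4-sigma gate, the convention of the widespread MOG2
    implementations; a tighter 2.5-sigma gate truncates the variance update
    and systematically underestimates heavy frame noise).  The best match
    (by weight/sigma) is updated; unmatched pixels replace their weakest
    component.  Components whose cumulative weight (in weight/sigma order)
    stays within ``background_ratio`` model the background; a pixel is
    foreground when its matched component is not one of them.  During the
    first frames the effective learning rate is 1/t so the model converges
    quickly.
    """

    INIT_VAR = 30.0**2
    VAR_FLOOR = 4.0
    MATCH_SIGMA2 = 16.0

    def __init__(self, shape: tuple[int, int], modes: int = 3,
                 learning_rate: float = 0.005, background_ratio: float = 0.7):
        self.k = modes
        self.alpha = learning_rate
        self.ratio = background_ratio
        self.t = 0
        self.weight = np.zeros((modes, *shape))
        self.mean = np.zeros((modes, *shape))
        self.var = np.full((modes, *shape), self.INIT_VAR)

    def apply(self, frame: np.ndarray) -> np.ndarray:
        """Update the model with one frame; return the foreground mask."""
        x = np.asarray(frame, dtype=float)
        self.t += 1
        if self.t == 1:
            self.weight[0] = 1.0
            self.mean[0] = x
            return np.zeros(x.shape, dtype=bool)
        alpha = max(self.alpha, 1.0 / self.t)

        d2 = (x[None] - self.mean) ** 2
        matched = d2 <= self.MATCH_SIGMA2 * self.var
        fitness = np.where(matched, self.weight / np.sqrt(self.var), -np.inf)
        best = np.argmax(fitness, axis=0)
        any_match = matched.any(axis=0)
        best_sel = np.zeros_like(matched)
        np.put_along_axis(best_sel, best[None], True, axis=0)
        best_sel &= any_match[None]

        self.weight = (1 - alpha) * self.weight + alpha * best_sel
        rho = alpha
        upd = best_sel
        delta = x[None] - self.mean
        self.mean = np.where(upd, self.mean + rho * delta, self.mean)
        self.var = np.where(upd, self.var + rho * (delta**2 - self.var), self.var)
        np.maximum(self.var, self.VAR_FLOOR, out=self.var)

        # unmatched pixels: replace the weakest component
        weakest = np.argmin(self.weight, axis=0)
        repl = np.zeros_like(matched)
        np.put_along_axis(repl, weakest[None], True, axis=0)
        repl &= ~any_match[None]
        self.mean = np.where(repl, x[None], self.mean)
        self.var = np.where(repl, self.INIT_VAR, self.var)
        self.weight = np.where(repl, alpha, self.weight)
        self.weight /= self.weight.sum(axis=0, keepdims=True)

        # background set: components covering `ratio` of weight, sorted by w/sigma
        rank = self.weight / np.sqrt(self.var)
        idx = np.argsort(-rank, axis=0)
        w_sorted = np.take_along_axis(self.weight, idx, axis=0)
        cum = np.cumsum(w_sorted, axis=0)
        bg_sorted = (cum - w_sorted) < self.ratio  # component needed to reach ratio
        is_bg = np.zeros_like(bg_sorted)
        np.put_along_axis(is_bg, idx, bg_sorted, axis=0)

        matched_is_bg = np.take_along_axis(is_bg, best[None], axis=0)[0]
        return ~any_match | (any_match & ~matched_is_bg)


def detect_gmm(frames: np.ndarray,
               params: DetectorParams | None = None) -> pd.DataFrame:
    """Motion detection over a frame sequence via background subtraction.

    Frames within the training window yield empty detection lists.  Returns
    a table with columns frame, x, y, area.
    """
    if params is None:
        params = DetectorParams()
    frames = np.asarray(frames)
    if len(frames) < params.gmm_training_frames:
        raise ValueError(
            f"need at least {params.gmm_training_frames} frames, got {len(frames)}")
    model = MixtureBackgroundModel(frames.shape[1:], params.gmm_modes,
                                   params.gmm_learning_rate,
                                   params.gmm_background_ratio)
    rows = []
    for f, frame in enumerate(frames):
        mask = model.apply(frame)
        if f < params.gmm_training_frames:
            continue
        for x, y, area in _clean_and_centroids(mask, params):
            rows.append((f, x, y, area))
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def detect_video(frames: np.ndarray, algo: str,
                 params: DetectorParams | None = None) -> pd.DataFrame:
    """Run a named detection algorithm over a whole frame stack.

    Returns a table with columns frame, x, y, area covering every frame
    (static methods) or every post-training frame (gmm).
    """
    if algo == "gmm":
        return detect_gmm(frames, params)
    if algo not in STATIC_METHODS:
        raise ValueError(f"unknown algorithm {algo!r}; choose from {ALGORITHMS}")
    rows = []
    for f, frame in enumerate(np.asarray(frames)):
        det = detect_static(frame, algo, params)
        for x, y, area in det.itertuples(index=False):
            rows.append((f, x, y, area))
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)
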