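"""Kernelized Correlation Filter (KCF) tracking on raw grayscale features.

A KCF tracker learns a ridge regression over all cyclic shifts of a padded
target patch.  Because the data matrix of cyclic shifts is circulant, both
training and dense evaluation diagonalise under the DFT: training solves

    alpha_f = y_f / (k_f^{xx} + lambda)

in the frequency domain, and detection evaluates the filter at every shift
of a new patch at FFT cost via the kernel correlation k^{xz}.  The Gaussian
kernel between all pairs of shifts is itself computable with one
cross-correlation:

    k^{xz}(tau) = exp(-(|x|^2 + |z|^2 - 2 (x * z)(tau)) / (sigma^2 N))

Features are mean-subtracted grayscale intensities under a cosine (Hann)
window; scale is fixed; the subpixel peak is refined with a 3-point
quadratic fit per axis.  Patches that extend past the image borders are
replicate-padded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .metrics import BoundingBox

__all__ = [
    "TrackerParams",
    "TrackState",
    "gaussian_response_target",
    "gaussian_kernel_correlation",
    "init_track",
    "track_step",
    "update_model",
    "to_grayscale",
]

#: BT.601 luma weights for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class TrackerParams:
    """KCF configuration (defaults follow the published KCF setup)."""

    padding: float = 1.5          # context area around the target
    kernel_sigma: float = 0.5     # Gaussian kernel bandwidth
    target_sigma_factor: float = 0.1  # regression target width vs target size
    lambda_reg: float = 1e-4      # ridge regularisation
    learning_rate: float = 0.075  # online model interpolation factor

    def __post_init__(self) -> None:
        if min(self.padding, self.kernel_sigma, self.target_sigma_factor,
               self.lambda_reg) <= 0:
            raise ValueError("tracker parameters must be positive")
        if not (0.0 <= self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in [0, 1]")


@dataclass
class TrackState:
    """Learned correlation-filter model plus the current box estimate."""

    model_alphaf: np.ndarray   # frequency-domain dual coefficients
    model_template: np.ndarray  # windowed, mean-subtracted training patch
    box: BoundingBox
    window: np.ndarray         # cosine taper, same shape as template
    yf: np.ndarray             # FFT of the Gaussian regression target
    params: TrackerParams
    last_response: float = 1.0


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """2-D grayscale float image from 2-D or 3-D (RGB/RGBA) input.

    uint8 input is rescaled to [0, 1].
    """
    frame = np.asarray(frame)
    if frame.dtype == np.uint8:
        frame = frame.astype(float) / 255.0
    else:
        frame = frame.astype(float)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3:
        return frame[..., :3] @ _LUMA
    raise ValueError(f"expected 2-D or 3-D image, got shape {frame.shape}")


def gaussian_response_target(h: int, w: int, sigma: float) -> np.ndarray:
    """2-D Gaussian regression target peaked at the zero-shift bin.

    Uses the wrap-around (FFT) shift convention: the peak sits at index
    (0, 0) and values decay with the cyclic distance to it; maximum is 1.
    """
    if h < 1 or w < 1:
        raise ValueError("target dimensions must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ys = np.arange(h)
    xs = np.arange(w)
    dy = np.minimum(ys, h - ys)  # cyclic distance to shift 0
    dx = np.minimum(xs, w - xs)
    return np.exp(-(dy[:, None] ** 2 + dx[None, :] ** 2) / (2.0 * sigma**2))


def gaussian_kernel_correlation(
    x: np.ndarray, z: np.ndarray, sigma: float
) -> np.ndarray:
    """Gaussian kernel between x and every cyclic shift of z, via FFT.

    Entry ``(i, j)`` equals ``exp(-||x - shift_{i,j}(z)||^2 / (sigma^2 N))``
    where ``shift_{i,j}`` rolls ``z`` by ``(i, j)``.  The squared distance
    expands into norms minus twice the circular cross-correlation, which is
    clamped at zero before exponentiation to guard round-off.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {z.shape}")
    n = x.size
    cross = np.real(np.fft.ifft2(np.fft.fft2(x) * np.conj(np.fft.fft2(z))))
    d2 = np.maximum((x**2).sum() + (z**2).sum() - 2.0 * cross, 0.0)
    return np.exp(-d2 / (sigma**2 * n))


def _patch_geometry(box: BoundingBox, padding: float) -> tuple[int, int, float, float]:
    ph = max(int(round(box.h * (1.0 + padding))), 4)
    pw = max(int(round(box.w * (1.0 + padding))), 4)
    cy = box.y + box.h / 2.0
    cx = box.x + box.w / 2.0
    return ph, pw, cy, cx


def _extract_patch(gray: np.ndarray, box: BoundingBox, padding: float) -> np.ndarray:
    """Padded patch centered on the box, replicate-padded at borders."""
    ph, pw, cy, cx = _patch_geometry(box, padding)
    H, W = gray.shape
    if ph > H or pw > W:
        raise ValueError(
            f"frame {H}x{W} smaller than tracking patch {ph}x{pw}"
        )
    rows = np.clip(int(round(cy)) - ph // 2 + np.arange(ph), 0, H - 1)
    cols = np.clip(int(round(cx)) - pw // 2 + np.arange(pw), 0, W - 1)
    return gray[np.ix_(rows, cols)]


def _preprocess(patch: np.ndarray, window: np.ndarray) -> np.ndarray:
    return (patch - patch.mean()) * window


def _train(
    patch: np.ndarray, window: np.ndarray, yf: np.ndarray, params: TrackerParams
) -> tuple[np.ndarray, np.ndarray]:
    x = _preprocess(patch, window)
    kf = np.fft.fft2(gaussian_kernel_correlation(x, x, params.kernel_sigma))
    alphaf = yf / (kf + params.lambda_reg)
    return alphaf, x


def init_track(
    frame: np.ndarray, box: BoundingBox, params: TrackerParams | None = None
) -> TrackState:
    """Train a fresh correlation filter on the target patch of one frame."""
    params = params or TrackerParams()
    gray = to_grayscale(frame)
    box = _clamp_box(box, gray.shape)
    patch = _extract_patch(gray, box, params.padding)
    ph, pw = patch.shape
    window = np.outer(np.hanning(ph), np.hanning(pw))
    sigma = params.target_sigma_factor * np.sqrt(box.w * box.h)
    yf = np.fft.fft2(gaussian_response_target(ph, pw, sigma))
    alphaf, x = _train(patch, window, yf, params)
    return TrackState(
        model_alphaf=alphaf,
        model_template=x,
        box=box,
        window=window,
        yf=yf,
        params=params,
        last_response=1.0,
    )


def _clamp_box(box: BoundingBox, shape: tuple[int, int]) -> BoundingBox:
    H, W = shape
    w = min(box.w, W)
    h = min(box.h, H)
    x = min(max(box.x, 0.0), W - w)
    y = min(max(box.y, 0.0), H - h)
    if w <= 0 or h <= 0:
        raise ValueError("degenerate box after clamping to frame")
    return BoundingBox(x, y, w, h)


def _subpixel(resp: np.ndarray, idx: int, axis_len: int, axis: int,
              peak: tuple[int, int]) -> float:
    """3-point quadratic refinement of the peak along one axis."""
    if axis == 0:
        lo = resp[(idx - 1) % axis_len, peak[1]]
        hi = resp[(idx + 1) % axis_len, peak[1]]
    else:
        lo = resp[peak[0], (idx - 1) % axis_len]
        hi = resp[peak[0], (idx + 1) % axis_len]
    mid = resp[peak]
    denom = 2.0 * mid - lo - hi
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (hi - lo) / denom, -0.5, 0.5))


def track_step(state: TrackState, frame: np.ndarray) -> tuple[BoundingBox, float]:
    """Locate the target in a new frame; returns (new box, peak response).

    The response map is the learned filter evaluated at every cyclic shift
    of the patch extracted at the previous location; its (wrap-aware,
    subpixel-refined) peak gives the displacement.  Box size is fixed.
    """
    gray = to_grayscale(frame)
    patch = _extract_patch(gray, state.box, state.params.padding)
    z = _preprocess(patch, state.window)
    kzx = gaussian_kernel_correlation(z, state.model_template,
                                      state.params.kernel_sigma)
    resp = np.real(np.fft.ifft2(np.fft.fft2(kzx) * state.model_alphaf))
    peak = np.unravel_index(int(np.argmax(resp)), resp.shape)
    ph, pw = resp.shape

    dy = peak[0] if peak[0] <= ph // 2 else peak[0] - ph
    dx = peak[1] if peak[1] <= pw // 2 else peak[1] - pw
    dy += _subpixel(resp, peak[0], ph, 0, peak)
    dx += _subpixel(resp, peak[1], pw, 1, peak)

    new_box = _clamp_box(
        BoundingBox(state.box.x + dx, state.box.y + dy, state.box.w, state.box.h),
        gray.shape,
    )
    state.box = new_box
    state.last_response = float(resp[peak])
    return new_box, state.last_response


def update_model(state: TrackState, frame: np.ndarray) -> TrackState:
    """Blend a freshly trained model at the current box into the state.

    With learning rate eta, the template and dual coefficients become
    ``(1 - eta) * old + eta * new``; eta = 0 is a no-op and eta = 1 equals
    re-initialisation at the current box.
    """
    eta = state.params.learning_rate
    if eta == 0.0:
        return state
    gray = to_grayscale(frame)
    patch = _extract_patch(gray, state.box, state.params.padding)
    alphaf_new, x_new = _train(patch, state.window, state.yf, state.params)
    return replace(
        state,
        model_alphaf=(1.0 - eta) * state.model_alphaf + eta * alphaf_new,
        model_template=(1.0 - eta) * state.model_template + eta * x_new,
    )
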