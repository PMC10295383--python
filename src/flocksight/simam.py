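"""Parameter-free attention by per-neuron energy minimization (SimAM).

Each neuron ``t`` in a channel of ``M`` neurons is scored by how linearly
separable it is from the other ``M - 1`` neurons.  The energy assigns the
target neuron the label +1 and every other neuron the label -1 and measures
the ridge-regularised squared error of the best linear transform:

    e_t(w, b) = (1/(M-1)) * sum_i (-1 - (w x_i + b))^2
                + (1 - (w t + b))^2 + lam * w^2

The stationary point has a closed form,

    w_t = 2 (t - mu_t) / ((t - mu_t)^2 + 2 sigma_t^2 + 2 lam)
    b_t = -(t + mu_t) w_t / 2

with mu_t, sigma_t^2 the mean and variance of the other M-1 neurons, and the
attained minimum is

    e_t* = 4 (sigma_t^2 + lam) / ((t - mu_t)^2 + 2 sigma_t^2 + 2 lam).

Low energy means the neuron stands out from its channel, so attention weights
are a decreasing function of e_t*: the refinement gates the feature map with
``sigmoid(1 / e*)``.  The fast variant substitutes the channel-wide mean and
variance for the leave-one-out statistics (all neurons in a channel assumed
identically distributed), turning the map into a single vectorised pass.

Statistics are always per channel; nothing crosses channels.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "energy",
    "closed_form_weights",
    "minimal_energy_exact",
    "minimal_energy_fast",
    "simam_refine",
    "DEFAULT_LAMBDA",
]

#: Ridge coefficient default, from the original SimAM configuration.
DEFAULT_LAMBDA: float = 1e-4


def energy(
    t: float,
    others: np.ndarray,
    omega: float,
    bias: float,
    lambda_reg: float,
) -> float:
    """Evaluate the separability energy at an arbitrary ``(omega, bias)``.

    ``others`` holds the M-1 non-target neurons of the channel.
    """
    others = np.asarray(others, dtype=float).ravel()
    if others.size == 0:
        raise ValueError("energy requires at least one non-target neuron")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be non-negative")
    distract = np.mean((-1.0 - (omega * others + bias)) ** 2)
    target = (1.0 - (omega * t + bias)) ** 2
    return float(distract + target + lambda_reg * omega**2)


def closed_form_weights(
    t: float,
    mu_loo: float,
    sigma2_loo: float,
    lambda_reg: float,
) -> tuple[float, float]:
    """Closed-form minimiser ``(omega_t, bias_t)`` of the energy.

    ``mu_loo`` / ``sigma2_loo`` are the leave-one-out mean and variance of
    the channel (all neurons except ``t``).  The denominator vanishes only
    for a constant channel with ``lambda_reg = 0``, which is an error.
    """
    denom = (t - mu_loo) ** 2 + 2.0 * sigma2_loo + 2.0 * lambda_reg
    if denom <= 0:
        raise ZeroDivisionError(
            "degenerate channel: zero energy denominator (constant channel "
            "with lambda_reg = 0)"
        )
    omega_t = 2.0 * (t - mu_loo) / denom
    bias_t = -0.5 * (t + mu_loo) * omega_t
    return float(omega_t), float(bias_t)


def _check_featuremap(fm: np.ndarray) -> np.ndarray:
    fm = np.asarray(fm, dtype=float)
    if fm.ndim != 3:
        raise ValueError(f"feature map must be C x H x W, got shape {fm.shape}")
    if fm.shape[1] * fm.shape[2] < 2:
        raise ValueError("each channel needs at least M = 2 neurons")
    if not np.all(np.isfinite(fm)):
        raise ValueError("feature map contains non-finite values")
    return fm


def minimal_energy_exact(fm: np.ndarray, lambda_reg: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Per-neuron minimal energy with exact leave-one-out statistics.

    For each neuron the mean/variance exclude that neuron, so this equals the
    true minimum of :func:`energy` over ``(omega, bias)`` at every position.
    Output has the shape of ``fm``; entries are strictly positive for
    ``lambda_reg > 0`` and exactly 2 on constant channels.
    """
    fm = _check_featuremap(fm)
    if lambda_reg <= 0:
        raise ValueError("lambda_reg must be positive")
    C, H, W = fm.shape
    M = H * W
    x = fm.reshape(C, M)

    s1 = x.sum(axis=1, keepdims=True)
    s2 = (x**2).sum(axis=1, keepdims=True)
    mu_loo = (s1 - x) / (M - 1)
    # population variance of the M-1 others: E[x^2] - (E[x])^2
    sigma2_loo = (s2 - x**2) / (M - 1) - mu_loo**2
    sigma2_loo = np.maximum(sigma2_loo, 0.0)  # guard fp round-off

    d2 = (x - mu_loo) ** 2
    e = 4.0 * (sigma2_loo + lambda_reg) / (d2 + 2.0 * sigma2_loo + 2.0 * lambda_reg)
    return e.reshape(C, H, W)


def minimal_energy_fast(fm: np.ndarray, lambda_reg: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Minimal-energy map with shared per-channel statistics.

    Substitutes the channel-wide mean and variance (over all M neurons) for
    the per-neuron leave-one-out statistics.  One vectorised pass per
    channel; converges to :func:`minimal_energy_exact` as M grows.
    """
    fm = _check_featuremap(fm)
    if lambda_reg <= 0:
        raise ValueError("lambda_reg must be positive")
    mu = fm.mean(axis=(1, 2), keepdims=True)
    sigma2 = fm.var(axis=(1, 2), keepdims=True)
    d2 = (fm - mu) ** 2
    return 4.0 * (sigma2 + lambda_reg) / (d2 + 2.0 * sigma2 + 2.0 * lambda_reg)


def simam_refine(
    fm: np.ndarray,
    lambda_reg: float = DEFAULT_LAMBDA,
    mode: str = "fast",
    return_energy: bool = False,
) -> np.ndarray:
    """Attention-refine a feature map: ``fm * sigmoid(1 / e*)`` elementwise.

    Distinctive neurons (low energy) receive gains approaching 1; neurons at
    the channel mean are damped toward ``sigmoid(1/2) ~ 0.62``.  Shape and
    sign pattern of the input are preserved.  ``mode`` selects the energy
    variant; ``return_energy=True`` returns the raw energy map instead of
    the gated features.
    """
    if mode == "fast":
        e = minimal_energy_fast(fm, lambda_reg)
    elif mode == "exact":
        e = minimal_energy_exact(fm, lambda_reg)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if return_energy:
        return e
    gate = 1.0 / (1.0 + np.exp(-1.0 / e))
    return np.asarray(fm, dtype=float) * gate
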