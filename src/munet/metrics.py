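"""Bias, standard deviation and NRMSE across noise realizations.

All three figures of merit compare a set of reconstructions
``theta_r`` (one per noise realization ``r``) against a common target
volume ``T`` and are normalized by the target's root energy rather than
voxel-wise, which avoids exaggeration from low-intensity voxels::

    b     = 100% * ||T - mean_r(theta_r)||_2 / ||T||_2
    sigma = 100% * sqrt(sum_j Var_r{theta_rj}) / ||T||_2
    eps   = 100% * sqrt(sum_j mean_r{(T_j - theta_rj)^2}) / ||T||_2

The variance is the population variance (divide by R): that is the unique
convention under which ``eps**2 == b**2 + sigma**2`` holds exactly, which
is relied upon when reading bias-versus-standard-deviation trade-off
curves (distance from the origin is then NRMSE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsTriple", "bias", "stddev", "nrmse", "metrics_triple"]


@dataclass(frozen=True)
class MetricsTriple:
    """Normalized bias / standard deviation / NRMSE, all in percent."""

    bias_pct: float
    std_pct: float
    nrmse_pct: float
    target_id: str = ""
    n_realizations: int = 0


def _stack(realizations, target, mask=None, min_r: int = 1) -> tuple[np.ndarray, np.ndarray]:
    theta = np.stack([np.asarray(v, dtype=np.float64) for v in realizations])
    T = np.asarray(target, dtype=np.float64)
    if theta.shape[1:] != T.shape:
        raise ValueError(f"realization shape {theta.shape[1:]} != target shape {T.shape}")
    if theta.shape[0] < min_r:
        raise ValueError(f"need at least {min_r} realizations, got {theta.shape[0]}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != T.shape:
            raise ValueError("mask shape mismatch")
        theta = theta[:, mask]
        T = T[mask]
    else:
        theta = theta.reshape(theta.shape[0], -1)
        T = T.ravel()
    norm = np.sqrt(np.sum(T**2))
    if norm == 0.0:
        raise ValueError("target is all-zero: normalizer undefined")
    return theta, T


def bias(realizations, target, mask=None) -> float:
    """Normalized bias ``b`` in percent of the ensemble mean vs the target."""
    theta, T = _stack(realizations, target, mask)
    m = theta.mean(axis=0)
    return 100.0 * np.sqrt(np.sum((T - m) ** 2)) / np.sqrt(np.sum(T**2))


def stddev(realizations, target, mask=None) -> float:
    """Normalized standard deviation ``sigma`` in percent (population variance)."""
    theta, T = _stack(realizations, target, mask, min_r=2)
    var = theta.var(axis=0)  # population (divide by R)
    return 100.0 * np.sqrt(np.sum(var)) / np.sqrt(np.sum(T**2))


def nrmse(realizations, target, mask=None) -> float:
    """Normalized root mean squared error ``eps`` in percent."""
    theta, T = _stack(realizations, target, mask)
    mse = np.mean((T[None, :] - theta) ** 2, axis=0)
    return 100.0 * np.sqrt(np.sum(mse)) / np.sqrt(np.sum(T**2))


def metrics_triple(realizations, target, target_id: str = "", mask=None) -> MetricsTriple:
    """All three metrics at once (``sigma`` requires at least 2 realizations)."""
    r = list(realizations)
    return MetricsTriple(
        bias_pct=bias(r, target, mask),
        std_pct=stddev(r, target, mask),
        nrmse_pct=nrmse(r, target, mask),
        target_id=target_id,
        n_realizations=len(r),
    )
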