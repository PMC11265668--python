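"""Brownian displacement and reflecting confinement to the disc.

Particles (enzymes, RNAs, enzyme-RNA complexes) move by overdamped Langevin
dynamics: each timestep every coordinate is incremented by
``sqrt(2 * D_tilde) * g`` with ``g ~ N(0, 1)``, where ``D_tilde`` is the
dimensionless per-step diffusion constant (physical diffusivity folded into
the timestep and the particle diameter sigma, the unit of length).  The
simulation space is a disc of radius ``r``; particles that step outside are
mirrored back radially.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

__all__ = ["langevin_step", "reflect_into_disc"]


def langevin_step(
    positions: np.ndarray, d_tilde: float, rng: np.random.Generator
) -> np.ndarray:
    """Displace every particle by one Brownian increment.

    Parameters
    ----------
    positions
        Array of shape ``(n, 2)``, coordinates in sigma units.
    d_tilde
        Dimensionless diffusion constant (>= 0).  Single-axis increments have
        variance ``2 * d_tilde``; the 2D mean squared displacement grows as
        ``4 * d_tilde`` per step.
    rng
        Source of the Gaussian increments.

    Returns
    -------
    New position array; the input is not modified.  No boundary handling is
    applied here (see :func:`reflect_into_disc`).
    """
    if d_tilde < 0:
        raise ConfigurationError(f"d_tilde must be >= 0, got {d_tilde}")
    positions = np.asarray(positions, dtype=float)
    if d_tilde == 0:
        return positions.copy()
    g = rng.standard_normal(positions.shape)
    return positions + np.sqrt(2.0 * d_tilde) * g


def reflect_into_disc(position: np.ndarray, r: float) -> np.ndarray:
    """Map positions into the disc of radius ``r`` by radial mirroring.

    A point at radial distance ``rho > r`` is moved to ``2r - rho`` at the
    same polar angle; the mirror is applied iteratively for the (rare) case
    ``rho > 2r``.  Interior points and points exactly on the boundary are
    returned unchanged.  Works on a single position ``(2,)`` or a batch
    ``(n, 2)``.
    """
    if r <= 0:
        raise ConfigurationError(f"disc radius must be > 0, got {r}")
    p = np.atleast_2d(np.asarray(position, dtype=float)).copy()
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite position passed to reflect_into_disc")
    rho = np.hypot(p[:, 0], p[:, 1])
    out = rho > r
    while np.any(out):
        scale = (2.0 * r - rho[out]) / rho[out]  # may be negative: through origin
        p[out] *= scale[:, None]
        rho = np.hypot(p[:, 0], p[:, 1])
        out = rho > r
    return p.reshape(np.asarray(position, dtype=float).shape)
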