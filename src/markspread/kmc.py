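"""Reaction-only kinetic Monte Carlo comparator (a pinned contact process).

The lattice of ``n_sites`` nucleosomes evolves in continuous time: a U site
with ``m`` modified neighbours gains the mark at propensity ``m * k_plus``
(additive over neighbours, the standard contact-process convention; a
binary mode is available for sensitivity checks), and any M site except the
nucleation point loses it at rate ``k_minus``.  The nucleation point is
held modified at all times.  The only dimensionless control parameter is
``K = k_plus / k_minus``.

The space-dependent variant replaces the uniform spreading rate with
``k_plus(i) = k0 * exp(-|i| / l_d)``, a phenomenological stand-in for the
diffusive length scale of the catalyst cloud in the full RD model;
``l_d = inf`` recovers the basic model.

For small lattices the continuous-time Markov chain is solved exactly
(:func:`master_equation_profile`), providing an independent oracle for the
Gillespie sampler.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Callable, Optional

import numpy as np
import scipy.sparse

from ._engine import gillespie_kernel
from .errors import ConfigurationError
from .stats import Profile

__all__ = [
    "KMCParams",
    "spatial_rate",
    "gillespie_run",
    "master_equation_profile",
]

RateFn = Callable[[int], float]


@dataclass
class KMCParams:
    """Parameters of the reaction-only model.

    ``n_sites`` may be even only for truncation studies (e.g. the two-site
    nucleation-point-plus-neighbour chain); the standard lattice is 61 sites,
    genomic labels j in [-30, 30], nucleation point at label 0 (array index
    ``(n_sites - 1) // 2``).
    """

    n_sites: int = 61
    k_plus: float = 1.0
    k_minus: float = 1.0
    k0: Optional[float] = None  # spatial variant amplitude
    l_d: Optional[float] = None  # spatial variant decay length (inf = basic)
    additive: bool = True
    n_events: int = 1_000_000
    burn_in_frac: float = 0.2
    seed: int = 0

    @property
    def K(self) -> float:
        """Ratio of the spreading rate to the removal rate."""
        k = self.k0 if self.k0 is not None else self.k_plus
        return k / self.k_minus

    @classmethod
    def from_K(cls, K: float, **kwargs) -> "KMCParams":
        return cls(k_plus=float(K), k_minus=1.0, **kwargs)

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ConfigurationError(f"n_sites must be >= 2, got {self.n_sites}")
        if self.k_plus < 0 or self.k_minus < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.k0 is not None and self.k0 < 0:
            raise ConfigurationError(f"k0 must be >= 0, got {self.k0}")
        if self.l_d is not None and not (self.l_d > 0):
            raise ConfigurationError(f"l_d must be > 0, got {self.l_d}")
        if self.n_events < 1:
            raise ConfigurationError("n_events must be >= 1")
        if not (0.0 <= self.burn_in_frac < 1.0):
            raise ConfigurationError("burn_in_frac must lie in [0, 1)")

    @property
    def np_index(self) -> int:
        return (self.n_sites - 1) // 2

    @property
    def site_labels(self) -> np.ndarray:
        return np.arange(self.n_sites) - self.np_index

    def rate_fn(self) -> RateFn:
        """Per-site spreading rate as a function of the genomic label."""
        if self.k0 is not None:
            k0, l_d = self.k0, self.l_d if self.l_d is not None else math.inf
            return lambda i: spatial_rate(i, k0, l_d)
        k = self.k_plus
        return lambda i: k


def spatial_rate(i: int, k0: float, l_d: float) -> float:
    """Exponentially decaying spreading rate ``k0 * exp(-|i| / l_d)``.

    ``l_d = inf`` is the sentinel for the space-independent basic model.
    """
    if not (l_d > 0):
        raise ConfigurationError(f"l_d must be > 0, got {l_d}")
    if math.isinf(l_d):
        return k0
    return k0 * math.exp(-abs(i) / l_d)


def _kplus_array(params: KMCParams, rate_fn: Optional[RateFn]) -> np.ndarray:
    fn = rate_fn if rate_fn is not None else params.rate_fn()
    return np.array([fn(int(i)) for i in params.site_labels], dtype=float)


def gillespie_run(
    params: KMCParams,
    rate_fn: Optional[RateFn] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Profile, dict]:
    """Sample the stationary profile by the Gillespie algorithm.

    Returns the time-weighted per-site P(M) (accumulated after the burn-in
    fraction of events) and a metadata dict.  ``rate_fn`` overrides the
    spreading-rate function derived from ``params``; ``rng`` only supplies
    the kernel seed when given (the kernel itself runs a dedicated seeded
    stream for bit-reproducibility).
    """
    params.validate()
    seed = params.seed if rng is None else int(rng.integers(2**31))
    kplus = _kplus_array(params, rate_fn)
    burn = int(params.burn_in_frac * params.n_events)
    p, n_events = gillespie_kernel(
        seed,
        params.n_sites,
        params.np_index,
        kplus,
        params.k_minus,
        params.additive,
        params.n_events,
        burn,
    )
    profile = Profile(params.site_labels, np.clip(p, 0.0, 1.0), n_samples=int(n_events))
    metadata = {
        "model": "kmc",
        "seed": seed,
        "params": asdict(params),
        "n_events": int(n_events),
    }
    return profile, metadata


def master_equation_profile(
    n_sites: int,
    params: KMCParams,
    rate_fn: Optional[RateFn] = None,
) -> Profile:
    """Exact stationary per-site P(M) of the continuous-time Markov chain.

    Enumerates all ``2**(n_sites - 1)`` U/M configurations with the
    nucleation point pinned M, builds the generator, solves ``pi Q = 0``
    and marginalises per site.  Tractable up to ``n_sites = 13``.
    """
    if n_sites > 13:
        raise ConfigurationError(
            f"master_equation_profile is limited to n_sites <= 13 "
            f"(2^{n_sites - 1} states requested)"
        )
    if n_sites < 2:
        raise ConfigurationError(f"n_sites must be >= 2, got {n_sites}")
    params = KMCParams(**{**asdict(params), "n_sites": n_sites})
    params.validate()
    np_index = params.np_index
    kplus = _kplus_array(params, rate_fn)
    free = [j for j in range(n_sites) if j != np_index]
    bit = {j: b for b, j in enumerate(free)}
    n_states = 1 << len(free)

    def occupied(state: int, j: int) -> bool:
        if j < 0 or j >= n_sites:
            return False
        if j == np_index:
            return True
        return bool(state >> bit[j] & 1)

    rows, cols, vals = [], [], []
    diag = np.zeros(n_states)
    for s in range(n_states):
        for j in free:
            b = bit[j]
            if occupied(s, j):
                rate = params.k_minus
                tgt = s & ~(1 << b)
            else:
                m = int(occupied(s, j - 1)) + int(occupied(s, j + 1))
                if params.additive:
                    rate = m * kplus[j]
                else:
                    rate = kplus[j] if m > 0 else 0.0
                tgt = s | (1 << b)
            if rate > 0:
                rows.append(s)
                cols.append(tgt)
                vals.append(rate)
                diag[s] -= rate
    q = scipy.sparse.coo_matrix(
        (vals + list(diag), (rows + list(range(n_states)), cols + list(range(n_states)))),
        shape=(n_states, n_states),
    ).tocsc()
    # stationary distribution: pi Q = 0, sum pi = 1 (replace one equation)
    a = q.transpose().toarray()
    a[-1, :] = 1.0
    b_vec = np.zeros(n_states)
    b_vec[-1] = 1.0
    pi = np.linalg.solve(a, b_vec)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    p = np.empty(n_sites)
    for j in range(n_sites):
        if j == np_index:
            p[j] = 1.0
        else:
            mask = 1 << bit[j]
            p[j] = pi[(np.arange(n_states) & mask) > 0].sum()
    return Profile(params.site_labels, np.clip(p, 0.0, 1.0), n_samples=n_states)
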