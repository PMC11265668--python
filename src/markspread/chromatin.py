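"""Nucleosome state updates: proximity-gated methylation and demethylation.

A U-site can gain the mark only when a catalytically competent complex (C)
is within the proximity radius of its spatial position.  The effective
per-step methylation probability is

    P_m_eff = delta_C * min(1, P_w + P_m * delta_nbr)

where ``delta_C`` is 1 iff at least one C is proximal (multiple proximal
complexes do not add), and ``delta_nbr`` is 1 iff *any* neighbour of the
site is in the M state (binary, not per-neighbour additive).  ``P_w`` is the
pure "writer" pathway (deposit without a marked neighbour, used in the
no-nucleation-point variant); ``P_m`` is the reader-writer pathway.  Each M
site loses the mark independently with probability ``P_dm``, except the
nucleation point while nucleation is enabled.

Methylation sweeps are synchronous: all draws are evaluated against the
pre-sweep lattice, so a site methylated this sweep cannot boost its
neighbour until the next one.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .state import SPECIES_C, STATE_M, STATE_U, LatticeState, ParticleSystem

__all__ = [
    "NeighborSystem",
    "effective_methylation_prob",
    "methylation_sweep",
    "demethylation_sweep",
]


class NeighborSystem:
    """For each site, the sites whose M state boosts its methylation.

    Linear mode: nearest genomic neighbours {i-1, i+1}.  Polymer mode: all
    beads in spatial contact (see :func:`markspread.polymer.contact_neighbors`).
    The relation is symmetric.
    """

    def __init__(self, neighbors: Sequence[Sequence[int]]):
        self._nbr = [np.asarray(sorted(n), dtype=np.int64) for n in neighbors]
        n = len(self._nbr)
        for i, nb in enumerate(self._nbr):
            if np.any(nb < 0) or np.any(nb >= n) or i in nb:
                raise ConfigurationError(f"invalid neighbor list for site {i}")
            for j in nb:
                if i not in self._nbr[j]:
                    raise ConfigurationError(
                        f"neighbor relation not symmetric: {i} -> {j}"
                    )

    @classmethod
    def linear(cls, n_sites: int) -> "NeighborSystem":
        nbrs = [
            [j for j in (i - 1, i + 1) if 0 <= j < n_sites] for i in range(n_sites)
        ]
        return cls(nbrs)

    def __len__(self) -> int:
        return len(self._nbr)

    def neighbors(self, site: int) -> np.ndarray:
        return self._nbr[site]

    def to_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (indptr, indices) for the compiled engine."""
        indptr = np.zeros(len(self._nbr) + 1, dtype=np.int64)
        for i, nb in enumerate(self._nbr):
            indptr[i + 1] = indptr[i] + len(nb)
        indices = np.concatenate(self._nbr) if self._nbr else np.empty(0, np.int64)
        return indptr, indices.astype(np.int64)

    def max_degree(self) -> int:
        return max((len(nb) for nb in self._nbr), default=0)


def effective_methylation_prob(
    site: int,
    lattice: LatticeState,
    neighbor_system: NeighborSystem,
    c_proximal: bool,
    p_w: float,
    p_m: float,
) -> float:
    """P_m_eff for one currently-U site (see module docstring).

    Calling this on an M site is a contract violation.
    """
    if lattice.states[site] != STATE_U:
        raise ValueError(f"effective_methylation_prob called on M site {site}")
    if not c_proximal:
        return 0.0
    nbr_m = any(lattice.states[j] == STATE_M for j in neighbor_system.neighbors(site))
    return min(1.0, p_w + (p_m if nbr_m else 0.0))


def _c_proximal_mask(
    lattice: LatticeState, system: ParticleSystem, d_prox: float
) -> np.ndarray:
    c_pos = system.of_species(SPECIES_C)
    if c_pos.shape[0] == 0:
        return np.zeros(lattice.n_sites, dtype=bool)
    d = lattice.site_positions[:, None, :] - c_pos[None, :, :]
    dist2 = (d ** 2).sum(axis=2)
    return (dist2 <= d_prox * d_prox).any(axis=1)


def methylation_sweep(
    lattice: LatticeState,
    system: ParticleSystem,
    neighbor_system: NeighborSystem,
    d_prox: float,
    p_w: float,
    p_m: float,
    rng: np.random.Generator,
) -> LatticeState:
    """One synchronous methylation attempt over every U site."""
    if d_prox <= 0:
        raise ConfigurationError(f"d_prox must be > 0, got {d_prox}")
    out = lattice.copy()
    prox = _c_proximal_mask(lattice, system, d_prox)
    for site in np.flatnonzero(lattice.states == STATE_U):
        p_eff = effective_methylation_prob(
            site, lattice, neighbor_system, bool(prox[site]), p_w, p_m
        )
        if p_eff > 0.0 and rng.random() < p_eff:
            out.states[site] = STATE_M
    return out


def demethylation_sweep(
    lattice: LatticeState,
    p_dm: float,
    nucleation_enabled: bool,
    rng: np.random.Generator,
) -> LatticeState:
    """Flip each M site to U independently with probability ``p_dm``.

    The nucleation site is excluded from the draw while nucleation is
    enabled.
    """
    if not (0.0 <= p_dm <= 1.0):
        raise ConfigurationError(f"P_dm must lie in [0, 1], got {p_dm}")
    out = lattice.copy()
    flip = (lattice.states == STATE_M) & (rng.random(lattice.n_sites) < p_dm)
    if nucleation_enabled:
        flip[lattice.np_index] = False
    out.states[flip] = STATE_U
    return out
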