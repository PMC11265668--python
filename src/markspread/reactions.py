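"""Stochastic particle birth, death, and species conversion.

The reaction network, with one Bernoulli trial per particle per timestep
(probabilities, not rates — there is no Poissonization):

* ``phi -> R`` with probability ``P_rp`` per step, only at the origin
  (the nucleation point's spatial position);
* ``R -> phi`` with probability ``P_rd`` per step, anywhere in space;
* ``E + R -> C`` with probability ``P_cp`` when an E and an R are within the
  proximity radius ``d_prox``; the C inherits the E's position and the R is
  consumed;
* ``C -> E`` with probability ``P_cd`` per step; the RNA component is
  destroyed, the enzyme persists.

Enzymes are never created or destroyed, so count(E) + count(C) is invariant
under all four operations combined.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .state import SPECIES_C, SPECIES_E, SPECIES_R, ParticleSystem

__all__ = ["produce_rna", "decay_rna", "form_complexes", "decay_complexes"]


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")


def produce_rna(
    system: ParticleSystem,
    p_rp: float,
    origin_position: np.ndarray,
    rng: np.random.Generator,
) -> ParticleSystem:
    """With probability ``p_rp``, append one R particle at the origin.

    Production is a single source: one Bernoulli draw per timestep, not one
    per site.
    """
    _check_prob("P_rp", p_rp)
    if rng.random() >= p_rp:
        return system.copy()
    pos = np.vstack([system.positions, np.asarray(origin_position, float).reshape(1, 2)])
    spc = np.append(system.species, np.int8(SPECIES_R))
    return ParticleSystem(pos, spc)


def decay_rna(
    system: ParticleSystem, p_rd: float, rng: np.random.Generator
) -> ParticleSystem:
    """Remove each R particle independently with probability ``p_rd``."""
    _check_prob("P_rd", p_rd)
    is_r = system.species == SPECIES_R
    doomed = is_r & (rng.random(len(system)) < p_rd)
    keep = ~doomed
    return ParticleSystem(system.positions[keep], system.species[keep])


def form_complexes(
    system: ParticleSystem,
    p_cp: float,
    d_prox: float,
    rng: np.random.Generator,
) -> ParticleSystem:
    """Pair up E and R particles within ``d_prox`` into C particles.

    Matching rule: R particles are visited in index order; each reacts with
    its nearest free E within ``d_prox``.  A successful reaction (probability
    ``p_cp``) converts the E to a C in place and removes the R; each particle
    participates in at most one reaction per step.
    """
    _check_prob("P_cp", p_cp)
    if d_prox <= 0:
        raise ConfigurationError(f"d_prox must be > 0, got {d_prox}")
    species = system.species.copy()
    positions = system.positions
    r_idx = np.flatnonzero(species == SPECIES_R)
    e_free = species == SPECIES_E
    consumed_r = np.zeros(len(system), dtype=bool)
    d2 = d_prox * d_prox
    for ri in r_idx:
        free = np.flatnonzero(e_free)
        if free.size == 0:
            break
        d = positions[free] - positions[ri]
        dist2 = d[:, 0] ** 2 + d[:, 1] ** 2
        j = int(np.argmin(dist2))
        if dist2[j] > d2:
            continue
        if p_cp >= 1.0 or rng.random() < p_cp:
            e = free[j]
            species[e] = SPECIES_C
            e_free[e] = False
            consumed_r[ri] = True
    keep = ~consumed_r
    return ParticleSystem(positions[keep], species[keep])


def decay_complexes(
    system: ParticleSystem, p_cd: float, rng: np.random.Generator
) -> ParticleSystem:
    """Convert each C back to an E (same position) with probability ``p_cd``.

    The bound RNA component is destroyed, not released.
    """
    _check_prob("P_cd", p_cd)
    species = system.species.copy()
    is_c = species == SPECIES_C
    flip = is_c & (rng.random(len(system)) < p_cd)
    species[flip] = SPECIES_E
    return ParticleSystem(system.positions.copy(), species)
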