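"""Parameters and run orchestrator for the reaction-diffusion model.

The model: a 1D lattice of ``N_n`` nucleosomes (U or M state, nucleation
point at genomic index 0) embedded in a 2D disc of radius ``r`` in which
``N_e`` enzyme particles and the RNAs produced at the nucleation point
diffuse and react.  Each timestep applies, in this fixed order:

1. Brownian displacement of every particle + reflection into the disc,
2. RNA decay (``P_rd``),
3. RNA production at the nucleation point (``P_rp``),
4. complex formation ``E + R -> C`` within ``d_prox`` (``P_cp``),
5. complex decay ``C -> E`` (``P_cd``),
6. synchronous methylation sweep (``P_w``, ``P_m``, gated on a proximal C),
7. demethylation sweep (``P_dm``),
8. nucleation-point re-assertion.

Decay precedes production so a particle cannot be born and die in the same
step, and all reactions follow movement.  Lattice state and particle
statistics are recorded every ``sample_interval`` steps after ``burn_in``.

All lengths are in sigma units (one particle diameter, one lattice
spacing).  The dimensionless diffusion constant ``D_tilde = mu*kB*T*dt /
sigma^2`` folds the physical mobility, temperature and timestep into a
single per-step constant; the default 2e-4 corresponds to a particle of
5-10 nm diffusing at ~1e-3 um^2/s on the model's timestep.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from ._engine import run_rd
from .chromatin import NeighborSystem
from .errors import ConfigurationError
from .state import SPECIES_C, SPECIES_E, SPECIES_R, ParticleSystem
from .stats import Profile, ShellDensity

__all__ = ["RDParams", "RunResult", "run_rd_simulation"]

_PROB_FIELDS = ("p_rp", "p_rd", "p_cp", "p_cd", "p_w", "p_m", "p_dm")


@dataclass
class RDParams:
    """Every probability, count and length governing one RD run.

    Defaults are the baseline conditions of the linear-lattice studies:
    61 sites, 500 enzymes in a 40-sigma disc, diffusion-limited
    complex formation (``p_cp = 1``), reader-writer pathway only
    (``p_w = 0``, ``p_m = 1``), slow complex decay.
    """

    n_nucleosomes: int = 61
    radius: float = 40.0
    n_enzymes: int = 500
    d_tilde: float = 2e-4
    p_rp: float = 1e-3
    p_rd: float = 1e-3
    p_cp: float = 1.0
    p_cd: float = 1e-6
    p_w: float = 0.0
    p_m: float = 1.0
    p_dm: float = 1e-3
    d_prox: float = 1.0
    nucleation_enabled: bool = True
    n_steps: int = 200_000
    burn_in: int = 100_000
    sample_interval: int = 500
    seed: int = 0
    rna_cap: int = 100_000
    shell_dr: float = 1.0

    def validate(self) -> None:
        n = self.n_nucleosomes
        if n < 1 or n % 2 == 0:
            raise ConfigurationError(
                f"n_nucleosomes must be an odd positive integer, got {n}"
            )
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.d_tilde < 0:
            raise ConfigurationError(f"d_tilde must be >= 0, got {self.d_tilde}")
        if self.d_prox <= 0:
            raise ConfigurationError(f"d_prox must be > 0, got {self.d_prox}")
        if self.n_enzymes < 0:
            raise ConfigurationError(f"n_enzymes must be >= 0, got {self.n_enzymes}")
        if self.radius < (n - 1) / 2:
            raise ConfigurationError(
                f"radius {self.radius} too small: the {n}-site lattice needs "
                f"radius >= {(n - 1) / 2} to fit inside the disc"
            )
        if self.burn_in >= self.n_steps:
            raise ConfigurationError(
                f"burn_in ({self.burn_in}) must be < n_steps ({self.n_steps})"
            )
        if self.sample_interval < 1:
            raise ConfigurationError(
                f"sample_interval must be >= 1, got {self.sample_interval}"
            )
        if self.rna_cap < 1:
            raise ConfigurationError(f"rna_cap must be >= 1, got {self.rna_cap}")
        if self.shell_dr <= 0:
            raise ConfigurationError(f"shell_dr must be > 0, got {self.shell_dr}")
        if not (0 <= self.seed < 2**31):
            raise ConfigurationError(f"seed must lie in [0, 2^31), got {self.seed}")

    @property
    def site_labels(self) -> np.ndarray:
        return np.arange(self.n_nucleosomes) - (self.n_nucleosomes - 1) // 2

    @property
    def n_samples(self) -> int:
        return (self.n_steps - self.burn_in) // self.sample_interval

    def replace(self, **kwargs) -> "RDParams":
        d = asdict(self)
        d.update(kwargs)
        return RDParams(**d)


@dataclass
class RunResult:
    """Aggregated output of one RD run."""

    profile: Profile
    shell_density: ShellDensity
    cprox: np.ndarray  # per-site <C^p>
    lattice_samples: np.ndarray  # (n_samples, n_sites) uint8
    species_counts: np.ndarray  # (n_samples, 3): E, R, C per sample
    particles: ParticleSystem  # final snapshot
    metadata: dict = field(default_factory=dict)

    @property
    def max_particle_radius(self) -> float:
        return self.metadata["max_particle_radius"]


def _build_geometry(
    params: RDParams, polymer
) -> tuple[np.ndarray, NeighborSystem, int]:
    if polymer is None:
        labels = params.site_labels
        site_pos = np.column_stack(
            [labels.astype(float), np.zeros(params.n_nucleosomes)]
        )
        neighbors = NeighborSystem.linear(params.n_nucleosomes)
    else:
        if polymer.n_beads != params.n_nucleosomes:
            raise ConfigurationError(
                f"polymer has {polymer.n_beads} beads but params.n_nucleosomes is "
                f"{params.n_nucleosomes}"
            )
        max_r = float(np.hypot(polymer.coords[:, 0], polymer.coords[:, 1]).max())
        if params.radius < max_r + 2.0:
            raise ConfigurationError(
                f"radius {params.radius} too small for polymer extent {max_r:.2f}: "
                f"need radius >= max bead radius + 2 sigma"
            )
        site_pos = polymer.coords.astype(float)
        neighbors = polymer.neighbor_system()
    np_index = (params.n_nucleosomes - 1) // 2
    return site_pos, neighbors, np_index


def run_rd_simulation(
    params: RDParams, polymer: Optional["PolymerConfig"] = None
) -> RunResult:
    """Execute one reaction-diffusion run and aggregate its statistics.

    Parameters
    ----------
    params
        Validated run parameters.
    polymer
        Optional frozen :class:`~markspread.polymer.PolymerConfig`; its beads
        become the nucleosome positions and its contact adjacency the
        spreading topology.  The configuration is static for the whole run.

    Returns
    -------
    :class:`RunResult` with the methylation profile, RNA shell density,
    complex-proximity profile, raw lattice samples and run metadata (seed,
    parameter echo, sample count, invariant diagnostics).
    """
    params.validate()
    site_pos, neighbors, np_index = _build_geometry(params, polymer)
    indptr, indices = neighbors.to_csr()

    (
        samples,
        species_counts,
        cprox_sum,
        shell_sum,
        ex,
        ey,
        is_c,
        rx,
        ry,
        max_radius,
        overflow,
    ) = run_rd(
        params.seed,
        params.n_steps,
        params.burn_in,
        params.sample_interval,
        params.d_tilde,
        params.radius,
        params.p_rp,
        params.p_rd,
        params.p_cp,
        params.p_cd,
        params.p_w,
        params.p_m,
        params.p_dm,
        params.d_prox,
        params.nucleation_enabled,
        np.ascontiguousarray(site_pos, dtype=np.float64),
        indptr,
        indices,
        np_index,
        params.n_enzymes,
        params.rna_cap,
        params.shell_dr,
    )
    if overflow:
        warnings.warn(
            f"RNA particle count hit rna_cap={params.rna_cap}; production events "
            "were dropped while at the cap",
            RuntimeWarning,
            stacklevel=2,
        )

    n_samples = samples.shape[0]
    profile = Profile.from_samples(samples, params.site_labels)
    shell = ShellDensity(
        edges=params.shell_dr
        * np.arange(int(np.ceil(params.radius / params.shell_dr)) + 1),
        counts=shell_sum / max(n_samples, 1),
    )
    cprox = cprox_sum / max(n_samples, 1)

    enz_species = np.where(is_c.astype(bool), SPECIES_C, SPECIES_E).astype(np.int8)
    positions = np.vstack([np.column_stack([ex, ey]), np.column_stack([rx, ry])])
    species = np.concatenate(
        [enz_species, np.full(rx.shape[0], SPECIES_R, dtype=np.int8)]
    )
    particles = ParticleSystem(positions, species)

    from . import __version__

    metadata = {
        "model": "rd",
        "version": __version__,
        "seed": params.seed,
        "params": asdict(params),
        "n_samples": n_samples,
        "topology": "linear" if polymer is None else f"polymer:{polymer.walk_type}",
        "max_particle_radius": float(max_radius),
        "enzyme_conservation_ok": bool(
            np.all(species_counts[:, 0] + species_counts[:, 2] == params.n_enzymes)
        ),
        "rna_overflow": bool(overflow),
    }
    return RunResult(
        profile=profile,
        shell_density=shell,
        cprox=cprox,
        lattice_samples=samples,
        species_counts=species_counts,
        particles=particles,
        metadata=metadata,
    )
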