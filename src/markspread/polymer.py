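"""Frozen 2D lattice polymers: generators, contact maps, ensemble runs.

Chromatin compaction is represented by a square-lattice polymer whose beads
are the nucleosomes: a self-avoiding walk (SAW) for swollen/open chromatin
and a plain random walk (RW) for compact chromatin (site revisits allowed,
hence many more spatial contacts).  Configurations are *frozen*: the
geometry is fixed for the whole spreading run, valid when spreading is fast
compared to polymer relaxation.  The nucleation bead is the central bead,
translated to the origin so that RNA production and the genomic coordinate
system match the linear-lattice setup.

SAWs are sampled with the pivot algorithm: start from a rod, propose a
random lattice symmetry applied to the tail beyond a random pivot bead,
accept if the result is self-avoiding, and discard a burn-in of accepted
pivots before using the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, ParseError
from .chromatin import NeighborSystem
from .stats import Profile

__all__ = [
    "PolymerConfig",
    "generate_rw_2d",
    "generate_saw_2d",
    "contact_neighbors",
    "run_polymer_ensemble",
    "read_polymer_config",
    "write_polymer_config",
]

_STEPS = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)], dtype=np.int64)

# the 7 non-identity symmetries of the square lattice (rotations + mirrors)
_SYMMETRIES = np.array(
    [
        [[0, -1], [1, 0]],   # rot 90
        [[-1, 0], [0, -1]],  # rot 180
        [[0, 1], [-1, 0]],   # rot 270
        [[-1, 0], [0, 1]],   # mirror x
        [[1, 0], [0, -1]],   # mirror y
        [[0, 1], [1, 0]],    # mirror diagonal
        [[0, -1], [-1, 0]],  # mirror anti-diagonal
    ],
    dtype=np.int64,
)


@dataclass
class PolymerConfig:
    """Frozen bead coordinates plus the contact cutoff that defines adjacency.

    Beads sit on the square lattice with unit bond length (sigma units), one
    bead per nucleosome.  The nucleation bead (central index) is at the
    origin.
    """

    coords: np.ndarray
    walk_type: str = "SAW"
    contact_cutoff: float = 1.5

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if self.coords.shape[0] < 2:
            raise ConfigurationError("polymer needs at least 2 beads")
        if self.walk_type not in ("SAW", "RW"):
            raise ConfigurationError(
                f"walk_type must be 'SAW' or 'RW', got {self.walk_type!r}"
            )
        if self.contact_cutoff < 1.0:
            raise ConfigurationError(
                f"contact_cutoff must be >= 1 (bond length), got {self.contact_cutoff}"
            )
        bond = np.hypot(*(np.diff(self.coords, axis=0).T))
        if not np.allclose(bond, 1.0):
            raise ConfigurationError("consecutive beads must be at distance 1")
        if self.walk_type == "SAW":
            rounded = {tuple(np.round(c).astype(int)) for c in self.coords}
            if len(rounded) != self.coords.shape[0]:
                raise ConfigurationError("SAW configuration has coincident beads")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def np_bead(self) -> int:
        return (self.n_beads - 1) // 2

    def end_to_end_sq(self) -> float:
        d = self.coords[-1] - self.coords[0]
        return float(d @ d)

    def neighbor_system(self) -> NeighborSystem:
        return contact_neighbors(self, self.contact_cutoff)


def _center_on_np(coords: np.ndarray) -> np.ndarray:
    return coords - coords[(coords.shape[0] - 1) // 2]


def generate_rw_2d(
    n_beads: int, rng: np.random.Generator, contact_cutoff: float = 1.5
) -> PolymerConfig:
    """Square-lattice random walk; each step uniform over the 4 directions."""
    if n_beads < 2:
        raise ConfigurationError(f"n_beads must be >= 2, got {n_beads}")
    steps = _STEPS[rng.integers(0, 4, size=n_beads - 1)]
    coords = np.vstack([np.zeros((1, 2), dtype=np.int64), np.cumsum(steps, axis=0)])
    return PolymerConfig(_center_on_np(coords), "RW", contact_cutoff)


def generate_saw_2d(
    n_beads: int,
    rng: np.random.Generator,
    contact_cutoff: float = 1.5,
    burn_in_pivots: Optional[int] = None,
    max_attempts: Optional[int] = None,
) -> PolymerConfig:
    """Self-avoiding walk sampled by the pivot algorithm.

    Starts from a rod and discards a burn-in of ``burn_in_pivots`` accepted
    pivots (default ``10 * n_beads``) before returning.  Raises if the
    attempt cap (default ``1000 * burn_in_pivots``) is exhausted — pivot
    acceptance on the 2D square lattice is high enough that this only
    triggers on pathological inputs.
    """
    if n_beads < 2:
        raise ConfigurationError(f"n_beads must be >= 2, got {n_beads}")
    if burn_in_pivots is None:
        burn_in_pivots = 10 * n_beads
    if max_attempts is None:
        max_attempts = max(1000 * burn_in_pivots, 10_000)
    coords = np.column_stack(
        [np.arange(n_beads, dtype=np.int64), np.zeros(n_beads, dtype=np.int64)]
    )
    accepted = 0
    attempts = 0
    while accepted < burn_in_pivots:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"pivot algorithm: no acceptance after {max_attempts} attempts"
            )
        if n_beads == 2:
            # rod of one bond: every pivot about an endpoint is acceptable
            op = _SYMMETRIES[rng.integers(0, 7)]
            coords[1] = coords[0] + (coords[1] - coords[0]) @ op.T
            accepted += 1
            continue
        p = int(rng.integers(1, n_beads - 1))
        op = _SYMMETRIES[rng.integers(0, 7)]
        tail = (coords[p + 1 :] - coords[p]) @ op.T + coords[p]
        head = {(int(x), int(y)) for x, y in coords[: p + 1]}
        if any((int(x), int(y)) in head for x, y in tail):
            continue
        if len({(int(x), int(y)) for x, y in tail}) != tail.shape[0]:
            # cannot happen: a lattice symmetry preserves self-avoidance of
            # the tail; kept as a cheap safety net for future edits
            continue
        coords[p + 1 :] = tail
        accepted += 1
    return PolymerConfig(_center_on_np(coords), "SAW", contact_cutoff)


def contact_neighbors(config: PolymerConfig, contact_cutoff: float) -> NeighborSystem:
    """Adjacency: backbone neighbours plus all bead pairs within the cutoff.

    The default cutoff 1.5 sigma captures diagonal and coincident contacts
    but excludes the next-nearest lattice shell (distance 2).
    """
    if contact_cutoff < 1.0:
        raise ConfigurationError(
            f"contact_cutoff must be >= 1, got {contact_cutoff}"
        )
    coords = config.coords
    n = coords.shape[0]
    d = coords[:, None, :] - coords[None, :, :]
    dist2 = (d**2).sum(axis=2)
    close = dist2 <= contact_cutoff**2
    nbrs = []
    for i in range(n):
        nb = set(np.flatnonzero(close[i]).tolist()) - {i}
        if i > 0:
            nb.add(i - 1)
        if i < n - 1:
            nb.add(i + 1)
        nbrs.append(sorted(nb))
    return NeighborSystem(nbrs)


def run_polymer_ensemble(
    params: "RDParams",
    n_configs: int,
    walk_type: str,
    rng: np.random.Generator,
    contact_cutoff: float = 1.5,
    configs: Optional[list[PolymerConfig]] = None,
):
    """Run the RD simulation over an ensemble of frozen configurations.

    Each of ``n_configs`` independently generated configurations (or the
    provided ``configs``) is used as a static geometry for one full RD run;
    per-run seeds are drawn from ``rng``.  Returns ``(per-config profiles,
    ensemble-average profile, configs)``, all indexed by genomic bead
    position.
    """
    from .core import run_rd_simulation

    if configs is None:
        if walk_type not in ("SAW", "RW"):
            raise ConfigurationError(f"walk_type must be 'SAW' or 'RW', got {walk_type}")
        gen = generate_saw_2d if walk_type == "SAW" else generate_rw_2d
        configs = []
        attempts = 0
        while len(configs) < n_configs:
            attempts += 1
            if attempts > 50 * n_configs:
                raise ConfigurationError(
                    f"could not generate {n_configs} configurations fitting inside "
                    f"radius {params.radius}; increase the disc radius"
                )
            config = gen(params.n_nucleosomes, rng, contact_cutoff)
            max_r = float(np.hypot(config.coords[:, 0], config.coords[:, 1]).max())
            # the ensemble conditions on configurations that fit the disc;
            # oversized draws (rare at the default radius) are redrawn
            if max_r + 2.0 <= params.radius:
                configs.append(config)
    profiles = []
    for config in configs:
        run_params = params.replace(seed=int(rng.integers(2**31)))
        result = run_rd_simulation(run_params, polymer=config)
        profiles.append(result.profile)
    mean_p = np.mean([pr.p for pr in profiles], axis=0)
    ensemble = Profile(
        profiles[0].sites, mean_p, n_samples=sum(pr.n_samples for pr in profiles)
    )
    return profiles, ensemble, configs


def write_polymer_config(config: PolymerConfig, path) -> None:
    """Plain-text export: one ``index x y`` row per bead."""
    with open(path, "w") as fh:
        fh.write(f"# walk_type={config.walk_type} contact_cutoff={config.contact_cutoff}\n")
        for i, (x, y) in enumerate(config.coords):
            fh.write(f"{i}\t{x:.1f}\t{y:.1f}\n")


def read_polymer_config(path, walk_type: Optional[str] = None) -> PolymerConfig:
    """Read and validate a plain-text polymer configuration."""
    rows = []
    wt = walk_type
    cutoff = 1.5
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("walk_type=") and wt is None:
                        wt = token.split("=", 1)[1]
                    if token.startswith("contact_cutoff="):
                        cutoff = float(token.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(
                    f"expected 'index x y', got {len(parts)} fields", path, ln
                )
            try:
                idx, x, y = int(parts[0]), float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(f"unparseable row: {exc}", path, ln) from None
            if idx != len(rows):
                raise ParseError(
                    f"bead index {idx} out of order (expected {len(rows)})", path, ln
                )
            rows.append((x, y))
    if len(rows) < 2:
        raise ParseError("polymer file has fewer than 2 beads", path)
    return PolymerConfig(np.array(rows), wt or "SAW", cutoff)
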