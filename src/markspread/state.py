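"""In-memory state containers: diffusing particles and the nucleosome lattice.

Species codes: 0 = E (enzyme), 1 = R (RNA-like particle), 2 = C (enzyme-RNA
complex).  Enzymes are conserved — an E can only convert to C and back — so
``count(E) + count(C)`` is constant over a run.  RNA is produced at the
nucleation point and decays anywhere, so its count fluctuates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SPECIES_E = 0
SPECIES_R = 1
SPECIES_C = 2
SPECIES_NAMES = {SPECIES_E: "E", SPECIES_R: "R", SPECIES_C: "C"}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}

STATE_U = 0
STATE_M = 1


@dataclass
class ParticleSystem:
    """Positions and species of every diffusing particle.

    ``positions`` has shape ``(n, 2)`` in sigma units, ``species`` holds the
    integer codes above.
    """

    positions: np.ndarray
    species: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.species = np.asarray(self.species, dtype=np.int8).reshape(-1)
        if self.positions.shape[0] != self.species.shape[0]:
            raise ValueError("positions and species lengths differ")

    @classmethod
    def empty(cls) -> "ParticleSystem":
        return cls(np.empty((0, 2)), np.empty(0, dtype=np.int8))

    def __len__(self) -> int:
        return self.species.shape[0]

    def count(self, code: int) -> int:
        return int(np.count_nonzero(self.species == code))

    def of_species(self, code: int) -> np.ndarray:
        """Positions of all particles of one species, shape ``(k, 2)``."""
        return self.positions[self.species == code]

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(self.positions.copy(), self.species.copy())


@dataclass
class LatticeState:
    """Per-nucleosome U/M state plus the geometry it lives on.

    ``states`` is a uint8 array (0 = U, 1 = M).  ``site_positions`` gives each
    nucleosome's spatial coordinate in the disc: ``(i, 0)`` for the linear
    lattice, the bead coordinate for a polymer.  Site *labels* are genomic
    indices centred on the nucleation point: ``i ∈ [-(N-1)/2, (N-1)/2]``.
    """

    states: np.ndarray
    site_positions: np.ndarray
    nucleation_enabled: bool = True
    np_index: int = field(default=-1)  # array index of the nucleation site

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.uint8).reshape(-1)
        self.site_positions = np.asarray(self.site_positions, dtype=float).reshape(-1, 2)
        if self.states.shape[0] != self.site_positions.shape[0]:
            raise ValueError("states and site_positions lengths differ")
        if self.np_index == -1:
            self.np_index = (self.n_sites - 1) // 2
        if self.nucleation_enabled:
            self.states[self.np_index] = STATE_M

    @classmethod
    def linear(cls, n_sites: int, nucleation_enabled: bool = True) -> "LatticeState":
        """All-U linear lattice with sites at ``(i, 0)``, i centred on 0."""
        labels = np.arange(n_sites) - (n_sites - 1) // 2
        pos = np.column_stack([labels.astype(float), np.zeros(n_sites)])
        return cls(np.zeros(n_sites, dtype=np.uint8), pos, nucleation_enabled)

    @property
    def n_sites(self) -> int:
        return self.states.shape[0]

    @property
    def site_labels(self) -> np.ndarray:
        return np.arange(self.n_sites) - (self.n_sites - 1) // 2

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.states.copy(),
            self.site_positions.copy(),
            self.nucleation_enabled,
            self.np_index,
        )
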