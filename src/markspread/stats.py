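"""Summary statistics of simulation output.

The central object is the methylation profile: per-site probability P(M)
estimated over post-burn-in samples (the simulation analogue of a ChIP-seq
enrichment track).  Its width is summarised by

    S_m = ( sum_i i^2 P_i  -  ( sum_i i P_i )^2 )^(1/2)

computed literally on the raw P_i by default — the P_i are *not* normalised
to unit mass, so S_m is a width-like second-moment statistic rather than a
true standard deviation.  A ``normalized=True`` mode (divide by sum P_i
first) is provided for cross-model comparisons; both modes coincide on
unit-mass profiles.  Kurtosis always normalises (it is undefined otherwise)
and is reported in the Pearson convention m4/m2^2, whose trends are
unchanged under the excess convention.

Spatial statistics: the RNA shell density rho_i = N_Ri / (pi (r_{i+1}^2 -
r_i^2)) over concentric shells of uniform width, and the complex-proximity
profile <C^p>: the mean number of C particles within d_prox of each
nucleosome position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Profile",
    "ShellDensity",
    "ProfileMoments",
    "profile_sd",
    "profile_kurtosis",
    "rna_shell_density",
    "complex_proximity_profile",
    "rna_length_scale",
    "fit_quadratic_trend",
    "profile_to_bedgraph",
]


@dataclass
class Profile:
    """Per-site P(M) estimates.

    ``sites`` are genomic labels (contiguous integers, nucleation point at
    0 for the standard setup); ``p`` are the probabilities; ``n_samples``
    how many lattice snapshots the estimate is based on.
    """

    sites: np.ndarray
    p: np.ndarray
    n_samples: int = 0

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int64).reshape(-1)
        self.p = np.asarray(self.p, dtype=float).reshape(-1)
        if self.sites.shape != self.p.shape:
            raise ValueError("sites and p must have equal length")
        if self.sites.size == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(self.sites) != 1):
            raise ValueError("profile sites must be contiguous")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("profile values must lie in [0, 1]")

    @classmethod
    def from_samples(cls, samples: np.ndarray, sites: np.ndarray) -> "Profile":
        """Mean over rows of a (n_samples, n_sites) 0/1 snapshot matrix."""
        samples = np.asarray(samples)
        return cls(sites, samples.mean(axis=0), n_samples=samples.shape[0])

    def symmetrized(self) -> "Profile":
        """Fold the profile about site 0: ``(P_i + P_{-i}) / 2``.

        The spreading model with a central nucleation point is mirror
        symmetric in distribution, so folding is a variance-reduction step
        for width estimates on finite ensembles: it zeroes the ``sum i P_i``
        cross term of S_m exactly, which otherwise fluctuates strongly on
        profiles of total mass > 1.  Requires sites symmetric about 0.
        """
        if self.sites.min() != -self.sites.max():
            raise ValueError("symmetrized() needs a site range symmetric about 0")
        return Profile(self.sites, 0.5 * (self.p + self.p[::-1]), self.n_samples)

    @staticmethod
    def average(profiles: Sequence["Profile"]) -> "Profile":
        """Equal-weight ensemble average of same-support profiles."""
        first = profiles[0]
        for pr in profiles[1:]:
            if not np.array_equal(pr.sites, first.sites):
                raise ValueError("profiles have different site supports")
        return Profile(
            first.sites,
            np.mean([pr.p for pr in profiles], axis=0),
            n_samples=sum(pr.n_samples for pr in profiles),
        )

    def moments(self) -> "ProfileMoments":
        return ProfileMoments(
            s_m=profile_sd(self),
            kurtosis=profile_kurtosis(self),
            mean_position=float(
                (self.sites * self.p).sum() / self.p.sum()
            ),
        )


@dataclass
class ShellDensity:
    """RNA number density over concentric shells of uniform width ``dr``."""

    edges: np.ndarray  # shell boundaries, length n_shells + 1
    counts: np.ndarray  # particles (or mean particles) per shell
    densities: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        areas = math.pi * (self.edges[1:] ** 2 - self.edges[:-1] ** 2)
        dens = self.counts / areas
        if self.densities is None:
            self.densities = dens
        else:
            self.densities = np.asarray(self.densities, dtype=float)
            if not np.allclose(self.densities, dens):
                raise ValueError("densities inconsistent with counts and shell areas")

    @property
    def shell_mid(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class ProfileMoments:
    s_m: float
    kurtosis: float
    mean_position: float

    def __post_init__(self):
        if self.s_m < 0:
            raise ValueError("S_m must be >= 0")


def profile_sd(profile: Profile, normalized: bool = False) -> float:
    """Profile width S_m (see module docstring).

    In literal mode the radicand ``sum i^2 P - (sum i P)^2`` can go negative
    for off-centre profiles of total mass > 1; that is a hard error rather
    than a NaN, and the normalized mode is the appropriate statistic there.
    """
    i = profile.sites.astype(float)
    p = profile.p
    if normalized:
        mass = p.sum()
        if mass <= 0:
            raise ValueError("cannot normalise an all-zero profile")
        p = p / mass
    radicand = float((i * i * p).sum() - (i * p).sum() ** 2)
    if radicand < 0:
        if radicand > -1e-12:  # numerical jitter on unit-mass profiles
            return 0.0
        raise ValueError(
            f"S_m radicand is negative ({radicand:.4g}): the literal (unnormalised) "
            "form is not meaningful for this profile; use normalized=True"
        )
    return math.sqrt(radicand)


def profile_kurtosis(profile: Profile) -> float:
    """Pearson kurtosis m4/m2^2 of the site index under normalised weights."""
    mass = profile.p.sum()
    if mass <= 0:
        raise ValueError("cannot normalise an all-zero profile")
    w = profile.p / mass
    i = profile.sites.astype(float)
    mu = float((i * w).sum())
    m2 = float(((i - mu) ** 2 * w).sum())
    if m2 <= 0:
        raise ValueError("kurtosis undefined: profile has zero variance")
    m4 = float(((i - mu) ** 4 * w).sum())
    return m4 / m2**2


def rna_shell_density(
    positions: np.ndarray, dr: float, r_max: float
) -> ShellDensity:
    """Bin particle radial distances into shells ``[r_i, r_i + dr)``.

    Particles beyond ``r_max`` are ignored.
    """
    if dr <= 0:
        raise ConfigurationError(f"shell width dr must be > 0, got {dr}")
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    n_shells = int(math.ceil(r_max / dr))
    edges = dr * np.arange(n_shells + 1)
    rho = np.hypot(positions[:, 0], positions[:, 1]) if positions.size else np.empty(0)
    counts, _ = np.histogram(rho, bins=edges)
    return ShellDensity(edges, counts.astype(float))


def complex_proximity_profile(
    c_positions_per_sample: Iterable[np.ndarray],
    site_positions: np.ndarray,
    d_prox: float,
) -> np.ndarray:
    """<C^p>: mean number of C particles within ``d_prox`` of each site.

    ``c_positions_per_sample`` yields one ``(k, 2)`` array of complex
    positions per recorded sample.
    """
    site_positions = np.asarray(site_positions, dtype=float).reshape(-1, 2)
    total = np.zeros(site_positions.shape[0])
    n = 0
    d2 = d_prox * d_prox
    for c_pos in c_positions_per_sample:
        c_pos = np.asarray(c_pos, dtype=float).reshape(-1, 2)
        n += 1
        if c_pos.shape[0] == 0:
            continue
        d = site_positions[:, None, :] - c_pos[None, :, :]
        total += ((d**2).sum(axis=2) <= d2).sum(axis=1)
    if n == 0:
        raise ValueError("no samples supplied")
    return total / n


def rna_length_scale(d_tilde_r: float, p_rd: float) -> float:
    """Diffusion-decay length l_r = sqrt(D_r / P_rd) in sigma units.

    The scale beyond which RNA is essentially absent: a particle decaying at
    per-step probability P_rd diffuses a root-mean-square distance of this
    order during its lifetime.  ``p_rd = 0`` returns ``inf``.
    """
    if d_tilde_r < 0:
        raise ConfigurationError(f"d_tilde_r must be >= 0, got {d_tilde_r}")
    if p_rd < 0:
        raise ConfigurationError(f"P_rd must be >= 0, got {p_rd}")
    if p_rd == 0:
        return math.inf
    return math.sqrt(d_tilde_r / p_rd)


def fit_quadratic_trend(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Least-squares fit of ``y = a x^2 + b x + c``; returns ``(a, b, c)``.

    Used for the profile-width-versus-enzyme-concentration trend.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 (x, y) points")
    if np.unique(x).size < 3:
        raise ValueError("degenerate design: need >= 3 distinct x values")
    coeffs = np.polynomial.polynomial.polyfit(x, y, 2)  # c, b, a
    c, b, a = (float(v) for v in coeffs)
    return a, b, c


def profile_to_bedgraph(
    profile: Profile,
    path,
    chrom: str = "chrSim",
    bin_size: int = 200,
) -> None:
    """Export a profile as a bedGraph track for genome-browser viewing.

    Site ``i`` maps to the half-open 0-based interval
    ``[(i + offset) * bin_size, (i + offset + 1) * bin_size)`` where the
    offset shifts the most negative site to coordinate 0.
    """
    offset = -int(profile.sites.min())
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{chrom}_PM"\n')
        for i, p in zip(profile.sites, profile.p):
            start = (int(i) + offset) * bin_size
            fh.write(f"{chrom}\t{start}\t{start + bin_size}\t{p:.6g}\n")
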