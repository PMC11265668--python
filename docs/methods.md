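# Methods

## The model

`markspread` simulates the establishment of a repressive histone-mark domain
(the H3K9me3 paradigm: nucleation at a specific locus, spreading by
reader–writer enzymes localised through the RNAi pathway) as a particle-based
reaction–diffusion (RD) process, and contrasts it with the purely kinetic
picture in which spreading is a contact process along the nucleosome chain.

The chromatin fragment is a lattice of `N_n` nucleosomes, each Unmodified (U)
or Modified (M), embedded in a 2D disc of radius `r` (all lengths in units of
the particle diameter sigma; the lattice spacing is 1 sigma, site `i = 0` is
the nucleation point, NP).  Three particle species diffuse in the disc by
overdamped Langevin dynamics with reflecting walls:

* **R** — RNA-like particles (coarse-grained RITS components), produced only
  at the NP with per-step probability `P_rp` and decaying anywhere with
  `P_rd`;
* **E** — enzymes, `N_e` of them, uniformly seeded and conserved;
* **C** — enzyme–RNA complexes, formed at probability `P_cp` when an E and an
  R come within the proximity radius `d_prox`, decaying back to E with
  `P_cd`.

A U nucleosome can gain the mark only while a C is within `d_prox` of its
position; the per-step probability is `min(1, P_w + P_m * 1[any neighbour M])`
(`P_w` = pure writer pathway, zero except in the no-nucleation study;
`P_m` = reader–writer pathway).  Marks are lost with `P_dm` per step, the NP
excepted while nucleation is enabled.  Each timestep applies, in a fixed
order: diffusion, R decay, R production, C formation, C decay, a synchronous
methylation sweep, demethylation, NP re-assertion.  Decay precedes production
so one particle cannot be born and die in a single step; reactions follow
movement.

The kinetic comparator (`kmc`) is a Gillespie-simulated contact process on
the same lattice: a U site with `m` modified neighbours gains the mark at
rate `m*k+`, any M site except the pinned NP loses it at rate `k-`; the only
control parameter is `K = k+/k-`.  A space-dependent variant
`k+(i) = k0*exp(-|i|/l_d)` phenomenologically mimics the catalyst cloud's
diffusive length scale; `l_d = inf` recovers the basic model exactly (same
seed, event for event).  For lattices of up to 13 sites the continuous-time
Markov chain is solved exactly (`master_equation_profile`), which serves as
the independent oracle for the sampler.

## Parameters, units, defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `N_n` | nucleosomes | 61 | standard lattice, labels −30..30 |
| `r` | disc radius (sigma) | 40 | fits the lattice with margin; enzyme concentration `N_e/(pi r^2)` ≈ 0.1 |
| `N_e` | enzymes | 500 | baseline of the enzyme-limitation study |
| `D_tilde` | per-step diffusion constant | 2e-4 | a 5–10 nm particle at ~1e-3 um^2/s on the model timestep; all species share it |
| `P_rp` | RNA production | 1e-3 | RNA density is insensitive to it over 1e-4..1e-3 |
| `P_rd` | RNA decay | 1e-3 | sets the RNA length scale `l_r = sqrt(D/P_rd)` ≈ 0.45 sigma |
| `P_cp` | complex formation | 1 | diffusion-limited formation |
| `P_cd` | complex decay | 1e-6 | slow catalyst turnover; the widest-spreading baseline |
| `P_w`, `P_m` | writer / reader-writer | 0, 1 | reader–writer regime; `P_w > 0` only in the no-NP study |
| `P_dm` | demethylation | 1e-3 | competition regime where R/C kinetics shape the profile |
| `d_prox` | proximity radius (sigma) | 1.0 | one particle diameter, used for both E–R and C–nucleosome contact |
| `n_steps`, `burn_in`, `sample_interval` | run schedule | 2e5 / 1e5 / 500 | see below |

The physical constants (mobility, kT, timestep) enter only through
`D_tilde`; there is no separate clock.

## Run lengths and what "steady state" means here

With `P_cd = 1e-6` the complex population never equilibrates on any
tractable horizon (its lifetime is 1e6 steps), so profiles in this regime
are finite-time ensemble statistics, not true stationary distributions.  The
default schedule — 2e5 steps, half discarded as burn-in, 200 retained
snapshots — was chosen once as the package's study condition: long enough
that the mark dynamics (lifetime `1/P_dm` = 1e3 steps) are well mixed and
the catalyst cloud has developed, short enough that parameter sweeps remain
interactive.  Trend studies (e.g. profile width versus `P_rd`) use 3e5
steps and several seeds.  The same caveat evidently applies to any
simulation of this model; reported widths grow slowly with run length in
the `P_cd -> 0` regime, but the orderings the package tests are insensitive
to the horizon.

## Statistics

The methylation profile is the per-site mean of the retained snapshots.  Its
width statistic

    S_m = ( sum_i i^2 P_i - (sum_i i P_i)^2 )^(1/2)

is computed literally on the raw `P_i` (no normalisation to unit mass) by
default; since the total mass typically exceeds 1, the cross term makes the
literal form meaningful only for profiles centred on the NP.  Two mitigations
are provided and used throughout the trend analyses: ensemble averaging over
seeds, and `Profile.symmetrized()`, which folds the profile about the NP.
Folding is exact variance reduction — the model with a central NP is mirror
symmetric in distribution, and folding zeroes the fluctuating cross term —
and on symmetric profiles it changes nothing.  A `normalized=True` mode
(divide by total mass) exists for cross-model comparisons; kurtosis always
normalises (Pearson convention `m4/m2^2`; trends are unchanged under the
excess convention).

Spatial statistics: RNA shell density `rho_i = N_i / (pi (r_{i+1}^2 -
r_i^2))` over 1-sigma shells, and the complex proximity profile `<C^p>`, the
mean number of C within `d_prox` of each nucleosome position.  The RNA
length scale is reported as `l_r = sqrt(D_r/P_rd)`, the dimensionally
consistent diffusion–decay length.  The width-versus-enzyme-concentration
trend is summarised by a least-squares quadratic, as is conventional for
this system.

## Polymer variant

Folded chromatin is represented by frozen square-lattice polymers with one
bead per nucleosome and unit bonds: self-avoiding walks (pivot algorithm:
rod start, random lattice-symmetry pivots, self-avoiding proposals accepted,
>= 10 n accepted pivots discarded as burn-in) for open chromatin and plain
random walks for compact chromatin.  Contact adjacency joins backbone
neighbours plus all bead pairs within `contact_cutoff` (default 1.5 sigma:
includes diagonal and coincident contacts, excludes the next-nearest lattice
shell at distance 2).  The nucleation bead is the central bead, translated
to the origin, so genomic coordinates match the linear lattice; for that
reason ensemble spreading runs use an odd bead count (101) while the
generators themselves accept any length.  Configurations are frozen for the
whole run — valid when spreading is faster than polymer relaxation — and
ensemble runs redraw the rare configuration whose beads would leave the
disc (the ensemble thus conditions on fitting the simulation region).  A
straight rod reduces the polymer machinery to the linear lattice exactly,
bit for bit at equal seed, which is tested.

## Numerical and implementation choices

* **Reflection**: radial mirroring `rho -> 2r - rho` at fixed angle, applied
  iteratively.  With the default step size (~0.02 sigma, against `r = 40`)
  this is the standard small-step approximation to reflected Brownian
  motion; any small-step-consistent scheme gives indistinguishable profiles.
* **Synchronous sweeps**: all methylation draws are evaluated against the
  pre-sweep lattice, so a mark cannot hop two sites in one step and sweep
  order cannot introduce artefacts.
* **Pair matching**: R particles are visited in index order; each reacts
  with its nearest free E within `d_prox`; one reaction per particle per
  step.  The C inherits the E position (the enzyme is the persistent
  entity); the bound R is destroyed on complex decay, matching `C -> E`.
* **Multiple proximal complexes do not add** — the methylation gate is a
  binary indicator, as is the neighbour-state boost.
* **Propensity convention (KMC)**: spreading propensity is additive over
  modified neighbours (`m * k+`), the standard contact-process convention; a
  binary mode is available as a sensitivity flag.
* **RNG**: each RD run consumes a single seeded PCG64 stream (initial
  placement, then Gaussian and uniform draws in fixed sub-step order),
  making runs bit-reproducible from the seed; the Gillespie sampler uses its
  own seeded stream.  RNA production is capped at `rna_cap` (default 1e5)
  with a warning, since the R population is the only unbounded count.
* **Degenerate inputs**: an all-zero profile has no kurtosis (explicit
  error), a negative S_m radicand is a loud failure rather than a NaN, and
  `P_rd = 0` yields an infinite RNA length scale sentinel.

## What the simulator does and does not emulate

The model captures catalyst diffusion, finite enzyme pools, RNA-mediated
localisation and neighbour-limited spreading.  It deliberately omits:
hydrodynamics and excluded volume between particles, 3D geometry (the disc
is 2D), multiple methylation states (me1/me2), acetylation competition,
nucleosome turnover, polymer relaxation during spreading, and liquid–liquid
phase separation of the constituents.  Passing trend tests therefore shows
that the implemented mechanism produces the expected orderings under the
stated conditions — not that real chromatin is quantitatively described;
in particular, comparison against experimental ChIP-seq tracks is out of
scope (only a bedGraph export is provided for browser viewing).

## Known limitations

* In the slow-complex-decay regime the profile is a finite-horizon
  statistic (above); widths from different run lengths are not comparable.
* The literal S_m is undefined (negative radicand) for strongly off-centre
  profiles of mass > 1; use the normalized mode or fold first.
* The pivot sampler's short burn-in (10 n accepted pivots from a rod) is
  adequate for the moment statistics tested here, but tail-sensitive
  observables may need longer chains.
* With `N_e = 0` and `P_rp > 0` the R population still evolves; the profile
  stays trivial but runtime is not zero.
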