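# markspread

Stochastic simulators of histone-modification spreading for quantitative
chromatin biology: a particle-based **reaction–diffusion (RD) model** in
which diffusing enzymes, RNAs and enzyme–RNA complexes react with a
nucleosome lattice, a **reaction-only Gillespie comparator** (a nucleation-
pinned contact process), **frozen-polymer variants** for folded chromatin,
and the statistics used to tell the two mechanisms apart.

## The problem

Repressive marks such as H3K9me3 nucleate at specific loci and spread to
neighbouring nucleosomes, yet remain confined to domains of finite size.
Classical models treat spreading as a purely kinetic contact process with a
spreading rate `k+` and removal rate `k-` (`K = k+/k-`).  `markspread`
instead simulates the constituents explicitly: RNA-like particles (R) are
produced at the nucleation point with probability `P_rp` per step and decay
with `P_rd`; they diffuse (Langevin dynamics, reflecting disc of radius
`r`), convert enzymes (E, `N_e` of them) into catalytically competent
complexes (C) on contact, and a U nucleosome near a C becomes modified with
probability

    P_eff = min(1, P_w + P_m * 1[a neighbour is modified]),

while any modified nucleosome relaxes with `P_dm`.  Diffusion and decay of
the catalysts set a natural length scale `l_r = sqrt(D/P_rd)` that limits
the domain, and enzyme limitation emerges from the finite pool rather than
from a rate-law correction.  Profile width is summarised by

    S_m = ( sum_i i^2 P_i - (sum_i i P_i)^2 )^(1/2)

with `P_i` the per-site modification probability, and profile shape by the
Pearson kurtosis; in the (S_m, kurtosis) plane RD profiles separate from
contact-process profiles of equal width.

## Worked example

```python
import numpy as np
from markspread import (RDParams, run_rd_simulation, profile_sd,
                        KMCParams, gillespie_run)

# reaction-diffusion run: 61 nucleosomes, 500 enzymes in a 40-sigma disc
res = run_rd_simulation(RDParams(p_rd=1e-3, p_dm=1e-2, seed=1))
prof = res.profile.symmetrized()
print("RD   S_m =", round(profile_sd(prof), 2))

# contact-process comparator at K = 0.9
kprof, _ = gillespie_run(KMCParams.from_K(0.9, n_events=1_000_000, seed=1))
print("KMC  S_m =", round(profile_sd(kprof.symmetrized()), 2))
print("complexes at end of RD run:", res.species_counts[-1, 2])
```

prints

```
RD   S_m = 1.67
KMC  S_m = 6.41
complexes at end of RD run: 13
```

i.e. with fast mark turnover (`P_dm = 1e-2`) the RD profile is much
narrower than a `K = 0.9` contact process, and only ~13 of the 500 enzymes
are complexed at any time — the catalyst pool, not the lattice kinetics,
confines the domain.  The same API drives polymer ensembles
(`run_polymer_ensemble`) and the exact small-lattice master-equation oracle
(`master_equation_profile`).

A command-line front end mirrors the library:

```sh
markspread simulate-rd  --p-rd 1e-4 --seed 3 --out runs/rd
markspread simulate-kmc --K 1.3 --out runs/kmc
markspread sweep --param1 p_rd 1e-5,1e-4,1e-3 --param2 p_cd 1e-6,1e-4,1e-2 --out runs/phase
markspread analyze runs/rd
```

Every run directory contains TSV tables plus a `metadata.json` sidecar
(full parameter echo, seed, schema version) from which it can be reproduced
byte for byte.

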