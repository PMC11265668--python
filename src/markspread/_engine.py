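"""Compiled inner loops for the reaction-diffusion run and the Gillespie run.

The RD kernel implements exactly the sub-step sequence documented in
:mod:`markspread.core` (diffuse -> R-decay -> R-production -> C-formation ->
C-decay -> methylation -> demethylation -> nucleation re-assert).  All
randomness is consumed, in that fixed sub-step order, from Gaussian and
uniform buffers pre-filled by a single seeded numpy generator, so a run is
bit-reproducible from its seed.  The kernel is resumable: it processes
timesteps until the buffers cannot cover another step's worst case, then
returns so the driver can refill them.

The pure-numpy operations in ``diffusion``/``reactions``/``chromatin``
define the same dynamics one sub-step at a time and are cross-validated
against these loops statistically in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# state_i slots
_STEP = 0
_NRNA = 1
_SI = 2
_OVERFLOW = 3
# state_f slots
_MAXR2 = 0


@njit(cache=True, inline="always")
def _reflect(x, y, r):
    rr = x * x + y * y
    while rr > r * r:
        rho = math.sqrt(rr)
        scale = (2.0 * r - rho) / rho  # negative -> through the origin
        x *= scale
        y *= scale
        rr = x * x + y * y
    return x, y


@njit(cache=True)
def rd_chunk(
    n_steps,
    burn_in,
    sample_interval,
    step_sd,
    radius,
    p_rp,
    p_rd,
    p_cp,
    p_cd,
    p_w,
    p_m,
    p_dm,
    d_prox,
    nucleation,
    site_pos,
    nbr_indptr,
    nbr_indices,
    np_index,
    rna_cap,
    shell_dr,
    ex,
    ey,
    is_c,
    rx,
    ry,
    rdead,
    lattice,
    old,
    c_list,
    samples,
    species_counts,
    cprox_sum,
    shell_sum,
    state_i,
    state_f,
    nbuf,
    ubuf,
):
    n_e = ex.shape[0]
    n_sites = site_pos.shape[0]
    n_shells = shell_sum.shape[0]
    n_samples = samples.shape[0]
    d2 = d_prox * d_prox
    ox = site_pos[np_index, 0]
    oy = site_pos[np_index, 1]

    step = state_i[_STEP]
    n_rna = state_i[_NRNA]
    si = state_i[_SI]
    max_r2 = state_f[_MAXR2]

    nptr = 0
    uptr = 0
    u_decay = n_e if p_cd > 0.0 else 0

    while step < n_steps:
        need_n = 2 * (n_e + n_rna)
        # decay (n_rna) + production (1) + formation (n_rna + 1, counting a
        # same-step birth) + complex decay + two lattice sweeps
        need_u = 2 * n_rna + 3 + u_decay + 2 * n_sites
        if nptr + need_n > nbuf.shape[0] or uptr + need_u > ubuf.shape[0]:
            break
        step += 1

        # (1) diffuse all particles, reflecting into the disc
        for k in range(n_e):
            x = ex[k] + step_sd * nbuf[nptr + 2 * k]
            y = ey[k] + step_sd * nbuf[nptr + 2 * k + 1]
            x, y = _reflect(x, y, radius)
            ex[k] = x
            ey[k] = y
            rr = x * x + y * y
            if rr > max_r2:
                max_r2 = rr
        nptr += 2 * n_e
        for k in range(n_rna):
            x = rx[k] + step_sd * nbuf[nptr + 2 * k]
            y = ry[k] + step_sd * nbuf[nptr + 2 * k + 1]
            x, y = _reflect(x, y, radius)
            rx[k] = x
            ry[k] = y
            rr = x * x + y * y
            if rr > max_r2:
                max_r2 = rr
        nptr += 2 * n_rna

        # (2) RNA decay
        if n_rna > 0 and p_rd > 0.0:
            k = 0
            while k < n_rna:
                u = ubuf[uptr]
                uptr += 1
                if u < p_rd:
                    n_rna -= 1
                    rx[k] = rx[n_rna]
                    ry[k] = ry[n_rna]
                else:
                    k += 1

        # (3) RNA production at the nucleation site's spatial position
        u = ubuf[uptr]
        uptr += 1
        if u < p_rp:
            if n_rna < rna_cap:
                rx[n_rna] = ox
                ry[n_rna] = oy
                n_rna += 1
            else:
                state_i[_OVERFLOW] = 1

        # (4) complex formation: each R, in index order, reacts with its
        # nearest free E within d_prox; at most one reaction per particle
        if n_rna > 0 and p_cp > 0.0:
            for k in range(n_rna):
                best = -1
                bestd = 0.0
                xr = rx[k]
                yr = ry[k]
                for e in range(n_e):
                    if is_c[e]:
                        continue
                    dx = ex[e] - xr
                    if dx > d_prox or dx < -d_prox:
                        continue
                    dy = ey[e] - yr
                    dd = dx * dx + dy * dy
                    if dd <= d2 and (best < 0 or dd < bestd):
                        best = e
                        bestd = dd
                if best >= 0:
                    ok = True
                    if p_cp < 1.0:
                        u = ubuf[uptr]
                        uptr += 1
                        ok = u < p_cp
                    if ok:
                        is_c[best] = 1
                        rdead[k] = 1
            m = 0
            for k in range(n_rna):
                if rdead[k] == 0:
                    rx[m] = rx[k]
                    ry[m] = ry[k]
                    m += 1
                rdead[k] = 0
            n_rna = m

        # (5) complex decay C -> E
        if p_cd > 0.0:
            for e in range(n_e):
                if is_c[e]:
                    u = ubuf[uptr]
                    uptr += 1
                    if u < p_cd:
                        is_c[e] = 0

        # (6) synchronous methylation sweep
        nc = 0
        for e in range(n_e):
            if is_c[e]:
                c_list[nc] = e
                nc += 1
        if nc > 0:
            for s in range(n_sites):
                old[s] = lattice[s]
            for s in range(n_sites):
                if old[s] != 0:
                    continue
                sx = site_pos[s, 0]
                sy = site_pos[s, 1]
                prox = False
                for q in range(nc):
                    e = c_list[q]
                    dx = ex[e] - sx
                    if dx > d_prox or dx < -d_prox:
                        continue
                    dy = ey[e] - sy
                    if dx * dx + dy * dy <= d2:
                        prox = True
                        break
                if not prox:
                    continue
                nbr_m = False
                for q in range(nbr_indptr[s], nbr_indptr[s + 1]):
                    if old[nbr_indices[q]] == 1:
                        nbr_m = True
                        break
                p_eff = p_w + (p_m if nbr_m else 0.0)
                if p_eff > 1.0:
                    p_eff = 1.0
                if p_eff > 0.0:
                    u = ubuf[uptr]
                    uptr += 1
                    if u < p_eff:
                        lattice[s] = 1

        # (7) demethylation (nucleation site exempt while enabled)
        if p_dm > 0.0:
            for s in range(n_sites):
                if lattice[s] == 1:
                    if nucleation and s == np_index:
                        continue
                    u = ubuf[uptr]
                    uptr += 1
                    if u < p_dm:
                        lattice[s] = 0

        # (8) nucleation-point re-assertion
        if nucleation:
            lattice[np_index] = 1

        # sampling
        if step > burn_in and (step - burn_in) % sample_interval == 0 and si < n_samples:
            for s in range(n_sites):
                samples[si, s] = lattice[s]
            species_counts[si, 0] = n_e - nc
            species_counts[si, 1] = n_rna
            species_counts[si, 2] = nc
            for s in range(n_sites):
                cnt = 0
                sx = site_pos[s, 0]
                sy = site_pos[s, 1]
                for q in range(nc):
                    e = c_list[q]
                    dx = ex[e] - sx
                    dy = ey[e] - sy
                    if dx * dx + dy * dy <= d2:
                        cnt += 1
                cprox_sum[s] += cnt
            for k in range(n_rna):
                sh = int(math.sqrt(rx[k] * rx[k] + ry[k] * ry[k]) / shell_dr)
                if sh < n_shells:
                    shell_sum[sh] += 1.0
            si += 1

    state_i[_STEP] = step
    state_i[_NRNA] = n_rna
    state_i[_SI] = si
    state_f[_MAXR2] = max_r2


def sample_uniform_disc(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform points on the disc by vectorised rejection from the square."""
    out = np.empty((n, 2))
    have = 0
    while have < n:
        cand = radius * (2.0 * rng.random((max(2 * (n - have), 16), 2)) - 1.0)
        good = cand[(cand**2).sum(axis=1) <= radius * radius]
        take = min(n - have, good.shape[0])
        out[have : have + take] = good[:take]
        have += take
    return out


def run_rd(
    seed,
    n_steps,
    burn_in,
    sample_interval,
    d_tilde,
    radius,
    p_rp,
    p_rd,
    p_cp,
    p_cd,
    p_w,
    p_m,
    p_dm,
    d_prox,
    nucleation,
    site_pos,
    nbr_indptr,
    nbr_indices,
    np_index,
    n_e,
    rna_cap,
    shell_dr,
):
    """Driver: allocate state, feed the kernel with refilled RNG buffers."""
    rng = np.random.Generator(np.random.PCG64(seed))
    n_sites = site_pos.shape[0]
    n_shells = int(np.ceil(radius / shell_dr))
    n_samples = (n_steps - burn_in) // sample_interval if n_steps > burn_in else 0

    init = sample_uniform_disc(n_e, radius, rng)
    ex = np.ascontiguousarray(init[:, 0])
    ey = np.ascontiguousarray(init[:, 1])
    is_c = np.zeros(n_e, np.uint8)
    rx = np.empty(rna_cap)
    ry = np.empty(rna_cap)
    rdead = np.zeros(rna_cap, np.uint8)
    lattice = np.zeros(n_sites, np.uint8)
    if nucleation:
        lattice[np_index] = 1
    old = np.zeros(n_sites, np.uint8)
    c_list = np.empty(max(n_e, 1), np.int64)

    samples = np.zeros((n_samples, n_sites), np.uint8)
    species_counts = np.zeros((n_samples, 3), np.int64)
    cprox_sum = np.zeros(n_sites)
    shell_sum = np.zeros(n_shells)
    state_i = np.zeros(4, np.int64)
    state_f = np.zeros(1)
    step_sd = math.sqrt(2.0 * d_tilde)
    u_decay = n_e if p_cd > 0.0 else 0

    chunk = 4096
    while state_i[_STEP] < n_steps:
        k = min(chunk, n_steps - state_i[_STEP])
        n_rna = int(state_i[_NRNA])
        slack = 64
        nbuf = rng.standard_normal(int(k * 2 * (n_e + n_rna + slack)))
        ubuf = rng.random(
            int(k * (2 * (n_rna + slack) + 1 + u_decay + 2 * n_sites))
        )
        before = state_i[_STEP]
        rd_chunk(
            n_steps,
            burn_in,
            sample_interval,
            step_sd,
            radius,
            p_rp,
            p_rd,
            p_cp,
            p_cd,
            p_w,
            p_m,
            p_dm,
            d_prox,
            nucleation,
            site_pos,
            nbr_indptr,
            nbr_indices,
            np_index,
            rna_cap,
            shell_dr,
            ex,
            ey,
            is_c,
            rx,
            ry,
            rdead,
            lattice,
            old,
            c_list,
            samples,
            species_counts,
            cprox_sum,
            shell_sum,
            state_i,
            state_f,
            nbuf,
            ubuf,
        )
        if state_i[_STEP] == before:  # RNA grew faster than the slack allowed
            chunk = max(chunk // 4, 16)

    n_rna = int(state_i[_NRNA])
    return (
        samples,
        species_counts,
        cprox_sum,
        shell_sum,
        ex,
        ey,
        is_c,
        rx[:n_rna].copy(),
        ry[:n_rna].copy(),
        math.sqrt(state_f[_MAXR2]),
        bool(state_i[_OVERFLOW]),
    )


@njit(cache=True)
def gillespie_kernel(
    seed,
    n_sites,
    np_index,
    kplus_site,
    k_minus,
    additive,
    n_events,
    burn_in_events,
):
    """Reaction-only contact process pinned M at the nucleation site.

    Event set: a U site j with m modified neighbours gains the mark at rate
    m * k_plus(j) (or k_plus(j) if any neighbour is modified, in binary
    mode); an M site j != NP loses it at rate k_minus.  Returns the
    time-weighted per-site P(M) accumulated after ``burn_in_events`` events,
    plus the number of events actually executed.
    """
    np.random.seed(seed)
    state = np.zeros(n_sites, np.uint8)
    state[np_index] = 1
    t_m = np.zeros(n_sites)
    total_t = 0.0
    rates = np.empty(n_sites)
    ev = 0
    while ev < n_events:
        total = 0.0
        for j in range(n_sites):
            rj = 0.0
            if state[j] == 0:
                m = 0
                if j > 0 and state[j - 1] == 1:
                    m += 1
                if j < n_sites - 1 and state[j + 1] == 1:
                    m += 1
                if additive:
                    rj = m * kplus_site[j]
                elif m > 0:
                    rj = kplus_site[j]
            elif j != np_index:
                rj = k_minus
            rates[j] = rj
            total += rj
        if total <= 0.0:
            # absorbing configuration (e.g. k_plus = 0 after all marks are
            # lost): the chain stays here forever, so the stationary profile
            # is the current state
            for j in range(n_sites):
                t_m[j] = float(state[j])
            total_t = 1.0
            break
        dt = -np.log(1.0 - np.random.random()) / total
        if ev >= burn_in_events:
            total_t += dt
            for j in range(n_sites):
                if state[j] == 1:
                    t_m[j] += dt
        u = np.random.random() * total
        acc = 0.0
        chosen = n_sites - 1
        for j in range(n_sites):
            acc += rates[j]
            if u < acc:
                chosen = j
                break
        state[chosen] = 1 - state[chosen]
        ev += 1
    if total_t <= 0.0:
        total_t = 1.0
    return t_m / total_t, ev
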