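"""Compiled inner loops for the Brownian-dynamics photon generators.

Both kernels integrate free 3-D diffusion of pointlike emitters through a
periodic box with an Euler-Maruyama step, modulate the photon rate by a
3-D Gaussian detection profile, and thin photon emission within each
macro-step assuming the rate is constant across the step.  Photon times are
emitted in step order and are sorted globally by the callers.

Units inside the kernels: lengths in um, times in seconds, rates in Hz.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _wrap(x, half_box):
    if x > half_box:
        return x - 2.0 * half_box
    if x < -half_box:
        return x + 2.0 * half_box
    return x


@njit(cache=True, fastmath=True)
def diffusion_photons(seed, n_steps, dt, n_mol, d_um2_s, half_box_um,
                      omega_um, s_ell, brightness_cps, k_onoff, k_offon,
                      out_times):
    """Photon arrival times from diffusing emitters with telegraph blinking.

    ``k_onoff[p]`` / ``k_offon[p]`` are the bright->dark and dark->bright
    rates (1/s) of independent two-state blink process ``p``; emission is
    gated off while any process is dark.  Returns the number of photons
    written to ``out_times`` or -1 on overflow.
    """
    np.random.seed(seed)
    n_proc = k_onoff.shape[0]
    step_sd = np.sqrt(2.0 * d_um2_s * dt)

    pos = np.empty((n_mol, 3))
    for i in range(n_mol):
        for ax in range(3):
            pos[i, ax] = (np.random.random() * 2.0 - 1.0) * half_box_um

    # blink states start from telegraph equilibrium
    dark = np.zeros((n_mol, n_proc), dtype=np.uint8)
    p_to_dark = np.empty(n_proc)
    p_to_bright = np.empty(n_proc)
    for p in range(n_proc):
        k_eq = k_onoff[p] / (k_onoff[p] + k_offon[p])
        for i in range(n_mol):
            if np.random.random() < k_eq:
                dark[i, p] = 1
        p_to_dark[p] = 1.0 - np.exp(-k_onoff[p] * dt)
        p_to_bright[p] = 1.0 - np.exp(-k_offon[p] * dt)

    inv_w2 = 2.0 / (omega_um * omega_um)
    inv_wz2 = 2.0 / (s_ell * omega_um * s_ell * omega_um)
    cnt = 0
    max_out = out_times.shape[0]
    for step in range(n_steps):
        t0 = step * dt
        for i in range(n_mol):
            for ax in range(3):
                pos[i, ax] = _wrap(pos[i, ax] + np.random.normal() * step_sd,
                                   half_box_um)
            bright = True
            for p in range(n_proc):
                if dark[i, p] == 1:
                    if np.random.random() < p_to_bright[p]:
                        dark[i, p] = 0
                    else:
                        bright = False
                else:
                    if np.random.random() < p_to_dark[p]:
                        dark[i, p] = 1
                        bright = False
            if not bright:
                continue
            w = np.exp(-(pos[i, 0] ** 2 + pos[i, 1] ** 2) * inv_w2
                       - pos[i, 2] ** 2 * inv_wz2)
            mean = brightness_cps * w * dt
            if mean < 1e-9:
                continue
            n_ph = np.random.poisson(mean)
            for _ in range(n_ph):
                if cnt >= max_out:
                    return -1
                out_times[cnt] = t0 + np.random.random() * dt
                cnt += 1
    return cnt


# Photon stream codes emitted by the ALEX kernel
CODE_DD = 0   # donor emission after donor excitation
CODE_DA = 1   # acceptor-channel photon after donor excitation (FRET+leak+direct)
CODE_AA = 2   # acceptor emission after acceptor excitation

# Molecule species
SP_DUAL = 0
SP_DONOR_ONLY = 1
SP_ACCEPTOR_ONLY = 2


@njit(cache=True, fastmath=True)
def alex_burst_photons(seed, n_steps, dt, n_mol, d_um2_s, half_box_um,
                       omega_um, s_ell, steps_per_half,
                       b_donor_cps, b_acceptor_cps,
                       e_states, occupancies, dwell_s,
                       gamma_true, leakage, direct_exc, bleach_rate,
                       frac_donor_only, frac_acceptor_only,
                       out_times, out_code, out_e, out_mol, out_bleach):
    """ALEX two-color photon generation for diffusing FRET-labeled molecules.

    Donor-excitation photons split between donor and acceptor channels
    according to the molecule's current FRET state E and gamma_true;
    spectral leakage and acceptor direct excitation add acceptor-channel
    photons at rates leakage*r_DD and direct_exc*r_AA.  Conformational
    states switch as a continuous-time chain with exponential dwell times.
    Acceptor photobleaching is a hazard proportional to illumination; a
    bleached molecule regains a fresh acceptor once it has drifted far from
    the focus (emulating exchange with the reservoir).

    Returns (n_photons, n_bleach_events); n_photons = -1 on overflow.
    """
    np.random.seed(seed)
    n_states = e_states.shape[0]
    step_sd = np.sqrt(2.0 * d_um2_s * dt)
    steps_per_cycle = 2 * steps_per_half

    pos = np.empty((n_mol, 3))
    species = np.empty(n_mol, dtype=np.uint8)
    state = np.empty(n_mol, dtype=np.int64)
    alive = np.ones(n_mol, dtype=np.uint8)
    for i in range(n_mol):
        for ax in range(3):
            pos[i, ax] = (np.random.random() * 2.0 - 1.0) * half_box_um
        u = np.random.random()
        if u < frac_donor_only:
            species[i] = SP_DONOR_ONLY
        elif u < frac_donor_only + frac_acceptor_only:
            species[i] = SP_ACCEPTOR_ONLY
        else:
            species[i] = SP_DUAL
        # initial conformational state by occupancy
        u = np.random.random()
        acc = 0.0
        state[i] = n_states - 1
        for k in range(n_states):
            acc += occupancies[k]
            if u < acc:
                state[i] = k
                break

    inv_w2 = 2.0 / (omega_um * omega_um)
    inv_wz2 = 2.0 / (s_ell * omega_um * s_ell * omega_um)
    cnt = 0
    n_bleach = 0
    max_out = out_times.shape[0]
    max_bleach = out_bleach.shape[0]

    for step in range(n_steps):
        t0 = step * dt
        # integer phase arithmetic: steps align exactly with the ALEX gates
        d_phase = (step % steps_per_cycle) < steps_per_half
        for i in range(n_mol):
            for ax in range(3):
                pos[i, ax] = _wrap(pos[i, ax] + np.random.normal() * step_sd,
                                   half_box_um)
            # conformational switching (dual-labeled only; others have no FRET)
            if n_states > 1:
                p_sw = 1.0 - np.exp(-dt / dwell_s[state[i]])
                if np.random.random() < p_sw:
                    u = np.random.random() * (1.0 - occupancies[state[i]])
                    acc = 0.0
                    new = state[i]
                    for k in range(n_states):
                        if k == state[i]:
                            continue
                        acc += occupancies[k]
                        if u < acc:
                            new = k
                            break
                    state[i] = new

            w = np.exp(-(pos[i, 0] ** 2 + pos[i, 1] ** 2) * inv_w2
                       - pos[i, 2] ** 2 * inv_wz2)

            # reservoir exchange: far from focus, restore a fresh acceptor
            if w < 1e-4:
                alive[i] = 1
                continue

            has_acceptor = (species[i] != SP_DONOR_ONLY) and alive[i] == 1
            has_donor = species[i] != SP_ACCEPTOR_ONLY
            e_cur = e_states[state[i]] if (species[i] == SP_DUAL
                                           and alive[i] == 1) else 0.0

            if bleach_rate > 0.0 and has_acceptor:
                if np.random.random() < 1.0 - np.exp(-bleach_rate * w * dt):
                    alive[i] = 0
                    if n_bleach < max_bleach:
                        out_bleach[n_bleach] = t0 + np.random.random() * dt
                        n_bleach += 1
                    has_acceptor = False
                    e_cur = 0.0

            r_dd = 0.0
            r_da = 0.0
            r_aa = 0.0
            if d_phase:
                if has_donor:
                    r_dd = b_donor_cps * w * (1.0 - e_cur)
                    r_da = b_donor_cps * w * gamma_true * e_cur \
                        + leakage * r_dd
                if has_acceptor:
                    r_da += direct_exc * b_acceptor_cps * w
            else:
                if has_acceptor:
                    r_aa = b_acceptor_cps * w

            for code in range(3):
                rate = r_dd if code == CODE_DD else (
                    r_da if code == CODE_DA else r_aa)
                if rate <= 0.0:
                    continue
                n_ph = np.random.poisson(rate * dt)
                for _ in range(n_ph):
                    if cnt >= max_out:
                        return -1, n_bleach
                    out_times[cnt] = t0 + np.random.random() * dt
                    out_code[cnt] = code
                    out_e[cnt] = e_cur
                    out_mol[cnt] = i
                    cnt += 1
    return cnt, n_bleach
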