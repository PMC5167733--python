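"""Numba kernels for the three-subpopulation ERP neural-mass network.

State layout, 9 states per node (base index ``9*i``):

====  =========================================
 +0   stellate (granular) depolarization
 +1   stellate current
 +2   pyramidal excitatory depolarization
 +3   pyramidal excitatory current
 +4   pyramidal inhibitory depolarization
 +5   pyramidal inhibitory current
 +6   inhibitory-interneuron depolarization
 +7   inhibitory-interneuron current
 +8   pyramidal (output) depolarization
====  =========================================

Each synapse is a second-order kernel v'' = (H/tau)*input - 2 v'/tau - v/tau^2.
Extrinsic couplings act on delayed pyramidal firing (one conduction delay for
all inter-node edges, a shorter one for the intrinsic recurrent terms); the
delayed potentials are read from the stored solution history by linear
interpolation, which is exact enough because both delays are multiples of the
integration step in the default configuration.
"""

import numpy as np
from numba import njit

__all__ = ["integrate_erp"]


@njit(cache=True, inline="always")
def _sigm(x, r, fs):
    # centred logistic: zero firing at rest, range (-fs/2, fs/2);
    # fs is the maximal population firing rate (2*e0), per ms
    return fs * (1.0 / (1.0 + np.exp(-r * x)) - 0.5)


@njit(cache=True, inline="always")
def _delayed_out(hist, n, k_avail, idx, out):
    """Pyramidal potentials at fractional history index ``idx`` (<=k_avail)."""
    if idx <= 0.0:
        for j in range(n):
            out[j] = 0.0
        return
    i0 = int(np.floor(idx))
    if i0 >= k_avail:
        i0 = k_avail - 1
    frac = idx - i0
    if frac > 1.0:
        frac = 1.0
    for j in range(n):
        a = hist[i0, 9 * j + 8]
        b = hist[i0 + 1, 9 * j + 8]
        out[j] = a + frac * (b - a)


@njit(cache=True)
def _rhs(x, u, x9_ext, x9_int, AF, AB, AL, sg,
         He, Hi, te, ti, g1, g2, g3, g4, r, fs, uscale, dxdt):
    n = sg.shape[0]
    ke = He / te
    ki = Hi / ti
    Sf = np.empty(n)
    for j in range(n):
        Sf[j] = _sigm(x9_ext[j], r, fs)
    for i in range(n):
        b = 9 * i
        exc_in = 0.0   # forward + lateral, into granular layer
        bwd_in = 0.0   # backward + lateral, into pyramidal + inhibitory
        for j in range(n):
            exc_in += (AF[i, j] + AL[i, j]) * Sf[j]
            bwd_in += (AB[i, j] + AL[i, j]) * Sf[j]
        s = sg[i]
        Si = _sigm(x9_int[i], r, fs)
        S1 = _sigm(x[b + 0], r, fs)
        S7 = _sigm(x[b + 6], r, fs)
        dxdt[b + 0] = x[b + 1]
        dxdt[b + 1] = ke * (exc_in + g1 * s * Si + uscale * u[i]) \
            - 2.0 * x[b + 1] / te - x[b + 0] / (te * te)
        dxdt[b + 2] = x[b + 3]
        dxdt[b + 3] = ke * (bwd_in + g2 * s * S1) \
            - 2.0 * x[b + 3] / te - x[b + 2] / (te * te)
        dxdt[b + 4] = x[b + 5]
        dxdt[b + 5] = ki * (g4 * s * S7) \
            - 2.0 * x[b + 5] / ti - x[b + 4] / (ti * ti)
        dxdt[b + 6] = x[b + 7]
        dxdt[b + 7] = ke * (bwd_in + g3 * s * Si) \
            - 2.0 * x[b + 7] / te - x[b + 6] / (te * te)
        dxdt[b + 8] = x[b + 3] - x[b + 5]


@njit(cache=True)
def _inputs_at(t, amp, mu, sd, u):
    n_comp, n = amp.shape
    for i in range(n):
        u[i] = 0.0
    for c in range(n_comp):
        g = np.exp(-0.5 * ((t - mu[c]) / sd[c]) ** 2)
        for i in range(n):
            u[i] += amp[c, i] * g
    return u


@njit(cache=True)
def integrate_erp(AF, AB, AL, sg, amp, mu, sd,
                  He, Hi, te, ti, g1, g2, g3, g4, r, fs, uscale,
                  d_ext, d_int, t0, dt, n_steps):
    """Fixed-step RK4 integration from rest; returns (history, ok).

    history has shape ``(n_steps + 1, 9 * n)``; ok is False when the solution
    left the finite range (divergent parameter regime).
    """
    n = sg.shape[0]
    m = 9 * n
    hist = np.zeros((n_steps + 1, m))
    x = np.zeros(m)
    xtmp = np.empty(m)
    u = np.empty(n)
    xe = np.empty(n)
    xi = np.empty(n)
    dx1 = np.empty(m)
    dx2 = np.empty(m)
    dx3 = np.empty(m)
    dx4 = np.empty(m)
    de = d_ext / dt
    di = d_int / dt
    for k in range(n_steps):
        t = t0 + k * dt
        # substep 1 (t)
        _delayed_out(hist, n, k, k - de, xe)
        _delayed_out(hist, n, k, k - di, xi)
        _inputs_at(t, amp, mu, sd, u)
        _rhs(x, u, xe, xi, AF, AB, AL, sg,
             He, Hi, te, ti, g1, g2, g3, g4, r, fs, uscale, dx1)
        # substeps 2+3 (t + dt/2) share the same delayed potentials
        _delayed_out(hist, n, k, k + 0.5 - de, xe)
        _delayed_out(hist, n, k, k + 0.5 - di, xi)
        _inputs_at(t + 0.5 * dt, amp, mu, sd, u)
        for s_ in range(m):
            xtmp[s_] = x[s_] + 0.5 * dt * dx1[s_]
        _rhs(xtmp, u, xe, xi, AF, AB, AL, sg,
             He, Hi, te, ti, g1, g2, g3, g4, r, fs, uscale, dx2)
        for s_ in range(m):
            xtmp[s_] = x[s_] + 0.5 * dt * dx2[s_]
        _rhs(xtmp, u, xe, xi, AF, AB, AL, sg,
             He, Hi, te, ti, g1, g2, g3, g4, r, fs, uscale, dx3)
        # substep 4 (t + dt)
        _delayed_out(hist, n, k, k + 1.0 - de, xe)
        _delayed_out(hist, n, k, k + 1.0 - di, xi)
        _inputs_at(t + dt, amp, mu, sd, u)
        for s_ in range(m):
            xtmp[s_] = x[s_] + dt * dx3[s_]
        _rhs(xtmp, u, xe, xi, AF, AB, AL, sg,
             He, Hi, te, ti, g1, g2, g3, g4, r, fs, uscale, dx4)
        bad = False
        for s_ in range(m):
            x[s_] = x[s_] + (dt / 6.0) * (dx1[s_] + 2.0 * dx2[s_]
                                          + 2.0 * dx3[s_] + dx4[s_])
            if not np.isfinite(x[s_]) or np.abs(x[s_]) > 1e6:
                bad = True
            hist[k + 1, s_] = x[s_]
        if bad:
            return hist, False
    return hist, True
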