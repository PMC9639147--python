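"""JIT-compiled step loops.

These are strict sequential recurrences (the two-step explicit integrator and
the quantum-jump walk), so they live in numba kernels; everything around them
is plain numpy.  The matrix-vector products are written out to avoid per-step
allocations — runs routinely take 10^5-10^6 steps.
"""

import numpy as np
from numba import njit

__all__ = ["leapfrog_loop", "sse_loop"]


@njit(cache=True)
def leapfrog_loop(energies, w, eps, dt, stride, c_prev, c_curr, out):
    """Two-step explicit ("second-order Euler") propagation of i dc/dt = H(t) c.

    H(t) = diag(energies) - eps[step] * W.  ``c_prev``/``c_curr`` hold the
    state at steps 0 and 1 (the caller performs the startup step); ``out`` is
    pre-allocated (n_stored, n) with out[0] = c(0).  Stores every
    ``stride``-th step.  Updates in place and returns the final state.
    """
    n_steps = eps.shape[0] - 1
    n = energies.shape[0]
    if stride == 1:
        out[1] = c_curr
    for step in range(1, n_steps):
        e = eps[step]
        for i in range(n):
            acc = energies[i] * c_curr[i]
            for j in range(n):
                acc -= e * w[i, j] * c_curr[j]
            c_prev[i] = c_prev[i] - 2j * dt * acc
        tmp = c_prev
        c_prev = c_curr
        c_curr = tmp
        nxt = step + 1
        if nxt % stride == 0:
            out[nxt // stride] = c_curr
    return c_curr.copy()


@njit(cache=True)
def sse_loop(energies, w, eps, dt, stride, c_prev, c_curr,
             gamma_state, src, tgt, rates, uni, out,
             jump_steps, jump_channels):
    """Quantum-jump stochastic propagation.

    Per step: jump probability p_q = rate_q |c_src(q)|^2 dt decides (Monte
    Carlo, uniforms in ``uni``) between a collapse onto the channel target and
    the no-jump evolution: a unitary leapfrog step followed by the diagonal
    damping exp(-gamma dt / 2) applied to both stored levels and a global
    renormalization (damping both levels equally keeps the two-step stencil
    stable).  Returns (n_jumps, error_flag); error_flag = 1 signals
    sum_q p_q > 0.1 (time step too large for the requested rates).
    """
    n_steps = eps.shape[0] - 1
    n = energies.shape[0]
    n_ch = rates.shape[0]
    damp = np.exp(-0.5 * gamma_state * dt)
    dissipative = gamma_state.max() > 0.0 if n > 0 else False
    n_jumps = 0
    max_log = jump_steps.shape[0]
    if stride == 1:
        out[1] = c_curr
    for step in range(1, n_steps):
        # jump decision from the (normalized) state at the current time
        ptot = 0.0
        for q in range(n_ch):
            a = c_curr[src[q]]
            ptot += rates[q] * (a.real * a.real + a.imag * a.imag) * dt
        if ptot > 0.1:
            return n_jumps, 1
        if n_ch > 0 and uni[step, 0] < ptot:
            # select the channel proportionally to its probability
            r = uni[step, 1] * ptot
            acc = 0.0
            qsel = n_ch - 1
            for q in range(n_ch):
                a = c_curr[src[q]]
                acc += rates[q] * (a.real * a.real + a.imag * a.imag) * dt
                if r < acc:
                    qsel = q
                    break
            a = c_curr[src[qsel]]
            phase = a / abs(a)
            for i in range(n):
                c_curr[i] = 0.0
            c_curr[tgt[qsel]] = phase
            # restart the two-step stencil: back-evolve one step under H0
            for i in range(n):
                c_prev[i] = c_curr[i] * np.exp(1j * energies[i] * dt)
            if n_jumps < max_log:
                jump_steps[n_jumps] = step
                jump_channels[n_jumps] = qsel
            n_jumps += 1
        else:
            e = eps[step]
            for i in range(n):
                acc = energies[i] * c_curr[i]
                for j in range(n):
                    acc -= e * w[i, j] * c_curr[j]
                c_prev[i] = c_prev[i] - 2j * dt * acc
            tmp = c_prev
            c_prev = c_curr
            c_curr = tmp
            if dissipative:
                # split-off dissipative part: damp both stencil levels, renormalize
                nrm = 0.0
                for i in range(n):
                    c_prev[i] *= damp[i]
                    c_curr[i] *= damp[i]
                    nrm += c_curr[i].real ** 2 + c_curr[i].imag ** 2
                nrm = np.sqrt(nrm)
                for i in range(n):
                    c_curr[i] /= nrm
                    c_prev[i] /= nrm
        nxt = step + 1
        if nxt % stride == 0:
            out[nxt // stride] = c_curr
    return n_jumps, 0
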