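"""Compiled inner loop for per-step action valuation.

The interval-selection step evaluates, for every action of the current
state, the joint interval, one residual and one marginal interval per
source, the generalization test, and the MOS/LUS selection rule.  Long
experiments run millions of such steps, so the loop is JIT-compiled with
numba.  :meth:`multisense.agent.MultisensoryAgent.action_values` holds the
equivalent (and authoritative) numpy implementation; a test asserts the two
produce identical trajectories, and the numpy path takes over transparently
when numba is unavailable.

Bound method codes: 0 = student_t, 1 = chebyshev, 2 = bernstein.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _interval(n, sum_r, sum_r2, method, tq, log_term, alpha, width):
    """One confidence interval from raw sufficient statistics."""
    if method == 1:  # chebyshev: needs one sample
        if n < 1.0:
            return -np.inf, np.inf
        q = sum_r / n
        half = width / (2.0 * np.sqrt(n * alpha))
        return q - half, q + half
    if n < 2.0:
        return -np.inf, np.inf
    q = sum_r / n
    var = (sum_r2 - n * q * q) / (n - 1.0)
    if var < 0.0:
        var = 0.0
    if method == 0:  # student_t
        half = tq[int(n) - 1] * np.sqrt(var / n)
    else:  # empirical bernstein
        half = np.sqrt(var) * np.sqrt(2.0 * log_term / n) + 3.0 * width * log_term / n
    return q - half, q + half


@njit(cache=False)
def select_kernel(
    nJ, sJ, s2J,        # joint row: (A,) each
    nM, sM, s2M,        # marginal rows stacked over sources: (m, A) each
    tq,                 # two-sided t quantiles indexed by dof
    alpha, log_term, width,
    method,             # 0 student_t, 1 chebyshev, 2 bernstein
    mos,                # True: MOS, False: LUS
    value, src_code, accepts,  # outputs: (A,), (A,), (m, A)
):
    A = nJ.shape[0]
    m = nM.shape[0]
    for a in range(A):
        m_lo, m_up = _interval(nJ[a], sJ[a], s2J[a], method, tq, log_term, alpha, width)
        best = m          # joint code
        if mos:
            best_up = -np.inf
        else:
            best_len = m_up - m_lo
            best_up = m_up
        for j in range(m):
            r_lo, r_up = _interval(
                nM[j, a] - nJ[a], sM[j, a] - sJ[a], s2M[j, a] - s2J[a],
                method, tq, log_term, alpha, width,
            )
            lo = r_lo if r_lo > m_lo else m_lo
            up = r_up if r_up < m_up else m_up
            acc = lo <= up
            accepts[j, a] = acc
            if not acc:
                continue
            b_lo, b_up = _interval(nM[j, a], sM[j, a], s2M[j, a], method, tq, log_term, alpha, width)
            if mos:
                if b_up > best_up:
                    best_up = b_up
                    best = j
            else:
                b_len = b_up - b_lo
                if b_len < best_len:
                    best_len = b_len
                    best_up = b_up
                    best = j
        if mos:
            if best == m:  # nothing accepted: fall back to the joint bound
                value[a] = m_up
            elif best_up > m_up:  # cap at the joint upper bound
                value[a] = m_up
                best = m
            else:
                value[a] = best_up
        else:
            if best_up > m_up:
                value[a] = m_up
                best = m
            else:
                value[a] = best_up
        src_code[a] = best
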