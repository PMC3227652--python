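"""Mass-action right-hand side of the two-compartment Smad network.

State layout (concentrations in nM, time in seconds)::

    0  R      free receptor                     (cytoplasm/membrane)
    1  LR     ligand-bound receptor
    2  LRa    active (phosphorylated) receptor
    3  LRaI   I-Smad-sequestered active receptor
    4  S_c    R-Smad, cytoplasm
    5  pS_c   phospho-R-Smad, cytoplasm
    6  C_c    Co-Smad, cytoplasm
    7  D_c    phospho-R-Smad homodimer, cytoplasm
    8  H_c    phospho-R-Smad/Co-Smad heterodimer, cytoplasm
    9  m_c    I-Smad mRNA, cytoplasm
    10 I      free I-Smad protein
    11 S_n    R-Smad, nucleus
    12 pS_n   phospho-R-Smad, nucleus
    13 C_n    Co-Smad, nucleus
    14 D_n    homodimer, nucleus
    15 H_n    heterodimer, nucleus (the monitored transcription factor)
    16 m_n    I-Smad mRNA, nucleus

The parameter vector has 20 entries: k1..k19 followed by the Hill
coefficient h of transcriptional activation.  Ligand L (nM) is a boundary
condition supplied by the caller and is never depleted.
"""

from __future__ import annotations

import numpy as np

N_STATE = 17
N_PARAM = 20

STATE_NAMES = (
    "R", "LR", "LRa", "LRaI",
    "S_c", "pS_c", "C_c", "D_c", "H_c", "m_c", "I",
    "S_n", "pS_n", "C_n", "D_n", "H_n", "m_n",
)

IDX_HN = 15

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=False, fastmath=False)(func)

except ImportError:  # pragma: no cover
    def _jit(func):
        return func


def _rhs(t, y, p, L):
    k1 = p[0]; k2 = p[1]; k3 = p[2]; k4 = p[3]; k5 = p[4]
    k6 = p[5]; k7 = p[6]; k8 = p[7]; k9 = p[8]; k10 = p[9]
    k11 = p[10]; k12 = p[11]; k13 = p[12]; k14 = p[13]; k15 = p[14]
    k16 = p[15]; k17 = p[16]; k18 = p[17]; k19 = p[18]; h = p[19]

    R = y[0]; LR = y[1]; LRa = y[2]
    S_c = y[4]; pS_c = y[5]; C_c = y[6]; D_c = y[7]; H_c = y[8]
    m_c = y[9]; I = y[10]
    S_n = y[11]; pS_n = y[12]; C_n = y[13]; D_n = y[14]; H_n = y[15]
    m_n = y[16]

    v_bind = k2 * L * R
    v_unbind = k1 * LR
    v_act = k3 * LR
    v_deact = k4 * LRa
    v_seq = k5 * LRa * I
    v_rel = k6 * y[3]
    v_phos = k7 * LRa * S_c

    imp_S = k8 * S_c
    exp_S = k9 * S_n
    imp_pS = k8 * pS_c
    exp_pS = k9 * pS_n
    imp_C = k8 * C_c
    exp_C = k9 * C_n

    v_Dc_f = k10 * pS_c * pS_c
    v_Dc_d = k11 * D_c
    v_Hc_f = k10 * pS_c * C_c
    v_Hc_d = k11 * H_c
    v_Dn_f = k10 * pS_n * pS_n
    v_Dn_d = k11 * D_n
    v_Hn_f = k10 * pS_n * C_n
    v_Hn_d = k11 * H_n

    imp_D = k12 * D_c
    imp_H = k12 * H_c
    v_deph = k13 * pS_n

    # Hill-type transcriptional activation by the nuclear heterodimer;
    # tiny solver-induced negatives are clipped to keep H_n**h real.
    hn = H_n if H_n > 0.0 else 0.0
    num = hn ** h
    v_txn = k14 * num / (k15 ** h + num)

    v_mexp = k16 * m_n
    v_mdeg = k17 * m_c
    v_tln = k18 * m_c
    v_ideg = k19 * I

    out = np.empty(17)
    out[0] = v_unbind - v_bind
    out[1] = v_bind - v_unbind - v_act + v_deact
    out[2] = v_act - v_deact - v_seq + v_rel
    out[3] = v_seq - v_rel
    out[4] = -v_phos - imp_S + exp_S
    out[5] = v_phos - imp_pS + exp_pS - 2.0 * v_Dc_f + 2.0 * v_Dc_d - v_Hc_f + v_Hc_d
    out[6] = -imp_C + exp_C - v_Hc_f + v_Hc_d
    out[7] = v_Dc_f - v_Dc_d - imp_D
    out[8] = v_Hc_f - v_Hc_d - imp_H
    out[9] = v_mexp - v_mdeg
    out[10] = v_tln - v_ideg - v_seq + v_rel
    out[11] = imp_S - exp_S + v_deph
    out[12] = imp_pS - exp_pS - v_deph - 2.0 * v_Dn_f + 2.0 * v_Dn_d - v_Hn_f + v_Hn_d
    out[13] = imp_C - exp_C - v_Hn_f + v_Hn_d
    out[14] = v_Dn_f - v_Dn_d + imp_D
    out[15] = v_Hn_f - v_Hn_d + imp_H
    out[16] = v_txn - v_mexp
    return out


rhs_core = _jit(_rhs)


def _rk4(y0, p, L, dt, n_steps, save_every):
    """Fixed-step classical Runge-Kutta integration at constant ligand.

    Returns the saved state matrix with ``n_steps // save_every + 1`` rows
    (row 0 is the initial condition).  Used as an independent oracle for the
    stiff variable-step solver; step size is the caller's responsibility.
    """
    n_save = n_steps // save_every + 1
    out = np.empty((n_save, 17))
    y = y0.copy()
    out[0] = y
    t = 0.0
    row = 1
    for i in range(n_steps):
        f1 = rhs_core(t, y, p, L)
        f2 = rhs_core(t + 0.5 * dt, y + 0.5 * dt * f1, p, L)
        f3 = rhs_core(t + 0.5 * dt, y + 0.5 * dt * f2, p, L)
        f4 = rhs_core(t + dt, y + dt * f3, p, L)
        y = y + (dt / 6.0) * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
        t += dt
        if (i + 1) % save_every == 0:
            out[row] = y
            row += 1
    return out


rk4_integrate = _jit(_rk4)


def stable_rk4_step(p, totals_max: float) -> float:
    """Conservative stable step (s) for the explicit oracle integrator.

    Bounds the fastest linearized rate by summing first-order rates and
    bimolecular rates times the largest concentration that conservation
    allows, then keeps ``dt * lambda_max`` well inside the RK4 stability
    region.
    """
    first_order = p[0] + p[2] + p[3] + p[5] + p[7] + p[8] + p[10] + p[11] + p[12] + p[15] + p[16] + p[17] + p[18]
    bimolecular = (p[1] + p[4] + p[6] + p[9]) * totals_max
    lam = first_order + bimolecular
    dt = 1.0 / lam if lam > 0 else 0.1
    return min(0.1, dt)
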