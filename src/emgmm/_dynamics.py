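"""Jit-compiled forward-dynamics kernel.

The per-cycle simulation (four Hill-type muscles driving a planar 2-DOF
link-segment model at 100 Hz) sits in the inner loop of every optimizer in
this package, so it is compiled with numba. The pure-Python operations in
:mod:`emgmm.model` define the same physics step-by-step and are used as the
reference in tests.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

DEG = 180.0 / math.pi
RAD = math.pi / 180.0

#: floor applied to the contractile-element length when clamping is requested
MIN_LCE = 1e-3


@njit(cache=True)
def simulate_kernel(act, p, sgn, limits, dyn, init, clamp_lce):
    """Integrate one activation-driven cycle.

    Parameters
    ----------
    act : (n, 4) muscle activations in [0, 1]
    p : (4, 6) per-muscle parameters [l_opt, F0, ma_wrist, ma_mcp, l_th0, K_PEE]
    sgn : (4,) +1 flexor / -1 extensor
    limits : (4,) wrist_lo, wrist_hi, mcp_lo, mcp_hi in degrees
    dyn : (6,) I_w, I_m, b_w, b_m, dt, fl_width
    init : (4,) theta_w, theta_m (deg), omega_w, omega_m (deg/s)
    clamp_lce : if True floor the CE length at MIN_LCE instead of flagging

    Returns
    -------
    wrist, mcp : (n,) angle series in degrees (state after each step)
    min_lce : smallest CE length encountered (degeneracy diagnostic)
    """
    n = act.shape[0]
    wrist = np.empty(n)
    mcp = np.empty(n)
    I_w, I_m, b_w, b_m, dt, w = dyn
    th_w = init[0] * RAD
    th_m = init[1] * RAD
    om_w = init[2] * RAD
    om_m = init[3] * RAD
    lo_w = limits[0] * RAD
    hi_w = limits[1] * RAD
    lo_m = limits[2] * RAD
    hi_m = limits[3] * RAD
    min_lce = 1e30

    for t in range(n):
        m_w = 0.0
        m_m = 0.0
        for j in range(4):
            l_opt = p[j, 0]
            lce = p[j, 4] / 100.0 * l_opt - sgn[j] * (p[j, 2] * th_w + p[j, 3] * th_m)
            if lce < min_lce:
                min_lce = lce
            if clamp_lce and lce < MIN_LCE:
                lce = MIN_LCE
            lt = lce / l_opt
            f = p[j, 1] * act[t, j] * math.exp(-((lt - 1.0) ** 2) / w)
            if lce > l_opt:
                f += p[j, 5] * (lce - l_opt) ** 2
            m_w += sgn[j] * p[j, 2] * f
            m_m += sgn[j] * p[j, 3] * f

        # velocity first (damping implicit), then position; clamp at limits
        om_w = (om_w + dt * m_w / I_w) / (1.0 + dt * b_w / I_w)
        om_m = (om_m + dt * m_m / I_m) / (1.0 + dt * b_m / I_m)
        th_w += dt * om_w
        th_m += dt * om_m
        if th_w < lo_w:
            th_w = lo_w
            om_w = 0.0
        elif th_w > hi_w:
            th_w = hi_w
            om_w = 0.0
        if th_m < lo_m:
            th_m = lo_m
            om_m = 0.0
        elif th_m > hi_m:
            th_m = hi_m
            om_m = 0.0
        wrist[t] = th_w * DEG
        mcp[t] = th_m * DEG

    return wrist, mcp, min_lce
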