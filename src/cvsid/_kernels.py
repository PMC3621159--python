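"""Compiled numerical kernels for the circulation ODEs.

All kernels take the packed parameter vector produced by
``CirculationParams.to_array()`` (layout in ``cvsid.params.PARAM_FIELDS``)
plus driver/forcing curves sampled on uniform periodic grids over one beat.
They are compiled with numba when available and fall back to pure Python
otherwise (identical semantics, slower).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA = True
except Exception:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# indices into the packed parameter vector (see params.PARAM_FIELDS)
I_E_LVF, I_VD_LVF, I_P0_LVF, I_LAM_LVF, I_V0_LVF = 0, 1, 2, 3, 4
I_E_RVF, I_VD_RVF, I_P0_RVF, I_LAM_RVF, I_V0_RVF = 5, 6, 7, 8, 9
I_E_SPT, I_VD_SPT, I_P0_SPT, I_LAM_SPT, I_V0_SPT = 10, 11, 12, 13, 14
I_P0_PCD, I_V0_PCD, I_LAM_PCD, I_PTH = 15, 16, 17, 18
I_E_AO, I_VD_AO, I_E_VC, I_VD_VC, I_E_PA, I_VD_PA, I_E_PU, I_VD_PU = (
    19, 20, 21, 22, 23, 24, 25, 26)
I_R_MT, I_R_AV, I_R_SYS, I_R_TC, I_R_PV, I_R_PUL = 27, 28, 29, 30, 31, 32
I_P_PU, I_P_VC, I_T = 33, 34, 35

SEPTUM_TOL = 1e-9  # mL; well inside the documented 1e-6 guarantee


@njit(cache=True)
def interp_periodic(grid: np.ndarray, T: float, t: float) -> float:
    """Linear interpolation of a uniform periodic sample grid over [0, T)."""
    n = grid.shape[0]
    pos = (t % T) / T * n
    i0 = int(math.floor(pos))
    frac = pos - i0
    i0 = i0 % n
    i1 = (i0 + 1) % n
    return grid[i0] * (1.0 - frac) + grid[i1] * frac


EXP_CLAMP = 50.0  # caps EDPVR exponents so far-from-physiological states
                  # during identification stay finite for the solver


@njit(cache=True)
def _safe_exp(x: float) -> float:
    if x > EXP_CLAMP:
        x = EXP_CLAMP
    return math.exp(x)


@njit(cache=True)
def fw_pressure(V: float, dri: float, E_es: float, V_d: float,
                P_0: float, lam: float, V_0: float) -> float:
    """Ventricular (or septal) free-wall pressure."""
    return dri * E_es * (V - V_d) + (1.0 - dri) * P_0 * (_safe_exp(lam * (V - V_0)) - 1.0)


@njit(cache=True)
def fw_dPdV(V: float, dri: float, E_es: float, V_d: float,
            P_0: float, lam: float, V_0: float) -> float:
    return dri * E_es + (1.0 - dri) * P_0 * lam * _safe_exp(lam * (V - V_0))


@njit(cache=True)
def septum_residual(Vs: float, V_lv: float, V_rv: float,
                    driL: float, driR: float, p: np.ndarray) -> float:
    P_spt = fw_pressure(Vs, driL, p[I_E_SPT], p[I_VD_SPT], p[I_P0_SPT],
                        p[I_LAM_SPT], p[I_V0_SPT])
    P_lvf = fw_pressure(V_lv - Vs, driL, p[I_E_LVF], p[I_VD_LVF], p[I_P0_LVF],
                        p[I_LAM_LVF], p[I_V0_LVF])
    P_rvf = fw_pressure(V_rv + Vs, driR, p[I_E_RVF], p[I_VD_RVF], p[I_P0_RVF],
                        p[I_LAM_RVF], p[I_V0_RVF])
    return P_spt - (P_lvf - P_rvf)


@njit(cache=True)
def solve_septum(V_lv: float, V_rv: float, driL: float, driR: float,
                 p: np.ndarray, guess: float) -> float:
    """Root of the septal pressure balance (monotone, hence unique).

    Newton iteration from a warm-start guess with a bisection fallback.
    """
    Vs = guess
    if Vs != Vs:  # poisoned warm start (NaN) -> neutral septum
        Vs = 0.0
    for _ in range(60):
        f = septum_residual(Vs, V_lv, V_rv, driL, driR, p)
        df = (fw_dPdV(Vs, driL, p[I_E_SPT], p[I_VD_SPT], p[I_P0_SPT],
                      p[I_LAM_SPT], p[I_V0_SPT])
              + fw_dPdV(V_lv - Vs, driL, p[I_E_LVF], p[I_VD_LVF], p[I_P0_LVF],
                        p[I_LAM_LVF], p[I_V0_LVF])
              + fw_dPdV(V_rv + Vs, driR, p[I_E_RVF], p[I_VD_RVF], p[I_P0_RVF],
                        p[I_LAM_RVF], p[I_V0_RVF]))
        if df <= 0.0:
            break
        step = f / df
        Vs -= step
        if abs(step) < SEPTUM_TOL:
            return Vs
    # bisection fallback on an expanding bracket
    lo, hi = -1.0, 1.0
    for _ in range(60):
        if septum_residual(lo, V_lv, V_rv, driL, driR, p) < 0.0:
            break
        lo *= 2.0
    for _ in range(60):
        if septum_residual(hi, V_lv, V_rv, driL, driR, p) > 0.0:
            break
        hi *= 2.0
    flo = septum_residual(lo, V_lv, V_rv, driL, driR, p)
    fhi = septum_residual(hi, V_lv, V_rv, driL, driR, p)
    if flo > 0.0 or fhi < 0.0:
        return np.nan
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = septum_residual(mid, V_lv, V_rv, driL, driR, p)
        if fm > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo < SEPTUM_TOL:
            break
    return 0.5 * (lo + hi)


@njit(cache=True)
def pressures_closed(y: np.ndarray, t: float, p: np.ndarray,
                     driL: np.ndarray, driR: np.ndarray,
                     vs_guess: float) -> np.ndarray:
    """Chamber pressures of the closed loop.

    Returns [P_lv, P_ao, P_vc, P_rv, P_pa, P_pu, V_spt, P_pcd].
    """
    T = p[I_T]
    dL = interp_periodic(driL, T, t)
    dR = interp_periodic(driR, T, t)
    V_lv, V_ao, V_vc, V_rv, V_pa, V_pu = y[0], y[1], y[2], y[3], y[4], y[5]
    Vs = solve_septum(V_lv, V_rv, dL, dR, p, vs_guess)
    P_lvf = fw_pressure(V_lv - Vs, dL, p[I_E_LVF], p[I_VD_LVF], p[I_P0_LVF],
                        p[I_LAM_LVF], p[I_V0_LVF])
    P_rvf = fw_pressure(V_rv + Vs, dR, p[I_E_RVF], p[I_VD_RVF], p[I_P0_RVF],
                        p[I_LAM_RVF], p[I_V0_RVF])
    P_pcd = p[I_P0_PCD] * (_safe_exp(p[I_LAM_PCD] * (V_lv + V_rv - p[I_V0_PCD])) - 1.0)
    P_lv = P_lvf + P_pcd + p[I_PTH]
    P_rv = P_rvf + P_pcd + p[I_PTH]
    P_ao = p[I_E_AO] * (V_ao - p[I_VD_AO])
    P_vc = p[I_E_VC] * (V_vc - p[I_VD_VC])
    P_pa = p[I_E_PA] * (V_pa - p[I_VD_PA])
    P_pu = p[I_E_PU] * (V_pu - p[I_VD_PU])
    out = np.empty(8)
    out[0] = P_lv
    out[1] = P_ao
    out[2] = P_vc
    out[3] = P_rv
    out[4] = P_pa
    out[5] = P_pu
    out[6] = Vs
    out[7] = P_pcd
    return out


@njit(cache=True)
def flows_from_pressures(P_lv: float, P_ao: float, P_vc: float, P_rv: float,
                         P_pa: float, P_pu: float, p: np.ndarray) -> np.ndarray:
    """Valve (diode) and vascular (ohmic) flows: [mt, av, sys, tc, pv, pul]."""
    q = np.empty(6)
    q[0] = max(0.0, (P_pu - P_lv) / p[I_R_MT])
    q[1] = max(0.0, (P_lv - P_ao) / p[I_R_AV])
    q[2] = (P_ao - P_vc) / p[I_R_SYS]
    q[3] = max(0.0, (P_vc - P_rv) / p[I_R_TC])
    q[4] = max(0.0, (P_rv - P_pa) / p[I_R_PV])
    q[5] = (P_pa - P_pu) / p[I_R_PUL]
    return q


@njit(cache=True)
def rhs_closed(t: float, y: np.ndarray, p: np.ndarray,
               driL: np.ndarray, driR: np.ndarray,
               vs_state: np.ndarray) -> np.ndarray:
    pr = pressures_closed(y, t, p, driL, driR, vs_state[0])
    if pr[6] == pr[6]:  # keep the warm start NaN-free
        vs_state[0] = pr[6]
    else:
        vs_state[0] = 0.0
    q = flows_from_pressures(pr[0], pr[1], pr[2], pr[3], pr[4], pr[5], p)
    dy = np.empty(6)
    dy[0] = q[0] - q[1]
    dy[1] = q[1] - q[2]
    dy[2] = q[2] - q[3]
    dy[3] = q[3] - q[4]
    dy[4] = q[4] - q[5]
    dy[5] = q[5] - q[0]
    return dy


@njit(cache=True)
def rhs_systemic(t: float, y: np.ndarray, p: np.ndarray, driL: np.ndarray,
                 f_vspt: np.ndarray, f_pcd: np.ndarray,
                 f_src: np.ndarray, f_snk: np.ndarray) -> np.ndarray:
    """Systemic submodel: states [V_lv, V_ao].

    Inlet pressure (pulmonary vein) and outlet pressure (vena cava) are
    periodic forcing curves; septal volume and pericardial pressure forcing
    reintroduce the ventricular coupling when identified in closed-loop
    context (all-zero curves give the fully decoupled submodel).
    """
    T = p[I_T]
    dL = interp_periodic(driL, T, t)
    Vs = interp_periodic(f_vspt, T, t)
    P_pcd = interp_periodic(f_pcd, T, t)
    P_pu = interp_periodic(f_src, T, t)
    P_vc = interp_periodic(f_snk, T, t)
    P_lv = fw_pressure(y[0] - Vs, dL, p[I_E_LVF], p[I_VD_LVF], p[I_P0_LVF],
                       p[I_LAM_LVF], p[I_V0_LVF]) + P_pcd + p[I_PTH]
    P_ao = p[I_E_AO] * (y[1] - p[I_VD_AO])
    q_mt = max(0.0, (P_pu - P_lv) / p[I_R_MT])
    q_av = max(0.0, (P_lv - P_ao) / p[I_R_AV])
    q_sys = (P_ao - P_vc) / p[I_R_SYS]
    dy = np.empty(2)
    dy[0] = q_mt - q_av
    dy[1] = q_av - q_sys
    return dy


@njit(cache=True)
def rhs_pulmonary(t: float, y: np.ndarray, p: np.ndarray, driR: np.ndarray,
                  f_vspt: np.ndarray, f_pcd: np.ndarray,
                  f_src: np.ndarray, f_snk: np.ndarray) -> np.ndarray:
    """Pulmonary submodel: states [V_rv, V_pa]; inlet P_vc, outlet P_pu."""
    T = p[I_T]
    dR = interp_periodic(driR, T, t)
    Vs = interp_periodic(f_vspt, T, t)
    P_pcd = interp_periodic(f_pcd, T, t)
    P_vc = interp_periodic(f_src, T, t)
    P_pu = interp_periodic(f_snk, T, t)
    P_rv = fw_pressure(y[0] + Vs, dR, p[I_E_RVF], p[I_VD_RVF], p[I_P0_RVF],
                       p[I_LAM_RVF], p[I_V0_RVF]) + P_pcd + p[I_PTH]
    P_pa = p[I_E_PA] * (y[1] - p[I_VD_PA])
    q_tc = max(0.0, (P_vc - P_rv) / p[I_R_TC])
    q_pv = max(0.0, (P_rv - P_pa) / p[I_R_PV])
    q_pul = (P_pa - P_pu) / p[I_R_PUL]
    dy = np.empty(2)
    dy[0] = q_tc - q_pv
    dy[1] = q_pv - q_pul
    return dy


@njit(cache=True)
def trace_closed(ts: np.ndarray, ys: np.ndarray, p: np.ndarray,
                 driL: np.ndarray, driR: np.ndarray) -> np.ndarray:
    """Pressures/flows along a sampled solution (rows: samples).

    Columns: P_lv, P_ao, P_vc, P_rv, P_pa, P_pu, V_spt, P_pcd,
             Q_mt, Q_av, Q_sys, Q_tc, Q_pv, Q_pul.
    """
    n = ts.shape[0]
    out = np.empty((n, 14))
    vs = 0.0
    for i in range(n):
        pr = pressures_closed(ys[i], ts[i], p, driL, driR, vs)
        vs = pr[6]
        q = flows_from_pressures(pr[0], pr[1], pr[2], pr[3], pr[4], pr[5], p)
        for j in range(8):
            out[i, j] = pr[j]
        for j in range(6):
            out[i, 8 + j] = q[j]
    return out


@njit(cache=True)
def trace_systemic(ts: np.ndarray, ys: np.ndarray, p: np.ndarray,
                   driL: np.ndarray, f_vspt: np.ndarray, f_pcd: np.ndarray,
                   f_src: np.ndarray, f_snk: np.ndarray) -> np.ndarray:
    """Columns: P_lv, P_ao, P_pu(src), P_vc(snk), Q_mt, Q_av, Q_sys."""
    T = p[I_T]
    n = ts.shape[0]
    out = np.empty((n, 7))
    for i in range(n):
        t = ts[i]
        dL = interp_periodic(driL, T, t)
        Vs = interp_periodic(f_vspt, T, t)
        P_pcd = interp_periodic(f_pcd, T, t)
        P_pu = interp_periodic(f_src, T, t)
        P_vc = interp_periodic(f_snk, T, t)
        P_lv = fw_pressure(ys[i, 0] - Vs, dL, p[I_E_LVF], p[I_VD_LVF],
                           p[I_P0_LVF], p[I_LAM_LVF], p[I_V0_LVF]) + P_pcd + p[I_PTH]
        P_ao = p[I_E_AO] * (ys[i, 1] - p[I_VD_AO])
        out[i, 0] = P_lv
        out[i, 1] = P_ao
        out[i, 2] = P_pu
        out[i, 3] = P_vc
        out[i, 4] = max(0.0, (P_pu - P_lv) / p[I_R_MT])
        out[i, 5] = max(0.0, (P_lv - P_ao) / p[I_R_AV])
        out[i, 6] = (P_ao - P_vc) / p[I_R_SYS]
    return out


@njit(cache=True)
def trace_pulmonary(ts: np.ndarray, ys: np.ndarray, p: np.ndarray,
                    driR: np.ndarray, f_vspt: np.ndarray, f_pcd: np.ndarray,
                    f_src: np.ndarray, f_snk: np.ndarray) -> np.ndarray:
    """Columns: P_rv, P_pa, P_vc(src), P_pu(snk), Q_tc, Q_pv, Q_pul."""
    T = p[I_T]
    n = ts.shape[0]
    out = np.empty((n, 7))
    for i in range(n):
        t = ts[i]
        dR = interp_periodic(driR, T, t)
        Vs = interp_periodic(f_vspt, T, t)
        P_pcd = interp_periodic(f_pcd, T, t)
        P_vc = interp_periodic(f_src, T, t)
        P_pu = interp_periodic(f_snk, T, t)
        P_rv = fw_pressure(ys[i, 0] + Vs, dR, p[I_E_RVF], p[I_VD_RVF],
                           p[I_P0_RVF], p[I_LAM_RVF], p[I_V0_RVF]) + P_pcd + p[I_PTH]
        P_pa = p[I_E_PA] * (ys[i, 1] - p[I_VD_PA])
        out[i, 0] = P_rv
        out[i, 1] = P_pa
        out[i, 2] = P_vc
        out[i, 3] = P_pu
        out[i, 4] = max(0.0, (P_vc - P_rv) / p[I_R_TC])
        out[i, 5] = max(0.0, (P_rv - P_pa) / p[I_R_PV])
        out[i, 6] = (P_pa - P_pu) / p[I_R_PUL]
    return out
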