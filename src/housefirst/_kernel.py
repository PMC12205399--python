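"""Numba kernels for the compartmental integrator.

The generator is represented as an edge list (from-state, to-state, rate)
plus a background-mortality term that is piecewise constant in the stratum's
current age year.  Occupancy is advanced with explicit RK4 at a fixed step;
integral outcomes (discounted accruals, event counts) use the trapezoidal
rule on the same grid.
"""

from __future__ import annotations

import numba
import numpy as np

# state indices shared with dynamics.py
D_OD = 28
D_OTHER = 29
N_STATES = 30


@numba.njit(cache=True, inline="always")
def _deriv(x, dx, ef, et, er, bg_mult, mu):
    for k in range(N_STATES):
        dx[k] = 0.0
    for e in range(ef.shape[0]):
        flow = er[e] * x[ef[e]]
        dx[ef[e]] -= flow
        dx[et[e]] += flow
    for k in range(N_STATES):
        if bg_mult[k] > 0.0:
            flow = mu * bg_mult[k] * x[k]
            dx[k] -= flow
            dx[D_OTHER] += flow


@numba.njit(cache=True, inline="always")
def _rk4_step(x, h, ef, et, er, bg_mult, mu, k1, k2, k3, k4, xt):
    _deriv(x, k1, ef, et, er, bg_mult, mu)
    for k in range(N_STATES):
        xt[k] = x[k] + 0.5 * h * k1[k]
    _deriv(xt, k2, ef, et, er, bg_mult, mu)
    for k in range(N_STATES):
        xt[k] = x[k] + 0.5 * h * k2[k]
    _deriv(xt, k3, ef, et, er, bg_mult, mu)
    for k in range(N_STATES):
        xt[k] = x[k] + h * k3[k]
    _deriv(xt, k4, ef, et, er, bg_mult, mu)
    for k in range(N_STATES):
        x[k] += h / 6.0 * (k1[k] + 2.0 * k2[k] + 2.0 * k3[k] + k4[k])


@numba.njit(cache=True)
def integrate_trajectory(x0_idx, ef, et, er, bg_mult, mu_tab, n_steps, h, occ):
    """Fill ``occ[s, k, t]`` for every stratum; returns 0, or 1 if occupancy
    went negative (step too large)."""
    n_strata, _, n_times = occ.shape
    k1 = np.empty(N_STATES)
    k2 = np.empty(N_STATES)
    k3 = np.empty(N_STATES)
    k4 = np.empty(N_STATES)
    xt = np.empty(N_STATES)
    x = np.empty(N_STATES)
    n_years = mu_tab.shape[1]
    for s in range(n_strata):
        for k in range(N_STATES):
            x[k] = 0.0
        x[x0_idx] = 1.0
        occ[s, :, 0] = x
        for step in range(n_times - 1):
            if step >= n_steps[s]:
                occ[s, :, step + 1] = x  # frozen past the age-100 horizon
                continue
            y = int((step + 0.5) * h)
            if y >= n_years:
                y = n_years - 1
            _rk4_step(x, h, ef, et, er, bg_mult, mu_tab[s, y],
                      k1, k2, k3, k4, xt)
            for k in range(N_STATES):
                if x[k] < -1e-9:
                    return 1
            occ[s, :, step + 1] = x
    return 0


@numba.njit(cache=True)
def integrate_outcomes(x0_idx, ef, et, er, bg_mult, mu_tab, bgc_tab, weights,
                       n_steps, h, rho, v_qol, v_hc, v_house, v_odt, v_live,
                       window_steps, out):
    """Cohort-weighted outcomes without storing the trajectory.

    ``out`` (length 7) receives: discounted QALYs, discounted health-care
    cost, discounted housing cost, overdose-window totals (all overdoses),
    overdose deaths, other-cause deaths at the window, and discounted
    life-years.  Returns 0, or 1 on negativity failure.
    """
    n_strata = weights.shape[0]
    k1 = np.empty(N_STATES)
    k2 = np.empty(N_STATES)
    k3 = np.empty(N_STATES)
    k4 = np.empty(N_STATES)
    xt = np.empty(N_STATES)
    x = np.empty(N_STATES)
    n_years = mu_tab.shape[1]
    for j in range(7):
        out[j] = 0.0
    for s in range(n_strata):
        w = weights[s]
        for k in range(N_STATES):
            x[k] = 0.0
        x[x0_idx] = 1.0
        # integrand values at the current grid point
        bgc = bgc_tab[s, 0]
        g_qol = 0.0
        g_hc = 0.0
        g_house = 0.0
        g_od = 0.0
        g_ly = 0.0
        for k in range(N_STATES):
            g_qol += v_qol[k] * x[k]
            g_hc += v_hc[k] * x[k] + bgc * v_live[k] * x[k]
            g_house += v_house[k] * x[k]
            g_od += v_odt[k] * x[k]
            g_ly += v_live[k] * x[k]
        acc_qol = 0.0
        acc_hc = 0.0
        acc_house = 0.0
        acc_od = 0.0
        acc_ly = 0.0
        for step in range(n_steps[s]):
            y = int((step + 0.5) * h)
            if y >= n_years:
                y = n_years - 1
            _rk4_step(x, h, ef, et, er, bg_mult, mu_tab[s, y],
                      k1, k2, k3, k4, xt)
            for k in range(N_STATES):
                if x[k] < -1e-9:
                    return 1
            t = (step + 1) * h
            disc = np.exp(-rho * t)
            bgc = bgc_tab[s, y]
            n_qol = 0.0
            n_hc = 0.0
            n_house = 0.0
            n_od = 0.0
            n_ly = 0.0
            for k in range(N_STATES):
                n_qol += v_qol[k] * x[k]
                n_hc += v_hc[k] * x[k] + bgc * v_live[k] * x[k]
                n_house += v_house[k] * x[k]
                n_od += v_odt[k] * x[k]
                n_ly += v_live[k] * x[k]
            n_qol *= disc
            n_hc *= disc
            n_house *= disc
            n_lyd = n_ly * disc
            acc_qol += 0.5 * h * (g_qol + n_qol)
            acc_hc += 0.5 * h * (g_hc + n_hc)
            acc_house += 0.5 * h * (g_house + n_house)
            acc_ly += 0.5 * h * (g_ly + n_lyd)
            if step < window_steps:
                acc_od += 0.5 * h * (g_od + n_od)
            g_qol = n_qol
            g_hc = n_hc
            g_house = n_house
            g_od = n_od
            g_ly = n_lyd
            if step + 1 == window_steps:
                out[4] += w * x[D_OD]
                out[5] += w * x[D_OTHER]
        if n_steps[s] < window_steps:
            # stratum reached the age cap inside the event window; counts
            # are frozen from the cap onward
            out[4] += w * x[D_OD]
            out[5] += w * x[D_OTHER]
        out[0] += w * acc_qol
        out[1] += w * acc_hc
        out[2] += w * acc_house
        out[3] += w * acc_od
        out[6] += w * acc_ly
    return 0
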