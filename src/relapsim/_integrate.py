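"""Numba-jitted adaptive Dormand-Prince (RK45) integration of the two disease models.

The treatment dose is piecewise constant, so the ODE right-hand side is smooth
only between dose breakpoints; the driver integrates segment by segment and
forces steps to land exactly on requested output times, which avoids both
discontinuity crossing and dense-output interpolation error.

Model ids: 0 = AML (state Q_H, A_H, Q_L, A_L; time in days),
           1 = CML (state X, Y, Z; time in months).
"""

import numpy as np
from numba import njit

# status codes returned by the driver
OK = 0
BLOWUP = 1  # non-finite state encountered
STEP_UNDERFLOW = 2


@njit(cache=True, fastmath=False)
def _rhs(model, y, p, dose, out):
    if model == 0:
        # p = (t_QA_H, t_AQ_H, p_H, d_H, t_QA_L, t_AQ_L, p_L, d_L, K_Q, K_A, c)
        Q_H, A_H, Q_L, A_L = y[0], y[1], y[2], y[3]
        K_Q, K_A, c = p[8], p[9], p[10]
        fQ = 1.0 - (Q_H + Q_L) / K_Q
        fA = 1.0 - (A_H + A_L) / K_A
        # healthy
        act_H = p[0] * Q_H * fA
        deact_H = p[1] * A_H * fQ
        out[0] = deact_H - act_H
        out[1] = act_H - deact_H + p[2] * A_H * fA - p[3] * A_H - c * dose * A_H
        # leukemic
        act_L = p[4] * Q_L * fA
        deact_L = p[5] * A_L * fQ
        out[2] = deact_L - act_L
        out[3] = act_L - deact_L + p[6] * A_L * fA - p[7] * A_L - c * dose * A_L
    else:
        # p = (p_XY, p_YX, p_Y, K_Y, e_TKI, m, p_Z, K_Z, r_Z, a)
        X, Y, Z = y[0], y[1], y[2]
        out[0] = p[1] * Y - p[0] * X
        out[1] = (p[0] * X - p[1] * Y + p[2] * Y * (1.0 - Y / p[3])
                  - p[4] * dose * Y - p[5] * Y * Z)
        out[2] = p[8] - p[9] * Z + p[6] * Z * Y / (p[7] + Y * Y)


@njit(cache=True)
def integrate(model, y0, p, seg_t, seg_dose, t_eval, rtol, atol):
    """Integrate from seg_t[0] to seg_t[-1]; return states at t_eval and a status."""
    ndim = y0.shape[0]
    nev = t_eval.shape[0]
    out = np.empty((nev, ndim))
    y = y0.copy()

    # Dormand-Prince coefficients
    c2, c3, c4, c5 = 0.2, 0.3, 0.8, 8.0 / 9.0
    a21 = 0.2
    a31, a32 = 3.0 / 40.0, 9.0 / 40.0
    a41, a42, a43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
    a51, a52, a53, a54 = (19372.0 / 6561.0, -25360.0 / 2187.0,
                          64448.0 / 6561.0, -212.0 / 729.0)
    a61, a62, a63, a64, a65 = (9017.0 / 3168.0, -355.0 / 33.0,
                               46732.0 / 5247.0, 49.0 / 176.0,
                               -5103.0 / 18656.0)
    b1, b3, b4, b5, b6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                          -2187.0 / 6784.0, 11.0 / 84.0)
    # embedded 4th-order weights
    e1, e3, e4, e5, e6, e7 = (5179.0 / 57600.0, 7571.0 / 16695.0,
                              393.0 / 640.0, -92097.0 / 339200.0,
                              187.0 / 2100.0, 1.0 / 40.0)

    k = np.empty((7, ndim))
    ytmp = np.empty(ndim)
    y5 = np.empty(ndim)
    y4 = np.empty(ndim)

    iev = 0
    nseg = seg_t.shape[0] - 1
    for iseg in range(nseg):
        t = seg_t[iseg]
        tend = seg_t[iseg + 1]
        dose = seg_dose[iseg]
        if tend <= t:
            continue
        h = (tend - t) / 20.0
        _rhs(model, y, p, dose, k[0])
        while t < tend - 1e-12 * max(1.0, abs(tend)):
            # emit any eval points we have reached exactly
            while iev < nev and t_eval[iev] <= t + 1e-9:
                for j in range(ndim):
                    out[iev, j] = y[j]
                iev += 1
            # cap step at segment end and at the next eval point
            hmax = tend - t
            if iev < nev and t_eval[iev] < tend:
                hmax = min(hmax, t_eval[iev] - t)
            if hmax <= 0.0:
                break
            if h > hmax:
                h = hmax
            accepted = False
            while not accepted:
                for j in range(ndim):
                    ytmp[j] = y[j] + h * a21 * k[0, j]
                _rhs(model, ytmp, p, dose, k[1])
                for j in range(ndim):
                    ytmp[j] = y[j] + h * (a31 * k[0, j] + a32 * k[1, j])
                _rhs(model, ytmp, p, dose, k[2])
                for j in range(ndim):
                    ytmp[j] = y[j] + h * (a41 * k[0, j] + a42 * k[1, j] + a43 * k[2, j])
                _rhs(model, ytmp, p, dose, k[3])
                for j in range(ndim):
                    ytmp[j] = y[j] + h * (a51 * k[0, j] + a52 * k[1, j]
                                          + a53 * k[2, j] + a54 * k[3, j])
                _rhs(model, ytmp, p, dose, k[4])
                for j in range(ndim):
                    ytmp[j] = y[j] + h * (a61 * k[0, j] + a62 * k[1, j] + a63 * k[2, j]
                                          + a64 * k[3, j] + a65 * k[4, j])
                _rhs(model, ytmp, p, dose, k[5])
                for j in range(ndim):
                    y5[j] = y[j] + h * (b1 * k[0, j] + b3 * k[2, j] + b4 * k[3, j]
                                        + b5 * k[4, j] + b6 * k[5, j])
                _rhs(model, y5, p, dose, k[6])
                for j in range(ndim):
                    y4[j] = y[j] + h * (e1 * k[0, j] + e3 * k[2, j] + e4 * k[3, j]
                                        + e5 * k[4, j] + e6 * k[5, j] + e7 * k[6, j])
                errnorm = 0.0
                finite = True
                for j in range(ndim):
                    if not np.isfinite(y5[j]):
                        finite = False
                        break
                    sc = atol + rtol * max(abs(y[j]), abs(y5[j]))
                    e = abs(y5[j] - y4[j]) / sc
                    if e > errnorm:
                        errnorm = e
                if not finite:
                    h *= 0.25
                    if h < 1e-12 * max(1.0, abs(tend)):
                        return out, BLOWUP
                    continue
                if errnorm <= 1.0:
                    accepted = True
                    t += h
                    for j in range(ndim):
                        y[j] = y5[j]
                        k[0, j] = k[6, j]  # FSAL
                    fac = 5.0 if errnorm == 0.0 else min(5.0, 0.9 * errnorm ** -0.2)
                    h = min(h * fac, tend - t if tend - t > 0 else h * fac)
                    if h <= 0.0:
                        h = 1e-8
                else:
                    h *= max(0.2, 0.9 * errnorm ** -0.2)
                    if h < 1e-13 * max(1.0, abs(tend)):
                        return out, STEP_UNDERFLOW
        # refresh FSAL derivative at the segment boundary with the new dose
        if iseg + 1 < nseg:
            _rhs(model, y, p, seg_dose[iseg + 1], k[0])

    while iev < nev and t_eval[iev] <= seg_t[-1] + 1e-9:
        for j in range(ndim):
            out[iev, j] = y[j]
        iev += 1
    return out, OK
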