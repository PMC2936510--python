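"""Independent oracle: direct minimization of the discretized shape functional.

This deliberately avoids the shooting solver's machinery: the tangent angle
``psi`` is discretized on a uniform arc-length grid, ``R`` follows from the
cumulative integral of ``cos(psi)``, and the Helfrich objective

    E[psi, s1] = sum 2 pi R_mid [ (kappa/2) (H_mid - H0(s_mid))^2 + sigma ] ds

is minimized with a generic quasi-Newton optimizer over the interior psi
values and the free total arc length ``s1``, with a quadratic penalty
enforcing the pinned rim ``R(s1) = R0``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def discrete_energy(psi, s1, field, kappa, sigma, R0, penalty=0.0):
    """Midpoint-rule energy of a psi-profile on a uniform grid over [0, s1].

    ``psi`` includes both endpoints (psi[0] = psi[-1] = 0 for a pinned
    patch).  Returns (energy, R_end).
    """
    n = psi.size
    s = np.linspace(0.0, s1, n)
    ds = s[1] - s[0]
    cosp = np.cos(psi)
    R = np.concatenate([[0.0], np.cumsum(0.5 * (cosp[1:] + cosp[:-1]) * ds)])
    psi_m = 0.5 * (psi[1:] + psi[:-1])
    R_m = 0.5 * (R[1:] + R[:-1])
    dpsi = np.diff(psi) / ds
    s_m = 0.5 * (s[1:] + s[:-1])
    H = dpsi + np.sin(psi_m) / np.where(R_m > 0, R_m, 1.0)
    # limit at the pole: H -> 2 psi'
    H[0] = 2.0 * dpsi[0]
    H0 = field(s_m)
    E = float(np.sum(2.0 * np.pi * R_m
                     * (0.5 * kappa * (H - H0) ** 2 + sigma) * ds))
    if penalty:
        E += penalty * (R[-1] - R0) ** 2
    return E, float(R[-1])


def discrete_energy_grad(psi, s1, field, kappa, sigma, R0, penalty=0.0):
    """Analytic gradient of :func:`discrete_energy` w.r.t. interior psi.

    Returns dE/dpsi for all nodes (the caller masks the fixed endpoints);
    the s1 derivative is cheap by central difference.
    """
    n = psi.size
    ds = s1 / (n - 1)
    s = np.linspace(0.0, s1, n)
    cosp = np.cos(psi)
    sinp = np.sin(psi)
    R = np.concatenate([[0.0], np.cumsum(0.5 * (cosp[1:] + cosp[:-1]) * ds)])
    psi_m = 0.5 * (psi[1:] + psi[:-1])
    R_m = 0.5 * (R[1:] + R[:-1])
    R_m_safe = np.where(R_m > 0, R_m, 1.0)
    dpsi = np.diff(psi) / ds
    s_m = 0.5 * (s[1:] + s[:-1])
    sin_m = np.sin(psi_m)
    cos_m = np.cos(psi_m)
    H = dpsi + sin_m / R_m_safe
    H[0] = 2.0 * dpsi[0]
    U = H - field(s_m)
    a = 2.0 * np.pi * R_m * kappa * U * ds          # dE/dH per interval
    # direct R_m sensitivity (through the area element and through H)
    dE_dRm = (2.0 * np.pi * (0.5 * kappa * U ** 2 + sigma) * ds
              - a * sin_m / R_m_safe ** 2)
    dE_dRm[0] = 2.0 * np.pi * (0.5 * kappa * U[0] ** 2 + sigma) * ds
    # map interval midpoints back to R nodes
    g_R = np.zeros(n)
    g_R[:-1] += 0.5 * dE_dRm
    g_R[1:] += 0.5 * dE_dRm
    if penalty:
        g_R[-1] += 2.0 * penalty * (R[-1] - R0)
    # R_j depends on psi_k through the trapezoid cumulative integral
    suffix = np.cumsum(g_R[::-1])[::-1]             # sum_{j>=k} g_R[j]
    S = suffix - 0.5 * g_R                          # interior trapezoid weight
    S[0] = 0.5 * (suffix[0] - g_R[0])               # half weight at the pole
    grad = -ds * sinp * S
    # direct psi dependence of H (slope and sin(psi_m) terms)
    dH_dpsi_lo = -1.0 / ds + 0.5 * cos_m / R_m_safe
    dH_dpsi_hi = 1.0 / ds + 0.5 * cos_m / R_m_safe
    dH_dpsi_lo[0] = -2.0 / ds
    dH_dpsi_hi[0] = 2.0 / ds
    grad[:-1] += a * dH_dpsi_lo
    grad[1:] += a * dH_dpsi_hi
    return grad


def minimize_functional(field, kappa, sigma, R0, n=401, psi_init=None,
                        s1_init=None, penalty=200.0, maxiter=4000):
    """Minimize the discretized functional; returns (energy, psi, s1, R_end).

    The rim constraint R(s1) = R0 is enforced by a two-stage quadratic
    penalty (the second stage multiplies the weight by 25).  Gradients are
    analytic in psi and finite-difference in s1.
    """
    s1 = float(s1_init if s1_init is not None else R0 * 1.02)
    if psi_init is None:
        psi_init = np.zeros(n)
    x0 = np.concatenate([psi_init[1:-1], [s1]])

    def objective(x, w):
        psi = np.concatenate([[0.0], x[:-1], [0.0]])
        E, _ = discrete_energy(psi, abs(x[-1]), field, kappa, sigma, R0,
                               penalty=w)
        return E

    def gradient(x, w):
        psi = np.concatenate([[0.0], x[:-1], [0.0]])
        s1v = abs(x[-1])
        g_psi = discrete_energy_grad(psi, s1v, field, kappa, sigma, R0,
                                     penalty=w)[1:-1]
        h = 1e-5 * max(s1v, 1.0)
        Ep, _ = discrete_energy(psi, s1v + h, field, kappa, sigma, R0, w)
        Em, _ = discrete_energy(psi, s1v - h, field, kappa, sigma, R0, w)
        return np.concatenate([g_psi, [np.sign(x[-1]) * (Ep - Em) / (2 * h)]])

    res = minimize(objective, x0, args=(penalty,), jac=gradient,
                   method="L-BFGS-B",
                   options={"maxiter": maxiter, "maxfun": 10 * maxiter})
    res = minimize(objective, res.x, args=(penalty * 25.0,), jac=gradient,
                   method="L-BFGS-B",
                   options={"maxiter": maxiter, "maxfun": 10 * maxiter})
    psi = np.concatenate([[0.0], res.x[:-1], [0.0]])
    s1 = abs(res.x[-1])
    E, R_end = discrete_energy(psi, s1, field, kappa, sigma, R0, penalty=0.0)
    return E, psi, s1, R_end


def deformation_energy_of(psi, s1, kappa):
    """E_c = (kappa/2) int H^2 dA of a discrete psi-profile."""
    n = psi.size
    s = np.linspace(0.0, s1, n)
    ds = s[1] - s[0]
    cosp = np.cos(psi)
    R = np.concatenate([[0.0], np.cumsum(0.5 * (cosp[1:] + cosp[:-1]) * ds)])
    psi_m = 0.5 * (psi[1:] + psi[:-1])
    R_m = 0.5 * (R[1:] + R[:-1])
    dpsi = np.diff(psi) / ds
    H = dpsi + np.sin(psi_m) / np.where(R_m > 0, R_m, 1.0)
    H[0] = 2.0 * dpsi[0]
    return float(np.sum(np.pi * kappa * R_m * H ** 2 * ds))
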