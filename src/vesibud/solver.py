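"""Axisymmetric Helfrich shape solver (shooting + continuation).

The membrane patch is an axisymmetric surface described by the tangent angle
``psi(s)`` of its meridian, with arc length ``s`` running from the pole
(``R = 0``) to the pinned rim (``R = R0``).  Shapes minimize the constrained
Helfrich functional

    E = int_0^{s1} 2 pi R [ (kappa/2) (H - H0(s))^2 + sigma ] ds
        + int_0^{s1} gamma(s) (R' - cos psi) ds,

where ``H = psi' + sin(psi)/R`` is the total (sum of principal) curvature,
``H0(s)`` the protein-imposed spontaneous curvature, ``sigma`` the frame
tension and ``gamma(s)`` the Lagrange multiplier enforcing the definition of
``R``.  Stationarity gives a five-dimensional first-order system in
``(psi, psi', R, z, gamma)``; because the total arc length ``s1`` is free,
the first integral (Hamiltonian) of the system must vanish, which supplies
the closure equation of the boundary-value problem.

Numerics
--------
* Internally the system is propagated in the variable ``U = H - H0`` instead
  of ``psi'``: ``U`` is continuous even across discontinuities of ``H0``
  (step/capsid fields), where ``psi'`` jumps by the step in ``H0``.
* The coordinate singularity at the pole is regularized by a leading-order
  series start at ``s = pole_epsilon``.
* Unknowns of the shooting problem are ``(psi'(0), gamma(0), s1)``; residuals
  are ``(psi(s1), R(s1) - R0, Hamiltonian(s1))``.
* Post-critical (overhung) branches are reached by numerical continuation:
  the field is ramped in fractional steps, each converged shot warm-starting
  the next (see :func:`march_field_family`).
* Lengths are scaled by ``R0`` and energies by ``kappa`` internally, so that
  at ``sigma = 0`` the dimensionless equations are independent of ``kappa``.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from .fields import CurvatureField

TWO_PI = 2.0 * math.pi
_PSI_LIMIT = 2.0 * math.pi


class IntegrationFailure(RuntimeError):
    """The trajectory left the physical domain (R <= 0 or |psi| > 2 pi)."""


class ContinuationFailure(RuntimeError):
    """Continuation could not reach the target field."""

    def __init__(self, message: str, last_fraction: float):
        super().__init__(message)
        self.last_fraction = last_fraction


@dataclass(frozen=True)
class SolverConfig:
    """Physical parameters and numerical knobs of the shape solver.

    Parameters
    ----------
    kappa : bending rigidity, k_BT.
    sigma : frame tension, k_BT / nm^2.
    R0 : patch radius at the pinned rim, nm.
    rel_tol, abs_tol : integrator tolerances.
    pole_epsilon : series-start offset from the pole, nm.
    continuation_steps : default number of field-ramp increments.
    min_step_fraction : smallest allowed continuation step.
    max_shoot_iters : residual-evaluation budget of one shooting solve.
    root_tol : max norm of boundary residuals at convergence (dimensionless).
    grid_points : number of output grid points of a solved profile.
    """

    kappa: float = 20.0
    sigma: float = 0.0
    R0: float = 500.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    pole_epsilon: float = 1e-3
    continuation_steps: int = 20
    min_step_fraction: float = 1.0 / 320.0
    max_shoot_iters: int = 400
    root_tol: float = 1e-8
    grid_points: int = 4001

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        for name in ("rel_tol", "abs_tol", "pole_epsilon", "root_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sigma_tilde(self) -> float:
        """Dimensionless tension sigma * R0^2 / kappa."""
        return self.sigma * self.R0 ** 2 / self.kappa


class _ScaledField:
    """Dimensionless view of a curvature field (lengths in units of R0)."""

    def __init__(self, field: CurvatureField, R0: float):
        self.field = field
        self.R0 = R0

    def __call__(self, s: float) -> float:
        return self.R0 * self.field._eval_scalar(s * self.R0)

    def deriv(self, s: float) -> float:
        return self.R0 ** 2 * self.field._deriv_scalar(s * self.R0)

    @property
    def breakpoints(self):
        return tuple(b / self.R0 for b in self.field.breakpoints)

    @property
    def support(self):
        return self.field.support / self.R0


# --------------------------------------------------------------------------
# dimensionless right-hand side, events, Hamiltonian
# --------------------------------------------------------------------------

def _rhs(s, y, f, sig):
    # y = (psi, U, R, z, g); U = H - H0, g = gamma / (2 pi kappa) * R0
    psi, U, R, _z, g = y
    sinp = math.sin(psi)
    k = sinp / R
    return (U + f(s) - k,
            g * k,
            math.cos(psi),
            sinp,
            0.5 * U * U + sig - U * k)


def _rhs_aug(s, y, f, sig):
    # augmented with the Hamiltonian source integral d(hsrc)/ds = R U dH0/ds
    base = _rhs(s, y[:5], f, sig)
    return base + (y[2] * y[1] * f.deriv(s),)


def _event_R(s, y, f, sig):
    return y[2]


_event_R.terminal = True
_event_R.direction = -1.0


def _event_psi(s, y, f, sig):
    return _PSI_LIMIT * _PSI_LIMIT - y[0] * y[0]


_event_psi.terminal = True
_event_psi.direction = -1.0


def _ham(y, H0_val, sig):
    """Dimensionless first integral (in units of 2 pi kappa / R0)."""
    psi, U, R, _z, g = y[:5]
    k = math.sin(psi) / R if R > 0 else 0.0
    u = U + H0_val - k
    return R * u * U - 0.5 * R * U * U + g * math.cos(psi) - sig * R


def _pole_state(a: float, g0: float, eps: float, f) -> np.ndarray:
    """Leading-order series start at s = eps (dimensionless)."""
    return np.array([a * eps, 2.0 * a - f(eps), eps, 0.5 * a * eps * eps, g0])


def _legs(eps: float, s1: float, breaks: Sequence[float]):
    pts = [eps]
    for b in sorted(breaks):
        if eps < b < s1:
            pts.append(b)
    pts.append(s1)
    return pts


def _integrate(x, fw, sig, cfg: SolverConfig, dense: bool = False,
               augmented: bool = False):
    """Integrate from the pole to s1.

    Returns (list of leg solutions, s_end, y_end, completed).
    """
    a, g0, s1 = x
    eps = cfg.pole_epsilon / cfg.R0
    y = _pole_state(a, g0, eps, fw)
    rhs = _rhs if not augmented else _rhs_aug
    if augmented:
        y = np.append(y, 0.0)
    sols = []
    pts = _legs(eps, s1, fw.breakpoints)
    for ta, tb in zip(pts[:-1], pts[1:]):
        sol = solve_ivp(rhs, (ta, tb), y, args=(fw, sig), method="DOP853",
                        rtol=cfg.rel_tol, atol=cfg.abs_tol,
                        events=(_event_R, _event_psi), dense_output=dense)
        sols.append(sol)
        if sol.status != 0 or not sol.success:
            return sols, sol.t[-1], sol.y[:, -1], False
        y = sol.y[:, -1].copy()
        if augmented:
            # Hamiltonian jump R * U * [H0] across a field discontinuity
            dH0 = fw(tb + 1e-12) - fw(tb - 1e-12)
            if dH0 != 0.0 and tb < s1:
                y[5] += y[2] * y[1] * dH0
    return sols, pts[-1], y, True


def _residuals(x, fw, sig, cfg: SolverConfig) -> np.ndarray:
    a, g0, s1 = x
    eps = cfg.pole_epsilon / cfg.R0
    if not np.all(np.isfinite(x)) or s1 <= 2.0 * eps:
        return np.array([1e3, 1e3, 1e3])
    _sols, s_end, y_end, ok = _integrate(x, fw, sig, cfg)
    h = _ham(y_end, fw(s_end), sig)
    res = np.array([y_end[0], y_end[2] - 1.0, h])
    if not ok:
        # smooth-ish penalty for shots that leave the physical domain
        res = res + 10.0 * (s1 - s_end)
    return res


def _solve_root(fw, sig, cfg: SolverConfig, x0):
    sol = _scipy_root(_residuals, np.asarray(x0, dtype=float),
                      args=(fw, sig, cfg), method="hybr",
                      options={"xtol": 1e-12, "eps": 1e-12,
                               "maxfev": cfg.max_shoot_iters})
    rnorm = float(np.max(np.abs(sol.fun)))
    ok = rnorm < cfg.root_tol
    return sol.x, ok, rnorm


_FLAT_X = np.array([0.0, 0.0, 1.0])


def march_field_family(field_fn: Callable[[float], CurvatureField],
                       config: SolverConfig,
                       x0: Optional[np.ndarray] = None,
                       logger=None) -> np.ndarray:
    """March the homotopy parameter t of ``field_fn(t)`` from 0 to 1.

    ``x0`` are converged (dimensionless) shooting unknowns for
    ``field_fn(0)`` (defaults to the flat solution).  Returns the converged
    unknowns for ``field_fn(1)``.  The step starts at
    ``1/continuation_steps`` and is halved on failure down to
    ``min_step_fraction``; successful steps double it back.
    """
    sig = config.sigma_tilde
    x = np.array(_FLAT_X if x0 is None else x0, dtype=float)
    t = 0.0
    dt0 = 1.0 / config.continuation_steps
    dt = dt0
    while t < 1.0 - 1e-12:
        t_try = min(1.0, t + dt)
        fw = _ScaledField(field_fn(t_try), config.R0)
        x_new, ok, rnorm = _solve_root(fw, sig, config, x)
        if logger is not None:
            logger.log(event="continuation_step", t=t_try, ok=ok,
                       residual=rnorm, x=list(x_new))
        if ok:
            t = t_try
            x = x_new
            dt = min(dt0, 2.0 * dt)
        else:
            dt *= 0.5
            if dt < config.min_step_fraction:
                raise ContinuationFailure(
                    f"continuation stalled at field fraction {t:.4f}", t)
    return x


# --------------------------------------------------------------------------
# solved profiles
# --------------------------------------------------------------------------

@dataclass
class MembraneProfile:
    """Discretized solution of the shape equations on [0, s1].

    Arrays are aligned on a common arc-length grid in physical units:
    ``s`` (nm), tangent angle ``psi`` (rad), radial and height coordinates
    ``R, z`` (nm), ``dpsi`` = psi'(s) (nm^-1), the Lagrange multiplier
    ``gamma`` (k_BT/nm) and the total curvature ``H`` (nm^-1).
    """

    s: np.ndarray
    psi: np.ndarray
    R: np.ndarray
    z: np.ndarray
    dpsi: np.ndarray
    gamma: np.ndarray
    H: np.ndarray
    s1: float
    config: SolverConfig
    field: Optional[CurvatureField] = None
    shoot_params: Optional[tuple] = None      # (psi'(0) 1/nm, gamma0 k_BT/nm, s1 nm)
    _x: Optional[np.ndarray] = None           # dimensionless shooting unknowns
    _hsrc: Optional[np.ndarray] = None        # Hamiltonian source integral

    # -- interpolation helpers -------------------------------------------
    def R_at(self, s):
        return np.interp(s, self.s, self.R)

    def psi_at(self, s):
        return np.interp(s, self.s, self.psi)

    def z_at(self, s):
        return np.interp(s, self.s, self.z)

    def H_at(self, s):
        return np.interp(s, self.s, self.H)

    def max_R(self, s_max: Optional[float] = None) -> float:
        m = slice(None) if s_max is None else self.s <= s_max
        return float(np.max(self.R[m]))

    def max_psi(self, s_max: Optional[float] = None) -> float:
        m = slice(None) if s_max is None else self.s <= s_max
        return float(np.max(self.psi[m]))

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the profile as CSV with a JSON metadata comment line."""
        meta = {
            "kappa": self.config.kappa, "sigma": self.config.sigma,
            "R0": self.config.R0, "s1": self.s1,
            "shoot_params": list(self.shoot_params) if self.shoot_params else None,
            "field": self.field.to_dict() if self.field is not None else None,
        }
        df = pd.DataFrame({
            "s_nm": self.s, "psi_rad": self.psi, "R_nm": self.R,
            "z_nm": self.z, "dpsi_per_nm": self.dpsi, "gamma": self.gamma,
        })
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            df.to_csv(fh, index=False)

    @staticmethod
    def from_csv(path) -> "MembraneProfile":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
            df = pd.read_csv(io.StringIO(first + fh.read()) if not first.startswith("#")
                             else fh)
        cfg = SolverConfig(kappa=meta.get("kappa", 20.0),
                           sigma=meta.get("sigma", 0.0),
                           R0=meta.get("R0", 500.0))
        fld = (CurvatureField.from_dict(meta["field"])
               if meta.get("field") else None)
        s = df["s_nm"].to_numpy()
        psi = df["psi_rad"].to_numpy()
        R = df["R_nm"].to_numpy()
        dpsi = df["dpsi_per_nm"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            H = dpsi + np.where(R > 0, np.sin(psi) / np.where(R > 0, R, 1.0), dpsi)
        sp = meta.get("shoot_params")
        return MembraneProfile(
            s=s, psi=psi, R=R, z=df["z_nm"].to_numpy(), dpsi=dpsi,
            gamma=df["gamma"].to_numpy(), H=H, s1=float(meta.get("s1", s[-1])),
            config=cfg, field=fld, shoot_params=tuple(sp) if sp else None,
            _x=None, _hsrc=None)


def _output_grid(fw, s1: float, eps: float, n: int) -> np.ndarray:
    """Arc-length grid (dimensionless), refined over the field's footprint."""
    support = fw.support
    if support <= 0:
        inner_end = 0.25 * s1
    else:
        inner_end = min(max(1.4 * support, 0.05), 0.8 * s1)
    n_inner = max(3, int(0.75 * n))
    n_outer = max(3, n - n_inner)
    nodes = np.concatenate([
        np.linspace(eps, inner_end, n_inner),
        np.linspace(inner_end, s1, n_outer + 1)[1:],
        np.asarray([b for b in fw.breakpoints if eps < b < s1]),
    ])
    return np.unique(nodes)


def _build_profile(x, field: CurvatureField, config: SolverConfig) -> MembraneProfile:
    fw = _ScaledField(field, config.R0)
    sig = config.sigma_tilde
    a, g0, s1 = x
    eps = config.pole_epsilon / config.R0
    sols, s_end, y_end, ok = _integrate(x, fw, sig, config, dense=True,
                                        augmented=True)
    if not ok:
        raise IntegrationFailure("converged parameters failed to integrate")
    grid = _output_grid(fw, s1, eps, config.grid_points)
    ys = np.empty((6, grid.size))
    # evaluate piecewise dense solutions (each leg's initial state already
    # carries the accumulated Hamiltonian-source jumps from _integrate)
    pts = _legs(eps, s1, fw.breakpoints)
    for sol, ta, tb in zip(sols, pts[:-1], pts[1:]):
        m = (grid >= ta - 1e-15) & (grid <= tb + 1e-15)
        ys[:, m] = sol.sol(np.clip(grid[m], sol.t[0], sol.t[-1]))
    psi_t, U_t, R_t, z_t, g_t, hsrc_t = ys
    H0_t = np.array([fw(sv) for sv in grid])
    H_t = U_t + H0_t
    sin_over_R = np.sin(psi_t) / R_t
    dpsi_t = H_t - sin_over_R
    # prepend the exact pole point
    s_phys = np.concatenate([[0.0], grid * config.R0])
    psi = np.concatenate([[0.0], psi_t])
    R = np.concatenate([[0.0], R_t * config.R0])
    z = np.concatenate([[0.0], z_t * config.R0])
    dpsi = np.concatenate([[a], dpsi_t]) / config.R0
    H = np.concatenate([[2.0 * a], H_t]) / config.R0
    gamma = (np.concatenate([[g0], g_t]) * TWO_PI * config.kappa / config.R0)
    hsrc = np.concatenate([[0.0], hsrc_t])
    shoot_params = (a / config.R0, TWO_PI * config.kappa * g0 / config.R0,
                    s1 * config.R0)
    return MembraneProfile(s=s_phys, psi=psi, R=R, z=z, dpsi=dpsi,
                           gamma=gamma, H=H, s1=s1 * config.R0,
                           config=config, field=field,
                           shoot_params=shoot_params,
                           _x=np.array(x, dtype=float), _hsrc=hsrc)


def _flat_profile(config: SolverConfig, field: Optional[CurvatureField]) -> MembraneProfile:
    n = config.grid_points
    s = np.linspace(0.0, config.R0, n)
    zeros = np.zeros(n)
    return MembraneProfile(
        s=s, psi=zeros.copy(), R=s.copy(), z=zeros.copy(),
        dpsi=zeros.copy(), gamma=TWO_PI * config.sigma * s, H=zeros.copy(),
        s1=config.R0, config=config, field=field,
        shoot_params=(0.0, 0.0, config.R0),
        _x=_FLAT_X.copy(), _hsrc=zeros.copy())


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def shape_equations_rhs(state, s: float, field: CurvatureField,
                        config: SolverConfig):
    """Euler-Lagrange right-hand side in physical units.

    ``state = (psi, psi', R, z, gamma)`` with gamma in k_BT/nm; returns the
    derivative of the state with respect to arc length s (nm).
    """
    psi, dpsi, R, _z, gamma = state
    if R <= 0:
        raise IntegrationFailure("R <= 0: evaluate the pole by series instead")
    kappa, sigma = config.kappa, config.sigma
    H0 = field._eval_scalar(s)
    dH0 = field._deriv_scalar(s)
    sinp, cosp = math.sin(psi), math.cos(psi)
    k = sinp / R
    U = dpsi + k - H0
    dU = gamma / (TWO_PI * kappa) * k
    ddpsi = dU + dH0 - (dpsi * cosp / R - sinp * cosp / R ** 2)
    dgamma = TWO_PI * (0.5 * kappa * U * U + sigma) - TWO_PI * kappa * U * k
    return (dpsi, ddpsi, cosp, sinp, dgamma)


def pole_series_start(a: float, gamma0: float, epsilon: float,
                      field: CurvatureField, config: SolverConfig):
    """Series-consistent state (psi, psi', R, z, gamma) at s = epsilon.

    ``a = psi'(0)``; the pole total curvature is H(0) = 2a.
    """
    return (a * epsilon, a, epsilon, 0.5 * a * epsilon ** 2, gamma0)


def shoot(field: CurvatureField, config: SolverConfig, guess) -> np.ndarray:
    """One shot from the pole: boundary residuals for ``guess``.

    ``guess = (psi'(0) [1/nm], gamma(0) [k_BT/nm], s1 [nm])``.  Returns
    ``(psi(s1), R(s1) - R0 [nm], Hamiltonian(s1) [k_BT/nm])``.
    """
    a, gamma0, s1 = guess
    x = np.array([a * config.R0,
                  gamma0 * config.R0 / (TWO_PI * config.kappa),
                  s1 / config.R0])
    fw = _ScaledField(field, config.R0)
    res = _residuals(x, fw, config.sigma_tilde, config)
    return np.array([res[0], res[1] * config.R0,
                     res[2] * TWO_PI * config.kappa / config.R0])


def solve_shape(field: CurvatureField, config: SolverConfig,
                warm_start: Optional[MembraneProfile] = None,
                logger=None) -> MembraneProfile:
    """Solve the shape equations under ``field``.

    With no warm start, the field amplitude is ramped from zero (flat
    membrane) by continuation.  A warm start from a nearby solved profile is
    attempted first and falls back to the amplitude ramp.
    """
    if field.amplitude == 0.0:
        return _flat_profile(config, field)
    fw = _ScaledField(field, config.R0)
    sig = config.sigma_tilde
    if warm_start is not None and warm_start._x is not None:
        x, ok, _ = _solve_root(fw, sig, config, warm_start._x)
        if ok:
            return _build_profile(x, field, config)
    x = march_field_family(lambda t: field.scaled(t), config, logger=logger)
    return _build_profile(x, field, config)


def hamiltonian_residual(profile: MembraneProfile,
                         field: Optional[CurvatureField] = None,
                         config: Optional[SolverConfig] = None) -> np.ndarray:
    """Corrected first-integral residual along the profile.

    Where ``H0`` varies the Hamiltonian is not conserved but satisfies
    ``dH/ds = 2 pi kappa R U dH0/ds``; the returned residual subtracts that
    source integral, so it vanishes (to integration tolerance) on a true
    solution.  Units: k_BT/nm.
    """
    field = field if field is not None else profile.field
    cfg = config if config is not None else profile.config
    R0, kappa = cfg.R0, cfg.kappa
    st = profile.s / R0
    Rt = profile.R / R0
    gt = profile.gamma * R0 / (TWO_PI * kappa)
    H0 = field(profile.s) * R0 if field is not None else np.zeros_like(st)
    Ht = profile.H * R0
    Ut = Ht - H0
    ut = profile.dpsi * R0
    h = (Rt * ut * Ut - 0.5 * Rt * Ut ** 2 + gt * np.cos(profile.psi)
         - cfg.sigma_tilde * Rt)
    if profile._hsrc is not None:
        src = profile._hsrc
    else:
        # trapezoid fallback for profiles without the integrated source
        dH0ds = (field.derivative(profile.s) * R0 ** 2
                 if field is not None else np.zeros_like(st))
        integrand = Rt * Ut * dH0ds
        src = np.concatenate([[0.0],
                              np.cumsum(0.5 * (integrand[1:] + integrand[:-1])
                                        * np.diff(st))])
        if field is not None:
            for b in field.breakpoints:
                bt = b / R0
                jump = (np.interp(bt, st, Rt) * np.interp(bt, st, Ut)
                        * (field(b + 1e-9) - field(b - 1e-9)) * R0)
                src = src + np.where(st > bt, jump, 0.0)
    res = h - h[0] - src
    return res * TWO_PI * kappa / R0
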