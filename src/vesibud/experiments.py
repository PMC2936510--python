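"""Orchestration of the budding experiments.

The computational experiments this module drives:

* ``run_area_sweep`` -- solve shapes along a ladder of coat extents s0 and
  tabulate the energetics; detect the critical coat area at which the
  mature-bud criterion (constricted neck + overhang) first holds.
* ``run_kappa_sweep`` -- for each bending rigidity, recalibrate the epsin
  range b self-consistently, grow the coat to maturity and record the bud
  diameter and epsin count.
* ``run_distribution`` -- build E_t(A_a) on the capsid ladder for the
  wildtype (WT) or CLAP-abrogated scenario and Boltzmann-weight the
  four intermediate categories.
* ``clathrin_scaling`` -- closed-form coat scaling relations.

Sweep semantics: the coat extent s0 is the continuous sweep variable.  For
the shell model, a shell is present at every lattice multiple (0, 18.5,
37, ... nm) not exceeding s0; the coat area ``A_a(s0)`` and neck radius
``R(s0)`` vary continuously with s0 between shell completions.  New shells
are ramped in by continuation (fractional outermost shell) purely as a
numerical homotopy; evaluated configurations always carry complete shells.

All computations are deterministic; random seeds are accepted for
interface uniformity and recorded in the log only.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field as dfield, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fields import (LATTICE_SPACING, CAPSID_H0, EPSIN_C0, EpsinShellField,
                     capsid_field)
from .solver import (ContinuationFailure, MembraneProfile, SolverConfig,
                     march_field_family, solve_shape, _build_profile)
from .energetics import (EnergyParams, MaturityRules, EnergyBreakdown,
                         calibrate_b, classify_intermediate, coat_area,
                         count_epsins, deformation_energy,
                         energy_breakdown, epsin_density_count,
                         intermediate_distribution, is_mature, neck_radius,
                         shell_positions_up_to, IntermediateDistribution)

#: per-epsin binding energy by scenario: full (ENTH+CLAP) in wildtype,
#: ENTH-only when the CLAP-clathrin interaction is abrogated.
SCENARIO_EPS = {"WT": -23.0, "CLAP": -14.0}


class JsonlLogger:
    """Minimal structured JSON-lines logger for solver diagnostics."""

    def __init__(self, path=None):
        self._fh = open(path, "a") if path else None

    def log(self, **kw):
        if self._fh is not None:
            self._fh.write(json.dumps(kw, default=str) + "\n")
            self._fh.flush()

    def close(self):
        if self._fh is not None:
            self._fh.close()
            self._fh = None


@dataclass
class ExperimentConfig:
    """One experiment stanza (defaults follow the model's parameter table)."""

    experiment: str = "area_sweep"      # area_sweep|kappa_sweep|calibrate|distribution|scaling
    model: str = "capsid"               # epsin_shells | capsid
    scenario: str = "WT"                # WT | CLAP
    solver: SolverConfig = dfield(default_factory=SolverConfig)
    energy: EnergyParams = dfield(default_factory=EnergyParams)
    rules: MaturityRules = dfield(default_factory=MaturityRules)
    C0: float = EPSIN_C0
    b: Optional[float] = None           # None -> calibrate self-consistently
    spacing: float = LATTICE_SPACING
    capsid_H0: float = CAPSID_H0
    s0_grid: tuple = tuple(np.arange(10.0, 80.0 + 1e-9, 5.0))
    kappa_grid: tuple = (10.0, 20.0, 30.0, 40.0, 50.0)
    max_shells: int = 8
    E_r_target: float = 14.0
    out_dir: Optional[str] = None
    seed: int = 0                       # reserved; the pipeline is deterministic

    def __post_init__(self):
        if len(self.s0_grid) == 0 or list(self.s0_grid) != sorted(self.s0_grid):
            raise ValueError("s0_grid must be non-empty and sorted")
        if len(self.kappa_grid) == 0 or list(self.kappa_grid) != sorted(self.kappa_grid):
            raise ValueError("kappa_grid must be non-empty and sorted")
        if self.scenario not in SCENARIO_EPS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.model not in ("epsin_shells", "capsid"):
            raise ValueError(f"unknown model {self.model!r}")

    @staticmethod
    def from_yaml(path, **overrides) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        solver = SolverConfig(**raw.pop("solver", {}))
        energy = EnergyParams(**raw.pop("energy", {}))
        rules = MaturityRules(**raw.pop("rules", {}))
        for key in ("s0_grid", "kappa_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return ExperimentConfig(solver=solver, energy=energy, rules=rules,
                                **raw)


# --------------------------------------------------------------------------
# ladder solvers
# --------------------------------------------------------------------------

def solve_capsid_ladder(s0_values: Sequence[float], config: SolverConfig,
                        H0: float = CAPSID_H0, march_step: float = 2.5,
                        logger=None):
    """Solve the capsid model at each coat extent, marching s0 upward.

    Returns ``(profiles, failures)``: a dict s0 -> MembraneProfile for every
    extent reached, and the list of (s0, last_reached_fraction) for extents
    the continuation could not reach (e.g. past complete bud closure).
    """
    s0_values = sorted(float(v) for v in s0_values)
    profiles: dict = {}
    failures: list = []
    x = None
    s0_prev = 0.0
    for s0 in s0_values:
        if s0 <= 0:
            profiles[s0] = solve_shape(capsid_field(H0, 0.0), config)
            continue
        n_sub = max(1, int(math.ceil((s0 - s0_prev) / march_step)))
        try:
            if x is None:
                prof = solve_shape(capsid_field(H0, s0), config, logger=logger)
                x = prof._x
            else:
                for i in range(n_sub):
                    lo = s0_prev + (s0 - s0_prev) * i / n_sub
                    hi = s0_prev + (s0 - s0_prev) * (i + 1) / n_sub
                    x = march_field_family(
                        lambda t, lo=lo, hi=hi: capsid_field(
                            H0, lo + t * (hi - lo)),
                        config, x0=x, logger=logger)
                prof = _build_profile(x, capsid_field(H0, s0), config)
        except ContinuationFailure as exc:
            failures.append((s0, exc.last_fraction))
            if logger is not None:
                logger.log(event="ladder_failure", s0=s0,
                           last_fraction=exc.last_fraction)
            break
        profiles[s0] = prof
        s0_prev = s0
    return profiles, failures


def grow_shell_profiles(config: SolverConfig, b: float, C0: float = EPSIN_C0,
                        spacing: float = LATTICE_SPACING, max_shells: int = 8,
                        logger=None):
    """Solve the shell model for 1..max_shells complete shells.

    Each new shell is ramped in by continuation (fractional outermost
    amplitude).  Returns ``(profiles, failures)`` keyed by shell count;
    growth stops at the first shell the membrane cannot accommodate
    (complete closure of the bud during the ramp).
    """
    profiles: dict = {}
    failures: list = []
    prof = solve_shape(EpsinShellField(C0=C0, b=b, n_shells=1,
                                       spacing=spacing), config,
                       logger=logger)
    profiles[1] = prof
    x = prof._x
    for n in range(2, max_shells + 1):
        try:
            x = march_field_family(
                lambda t, n=n: EpsinShellField(C0=C0, b=b, n_shells=n,
                                               spacing=spacing, partial=t),
                config, x0=x, logger=logger)
        except ContinuationFailure as exc:
            failures.append((n, exc.last_fraction))
            if logger is not None:
                logger.log(event="shell_growth_stop", n_shells=n,
                           last_fraction=exc.last_fraction)
            break
        profiles[n] = _build_profile(
            x, EpsinShellField(C0=C0, b=b, n_shells=n, spacing=spacing),
            config)
    return profiles, failures


def _shell_count(s0: float, spacing: float) -> int:
    return int(math.floor(s0 / spacing + 1e-9)) + 1


def coat_extent_limit(profile: MembraneProfile, bud_region: float = 150.0) -> float:
    """Largest physically meaningful coat extent on a profile.

    For an overhung bud the coat cannot extend past the neck (the minimum
    of R(s) beyond the bud equator); for shallow profiles the whole patch
    is available.
    """
    if profile.max_psi() <= 0.5 * math.pi:
        return profile.s1
    dR = np.diff(profile.R)
    falling = np.nonzero(dR < 0)[0]
    if falling.size == 0:
        return profile.s1
    i_eq = int(falling[0])                      # bud equator: R stops rising
    rising = np.nonzero(dR[i_eq:] > 0)[0]
    if rising.size == 0:
        return profile.s1
    i_neck = i_eq + int(rising[0])              # neck: R starts rising again
    return float(profile.s[i_neck])


def _breakdown_row(prof: MembraneProfile, s0: float, cfg: ExperimentConfig,
                   n_epsins=None, eps_epsin=None,
                   round_for_binding=True) -> dict:
    bd = energy_breakdown(prof, s0, energy=cfg.energy,
                          kappa=cfg.solver.kappa, spacing=cfg.spacing,
                          n_epsins=n_epsins, eps_epsin=eps_epsin,
                          round_for_binding=round_for_binding,
                          rules=cfg.rules)
    row = {k: getattr(bd, k) for k in
           ("s0", "E_c", "E_a", "E_r", "E_t", "A_a", "neck_radius",
            "n_epsins", "n_epsins_rounded", "bud_diameter", "category")}
    row["mature"] = is_mature(prof, s0, cfg.rules)
    return row


# --------------------------------------------------------------------------
# experiments
# --------------------------------------------------------------------------

def run_area_sweep(config: ExperimentConfig, logger=None):
    """Sweep the coat extent; tabulate energetics and find the critical area.

    Returns ``(table, profiles, summary)``.  ``profiles`` is keyed by s0 for
    the capsid model and by shell count for the shell model; ``summary``
    holds the first mature grid point and a bisection-refined estimate of
    the critical coat area.
    """
    cfg = config
    grid = [float(v) for v in cfg.s0_grid]
    rows = []
    if cfg.model == "capsid":
        profiles, failures = solve_capsid_ladder(grid, cfg.solver,
                                                 H0=cfg.capsid_H0,
                                                 logger=logger)
        prof_for = lambda s0: profiles.get(s0)
    else:
        b = cfg.b
        if b is None:
            b = calibrate_b(cfg.solver.kappa, cfg.E_r_target, cfg.C0,
                            solver=cfg.solver).b
        shell_profiles, failures = grow_shell_profiles(
            cfg.solver, b, C0=cfg.C0, spacing=cfg.spacing,
            max_shells=cfg.max_shells, logger=logger)
        profiles = shell_profiles
        n_max = max(shell_profiles)

        # a shell the membrane cannot accommodate (the bud closes while it
        # assembles) never forms; larger coat extents are evaluated on the
        # largest assembled-shell configuration
        def prof_for(s0):
            n = _shell_count(s0, cfg.spacing)
            return shell_profiles.get(min(n, n_max))

    for s0 in grid:
        prof = prof_for(s0)
        if prof is None or s0 > prof.s1:
            continue
        if cfg.model == "epsin_shells" and s0 > coat_extent_limit(prof):
            continue        # the coat cannot extend past the neck
        rows.append(_breakdown_row(prof, s0, cfg))
    table = pd.DataFrame(rows)

    summary = {"model": cfg.model, "kappa": cfg.solver.kappa,
               "failures": failures}
    if cfg.model == "epsin_shells":
        summary["b"] = b
    mature_rows = table[table["mature"]] if len(table) else table
    if len(mature_rows):
        first = mature_rows.iloc[0]
        summary.update(first_mature_s0=float(first["s0"]),
                       first_mature_A_a=float(first["A_a"]),
                       first_mature_n_epsins=float(first["n_epsins"]))
        # refine the onset of maturity by bisection on s0
        lo_candidates = table[(table["s0"] < first["s0"]) & (~table["mature"])]
        if len(lo_candidates):
            lo = float(lo_candidates.iloc[-1]["s0"])
            hi = float(first["s0"])
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                prof = prof_for(mid)
                if prof is not None and is_mature(prof, mid, cfg.rules):
                    hi = mid
                else:
                    lo = mid
                if hi - lo < 1e-3:
                    break
            prof = prof_for(hi)
            summary.update(critical_s0=hi,
                           critical_A_a=coat_area(prof, hi))
    if cfg.out_dir:
        _write_sweep_outputs(cfg, table, profiles, summary)
    return table, profiles, summary


def _march_partial_shell_to_maturity(cfg: ExperimentConfig,
                                     solver: SolverConfig, b: float,
                                     n_next: int, x0, logger=None):
    """Grow a fractional outermost shell until the mature-bud criterion holds.

    For some rigidities no integer-shell configuration has a constricted
    neck (the next complete shell cannot assemble); since shells assemble
    epsin by epsin, a partially populated outer ring is a physical
    intermediate.  Returns ``(partial, profile, mode)`` with mode
    ``"partial_shell"`` at the first mature fraction (0.05 resolution), or
    ``"fold_snap"`` with the last solvable pre-fold state when the branch
    terminates (the bud snaps toward closure) before the criterion holds.
    """
    spacing = cfg.spacing
    s0 = (n_next - 1) * spacing
    lam, x, dl = 0.0, np.asarray(x0, float), 0.05
    prof = None
    while lam < 1.0 - 1e-9:
        lam_try = min(1.0, lam + dl)
        field = EpsinShellField(C0=cfg.C0, b=b, n_shells=n_next,
                                spacing=spacing, partial=lam_try)
        try:
            x_new = march_field_family(
                lambda t, a=lam, c=lam_try: EpsinShellField(
                    C0=cfg.C0, b=b, n_shells=n_next, spacing=spacing,
                    partial=a + t * (c - a)),
                solver, x0=x, logger=logger)
        except ContinuationFailure:
            dl *= 0.5
            if dl < 0.01:
                break
            continue
        lam, x = lam_try, x_new
        prof = _build_profile(x, field, solver)
        if s0 <= prof.s1 and is_mature(prof, s0, cfg.rules):
            return lam, prof, "partial_shell"
    return (lam, prof, "fold_snap") if prof is not None else (None, None, None)


def run_kappa_sweep(config: ExperimentConfig, logger=None) -> pd.DataFrame:
    """Self-consistent b and mature-bud geometry across bending rigidities.

    For each kappa: recalibrate b (single-epsin energy balance), grow
    shells to maturity and record the shell count, epsin census, coat area
    and bud diameter at the first mature coat extent.  Per-kappa failures
    are recorded as NaN rows and the sweep continues.
    """
    cfg = config
    rows = []
    for kappa in cfg.kappa_grid:
        solver = replace(cfg.solver, kappa=float(kappa))
        row = {"kappa": float(kappa)}
        try:
            cal = calibrate_b(float(kappa), cfg.E_r_target, cfg.C0,
                              solver=solver)
            row["b"] = cal.b
            # stiffer membranes bud at larger diameters; sweep far enough
            # in coat extent for the neck to constrict
            s0_max = max(90.0, 105.0 * math.sqrt(float(kappa) / 20.0))
            sub = replace(cfg, solver=solver, b=cal.b, model="epsin_shells",
                          s0_grid=tuple(np.arange(1.0, s0_max + 1e-9, 1.0)))
            table, profiles, summary = run_area_sweep(sub, logger=logger)
            if "first_mature_s0" in summary:
                s0c = summary["critical_s0"]
                n = min(_shell_count(s0c, cfg.spacing), max(profiles))
                prof = profiles[n]
                census = count_epsins(
                    prof, shell_positions_up_to(
                        min(s0c, (n - 1) * cfg.spacing), cfg.spacing),
                    cfg.spacing)
                row.update(n_shells_to_mature=float(n), s0_mature=s0c,
                           A_a=coat_area(prof, s0c),
                           n_epsins=census.total,
                           n_epsins_rounded=census.total_rounded,
                           bud_diameter=2.0 * prof.max_R(s0c),
                           E_c=deformation_energy(prof, float(kappa)),
                           maturity_mode="complete_shells")
            else:
                # no complete-shell configuration constricts: refine with a
                # partially assembled outermost ring
                n_next = max(profiles) + 1
                lam, prof, mode = _march_partial_shell_to_maturity(
                    cfg, solver, cal.b, n_next, profiles[max(profiles)]._x,
                    logger=logger)
                if prof is not None:
                    s0c = (n_next - 1) * cfg.spacing
                    census = count_epsins(
                        prof, shell_positions_up_to(s0c, cfg.spacing),
                        cfg.spacing)
                    n_total = census.total - (1.0 - lam) * census.counts[-1]
                    row.update(n_shells_to_mature=n_next - 1 + lam,
                               s0_mature=s0c, A_a=coat_area(prof, s0c),
                               n_epsins=n_total,
                               n_epsins_rounded=int(np.rint(n_total)),
                               bud_diameter=2.0 * prof.max_R(s0c),
                               E_c=deformation_energy(prof, float(kappa)),
                               maturity_mode=mode)
        except Exception as exc:   # pragma: no cover - defensive per-kappa guard
            row["error"] = str(exc)
            if logger is not None:
                logger.log(event="kappa_sweep_failure", kappa=kappa,
                           error=str(exc))
        rows.append(row)
    df = pd.DataFrame(rows)
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        df.to_csv(os.path.join(cfg.out_dir, "sweep_summary.csv"), index=False)
    return df


def run_distribution(config: ExperimentConfig, logger=None,
                     profiles: Optional[dict] = None):
    """Boltzmann distribution of capsid-ladder intermediates for a scenario.

    E_t(A_a) = E_c + E_a + eps_epsin * N(A_a) with the smooth lattice-cell
    density N(A_a) = max(1, A_a/spacing^2); eps_epsin is -23 k_BT (WT,
    ENTH+CLAP) or -14 k_BT (CLAP antibody, ENTH only).  Ladder points past
    complete bud closure are skipped (recorded in the log).

    Returns ``(table, distribution, profiles)``.
    """
    cfg = config
    eps = SCENARIO_EPS[cfg.scenario]
    if profiles is None:
        profiles, _failures = solve_capsid_ladder(
            [s for s in cfg.s0_grid if s > 0], cfg.solver, H0=cfg.capsid_H0,
            logger=logger)
    rows = []
    breakdowns = []
    for s0, prof in profiles.items():
        A_a = coat_area(prof, s0)
        n_sm = epsin_density_count(A_a, cfg.spacing)
        row = _breakdown_row(prof, s0, cfg, n_epsins=n_sm, eps_epsin=eps,
                             round_for_binding=False)
        census = count_epsins(prof, shell_positions_up_to(s0, cfg.spacing),
                              cfg.spacing)
        row["n_epsins_census"] = census.total
        rows.append(row)
        breakdowns.append(energy_breakdown(
            prof, s0, energy=cfg.energy, kappa=cfg.solver.kappa,
            spacing=cfg.spacing, n_epsins=n_sm, eps_epsin=eps,
            round_for_binding=False, rules=cfg.rules))
    table = pd.DataFrame(rows)
    dist = intermediate_distribution(breakdowns)
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        table.to_csv(os.path.join(cfg.out_dir,
                                  f"energies_{cfg.scenario}.csv"), index=False)
        with open(os.path.join(cfg.out_dir,
                               f"distribution_{cfg.scenario}.json"), "w") as fh:
            json.dump(dist.to_dict(), fh, indent=2)
    return table, dist, profiles


# --------------------------------------------------------------------------
# closed-form clathrin scaling relations
# --------------------------------------------------------------------------

def clathrin_scaling(d: float) -> dict:
    """Empirical coat scalings for a vesicle of diameter d (nm).

    Number of triskelia ~ 0.031 d^(7/4) (rounded to nearest integer) and
    coat area pi d^2.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    n_real = 0.031 * d ** 1.75
    return {"n_triskelia": int(np.rint(n_real)), "n_triskelia_real": n_real,
            "coat_area_nm2": math.pi * d * d}


def tubule_C0(diameter: float) -> float:
    """Curvature of a membrane tubule of given diameter: C0 = 2/d (nm^-1)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return 2.0 / diameter


# --------------------------------------------------------------------------
# output plumbing
# --------------------------------------------------------------------------

def _write_sweep_outputs(cfg: ExperimentConfig, table: pd.DataFrame,
                         profiles: dict, summary: dict) -> None:
    os.makedirs(cfg.out_dir, exist_ok=True)
    table.to_csv(os.path.join(cfg.out_dir, "energies.csv"), index=False)
    with open(os.path.join(cfg.out_dir, "sweep_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    prof_dir = os.path.join(cfg.out_dir, "profiles")
    os.makedirs(prof_dir, exist_ok=True)
    for key, prof in profiles.items():
        prof.to_csv(os.path.join(prof_dir, f"profile_{key}.csv"))
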