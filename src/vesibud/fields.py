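"""Spontaneous-curvature fields imposed on the membrane by coat proteins.

Every field maps meridional arc length ``s`` (nm, measured from the pole of
the axisymmetric patch) to an imposed curvature ``H0(s)`` in nm^-1, using the
sum-of-principal-curvatures convention (a sphere of diameter ``d`` has total
curvature ``4/d``; a tubule of diameter ``d`` has ``2/d``).

Three field kinds are provided:

* ``single_epsin_field`` -- the Gaussian curvature footprint of one membrane
  inserted epsin ENTH domain, ``H0(s) = C0 * exp(-(s - c)^2 / b^2)``.
* ``shell_field`` -- additive superposition of concentric epsin shells
  templated by the clathrin lattice at 18.5 nm arc spacing.
* ``capsid_field`` -- a step function, constant curvature under the coat and
  zero outside, the simplest stand-in for the collective epsin field.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from typing import ClassVar

import numpy as np

#: Clathrin lattice vertex spacing (nm), which templates the epsin shells.
LATTICE_SPACING = 18.5
#: Plateau curvature of the capsid (step) model, nm^-1 (= 4/d for d = 50 nm).
CAPSID_H0 = 0.08
#: Peak curvature induced by one epsin, nm^-1 (from 20-nm tubule diameter).
EPSIN_C0 = 0.1


class CurvatureField:
    """Abstract spontaneous-curvature field H0(s).

    Subclasses are frozen dataclasses; field evaluation is pure.
    """

    kind: ClassVar[str] = "abstract"

    def __call__(self, s):
        """Evaluate H0 at arc length ``s`` (nm); accepts scalars or arrays."""
        raise NotImplementedError

    def derivative(self, s):
        """dH0/ds at ``s`` (defined piecewise; zero a.e. for step fields)."""
        raise NotImplementedError

    def _eval_scalar(self, s: float) -> float:
        """Fast scalar evaluation used in the ODE right-hand side."""
        return float(self(s))

    def _deriv_scalar(self, s: float) -> float:
        return float(self.derivative(s))

    @property
    def amplitude(self) -> float:
        """Overall amplitude scale (zero amplitude means a flat field)."""
        raise NotImplementedError

    @property
    def breakpoints(self) -> tuple:
        """Arc-length positions (nm) where H0 is discontinuous."""
        return ()

    @property
    def support(self) -> float:
        """Arc length (nm) beyond which the field is negligible."""
        raise NotImplementedError

    def scaled(self, factor: float) -> "CurvatureField":
        """Return a copy with the amplitude multiplied by ``factor``."""
        raise NotImplementedError

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["kind"] = self.kind
        return d

    @staticmethod
    def from_dict(d: dict) -> "CurvatureField":
        d = dict(d)
        kind = d.pop("kind")
        cls = _FIELD_KINDS.get(kind)
        if cls is None:
            raise ValueError(f"unknown curvature field kind: {kind!r}")
        return cls(**d)

    def to_csv(self, path, s_max: float | None = None, n: int = 501) -> None:
        """Export the field sampled on [0, s_max] as two-column CSV."""
        if s_max is None:
            s_max = max(self.support * 1.5, 1.0)
        s = np.linspace(0.0, s_max, n)
        np.savetxt(path, np.column_stack([s, self(s)]), delimiter=",",
                   header="s_nm,H0_per_nm", comments="")


@dataclass(frozen=True)
class SingleEpsinField(CurvatureField):
    """Gaussian curvature field of a single epsin centered at ``center``."""

    kind: ClassVar[str] = "single_epsin"
    C0: float = EPSIN_C0
    b: float = 8.3
    center: float = 0.0

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("Gaussian range b must be positive")

    def __call__(self, s):
        x = (np.asarray(s, dtype=float) - self.center) / self.b
        return self.C0 * np.exp(-x * x)

    def derivative(self, s):
        x = (np.asarray(s, dtype=float) - self.center) / self.b
        return self.C0 * np.exp(-x * x) * (-2.0 * x / self.b)

    def _eval_scalar(self, s):
        x = (s - self.center) / self.b
        return self.C0 * math.exp(-x * x)

    def _deriv_scalar(self, s):
        x = (s - self.center) / self.b
        return -2.0 * x / self.b * self.C0 * math.exp(-x * x)

    @property
    def amplitude(self):
        return abs(self.C0)

    @property
    def support(self):
        return self.center + 6.0 * self.b

    def scaled(self, factor):
        return replace(self, C0=self.C0 * factor)


@dataclass(frozen=True)
class EpsinShellField(CurvatureField):
    """Sum of Gaussian shells at arc positions 0, spacing, 2*spacing, ...

    ``partial`` scales the outermost shell only; it is the natural
    continuation parameter when a new shell is added to a growing coat
    (partial = 1 is a complete shell).
    """

    kind: ClassVar[str] = "epsin_shells"
    C0: float = EPSIN_C0
    b: float = 8.3
    n_shells: int = 1
    spacing: float = LATTICE_SPACING
    partial: float = 1.0

    def __post_init__(self):
        if self.n_shells < 1:
            raise ValueError("need at least one epsin shell")
        if self.b <= 0 or self.spacing <= 0:
            raise ValueError("b and spacing must be positive")

    @property
    def shell_positions(self) -> tuple:
        return tuple((i - 1) * self.spacing for i in range(1, self.n_shells + 1))

    @property
    def _amps(self) -> tuple:
        a = [self.C0] * self.n_shells
        a[-1] *= self.partial
        return tuple(a)

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        for pos, amp in zip(self.shell_positions, self._amps):
            x = (s - pos) / self.b
            out = out + amp * np.exp(-x * x)
        return out

    def derivative(self, s):
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        for pos, amp in zip(self.shell_positions, self._amps):
            x = (s - pos) / self.b
            out = out + amp * np.exp(-x * x) * (-2.0 * x / self.b)
        return out

    def _eval_scalar(self, s):
        tot = 0.0
        for pos, amp in zip(self.shell_positions, self._amps):
            x = (s - pos) / self.b
            tot += amp * math.exp(-x * x)
        return tot

    def _deriv_scalar(self, s):
        tot = 0.0
        for pos, amp in zip(self.shell_positions, self._amps):
            x = (s - pos) / self.b
            tot += -2.0 * x / self.b * amp * math.exp(-x * x)
        return tot

    @property
    def amplitude(self):
        return abs(self.C0)

    @property
    def support(self):
        return self.shell_positions[-1] + 6.0 * self.b

    def scaled(self, factor):
        return replace(self, C0=self.C0 * factor)


@dataclass(frozen=True)
class CapsidField(CurvatureField):
    """Step field: H0(s) = H0_capsid for s < s0, zero for s >= s0.

    The step is right-open: the coat edge itself carries no imposed
    curvature.
    """

    kind: ClassVar[str] = "capsid"
    H0_capsid: float = CAPSID_H0
    s0: float = 50.0

    def __post_init__(self):
        if self.s0 < 0:
            raise ValueError("coat extent s0 must be non-negative")

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        return np.where(s < self.s0, self.H0_capsid, 0.0)

    def derivative(self, s):
        return np.zeros_like(np.asarray(s, dtype=float))

    def _eval_scalar(self, s):
        return self.H0_capsid if s < self.s0 else 0.0

    def _deriv_scalar(self, s):
        return 0.0

    @property
    def amplitude(self):
        return abs(self.H0_capsid) if self.s0 > 0 else 0.0

    @property
    def breakpoints(self):
        if self.s0 > 0 and self.H0_capsid != 0.0:
            return (self.s0,)
        return ()

    @property
    def support(self):
        return self.s0

    def scaled(self, factor):
        return replace(self, H0_capsid=self.H0_capsid * factor)


_FIELD_KINDS = {
    cls.kind: cls for cls in (SingleEpsinField, EpsinShellField, CapsidField)
}


def single_epsin_field(C0: float = EPSIN_C0, b: float = 8.3,
                       center: float = 0.0) -> SingleEpsinField:
    """Gaussian field of one epsin: H0(s) = C0 exp(-(s-center)^2/b^2)."""
    if C0 < 0:
        raise ValueError("C0 must be non-negative")
    return SingleEpsinField(C0=C0, b=b, center=center)


def shell_field(C0: float = EPSIN_C0, b: float = 8.3, n_shells: int = 1,
                spacing: float = LATTICE_SPACING) -> EpsinShellField:
    """Concentric epsin shells at 0, spacing, 2*spacing, ... (arc length)."""
    if C0 < 0:
        raise ValueError("C0 must be non-negative")
    return EpsinShellField(C0=C0, b=b, n_shells=n_shells, spacing=spacing)


def capsid_field(H0: float = CAPSID_H0, s0: float = 50.0) -> CapsidField:
    """Step ("capsid") field: H0 under the coat (s < s0), zero outside."""
    return CapsidField(H0_capsid=H0, s0=s0)
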