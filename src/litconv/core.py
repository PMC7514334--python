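"""Characteristic performance functions of the two-flux converter.

Everything here is expressed in the reduced (dimensionless) variables
of the linear flux-force model with phenomenological stoichiometry
Z = 1: the operating variable is the force ratio x = X1/X2 and the
single shape parameter is the degree of coupling q.  Reduced values are
converted to absolute ones by the prefactor T*L22*Delta^2 carried by
:class:`DriveConditions` (entropy production divides by T).

Reduced closed forms (all polynomial or rational in x):

====================  =======================================
efficiency            eta = -x(q + Zx) / (qx + 1/Z)
power                 p = -x(x + q)
entropy production    s = x^2 + 2qx + 1
ecological function   e = p - s = -(2x^2 + 3qx + 1)
efficient power       pe = eta * p = x^2 (x + q)^2 / (qx + 1)
====================  =======================================

The physical working range (non-negative power delivered against the
output force) is x in [-q, 0].  At complete coupling (q = 1) the
efficiency reduces to eta = -x and the converter can reach the
reversible point x = -1 where dissipation vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "DriveConditions",
    "OperatingPoint",
    "FunctionValues",
    "FUNCTION_IDS",
    "efficiency",
    "eta_max",
    "x_from_eta",
    "power_output",
    "entropy_production",
    "ecological_function",
    "efficient_power",
    "characteristic_vs_eta",
    "evaluate",
    "reduced_function",
]

Branch = Literal["upper", "lower"]

#: Identifiers of the characteristic functions, as used across the package.
FUNCTION_IDS = ("power", "ecological", "efficient_power")


@dataclass(frozen=True)
class DriveConditions:
    """Absolute scale of the reduced performance functions.

    Parameters
    ----------
    T
        Temperature (K).
    Delta
        Driving force X2 = mu1 - mu4 (energy per mole, or dimensionless
        in reduced mode).
    L22
        Diagonal phenomenological coefficient, ``A*(beta-1)``.

    The attribute :attr:`scale` = T*L22*Delta^2 multiplies reduced power,
    ecological and efficient-power values; absolute entropy production
    uses ``scale/T = L22*Delta^2`` so that the ecological identity
    E = P - T*sigma holds exactly in absolute units as well.
    """

    T: float = 1.0
    Delta: float = 1.0
    L22: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got T={self.T}")
        if self.L22 <= 0:
            raise ValueError(f"L22 must be positive, got L22={self.L22}")
        if self.Delta == 0:
            raise ValueError("driving force Delta must be nonzero")

    @property
    def scale(self) -> float:
        """Prefactor T*L22*Delta^2 converting reduced values to absolute."""
        return self.T * self.L22 * self.Delta**2

    @property
    def sigma_scale(self) -> float:
        """Prefactor L22*Delta^2 (= scale/T) for absolute entropy production."""
        return self.L22 * self.Delta**2


def _check_q(q: float) -> None:
    if not 0.0 < q <= 1.0:
        raise ValueError(f"degree of coupling q must lie in (0, 1], got q={q}")


def efficiency(x, q: float, Z: float = 1.0):
    """Efficiency eta = -x(q + Zx) / (qx + 1/Z) of the converter.

    Accepts scalar or array ``x``.  Zero at x = 0 (no output force) and
    at x = -q/Z (zero output flux); has a pole at x = -1/(qZ), outside
    the working range.  For q = 1, Z = 1 it reduces to eta = -x.
    """
    _check_q(q)
    if Z <= 0:
        raise ValueError(f"phenomenological stoichiometry Z must be > 0, got {Z}")
    x = np.asarray(x, dtype=float)
    denom = q * x + 1.0 / Z
    if np.any(denom == 0.0):
        raise ZeroDivisionError(
            f"efficiency pole at x = -1/(q*Z) = {-1.0 / (q * Z):.6g}: "
            "the input flux J2 vanishes there"
        )
    out = -x * (q + Z * x) / denom
    return out.item() if out.ndim == 0 else out


def eta_max(q: float) -> float:
    """Maximal attainable efficiency ``q^2 / (1 + sqrt(1-q^2))^2``.

    The smaller root of eta^2 - (4/q^2 - 2) eta + 1 = 0, i.e. the
    efficiency at which the two force-ratio branches of
    :func:`x_from_eta` coincide.  Equals 1 iff q = 1.
    """
    _check_q(q)
    return q**2 / (1.0 + math.sqrt(1.0 - q**2)) ** 2


def x_from_eta(eta: float, q: float) -> tuple[float, float]:
    """Invert eta(x) at Z = 1: both force-ratio roots ``(upper, lower)``.

    Roots of x^2 + q(1+eta)x + eta = 0, equivalently
    x = q[-(1+eta) +/- R]/2 with R = sqrt((1+eta)^2 - 4 eta/q^2).
    "upper" is the root of smaller magnitude (the + sign), "lower" the
    larger; they coincide iff eta = eta_max(q).  At eta = 0 the roots
    are the two zero-efficiency points {0, -q}.

    At complete coupling (q = 1) the quadratic factors as
    (x + 1)(x + eta): the lower root is pinned at the efficiency pole
    x = -1 (the reversible point, where clearing the denominator
    introduced it) and only the upper root x = -eta is a genuine
    operating point.
    """
    _check_q(q)
    if eta < 0:
        raise ValueError(f"efficiency must be non-negative, got eta={eta}")
    disc = (1.0 + eta) ** 2 - 4.0 * eta / q**2
    if disc < 0:
        if disc > -1e-12 * max(1.0, (1.0 + eta) ** 2):  # round-off at the apex
            disc = 0.0
        else:
            raise ValueError(
                f"efficiency {eta} above maximal for this coupling "
                f"(eta_max({q}) = {eta_max(q):.6g})"
            )
    r = math.sqrt(disc)
    upper = 0.5 * q * (-(1.0 + eta) + r)
    lower = 0.5 * q * (-(1.0 + eta) - r)
    return upper, lower


def power_output(x, q: float):
    """Reduced power output p = -x(x + q), in units of T*L22*Delta^2.

    Equal to q^2 v(1-v) with the reduced flux v = -x/q.  Non-negative
    exactly on the working range x in [-q, 0], with zeros at both ends.
    """
    _check_q(q)
    x = np.asarray(x, dtype=float)
    out = -x * (x + q)
    return out.item() if out.ndim == 0 else out


def entropy_production(x, q: float):
    """Reduced dissipation sigma = x^2 + 2qx + 1, in units of L22*Delta^2.

    Derived from the dissipation identity T*sigma = J1 X1 + J2 X2 with
    the symmetric Onsager matrix (L11 = L22, L12 = q L22).  Non-negative
    everywhere; vanishes only at the reversible point x = -1 with q = 1.
    """
    _check_q(q)
    x = np.asarray(x, dtype=float)
    out = x**2 + 2.0 * q * x + 1.0
    return out.item() if out.ndim == 0 else out


def ecological_function(x, q: float):
    """Reduced ecological function e = -(2x^2 + 3qx + 1).

    Identically equal to power minus dissipation (E = P - T*sigma in
    absolute units): a compromise criterion that trades power against
    entropy production.  Maximum at x = -3q/4.
    """
    _check_q(q)
    x = np.asarray(x, dtype=float)
    out = -(2.0 * x**2 + 3.0 * q * x + 1.0)
    return out.item() if out.ndim == 0 else out


def efficient_power(x, q: float):
    """Reduced efficient power pe = eta * p = x^2 (x+q)^2 / (qx + 1).

    Weights power by efficiency; its maximum lies between the maximum
    power and maximum ecological operating points.  At q = 1 the pole
    of the efficiency at x = -1 is removable (the expression reduces to
    x^2 (x + 1)), so the complete-coupling case is evaluated in that
    cancelled form.
    """
    _check_q(q)
    x = np.asarray(x, dtype=float)
    if q == 1.0:
        out = x**2 * (x + 1.0)
        return out.item() if out.ndim == 0 else out
    denom = q * x + 1.0
    if np.any(denom == 0.0):
        raise ZeroDivisionError(
            f"efficient power inherits the efficiency pole at x = {-1.0 / q:.6g}"
        )
    out = x**2 * (x + q) ** 2 / denom
    return out.item() if out.ndim == 0 else out


_REDUCED = {
    "power": power_output,
    "ecological": ecological_function,
    "efficient_power": efficient_power,
    "sigma": entropy_production,
    "efficiency": efficiency,
}


def reduced_function(function_id: str):
    """Look up a reduced characteristic function ``f(x, q)`` by name."""
    try:
        return _REDUCED[function_id]
    except KeyError:
        raise ValueError(
            f"unknown function {function_id!r}; choose from {sorted(_REDUCED)}"
        ) from None


def characteristic_vs_eta(
    function_id: str, eta: float, q: float, branch: Branch = "lower"
) -> float:
    """Characteristic function evaluated along the efficiency axis.

    Computed by composition: invert eta -> x on the requested branch
    with :func:`x_from_eta`, then evaluate the x-domain closed form.
    For q = 1 this reproduces the complete-coupling limits
    P ~ eta(1-eta), E ~ (2 eta - 1)(1 - eta) and Pe ~ eta^2 (1-eta).
    """
    if function_id not in FUNCTION_IDS:
        raise ValueError(
            f"unknown function {function_id!r}; choose from {FUNCTION_IDS}"
        )
    if branch not in ("upper", "lower"):
        raise ValueError(f"branch must be 'upper' or 'lower', got {branch!r}")
    upper, lower = x_from_eta(eta, q)
    x = upper if branch == "upper" else lower
    return float(reduced_function(function_id)(x, q))


@dataclass(frozen=True)
class OperatingPoint:
    """A single operating point of the converter at Z = 1.

    Carries the force ratio x together with the derived efficiency and
    the reduced flux variable v = -x/q; ``branch`` records which root
    of the eta -> x inversion produced the point, when applicable.
    """

    x: float
    q: float
    branch: Branch | None = None

    @property
    def eta(self) -> float:
        return float(efficiency(self.x, self.q))

    @property
    def v(self) -> float:
        return -self.x / self.q

    @classmethod
    def from_eta(cls, eta: float, q: float, branch: Branch) -> "OperatingPoint":
        upper, lower = x_from_eta(eta, q)
        return cls(x=upper if branch == "upper" else lower, q=q, branch=branch)


@dataclass(frozen=True)
class FunctionValues:
    """All four reduced characteristic values at one operating point."""

    power: float
    entropy_production: float
    ecological: float
    efficient_power: float

    def absolute(self, drive: DriveConditions) -> "FunctionValues":
        """Convert to absolute units using the drive-condition scale."""
        s = drive.scale
        return FunctionValues(
            power=self.power * s,
            entropy_production=self.entropy_production * drive.sigma_scale,
            ecological=self.ecological * s,
            efficient_power=self.efficient_power * s,
        )


def evaluate(x: float, q: float) -> FunctionValues:
    """Evaluate all reduced characteristic functions at one point."""
    return FunctionValues(
        power=float(power_output(x, q)),
        entropy_production=float(entropy_production(x, q)),
        ecological=float(ecological_function(x, q)),
        efficient_power=float(efficient_power(x, q)),
    )
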