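"""Optimal operating regimes of the linear energy converter.

Three optimization criteria are analyzed, each yielding an efficiency
at which its objective is maximal over the working range x in (-q, 0):

* **MPO** — maximum power output; the converter delivers the most free
  energy per unit time, at efficiency ``(1/2) q^2/(2 - q^2)``.
* **MEF** — maximum ecological function (power minus dissipation), a
  compromise favouring cleaner operation, at ``(3/4) q^2/(4 - 3q^2)``.
* **MEPF** — maximum efficient power (efficiency times power); its
  maximizing force ratio is the interior root of the stationarity
  quadratic ``3q x^2 + (4 + q^2) x + 2q = 0``.

At complete coupling (q = 1) these give the landmark efficiencies 1/2,
3/4 and 2/3.  Every closed form is backed by an independent numeric
oracle (:func:`numeric_argmax`, bounded Brent maximization) so that a
transcription error in an analytic expression cannot pass silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.optimize import minimize_scalar

from .core import FUNCTION_IDS, efficiency, eta_max, reduced_function

__all__ = [
    "RegimeResult",
    "REGIMES",
    "eta_mpo",
    "eta_mef",
    "eta_mepf",
    "eta_mepf_closed_form",
    "x_star_mepf",
    "eta_max",
    "numeric_argmax",
    "optimal_point",
    "series_expansion",
]

Regime = Literal["MPO", "MEF", "MEPF"]

#: Regime label -> characteristic-function identifier.
REGIMES: dict[str, str] = {
    "MPO": "power",
    "MEF": "ecological",
    "MEPF": "efficient_power",
}


@dataclass(frozen=True)
class RegimeResult:
    """Optimum of one characteristic function at one coupling.

    ``method`` records whether the numbers came from the closed form or
    from bounded scalar maximization; ``residual`` is the absolute
    difference in maximizing efficiency when both routes were run.
    """

    regime: str
    q: float
    eta_star: float
    x_star: float
    value_star: float
    method: Literal["analytic", "numeric"]
    residual: float | None = None


def _check_q(q: float) -> None:
    if not 0.0 < q <= 1.0:
        raise ValueError(f"degree of coupling q must lie in (0, 1], got q={q}")


def eta_mpo(q: float) -> float:
    """Efficiency at maximum power output, ``(1/2) q^2 / (2 - q^2)``.

    The power -x(x+q) peaks at x* = -q/2; mapping through the
    efficiency function gives this closed form.  Equals 1/2 at q = 1.
    """
    _check_q(q)
    return 0.5 * q**2 / (2.0 - q**2)


def eta_mef(q: float) -> float:
    """Efficiency at maximum ecological function, ``(3/4) q^2 / (4 - 3q^2)``.

    The ecological function -(2x^2 + 3qx + 1) peaks at x* = -3q/4.
    Equals 3/4 at q = 1 — cleaner than maximum power operation.
    """
    _check_q(q)
    return 0.75 * q**2 / (4.0 - 3.0 * q**2)


def x_star_mepf(q: float) -> float:
    """Maximizing force ratio of the efficient power.

    Interior root (in (-q, 0)) of the stationarity quadratic
    ``3q x^2 + (4 + q^2) x + 2q = 0`` obtained from
    d/dx [x^2 (x+q)^2 / (qx+1)] = 0.  At q = 1 the other root, x = -1,
    is the reversible zero-power point and is rejected.
    """
    _check_q(q)
    a, b, c = 3.0 * q, 4.0 + q**2, 2.0 * q
    disc = b**2 - 4.0 * a * c
    r = math.sqrt(disc)
    roots = ((-b + r) / (2.0 * a), (-b - r) / (2.0 * a))
    interior = [x for x in roots if -q < x < 0.0]
    if len(interior) != 1:  # cannot happen for q in (0,1]; guard regardless
        raise RuntimeError(
            f"expected one stationary point interior to (-{q}, 0), got {roots}"
        )
    return interior[0]


def eta_mepf(q: float) -> float:
    """Efficiency at maximum efficient power.

    The interior stationarity root mapped through the efficiency
    function.  Equals 2/3 exactly at q = 1.
    """
    return float(efficiency(x_star_mepf(q), q))


def eta_mepf_closed_form(q: float) -> float:
    """Closed-form efficiency at maximum efficient power (cross-check).

    ``2 * [4/(3 q^2) - 2/3 - (1/12) sqrt((8 - 16/q^2)^2 - 48)]``.
    Provided as an independent algebraic route; must agree with
    :func:`eta_mepf` on the whole q range (asserted in the test suite,
    discrepancies are reported rather than reconciled).
    """
    _check_q(q)
    inner = (8.0 - 16.0 / q**2) ** 2 - 48.0
    return 2.0 * (4.0 / (3.0 * q**2) - 2.0 / 3.0 - math.sqrt(inner) / 12.0)


def numeric_argmax(
    function_id: str, q: float, tolerance: float = 1e-10
) -> RegimeResult:
    """Numerically maximize a characteristic function over the force ratio.

    Bounded Brent minimization of the negated reduced function over
    x in (-q, 0) — widened to (-1, 0) for the ecological function,
    whose optimum x = -3q/4 stays interior either way but whose value
    is negative near the right edge for small q.  Deterministic for
    fixed inputs; serves as the independent oracle for the closed forms.
    """
    if function_id not in FUNCTION_IDS:
        raise ValueError(
            f"unknown function {function_id!r}; choose from {FUNCTION_IDS}"
        )
    _check_q(q)
    f = reduced_function(function_id)
    lo = -1.0 if function_id == "ecological" else -q
    res = minimize_scalar(
        lambda x: -f(x, q),
        bounds=(lo, 0.0),
        method="bounded",
        options={"xatol": tolerance},
    )
    if not res.success:
        raise RuntimeError(
            f"bounded maximization of {function_id} at q={q} did not "
            f"converge: {res.message}; best iterate x={res.x}"
        )
    x_star = float(res.x)
    regime = {v: k for k, v in REGIMES.items()}[function_id]
    return RegimeResult(
        regime=regime,
        q=q,
        eta_star=float(efficiency(x_star, q)),
        x_star=x_star,
        value_star=float(-res.fun),
        method="numeric",
    )


_ANALYTIC_ETA = {"MPO": eta_mpo, "MEF": eta_mef, "MEPF": eta_mepf}
_ANALYTIC_X = {
    "MPO": lambda q: -q / 2.0,
    "MEF": lambda q: -3.0 * q / 4.0,
    "MEPF": x_star_mepf,
}


def optimal_point(
    regime: Regime, q: float, *, numeric_check: bool = True
) -> RegimeResult:
    """Analytic optimum of one regime, optionally validated numerically.

    Returns the closed-form result; when ``numeric_check`` is on, runs
    :func:`numeric_argmax` as well and stores the |analytic - numeric|
    efficiency residual (expected below 1e-8).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    _check_q(q)
    x_star = _ANALYTIC_X[regime](q)
    eta_star = _ANALYTIC_ETA[regime](q)
    value = float(reduced_function(REGIMES[regime])(x_star, q))
    residual = None
    if numeric_check:
        residual = abs(eta_star - numeric_argmax(REGIMES[regime], q).eta_star)
    return RegimeResult(
        regime=regime,
        q=q,
        eta_star=eta_star,
        x_star=x_star,
        value_star=value,
        method="analytic",
        residual=residual,
    )


def series_expansion(regime: str, q: float, order: int = 4) -> float:
    """Small-q expansion of the maximizing efficiency.

    MPO: ``q^2/4 + q^4/8``; MEF: ``3 q^2/16 + 9 q^4/64``; both with
    O(q^6) remainder.  ``order`` may be 2 or 4.
    """
    if not 0.0 <= q <= 1.0:  # q = 0 admissible here: expansion point
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if order not in (2, 4):
        raise ValueError(f"order must be 2 or 4, got {order}")
    if regime == "MPO":
        coeffs = (0.25, 0.125)
    elif regime == "MEF":
        coeffs = (3.0 / 16.0, 9.0 / 64.0)
    else:
        raise ValueError(
            f"series expansion available for MPO and MEF only, got {regime!r}"
        )
    out = coeffs[0] * q**2
    if order == 4:
        out += coeffs[1] * q**4
    return out
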