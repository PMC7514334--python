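"""Enzymatic-reaction parameterization of the linear energy converter.

A three-step enzymatic cycle (substrate binding, internal conversion
driven by ATP hydrolysis, product release) couples one exothermic and
one endothermic reaction.  Near equilibrium the mass-action net
velocities linearize to an Onsager flux-force system with two fluxes
and two forces.  This module builds the phenomenological coefficient
matrix from the kinetic amplitudes and provides the underlying rate
laws: Arrhenius rate constants, activation-energy geometry of the
chemical-potential landscape, and the exact and linearized net
velocities of a single reaction step.

Conventions
-----------
* All energies are per mole; the default gas constant is
  :data:`R_GAS` = 8.314 J K^-1 mol^-1.  A dimensionless mode is the
  default throughout the package: set ``R*T = 1`` (i.e. pass affinities
  already scaled by RT).
* The amplitude topology is fixed to ``A1 = A3 = A``, ``A2 = beta*A``,
  which yields ``L11 = L22 = A*(beta-1)``, ``L12 = L21 = A`` and hence
  phenomenological stoichiometry Z = 1 and degree of coupling
  q = 1/(beta-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "R_GAS",
    "ChemicalPotentialProfile",
    "ConverterCoefficients",
    "arrhenius_rate",
    "activation_energies",
    "net_velocity_nonlinear",
    "net_velocity_linear",
    "build_converter",
    "q_from_beta",
    "beta_from_q",
]

#: Gas constant in J K^-1 mol^-1.
R_GAS = 8.314


@dataclass(frozen=True)
class ChemicalPotentialProfile:
    """Chemical-potential landscape of the three-step reaction sequence.

    Parameters
    ----------
    mu1, mu2, mu3, mu4
        Chemical potentials of the four states along the reaction
        coordinate (energy per mole).  Step affinities are
        ``alpha_i = mu_i - mu_{i+1}``; their signs are unconstrained
        (the middle step is endothermic in the driven direction).
    h1, h2, h3
        Activation barrier heights above the preceding state for each
        step (energy per mole, non-negative).
    T
        Absolute temperature in K.
    R
        Gas constant, same energy units per mole per K.
    """

    mu1: float
    mu2: float
    mu3: float
    mu4: float
    h1: float = 0.0
    h2: float = 0.0
    h3: float = 0.0
    T: float = 298.15
    R: float = R_GAS

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got T={self.T}")
        if self.R <= 0:
            raise ValueError(f"gas constant must be positive, got R={self.R}")
        for name in ("h1", "h2", "h3"):
            if getattr(self, name) < 0:
                raise ValueError(f"barrier height {name} must be >= 0")
        for name in ("mu1", "mu2", "mu3", "mu4"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"chemical potential {name} must be finite")

    @property
    def affinities(self) -> tuple[float, float, float]:
        """Step affinities ``(mu1-mu2, mu2-mu3, mu3-mu4)``."""
        return (self.mu1 - self.mu2, self.mu2 - self.mu3, self.mu3 - self.mu4)


@dataclass(frozen=True)
class ConverterCoefficients:
    """Onsager matrix of the two-flux converter and its descriptors.

    Built by :func:`build_converter`; not intended to be constructed by
    hand.  Invariants: ``L12 == L21`` (Onsager symmetry),
    ``L11 == L22 == A*(beta-1)``, ``q == 1/(beta-1)`` and ``Z == 1``.
    """

    A: float
    beta: float
    L11: float = field(init=False)
    L12: float = field(init=False)
    L21: float = field(init=False)
    L22: float = field(init=False)
    q: float = field(init=False)
    Z: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "L11", self.A * (self.beta - 1.0))
        object.__setattr__(self, "L22", self.A * (self.beta - 1.0))
        object.__setattr__(self, "L12", self.A)
        object.__setattr__(self, "L21", self.A)
        object.__setattr__(self, "q", 1.0 / (self.beta - 1.0))
        object.__setattr__(self, "Z", 1.0)

    @property
    def det(self) -> float:
        """Determinant of the Onsager matrix, ``L11*L22 - L12*L21``.

        Non-negative for a passive converter; zero iff q = 1.
        """
        return self.L11 * self.L22 - self.L12 * self.L21


def arrhenius_rate(F: float, Ea: float, T: float, R: float = R_GAS) -> float:
    """Arrhenius rate constant ``F * exp(-Ea / (R*T))``.

    Parameters
    ----------
    F
        Frequency factor (> 0), units of the returned rate constant.
    Ea
        Activation energy per mole.  ``Ea = inf`` is allowed and gives 0.
    T, R
        Temperature and gas constant, both strictly positive.
    """
    if F <= 0:
        raise ValueError(f"frequency factor must be positive, got F={F}")
    if T <= 0 or R <= 0:
        raise ValueError(f"T and R must be positive, got T={T}, R={R}")
    return F * math.exp(-Ea / (R * T))


def activation_energies(
    profile: ChemicalPotentialProfile,
) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float]]:
    """Forward/backward activation energies of the three steps.

    For step *i* the forward barrier measured from state *i* is
    ``E_i = h_i + mu_{i+1} - mu_i`` when the step is uphill and the
    backward barrier is the bare height ``E_{-i} = h_i``; the
    difference ``E_i - E_{-i}`` always equals ``mu_{i+1} - mu_i``, so
    detailed balance is built into the geometry.

    Returns
    -------
    tuple of (forward, backward) pairs, one per step.
    """
    mus = (profile.mu1, profile.mu2, profile.mu3, profile.mu4)
    hs = (profile.h1, profile.h2, profile.h3)
    return tuple(
        (h + mus[i + 1] - mus[i], h) for i, h in enumerate(hs)
    )  # type: ignore[return-value]


def net_velocity_nonlinear(
    Ai: float, delta_mu: float, T: float = 1.0, R: float = 1.0
) -> float:
    """Exact net velocity ``Ai * (1 - exp(-delta_mu/(R*T)))`` of one step.

    Zero iff the step affinity ``delta_mu`` is zero, shares its sign,
    and saturates at the amplitude ``Ai`` for large forward affinity.
    Defaults put the affinity in units of RT.  Uses ``expm1`` so small
    affinities do not lose precision to cancellation.
    """
    if Ai <= 0:
        raise ValueError(f"amplitude must be positive, got Ai={Ai}")
    if T <= 0 or R <= 0:
        raise ValueError(f"T and R must be positive, got T={T}, R={R}")
    return -Ai * math.expm1(-delta_mu / (R * T))


def net_velocity_linear(
    Ai: float, delta_mu: float, T: float = 1.0, R: float = 1.0
) -> float:
    """Linearized net velocity ``Ai * delta_mu / (R*T)``.

    The exact first-order Taylor coefficient of
    :func:`net_velocity_nonlinear` at zero affinity; the relative error
    against the exact form at affinity ``eps*R*T`` is ``eps/2 + O(eps^2)``.
    """
    if Ai <= 0:
        raise ValueError(f"amplitude must be positive, got Ai={Ai}")
    if T <= 0 or R <= 0:
        raise ValueError(f"T and R must be positive, got T={T}, R={R}")
    return Ai * delta_mu / (R * T)


def q_from_beta(beta: float) -> float:
    """Degree of coupling ``q = 1/(beta-1)`` from the amplitude ratio."""
    if beta <= 1.0:
        raise ValueError(f"beta must exceed 1, got beta={beta}")
    return 1.0 / (beta - 1.0)


def beta_from_q(q: float) -> float:
    """Amplitude ratio ``beta = 1 + 1/q`` from the degree of coupling."""
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must lie in (0, 1], got q={q}")
    return 1.0 + 1.0 / q


def build_converter(
    A: float, beta: float, *, allow_overcoupling: bool = False
) -> ConverterCoefficients:
    """Build the Onsager matrix from the amplitude A and ratio beta.

    ``beta >= 2`` corresponds to q <= 1; ``beta`` in (1, 2) gives q > 1,
    which violates the Cauchy-Schwarz bound ``det L >= 0`` of a passive
    converter and is rejected unless ``allow_overcoupling`` is set
    (exploration only).
    """
    if A <= 0:
        raise ValueError(f"amplitude must be positive, got A={A}")
    if beta <= 1.0:
        raise ValueError(
            f"beta must exceed 1 (got beta={beta}): the diagonal coefficients "
            "A*(beta-1) would vanish or turn negative"
        )
    if beta < 2.0 and not allow_overcoupling:
        raise ValueError(
            f"beta={beta} gives q={1.0 / (beta - 1.0):.4g} > 1, violating "
            "converter passivity (det L < 0); pass allow_overcoupling=True "
            "to override"
        )
    return ConverterCoefficients(A=A, beta=beta)
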