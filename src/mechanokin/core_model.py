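"""Rate laws and closed-form kinetic quantities for a force-sensing binding scheme.

The central object is the Bell-Evans rate law

    k(F) = k0 * exp(+/- F * x_dagger / kT)

with ``k0`` the intrinsic (zero-force) rate in 1/s, ``x_dagger`` the distance
to the transition state in nm, and the sign set by whether force accelerates
the transition (unfolding, unbinding) or suppresses it (folding, binding of a
coil-to-helix partner).  On top of it sit the composite quantities used to
describe vinculin binding to a stretched talin rod domain: the talin
unfolding probability, the biphasic observed binding rate
``r_B(F) = k_B(F) * P_U(F)`` (binding requires an unfolded talin exposing its
vinculin-binding sites, but the coil-to-helix contraction that accompanies
binding is opposed by force), force-dependent dissociation constants, and the
crossover force at which an unbinding rate matches a competing first-order
process such as bound-state maturation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "ForceSense",
    "ThermalContext",
    "BellEvansParams",
    "TalinFoldingParams",
    "BindingModelParams",
    "bell_evans_rate",
    "unfolding_probability",
    "binding_rate",
    "dissociation_constant",
    "crossover_force",
]

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM_PER_K = 1.380649e-2


class ForceSense(str, enum.Enum):
    """Direction of the force dependence of a Bell-Evans rate."""

    force_accelerated = "force_accelerated"
    force_suppressed = "force_suppressed"

    @property
    def sign(self) -> float:
        return 1.0 if self is ForceSense.force_accelerated else -1.0


@dataclass(frozen=True)
class ThermalContext:
    """Temperature and the derived thermal energy kT (pN nm)."""

    temperature_K: float = 298.0

    def __post_init__(self) -> None:
        if not (self.temperature_K > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature_K}")

    @property
    def kT(self) -> float:
        return BOLTZMANN_PN_NM_PER_K * self.temperature_K

    @classmethod
    def from_kT(cls, kT_pN_nm: float) -> "ThermalContext":
        """Build a context from a stated thermal energy (e.g. 4.114 pN nm)."""
        if not (kT_pN_nm > 0):
            raise ValueError("kT must be positive")
        return cls(temperature_K=kT_pN_nm / BOLTZMANN_PN_NM_PER_K)


@dataclass(frozen=True)
class BellEvansParams:
    """A single Bell-Evans rate law k(F) = k0 exp(+/- F x_dagger / kT)."""

    k0_per_s: float
    x_dagger_nm: float
    sense: ForceSense = ForceSense.force_accelerated

    def __post_init__(self) -> None:
        if not (self.k0_per_s > 0):
            raise ValueError(f"k0 must be positive, got {self.k0_per_s}")
        if not (self.x_dagger_nm >= 0):
            raise ValueError(f"x_dagger must be non-negative, got {self.x_dagger_nm}")
        if not isinstance(self.sense, ForceSense):
            object.__setattr__(self, "sense", ForceSense(self.sense))

    def rate(self, force_pN: float, therm: ThermalContext) -> float:
        return bell_evans_rate(self, force_pN, therm)

    @classmethod
    def from_rate_at_force(
        cls,
        rate_per_s: float,
        force_pN: float,
        x_dagger_nm: float,
        sense: ForceSense,
        therm: ThermalContext,
    ) -> "BellEvansParams":
        """Anchor a law by the rate it must produce at a given force.

        Useful when a timescale is measured at a probe force (k(F_probe)
        known) and the slope x_dagger is taken from an independent fit.
        """
        sense = ForceSense(sense)
        k0 = rate_per_s * math.exp(-sense.sign * force_pN * x_dagger_nm / therm.kT)
        return cls(k0_per_s=k0, x_dagger_nm=x_dagger_nm, sense=sense)


@dataclass(frozen=True)
class TalinFoldingParams:
    """Paired unfolding / folding laws of the talin force-sensor domain."""

    unfold: BellEvansParams
    fold: BellEvansParams

    def __post_init__(self) -> None:
        if self.unfold.sense is not ForceSense.force_accelerated:
            raise ValueError("talin unfolding must be force_accelerated")
        if self.fold.sense is not ForceSense.force_suppressed:
            raise ValueError("talin folding must be force_suppressed")


@dataclass(frozen=True)
class BindingModelParams:
    """Inputs of the biphasic observed binding rate r_B(F) = k_B(F) P_U(F).

    ``bind`` is the Bell-Evans law for binding to an *exposed* site at the
    working concentration; ``concentration_nM`` records that concentration so
    dissociation constants can be put on a per-molar scale.
    """

    bind: BellEvansParams
    talin: TalinFoldingParams
    concentration_nM: float = 20.0

    def __post_init__(self) -> None:
        if self.bind.sense is not ForceSense.force_suppressed:
            raise ValueError("the binding branch must be force_suppressed")
        if not (self.concentration_nM > 0):
            raise ValueError("concentration must be positive")


def _check_force(force_pN: float) -> float:
    force_pN = float(force_pN)
    if not math.isfinite(force_pN):
        raise ValueError(f"force must be finite, got {force_pN}")
    if force_pN < 0:
        raise ValueError(f"force must be non-negative, got {force_pN}")
    return force_pN


def bell_evans_rate(
    params: BellEvansParams, force_pN: float, therm: ThermalContext | None = None
) -> float:
    """Evaluate k(F) = k0 exp(+/- F x_dagger / kT) in 1/s."""
    therm = therm or ThermalContext()
    force_pN = _check_force(force_pN)
    return params.k0_per_s * math.exp(
        params.sense.sign * force_pN * params.x_dagger_nm / therm.kT
    )


def unfolding_probability(
    talin: TalinFoldingParams, force_pN: float, therm: ThermalContext | None = None
) -> float:
    """Equilibrium probability that talin is unfolded: r_U / (r_U + r_F)."""
    therm = therm or ThermalContext()
    r_u = bell_evans_rate(talin.unfold, force_pN, therm)
    r_f = bell_evans_rate(talin.fold, force_pN, therm)
    return r_u / (r_u + r_f)


def binding_rate(
    model: BindingModelParams, force_pN: float, therm: ThermalContext | None = None
) -> float:
    """Observed binding rate r_B(F) = k_B(F) * P_U(F) at the working concentration.

    The product of a force-suppressed binding branch with the rising talin
    unfolding probability is biphasic: it vanishes at forces too low to expose
    the binding sites and again at forces that prevent the coil-to-helix
    contraction, with a single interior maximum in between.
    """
    therm = therm or ThermalContext()
    return bell_evans_rate(model.bind, force_pN, therm) * unfolding_probability(
        model.talin, force_pN, therm
    )


def dissociation_constant(
    model: BindingModelParams,
    unbind: BellEvansParams,
    force_pN: float,
    therm: ThermalContext | None = None,
) -> float:
    """Force-dependent K_d in nM: off-rate over per-molar on-rate.

    The observed on-rate r_B(F) is measured at ``model.concentration_nM``;
    dividing by that concentration gives the bimolecular on-rate, and
    K_d(F) = r_Ub(F) / (r_B(F) / C).
    """
    therm = therm or ThermalContext()
    r_on = binding_rate(model, force_pN, therm)
    if r_on <= 0:
        raise ZeroDivisionError("binding rate is zero; K_d undefined at this force")
    r_off = bell_evans_rate(unbind, force_pN, therm)
    return r_off / (r_on / model.concentration_nM)


@dataclass(frozen=True)
class CrossoverResult:
    force_pN: float
    below_zero: bool = False  # True when the competing rate is already faster at F=0


def crossover_force(
    unbind: BellEvansParams,
    competing_rate_per_s: float,
    therm: ThermalContext | None = None,
) -> CrossoverResult:
    """Force F* at which a force-accelerated rate equals a competing rate.

    Solves k0 exp(F* x_dagger / kT) = competing_rate in closed form.  When the
    competing process is already faster at zero force (competing_rate <= k0)
    the formal solution is non-positive; 0 is returned with ``below_zero``
    set, so callers can tell "no positive crossover" from a true crossover at
    the origin.
    """
    therm = therm or ThermalContext()
    if not (competing_rate_per_s > 0):
        raise ValueError("competing rate must be positive")
    if unbind.sense is not ForceSense.force_accelerated:
        raise ValueError("crossover is defined for a force_accelerated law")
    if not (unbind.x_dagger_nm > 0):
        raise ValueError("crossover requires x_dagger > 0")
    f_star = therm.kT / unbind.x_dagger_nm * math.log(
        competing_rate_per_s / unbind.k0_per_s
    )
    if f_star <= 0:
        return CrossoverResult(force_pN=0.0, below_zero=f_star < 0)
    return CrossoverResult(force_pN=f_star)
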