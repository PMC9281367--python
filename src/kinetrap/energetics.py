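"""Free-energy / rate-constant conversions via transition-state theory.

A first-order rate constant is written ``k = A · exp(-ΔG‡ / RT)`` with a
symbolic prefactor ``A``.  Absolute rates are therefore a convention (the
default prefactor is 1 s⁻¹); only *ratios* of rates, i.e. differences of
barrier heights (ΔΔG), carry physical meaning in this package.  The useful
correspondences at 298 K are

    ΔΔG = RT·ln(fold):   10-fold slowing  ↔ 1.364 kcal/mol (≈ 1.4)
                         100-fold slowing ↔ 2.727 kcal/mol (≈ 2.8)

The module also represents explicit free-energy ladders (ground states
alternating with barriers) for an unbound and a binder-bound branch of a
reaction, and classifies the bound branch as *uniform binding* (every state
shifted equally, all barrier heights preserved), *negative catalysis* (some
barrier raised), or *positive catalysis* (some barrier lowered).

Units: kcal/mol for free energies, Kelvin for temperature, s⁻¹ for rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
import yaml

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "ThermalContext",
    "ProfileState",
    "FreeEnergyProfile",
    "RateConstant",
    "BinderClass",
    "ddg_from_fold",
    "fold_from_ddg",
    "rate_from_halflife",
    "halflife_from_rate",
    "barrier_rate",
    "apply_uniform_shift",
    "classify_binder",
]

#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.987e-3

#: Default temperature (K); RT·ln(10) ≈ 1.364 kcal/mol at this temperature.
DEFAULT_TEMPERATURE_K = 298.0


@dataclass(frozen=True)
class ThermalContext:
    """Thermodynamic context: gas constant R (kcal/mol/K) and temperature T (K)."""

    R: float = GAS_CONSTANT_KCAL
    T: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"gas constant must be positive, got {self.R}")
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")

    @property
    def rt(self) -> float:
        """Thermal energy R·T in kcal/mol."""
        return self.R * self.T


@dataclass(frozen=True)
class RateConstant:
    """A labelled first-order rate constant (s⁻¹)."""

    value: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"rate constant must be >= 0, got {self.value}")


class StateKind(str, Enum):
    GROUND = "ground"
    BARRIER = "barrier"


@dataclass(frozen=True)
class ProfileState:
    """One state on a free-energy ladder: a ground state or a barrier."""

    name: str
    kind: StateKind
    G: float  # kcal/mol

    @classmethod
    def ground(cls, name: str, G: float) -> "ProfileState":
        return cls(name, StateKind.GROUND, G)

    @classmethod
    def barrier(cls, name: str, G: float) -> "ProfileState":
        return cls(name, StateKind.BARRIER, G)


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Ordered ladder of state free energies for one branch of a reaction.

    States must alternate ground/barrier/ground/… starting and ending on a
    ground state, and every barrier must sit at or above both flanking
    ground states.

    Parameters
    ----------
    branch
        Label for the branch, conventionally ``"unbound"`` or ``"bound"``.
    states
        The ordered states (kcal/mol).
    """

    branch: str
    states: tuple[ProfileState, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("state names must be unique within a profile")
        if not self.states:
            raise ValueError("profile needs at least one state")
        for i, s in enumerate(self.states):
            expected = StateKind.GROUND if i % 2 == 0 else StateKind.BARRIER
            if s.kind != expected:
                raise ValueError(
                    f"state {s.name!r} at position {i} must be {expected.value}; "
                    "profiles alternate ground/barrier/ground/…"
                )
        if self.states[-1].kind != StateKind.GROUND:
            raise ValueError("profile must end on a ground state")
        for i, s in enumerate(self.states):
            if s.kind == StateKind.BARRIER:
                hi = max(self.states[i - 1].G, self.states[i + 1].G)
                if s.G < hi - 1e-12:
                    raise ValueError(
                        f"barrier {s.name!r} (G={s.G}) lies below a flanking "
                        "ground state"
                    )

    def __getitem__(self, name: str) -> ProfileState:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(f"no state named {name!r} in branch {self.branch!r}")

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    def barrier_heights(self) -> dict[str, float]:
        """Height of each barrier above its *preceding* (reactant-side) ground state."""
        out: dict[str, float] = {}
        for i, s in enumerate(self.states):
            if s.kind == StateKind.BARRIER:
                out[s.name] = s.G - self.states[i - 1].G
        return out

    # -- serialization (structured text) ------------------------------------

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "states": [
                {"name": s.name, "kind": s.kind.value, "G": s.G} for s in self.states
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FreeEnergyProfile":
        states = tuple(
            ProfileState(s["name"], StateKind(s["kind"]), float(s["G"]))
            for s in d["states"]
        )
        return cls(branch=d["branch"], states=states)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FreeEnergyProfile":
        return cls.from_dict(yaml.safe_load(text))


class BinderClass(str, Enum):
    """Classification of a bound branch relative to the unbound one."""

    UNIFORM = "uniform"
    NEGATIVE_CATALYSIS = "negative_catalysis"
    POSITIVE_CATALYSIS = "positive_catalysis"
    MIXED = "mixed"


# ---------------------------------------------------------------------------
# scalar conversions
# ---------------------------------------------------------------------------

def ddg_from_fold(fold: float, ctx: ThermalContext | None = None) -> float:
    """Barrier destabilization ΔΔG (kcal/mol) producing a ``fold``-fold slowing.

    ``ΔΔG = RT·ln(fold)``.  A fold of 10 at 298 K gives 1.364 kcal/mol.
    Destabilization is defined as slowing, so ``fold`` must be ≥ 1.
    """
    ctx = ctx or ThermalContext()
    if fold < 1:
        raise ValueError(f"fold must be >= 1 (a slowing), got {fold}")
    return ctx.rt * math.log(fold)


def fold_from_ddg(ddg: float, ctx: ThermalContext | None = None) -> float:
    """Fold rate reduction produced by a barrier destabilization ΔΔG ≥ 0 (kcal/mol)."""
    ctx = ctx or ThermalContext()
    if ddg < 0:
        raise ValueError(f"ddg must be >= 0, got {ddg}")
    return math.exp(ddg / ctx.rt)


def rate_from_halflife(t_half: float) -> float:
    """First-order rate constant (s⁻¹) of a decay with half-life ``t_half`` (s)."""
    if t_half <= 0:
        raise ValueError(f"half-life must be positive, got {t_half}")
    return math.log(2.0) / t_half


def halflife_from_rate(k: float) -> float:
    """Half-life (s) of a first-order decay with rate constant ``k`` (s⁻¹)."""
    if k <= 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    return math.log(2.0) / k


# ---------------------------------------------------------------------------
# profile operations
# ---------------------------------------------------------------------------

def barrier_rate(
    profile: FreeEnergyProfile,
    ground: str,
    barrier: str,
    prefactor: float = 1.0,
    ctx: ThermalContext | None = None,
) -> RateConstant:
    """Rate constant over a barrier: ``k = A·exp(-(G_barrier - G_ground)/RT)``.

    The prefactor ``A`` (s⁻¹) stands in for the vibrational frequency factor
    and is a user convention (default 1 s⁻¹): only ratios of such rates are
    physically meaningful.
    """
    ctx = ctx or ThermalContext()
    g = profile[ground]
    b = profile[barrier]
    if b.kind != StateKind.BARRIER:
        raise ValueError(f"{barrier!r} is not a barrier state")
    if g.kind != StateKind.GROUND:
        raise ValueError(f"{ground!r} is not a ground state")
    height = b.G - g.G
    if height < -1e-12:
        raise ValueError(
            f"barrier {barrier!r} lies below ground {ground!r} (height {height})"
        )
    k = prefactor * math.exp(-max(height, 0.0) / ctx.rt)
    return RateConstant(k, label=f"{profile.branch}:{ground}->{barrier}")


def apply_uniform_shift(
    profile: FreeEnergyProfile, shift: float
) -> FreeEnergyProfile:
    """Uniformly stabilize a branch: subtract ``shift`` (kcal/mol) from every state.

    Barrier *heights* — and hence every ``barrier_rate`` — are unchanged, which
    is precisely why a uniform binder cannot accelerate a unimolecular
    reaction.
    """
    states = tuple(replace(s, G=s.G - shift) for s in profile.states)
    return FreeEnergyProfile(branch=profile.branch, states=states)


def classify_binder(
    unbound: FreeEnergyProfile,
    bound: FreeEnergyProfile,
    tol: float = 1e-9,
) -> BinderClass:
    """Classify a bound branch against the unbound one.

    * ``uniform`` — every state shifted by the same amount (within ``tol``
      kcal/mol): barrier heights preserved, rates unchanged.
    * ``negative_catalysis`` — at least one barrier height strictly larger on
      the bound branch (and none smaller): some route slowed.
    * ``positive_catalysis`` — at least one barrier height smaller (and none
      larger): some route accelerated.
    * ``mixed`` — barriers moved in both directions, or unequal ground-state
      shifts with no barrier-height change.

    The two profiles must contain the same state names in the same order.
    """
    if unbound.state_names != bound.state_names:
        raise ValueError(
            "profiles must share state names/order: "
            f"{unbound.state_names} vs {bound.state_names}"
        )
    shifts = [u.G - b.G for u, b in zip(unbound.states, bound.states)]
    if max(shifts) - min(shifts) <= tol:
        return BinderClass.UNIFORM

    h_un = unbound.barrier_heights()
    h_bd = bound.barrier_heights()
    raised = any(h_bd[n] > h_un[n] + tol for n in h_un)
    lowered = any(h_bd[n] < h_un[n] - tol for n in h_un)
    if raised and not lowered:
        return BinderClass.NEGATIVE_CATALYSIS
    if lowered and not raised:
        return BinderClass.POSITIVE_CATALYSIS
    return BinderClass.MIXED
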