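"""Kinetic-scheme data model and builders for the three binder schemes.

A :class:`KineticScheme` is a small mass-action reaction network made of

* species (substrate, products, binder, binder–ligand complexes, downstream
  product) with initial concentrations in μM,
* reversible *binding* steps ``binder + ligand ⇌ complex`` parameterized by an
  association constant ``K_assoc`` (μM⁻¹) and an on-rate ``k_on``
  (μM⁻¹·s⁻¹), with ``k_off = k_on / K_assoc``,
* irreversible first-order *conversion* steps ``reactant → product`` (s⁻¹).

Transition states are deliberately NOT explicit species: uniform binding of
the transition state is encoded by giving the bound conversion the same rate
constant as the free one, and negative catalysis by reducing only the bound
rate toward the disfavored product.  This keeps the ODE system well-posed
while exactly capturing the transition-state-theory bookkeeping.

Three builders produce the schemes studied in this package:

* :func:`build_uniform_binder_scheme` — a single conversion S → P in the
  presence of a uniform binder U (species S, P, U, US, UP).
* :func:`build_two_product_scheme` — kinetic partitioning S → P1 / S → P2
  with a binder Q that may slow the bound S → P2 route (species S, P1, P2,
  Q, QS, QP1, QP2).
* :func:`build_coupled_scheme` — the two-product scheme plus an irreversible
  downstream reaction free-P1 → Pstar that releases the trapped product.

Units package-wide: μM, s, kcal/mol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import yaml

__all__ = [
    "Role",
    "Lineage",
    "SpeciesState",
    "BindingStep",
    "ConversionStep",
    "KineticScheme",
    "build_uniform_binder_scheme",
    "build_two_product_scheme",
    "build_coupled_scheme",
    "validate",
    "scheme_to_dict",
    "scheme_from_dict",
    "save_scheme",
    "load_scheme",
    "DEFAULT_K_ON",
]

#: Default association on-rate (μM⁻¹·s⁻¹).  The figures give only equilibrium
#: constants; at μM concentrations an on-rate of 1 μM⁻¹·s⁻¹ equilibrates
#: binding within seconds, far faster than the 10⁻²–10⁻⁵ s⁻¹ conversions, so
#: the simulated schemes sit in the rapid-equilibrium regime the free-energy
#: diagrams assume.
DEFAULT_K_ON = 1.0

_REL_TOL = 1e-12


class Role(str, Enum):
    SUBSTRATE = "substrate"
    PRODUCT = "product"
    BINDER = "binder"
    COMPLEX = "complex"
    DOWNSTREAM = "downstream"


class Lineage(str, Enum):
    P1 = "P1"
    P2 = "P2"
    NONE = "none"


@dataclass(frozen=True)
class SpeciesState:
    """A chemical species with its role, product lineage and initial concentration (μM)."""

    name: str
    role: Role
    lineage: Lineage = Lineage.NONE
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ValueError(
                f"initial concentration of {self.name!r} must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass(frozen=True)
class BindingStep:
    """Reversible binding ``binder + ligand ⇌ complex``.

    ``K_assoc`` is the association (binding) constant in μM⁻¹; ``k_off`` is
    derived as ``k_on / K_assoc``.
    """

    binder: str
    ligand: str
    complex: str
    K_assoc: float
    k_on: float = DEFAULT_K_ON

    def __post_init__(self) -> None:
        if self.K_assoc <= 0:
            raise ValueError(f"K_assoc must be > 0, got {self.K_assoc}")
        if self.k_on <= 0:
            raise ValueError(f"k_on must be > 0, got {self.k_on}")

    @property
    def k_off(self) -> float:
        """Dissociation rate (s⁻¹), ``k_on / K_assoc``."""
        return self.k_on / self.K_assoc


@dataclass(frozen=True)
class ConversionStep:
    """Irreversible first-order conversion ``reactant → product`` at rate ``k`` (s⁻¹)."""

    reactant: str
    product: str
    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"rate constant must be >= 0, got {self.k}")


@dataclass(frozen=True)
class KineticScheme:
    """A mass-action scheme: species, binding steps, conversions, conservation groups.

    ``conservation_groups`` maps a group label (``"binder_material"``,
    ``"substrate_material"``) to the species whose concentrations sum to a
    conserved total; complexes appear in both groups.  ``metadata`` records
    whether the scheme is a uniform binder (``is_uniform``) and the
    negative-catalysis fold ``nc_fold`` (bound-route slowing factor toward
    the solution-favored product; ``inf`` if that route is fully blocked).
    """

    name: str
    species: tuple[SpeciesState, ...]
    bindings: tuple[BindingStep, ...] = ()
    conversions: tuple[ConversionStep, ...] = ()
    conservation_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "bindings", tuple(self.bindings))
        object.__setattr__(self, "conversions", tuple(self.conversions))
        names = self.species_names
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"no species named {name!r} in scheme {self.name!r}")

    def __getitem__(self, name: str) -> SpeciesState:
        return self.species[self.species_index(name)]

    @property
    def initial_state(self):
        import numpy as np

        return np.array([s.initial_concentration for s in self.species], dtype=float)

    def lineage_species(self, lineage: Lineage) -> tuple[str, ...]:
        return tuple(
            s.name
            for s in self.species
            if s.lineage == lineage and s.role != Role.SUBSTRATE
        )

    def substrate_pool(self) -> tuple[str, ...]:
        """Species holding unconverted substrate material (free S and S-complexes)."""
        free = [s.name for s in self.species if s.role == Role.SUBSTRATE]
        bound = [
            b.complex for b in self.bindings if b.ligand in free
        ]
        return tuple(free + bound)

    @property
    def rate_scales(self) -> tuple[float, float]:
        """(fastest, slowest) nonzero first-order timescale-setting rates in the scheme."""
        rates = [b.k_off for b in self.bindings]
        rates += [c.k for c in self.conversions if c.k > 0]
        # binding pseudo-first-order rate at initial concentrations
        for b in self.bindings:
            conc = max(
                self[b.binder].initial_concentration,
                self[b.ligand].initial_concentration,
            )
            if conc > 0:
                rates.append(b.k_on * conc)
        rates = [r for r in rates if r > 0]
        if not rates:
            return (0.0, 0.0)
        return (max(rates), min(rates))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _binder_groups(
    binder: str, complexes: Sequence[str], ligand_material: Sequence[str]
) -> dict[str, tuple[str, ...]]:
    return {
        "binder_material": (binder, *complexes),
        "substrate_material": tuple(ligand_material),
    }


def build_uniform_binder_scheme(
    k: float,
    K: float,
    k_on: float = DEFAULT_K_ON,
    S0: float = 1.0,
    U0: float = 1.0,
) -> KineticScheme:
    """Single conversion S → P with a uniform binder U.

    U binds substrate and product with the same association constant ``K``
    (μM⁻¹), and the bound conversion US → UP proceeds at the same rate ``k``
    (s⁻¹) as the free one — the encoding of equal binding of S, the
    transition state, and P.  ``U0 = 0`` degenerates to the pure solution
    reaction.
    """
    if k <= 0 or K <= 0 or k_on <= 0 or S0 <= 0 or U0 < 0:
        raise ValueError("k, K, k_on, S0 must be > 0 and U0 >= 0")
    species = (
        SpeciesState("S", Role.SUBSTRATE, Lineage.NONE, S0),
        SpeciesState("P", Role.PRODUCT, Lineage.P1, 0.0),
        SpeciesState("U", Role.BINDER, Lineage.NONE, U0),
        SpeciesState("US", Role.COMPLEX, Lineage.NONE, 0.0),
        SpeciesState("UP", Role.COMPLEX, Lineage.P1, 0.0),
    )
    bindings = (
        BindingStep("U", "S", "US", K, k_on),
        BindingStep("U", "P", "UP", K, k_on),
    )
    conversions = (
        ConversionStep("S", "P", k),
        ConversionStep("US", "UP", k),
    )
    groups = _binder_groups("U", ("US", "UP"), ("S", "P", "US", "UP"))
    return KineticScheme(
        name="uniform_binder",
        species=species,
        bindings=bindings,
        conversions=conversions,
        conservation_groups=groups,
        metadata={"is_uniform": True, "nc_fold": 1.0, "kind": "A"},
    )


def _nc_fold(k_free: float, k_bound: float) -> float:
    if k_bound == 0:
        return math.inf
    return k_free / k_bound


def build_two_product_scheme(
    k1_non: float,
    k2_non: float,
    k1_bound: float,
    k2_bound: float,
    K: float,
    k_on: float = DEFAULT_K_ON,
    S0: float = 1.0,
    Q0: float = 1.0,
) -> KineticScheme:
    """Kinetic partitioning S → P1 / S → P2 with binder Q.

    In solution P2 is favored (conventionally ``k2_non = 10·k1_non``).  Q
    binds S, P1 and P2 uniformly with association constant ``K``; the bound
    conversions run at ``k1_bound`` and ``k2_bound``.  A uniform binder has
    bound rates equal to the free ones; negative catalysis of the P2 route
    is a reduced ``k2_bound`` (``nc_fold = k2_non / k2_bound``).
    """
    for nm, v in [("k1_non", k1_non), ("k2_non", k2_non),
                  ("k1_bound", k1_bound), ("k2_bound", k2_bound)]:
        if v < 0:
            raise ValueError(f"{nm} must be >= 0, got {v}")
    if K <= 0 or k_on <= 0 or S0 <= 0 or Q0 < 0:
        raise ValueError("K, k_on, S0 must be > 0 and Q0 >= 0")
    species = (
        SpeciesState("S", Role.SUBSTRATE, Lineage.NONE, S0),
        SpeciesState("P1", Role.PRODUCT, Lineage.P1, 0.0),
        SpeciesState("P2", Role.PRODUCT, Lineage.P2, 0.0),
        SpeciesState("Q", Role.BINDER, Lineage.NONE, Q0),
        SpeciesState("QS", Role.COMPLEX, Lineage.NONE, 0.0),
        SpeciesState("QP1", Role.COMPLEX, Lineage.P1, 0.0),
        SpeciesState("QP2", Role.COMPLEX, Lineage.P2, 0.0),
    )
    bindings = (
        BindingStep("Q", "S", "QS", K, k_on),
        BindingStep("Q", "P1", "QP1", K, k_on),
        BindingStep("Q", "P2", "QP2", K, k_on),
    )
    conversions = (
        ConversionStep("S", "P1", k1_non),
        ConversionStep("S", "P2", k2_non),
        ConversionStep("QS", "QP1", k1_bound),
        ConversionStep("QS", "QP2", k2_bound),
    )
    groups = _binder_groups(
        "Q", ("QS", "QP1", "QP2"), ("S", "P1", "P2", "QS", "QP1", "QP2")
    )
    is_uniform = (
        math.isclose(k1_bound, k1_non, rel_tol=_REL_TOL)
        and math.isclose(k2_bound, k2_non, rel_tol=_REL_TOL)
    )
    return KineticScheme(
        name="two_product",
        species=species,
        bindings=bindings,
        conversions=conversions,
        conservation_groups=groups,
        metadata={
            "is_uniform": is_uniform,
            "nc_fold": _nc_fold(k2_non, k2_bound),
            "kind": "two-product",
        },
    )


def build_coupled_scheme(
    k1_non: float,
    k2_non: float,
    k1_bound: float,
    k2_bound: float,
    K: float,
    k_f: float,
    k_on: float = DEFAULT_K_ON,
    S0: float = 1.0,
    Q0: float = 1.0,
) -> KineticScheme:
    """Two-product scheme plus a downstream irreversible reaction P1 → Pstar.

    The downstream step acts on *free* P1 only, at rate ``k_f`` (s⁻¹);
    release of trapped QP1 proceeds via dissociation followed by the
    downstream conversion, which pulls the binder back to its unbound state.
    Pstar does not bind Q.  ``k_f = 0`` reduces exactly to the two-product
    scheme (plus an inert Pstar species).
    """
    if k_f < 0:
        raise ValueError(f"k_f must be >= 0, got {k_f}")
    base = build_two_product_scheme(
        k1_non, k2_non, k1_bound, k2_bound, K, k_on=k_on, S0=S0, Q0=Q0
    )
    species = base.species + (
        SpeciesState("Pstar", Role.DOWNSTREAM, Lineage.P1, 0.0),
    )
    conversions = base.conversions + (ConversionStep("P1", "Pstar", k_f),)
    groups = dict(base.conservation_groups)
    groups["substrate_material"] = groups["substrate_material"] + ("Pstar",)
    meta = dict(base.metadata)
    meta.update({"kind": "coupled", "k_f": k_f})
    return KineticScheme(
        name="coupled",
        species=species,
        bindings=base.bindings,
        conversions=conversions,
        conservation_groups=groups,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(scheme: KineticScheme) -> list[str]:
    """Check scheme invariants; returns a list of human-readable violations.

    An empty list means the scheme is structurally and numerically
    consistent.  Violations are data, not exceptions: the integrator refuses
    invalid schemes, but callers may inspect or report them.
    """
    violations: list[str] = []
    names = set(scheme.species_names)

    for b in scheme.bindings:
        for attr in ("binder", "ligand", "complex"):
            if getattr(b, attr) not in names:
                violations.append(
                    f"binding {b.binder}+{b.ligand}: unknown species {getattr(b, attr)!r}"
                )
        if abs(b.k_off * b.K_assoc - b.k_on) > _REL_TOL * b.k_on:
            violations.append(
                f"binding {b.binder}+{b.ligand}: k_off*K_assoc != k_on"
            )
    for c in scheme.conversions:
        for attr in ("reactant", "product"):
            if getattr(c, attr) not in names:
                violations.append(
                    f"conversion {c.reactant}->{c.product}: unknown species "
                    f"{getattr(c, attr)!r}"
                )

    complex_targets = {b.complex for b in scheme.bindings}
    for s in scheme.species:
        if s.role == Role.COMPLEX and s.name not in complex_targets:
            violations.append(f"complex {s.name!r} has no binding step")

    binder_names = {s.name for s in scheme.species if s.role == Role.BINDER}
    for b in scheme.bindings:
        if b.binder not in binder_names:
            violations.append(f"binding {b.complex}: {b.binder!r} is not a binder")

    # conversions stay within a compartment (free or bound to the same binder),
    # except downstream steps whose product has the downstream role
    complex_of = {b.complex: b.binder for b in scheme.bindings}
    for c in scheme.conversions:
        if c.reactant not in names or c.product not in names:
            continue
        if scheme[c.product].role == Role.DOWNSTREAM:
            if c.reactant in complex_of:
                violations.append(
                    f"downstream conversion {c.reactant}->{c.product} must act "
                    "on a free species"
                )
            continue
        same_free = c.reactant not in complex_of and c.product not in complex_of
        same_bound = (
            c.reactant in complex_of
            and c.product in complex_of
            and complex_of[c.reactant] == complex_of[c.product]
        )
        if not (same_free or same_bound):
            violations.append(
                f"conversion {c.reactant}->{c.product} crosses compartments"
            )

    # conservation groups cover every species
    grouped = set()
    for members in scheme.conservation_groups.values():
        for m in members:
            if m not in names:
                violations.append(f"conservation group member {m!r} unknown")
            grouped.add(m)
    ungrouped = names - grouped
    if ungrouped:
        violations.append(f"species in no conservation group: {sorted(ungrouped)}")

    # metadata consistency for uniform schemes
    if scheme.metadata.get("is_uniform"):
        ks = {b.K_assoc for b in scheme.bindings}
        if len(ks) > 1:
            violations.append("is_uniform scheme has unequal association constants")
    return violations


# ---------------------------------------------------------------------------
# serialization (lossless structured-text round trip)
# ---------------------------------------------------------------------------

def _fmt(x: float):
    # shortest-repr floats: YAML/JSON round-trip is bit-lossless
    return float(x)


def scheme_to_dict(scheme: KineticScheme) -> dict:
    return {
        "name": scheme.name,
        "species": [
            {
                "name": s.name,
                "role": s.role.value,
                "lineage": s.lineage.value,
                "initial_concentration": _fmt(s.initial_concentration),
            }
            for s in scheme.species
        ],
        "bindings": [
            {
                "binder": b.binder,
                "ligand": b.ligand,
                "complex": b.complex,
                "K_assoc": _fmt(b.K_assoc),
                "k_on": _fmt(b.k_on),
            }
            for b in scheme.bindings
        ],
        "conversions": [
            {"reactant": c.reactant, "product": c.product, "k": _fmt(c.k)}
            for c in scheme.conversions
        ],
        "conservation_groups": {
            k: list(v) for k, v in scheme.conservation_groups.items()
        },
        "metadata": {
            k: ("inf" if isinstance(v, float) and math.isinf(v) else v)
            for k, v in scheme.metadata.items()
        },
    }


def scheme_from_dict(d: dict) -> KineticScheme:
    meta = dict(d.get("metadata", {}))
    if meta.get("nc_fold") == "inf":
        meta["nc_fold"] = math.inf
    return KineticScheme(
        name=d["name"],
        species=tuple(
            SpeciesState(
                s["name"],
                Role(s["role"]),
                Lineage(s.get("lineage", "none")),
                float(s.get("initial_concentration", 0.0)),
            )
            for s in d["species"]
        ),
        bindings=tuple(
            BindingStep(
                b["binder"], b["ligand"], b["complex"],
                float(b["K_assoc"]), float(b.get("k_on", DEFAULT_K_ON)),
            )
            for b in d.get("bindings", [])
        ),
        conversions=tuple(
            ConversionStep(c["reactant"], c["product"], float(c["k"]))
            for c in d.get("conversions", [])
        ),
        conservation_groups={
            k: tuple(v) for k, v in d.get("conservation_groups", {}).items()
        },
        metadata=meta,
    )


def save_scheme(scheme: KineticScheme, path) -> None:
    """Write a scheme as YAML (``.yaml``/``.yml``) or JSON (anything else)."""
    d = scheme_to_dict(scheme)
    text = (
        yaml.safe_dump(d, sort_keys=False)
        if str(path).endswith((".yaml", ".yml"))
        else json.dumps(d, indent=2)
    )
    with open(path, "w") as fh:
        fh.write(text)


def load_scheme(path) -> KineticScheme:
    with open(path) as fh:
        text = fh.read()
    d = yaml.safe_load(text)
    return scheme_from_dict(d)
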