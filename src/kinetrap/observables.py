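"""Observables: product totals, lineage ratios, binder occupancy, invariance.

All conversions in these schemes are irreversible, so each product *lineage*
(free product + binder-bound product + downstream product) is a
monotonically non-decreasing pool, and

    P1-lineage + P2-lineage + unconverted substrate = S0

at every time point.  The central observables are:

* :func:`total_product` — P_tot = free + bound product for single-lineage
  schemes; invariant to binding strength for a uniform binder.
* :func:`product_ratio` — the P1:P2 lineage ratio at completion, the
  quantity negative catalysis moves away from the solution value k1/k2.
* :func:`binder_state` — binder occupancy fractions, which show the trapped
  product (QP1) and its release by a coupled downstream reaction.
* :func:`invariance_metric` — the maximum deviation of P_tot across schemes
  differing only in binding strength (zero for ideal uniform binders).
* :func:`qe_ratio_oracle` — an independent rapid-equilibrium estimate of the
  product ratio used to cross-check the full ODE route in tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .engine import Trajectory, simulate
from .scheme import KineticScheme, Lineage

__all__ = [
    "LineageTotals",
    "lineage_totals",
    "total_product",
    "product_ratio",
    "binder_state",
    "invariance_metric",
    "qe_ratio_oracle",
    "equilibrium_bound_fraction",
]

COMPLETION_THRESHOLD = 1e-4


@dataclass(frozen=True)
class LineageTotals:
    """Per-lineage product time series (μM) on a trajectory's time grid."""

    t: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.p1 + self.p2


def lineage_totals(traj: Trajectory) -> LineageTotals:
    """Sum each product lineage: P1 = P1 + QP1 + Pstar, P2 = P2 + QP2."""
    scheme = traj.scheme

    def total(lineage: Lineage) -> np.ndarray:
        names = scheme.lineage_species(lineage)
        if not names:
            return np.zeros_like(traj.t)
        cols = [scheme.species_index(n) for n in names]
        return traj.y[:, cols].sum(axis=1)

    return LineageTotals(t=traj.t, p1=total(Lineage.P1), p2=total(Lineage.P2))


def total_product(traj: Trajectory) -> np.ndarray:
    """P_tot(t) = free + bound product (μM) for a single-lineage scheme."""
    lt = lineage_totals(traj)
    n_lineages = sum(
        bool(traj.scheme.lineage_species(l)) for l in (Lineage.P1, Lineage.P2)
    )
    if n_lineages != 1:
        raise ValueError(
            "total_product applies to single-product schemes; "
            "use lineage_totals for multi-lineage schemes"
        )
    return lt.total


def product_ratio(traj: Trajectory, at: float | str = "completion") -> float:
    """P1:P2 lineage ratio at a requested time.

    ``at="completion"`` (default) uses the trajectory's final point and
    requires a trajectory from :func:`~kinetrap.engine.simulate_to_completion`
    flagged completed; a float selects the first grid time ≥ that value.
    A zero P2 lineage yields ``inf`` with a warning.
    """
    lt = lineage_totals(traj)
    if not traj.scheme.lineage_species(Lineage.P2):
        raise ValueError("product_ratio requires a two-product or coupled scheme")
    if isinstance(at, str):
        if at != "completion":
            raise ValueError(f"unknown time selector {at!r}")
        if traj.completed is False:
            warnings.warn(
                "trajectory did not reach completion; ratio taken at final time",
                stacklevel=2,
            )
        i = len(lt.t) - 1
    else:
        if at < lt.t[0] or at > lt.t[-1]:
            raise ValueError(f"time {at} outside trajectory range")
        i = int(np.searchsorted(lt.t, at))
    if lt.p2[i] <= 0:
        warnings.warn("P2 lineage is zero; ratio is infinite", stacklevel=2)
        return math.inf
    return float(lt.p1[i] / lt.p2[i])


def binder_state(traj: Trajectory) -> dict[str, np.ndarray]:
    """Fractions of total binder material: free binder and each complex.

    Returns ``{species_name: fraction(t)}``; fractions sum to 1 (±1e-9) at
    every time point.
    """
    scheme = traj.scheme
    members = scheme.conservation_groups.get("binder_material")
    if not members:
        raise ValueError("scheme has no binder")
    total = traj.group_total("binder_material")
    if np.any(total <= 0):
        raise ValueError("binder total is zero; fractions undefined")
    return {m: traj.species(m) / total for m in members}


def invariance_metric(
    schemes: list[KineticScheme],
    t_end: float | None = None,
    n_points: int = 400,
) -> float:
    """Max relative deviation of P_tot across schemes differing only in binding.

    The schemes must be identical except for their association constants
    and/or on-rates (and the derived off-rates); anything else — rates,
    initial concentrations, topology — raises a structural error.  Returns
    ``max over time and scheme pairs of |ΔP_tot| / S0``; for ideal uniform
    binders this is zero because P_tot is independent of binding strength.
    """
    if len(schemes) < 2:
        raise ValueError("need at least two schemes to compare")
    ref = schemes[0]

    def skeleton(s: KineticScheme):
        return (
            s.species,
            tuple((b.binder, b.ligand, b.complex) for b in s.bindings),
            s.conversions,
        )

    for s in schemes[1:]:
        if skeleton(s) != skeleton(ref):
            raise ValueError(
                "schemes must be identical apart from binding constants"
            )
    if t_end is None:
        from .engine import total_conversion_hazard

        hazard = total_conversion_hazard(ref)
        if hazard <= 0:
            raise ValueError("supply t_end for schemes with zero conversion rates")
        t_end = 10.0 / hazard
    s0 = sum(ref[n].initial_concentration for n in ref.substrate_pool())
    curves = [
        total_product(simulate(s, t_end, n_points=n_points)) for s in schemes
    ]
    worst = 0.0
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            worst = max(worst, float(np.max(np.abs(curves[i] - curves[j])) / s0))
    return worst


# ---------------------------------------------------------------------------
# rapid-equilibrium oracle
# ---------------------------------------------------------------------------

def equilibrium_bound_fraction(K: float, Q_tot: float, L_tot: float) -> float:
    """Bound fraction of ligand at binding equilibrium (all ligands sharing K).

    Solves ``Q_free`` from the closure ``Q_tot = Q_free + L_tot·f`` with
    ``f = K·Q_free / (1 + K·Q_free)``, a quadratic in ``Q_free``; returns f.
    """
    if K <= 0 or Q_tot < 0 or L_tot < 0:
        raise ValueError("K must be > 0 and totals >= 0")
    if Q_tot == 0:
        return 0.0
    # K·Q_free² + (1 + K·(L_tot - Q_tot))·Q_free - Q_tot = 0
    b = 1.0 + K * (L_tot - Q_tot)
    disc = b * b + 4.0 * K * Q_tot
    q_free = (-b + math.sqrt(disc)) / (2.0 * K)
    return K * q_free / (1.0 + K * q_free)


def qe_ratio_oracle(
    k1_non: float,
    k2_non: float,
    k1_b: float,
    k2_b: float,
    K: float,
    S0: float,
    Q0: float,
    n_steps: int = 20_000,
) -> float:
    """Completion P1:P2 ratio under the rapid-equilibrium approximation.

    Treats binding as instantaneously equilibrated: because substrate and
    both products share the same association constant, the bound fraction
    ``f`` of every ligand follows from a single quadratic closure (and stays
    constant as substrate converts to product).  The substrate pool then
    drains with effective hazards ``(1-f)·k_i_non + f·k_i_b``, integrated
    with a plain explicit fine-step scheme.  Used in tests as an independent
    cross-check of the full mass-action route; it ignores the pre-equilibrium
    transient in which free substrate reacts before being sequestered.
    """
    if min(k1_non, k2_non, k1_b, k2_b) < 0 or K <= 0 or S0 <= 0 or Q0 < 0:
        raise ValueError("rates must be >= 0; K, S0 > 0; Q0 >= 0")
    s, p1, p2 = S0, 0.0, 0.0
    h_ref = (k1_non + k2_non + k1_b + k2_b) or 1.0
    t_end = 2.0 * math.log(1.0 / COMPLETION_THRESHOLD) / (h_ref / 2.0)
    dt = t_end / n_steps
    for _ in range(n_steps):
        f = equilibrium_bound_fraction(K, Q0, S0)  # total ligand is conserved = S0
        h1 = (1.0 - f) * k1_non + f * k1_b
        h2 = (1.0 - f) * k2_non + f * k2_b
        # exact exponential sub-step for the linear drain
        h = h1 + h2
        if h == 0:
            break
        ds = s * (1.0 - math.exp(-h * dt))
        s -= ds
        p1 += ds * h1 / h
        p2 += ds * h2 / h
        if s < COMPLETION_THRESHOLD * S0:
            break
    if p2 <= 0:
        return math.inf
    return p1 / p2
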