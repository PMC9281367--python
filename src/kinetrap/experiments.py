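"""End-to-end experiments: the four headline computations of the analysis.

Each ``run_*`` composes the scheme builders, the stiff integrator and the
observables into one reproducible, deterministic computation:

* :func:`run_uniform_invariance` — a uniform binder cannot accelerate a
  unimolecular reaction: the total-product curve P_tot(t) is identical for
  association constants spanning four orders of magnitude and matches the
  solution closed form S0·(1 − e^(−kt)), even though the bound/free product
  partition varies strongly.
* :func:`run_product_diversion` — kinetic partitioning S → P1 / S → P2 with
  the solution bias k2 = 10·k1: a uniform binder leaves the completion
  ratio at 1:10; slowing only the bound S → P2 route 10-fold brings it to
  ≈1, and 100-fold to ≈10:1 — the binder diverts the reaction to the
  kinetically disfavored product without accelerating anything.
* :func:`run_coupled_release` — coupling the trapped product P1 to a
  downstream irreversible reaction P1 → Pstar releases it: the binder-bound
  pool QP1 dominates at first, then drains into free Pstar while the binder
  returns to its unbound state.
* :func:`run_ratio_grid` — the completion P1:P2 ratio as a surface over
  binder:substrate ratio × negative-catalysis fold, monotone in both axes.

All runs are deterministic (no randomness anywhere in the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trajectory, simulate, simulate_to_completion
from .observables import (
    binder_state,
    invariance_metric,
    lineage_totals,
    product_ratio,
    total_product,
)
from .scheme import (
    DEFAULT_K_ON,
    KineticScheme,
    build_coupled_scheme,
    build_two_product_scheme,
    build_uniform_binder_scheme,
)

__all__ = [
    "InvarianceResult",
    "DiversionResult",
    "CoupledResult",
    "RatioGrid",
    "run_uniform_invariance",
    "run_product_diversion",
    "run_coupled_release",
    "run_ratio_grid",
    "DIVERSION_VARIANTS",
    "TIGHT_K",
]

# Solution-reaction rates shared by the partitioning experiments (s⁻¹):
# the disfavored route k1 and the 10× faster favored route k2.
K1_NON = 1e-3
K2_NON = 1e-2

#: Bound S→P2 rate (s⁻¹) per variant: uniform, 10-fold and 100-fold slowing.
DIVERSION_VARIANTS = {
    "uniform": K2_NON,
    "nc10": 1e-3,
    "nc100": 1e-4,
}

#: Association constants (μM⁻¹) for the tight-binding regime, chosen per
#: variant so that the free-substrate pool contributes < 2% of conversion
#: flux (leakage scales as k2_non/√K at equimolar binder and substrate).
TIGHT_K = {"uniform": 1e6, "nc10": 1e6, "nc100": 1e8}

#: On-rate (μM⁻¹·s⁻¹) for the tight-binding regime.  At equimolar binder
#: and substrate, binding equilibration is a second-order annihilation whose
#: tail is slow at ordinary protein on-rates, so free substrate would leak
#: product-2 flux well above the regime's < 2% premise; a diffusion-limited
#: on-rate (10⁹ M⁻¹ s⁻¹) makes sequestration genuinely rapid.
TIGHT_K_ON = 1e3

#: Ambiguous default association constant (μM⁻¹) for the partitioning
#: schemes, shared with the coupled-release experiment.
DEFAULT_K = 1e4


@dataclass(frozen=True)
class InvarianceResult:
    """P_tot curves across binding strengths plus the invariance metric."""

    K_values: tuple[float, ...]
    trajectories: tuple[Trajectory, ...]
    metric: float               # max |ΔP_tot|/S0 across K pairs and time
    closed_form_dev: float      # max |P_tot − S0(1−e^(−kt))|/S0
    partition_spread: float     # max over K pairs of |bound-product fraction difference|

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for K, traj in zip(self.K_values, self.trajectories):
            df = traj.to_dataframe()
            df["P_tot"] = total_product(traj)
            df.insert(0, "K_assoc", K)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def run_uniform_invariance(
    K_list: tuple[float, ...] = (1e-4, 1e-2, 1.0),
    k: float = K1_NON,
    S0: float = 1.0,
    U0: float = 1.0,
    k_on: float = DEFAULT_K_ON,
    n_points: int = 400,
) -> InvarianceResult:
    """Uniform-binder invariance: P_tot(t) is independent of binding strength.

    Builds one single-product uniform-binder scheme per association constant
    in ``K_list``, integrates all to 10 conversion half-lives on a common
    grid, and reports the pairwise invariance metric, the deviation from the
    closed form S0·(1 − e^(−kt)), and how strongly the bound/unbound product
    partition varies with K (it should, even though P_tot does not).
    """
    schemes = [
        build_uniform_binder_scheme(k=k, K=K, k_on=k_on, S0=S0, U0=U0)
        for K in K_list
    ]
    t_end = 10.0 * np.log(2.0) / k
    trajs = [simulate(s, t_end, n_points=n_points) for s in schemes]
    metric = invariance_metric(schemes, t_end=t_end, n_points=n_points)

    closed_dev = 0.0
    for traj in trajs:
        expected = S0 * (1.0 - np.exp(-k * traj.t))
        closed_dev = max(
            closed_dev, float(np.max(np.abs(total_product(traj) - expected)) / S0)
        )

    bound_fracs = []
    for traj in trajs:
        ptot = total_product(traj)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(ptot > 0, traj.species("UP") / ptot, 0.0)
        bound_fracs.append(frac[-1])
    partition_spread = float(max(bound_fracs) - min(bound_fracs))
    return InvarianceResult(
        K_values=tuple(K_list),
        trajectories=tuple(trajs),
        metric=metric,
        closed_form_dev=closed_dev,
        partition_spread=partition_spread,
    )


@dataclass(frozen=True)
class DiversionResult:
    """Completion P1:P2 ratio for one partitioning variant and regime."""

    variant: str
    regime: str
    scheme: KineticScheme
    trajectory: Trajectory
    ratio: float
    free_pool_leakage: float  # fraction of P2 lineage formed from free substrate

    def summary(self) -> dict:
        return {
            "variant": self.variant,
            "regime": self.regime,
            "K_assoc": self.scheme.bindings[0].K_assoc,
            "nc_fold": self.scheme.metadata["nc_fold"],
            "ratio": self.ratio,
            "completion_time_s": self.trajectory.completion_time,
        }


def _diversion_scheme(
    variant: str, regime: str, S0: float, Q0: float, k_on: float
) -> KineticScheme:
    if variant not in DIVERSION_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(DIVERSION_VARIANTS)}"
        )
    if regime == "default":
        K = DEFAULT_K
    elif regime == "tight":
        K = TIGHT_K[variant]
        k_on = TIGHT_K_ON
    else:
        raise ValueError(f"unknown regime {regime!r}; expected 'default' or 'tight'")
    return build_two_product_scheme(
        k1_non=K1_NON,
        k2_non=K2_NON,
        k1_bound=K1_NON,
        k2_bound=DIVERSION_VARIANTS[variant],
        K=K,
        k_on=k_on,
        S0=S0,
        Q0=Q0,
    )


def run_product_diversion(
    variant: str = "nc100",
    regime: str = "tight",
    S0: float = 1.0,
    Q0: float = 1.0,
    k_on: float = DEFAULT_K_ON,
) -> DiversionResult:
    """Completion P1:P2 ratio for the two-product scheme.

    ``variant`` selects the bound S→P2 rate (``uniform``, ``nc10``,
    ``nc100``); ``regime`` selects the association constant: ``"tight"``
    pins the tight-binding regime in which free-pool leakage is negligible,
    ``"default"`` uses K = 10⁴ μM⁻¹ where the ~1% free substrate leaks P2
    flux and the nc100 ratio computes visibly below its fully-sequestered
    value (both are reported, neither hidden).
    """
    scheme = _diversion_scheme(variant, regime, S0, Q0, k_on)
    traj = simulate_to_completion(scheme)
    ratio = product_ratio(traj, at="completion")

    # leakage: P2 formed from free substrate as a fraction of the P2 lineage
    k2b = DIVERSION_VARIANTS[variant]
    s_free = traj.species("S")
    qs = traj.species("QS")
    free_flux = np.trapezoid(K2_NON * s_free, traj.t)
    bound_flux = np.trapezoid(k2b * qs, traj.t)
    total = free_flux + bound_flux
    leakage = float(free_flux / total) if total > 0 else 0.0
    return DiversionResult(
        variant=variant,
        regime=regime,
        scheme=scheme,
        trajectory=traj,
        ratio=ratio,
        free_pool_leakage=leakage,
    )


@dataclass(frozen=True)
class CoupledResult:
    """Coupled-release experiment: trapped product drained by a downstream step."""

    scheme: KineticScheme
    short_window: Trajectory   # the first ~100 min
    long_window: Trajectory    # out to steady state
    dominant_product_short: str
    final_free_binder_fraction: float
    final_pstar: float
    final_p2_lineage: float
    steady: bool               # all derivative magnitudes < 1e-12 μM/s at the end

    def summary(self) -> dict:
        return {
            "dominant_product_short": self.dominant_product_short,
            "final_free_binder_fraction": self.final_free_binder_fraction,
            "final_pstar_uM": self.final_pstar,
            "final_p2_lineage_uM": self.final_p2_lineage,
            "steady": self.steady,
        }


def run_coupled_release(
    K: float = DEFAULT_K,
    k1: float = K1_NON,
    k2_non: float = K2_NON,
    k2_bound: float = 1e-5,
    k_f: float = 0.1,
    S0: float = 1.0,
    Q0: float = 2.0,
    k_on: float = DEFAULT_K_ON,
    short_t_end: float = 6000.0,
    long_t_end: float = 4e6,
) -> CoupledResult:
    """Release of the kinetically trapped product by a coupled reaction.

    The default parameters are the coupled-scheme study conditions: uniform
    binding at K = 10⁴ μM⁻¹, a 1000-fold slower bound S→P2 conversion
    (10⁻⁵ vs 10⁻² s⁻¹), unchanged S→P1 at 10⁻³ s⁻¹, and a downstream
    free-P1 → Pstar step at 0.1 s⁻¹.  Two windows are integrated: the first
    ~100 min, in which nearly all substrate converts to binder-bound P1,
    and a long horizon on which Pstar accumulates and the binder returns to
    its free state.

    The default binder excess Q0 = 2·S0 realizes the scheme's stoichiometric
    prerequisite ([Q]0 ≥ [S]0) with a strict margin: at a finite on-rate,
    exactly equimolar binder leaves the last traces of free substrate
    sequestered only by a slow second-order tail, during which the fast
    solution route leaks several percent of the material into binder-bound
    P2 that never releases — permanently occupying that binder fraction.  A
    strict excess makes sequestration pseudo-first-order and rapid, as the
    trapping argument assumes.
    """
    scheme = build_coupled_scheme(
        k1_non=k1, k2_non=k2_non, k1_bound=k1, k2_bound=k2_bound,
        K=K, k_f=k_f, k_on=k_on, S0=S0, Q0=Q0,
    )
    short = simulate(scheme, short_t_end)
    long = simulate(scheme, long_t_end)

    product_names = [
        s.name for s in scheme.species
        if s.role.value in ("product", "complex", "downstream")
        and s.name != "QS"
    ]
    finals = {n: short.species(n)[-1] for n in product_names}
    dominant = max(finals, key=finals.get)

    fractions = binder_state(long)
    free_q = float(fractions["Q"][-1])
    lt = lineage_totals(long)
    from .engine import compile_scheme

    dy = compile_scheme(scheme).rhs(long.t[-1], long.y[-1])
    return CoupledResult(
        scheme=scheme,
        short_window=short,
        long_window=long,
        dominant_product_short=dominant,
        final_free_binder_fraction=free_q,
        final_pstar=float(long.species("Pstar")[-1]),
        final_p2_lineage=float(lt.p2[-1]),
        steady=bool(np.max(np.abs(dy)) < 1e-12),
    )


@dataclass(frozen=True)
class RatioGrid:
    """Completion P1:P2 ratio surface over binder excess × negative-catalysis fold."""

    q_over_s: tuple[float, ...]
    nc_folds: tuple[float, ...]
    ratios: np.ndarray  # shape (len(q_over_s), len(nc_folds))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.ratios,
            index=pd.Index(self.q_over_s, name="Q0_over_S0"),
            columns=pd.Index(self.nc_folds, name="nc_fold"),
        )
        return df

    def monotone_report(self) -> dict[str, bool]:
        """Non-decreasing along both axes (within a 1e-9 slack for flat columns)."""
        eps = 1e-9
        rows_ok = bool(np.all(np.diff(self.ratios, axis=0) >= -eps * self.ratios[:-1]))
        cols_ok = bool(np.all(np.diff(self.ratios, axis=1) >= -eps * self.ratios[:, :-1]))
        return {"monotone_in_binder": rows_ok, "monotone_in_nc_fold": cols_ok}


def run_ratio_grid(
    q_over_s: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0),
    nc_folds: tuple[float, ...] = (1.0, 10.0, 100.0, 1e3, 1e4),
    k1: float = K1_NON,
    K: float = 1e6,
    S0: float = 1.0,
    k_on: float = DEFAULT_K_ON,
) -> RatioGrid:
    """Completion-ratio surface: binder concentration × degree of negative catalysis.

    Every cell builds a two-product scheme with the solution bias
    k2 = 10·k1, bound S→P2 slowed by the cell's fold, tight binding
    (K = 10⁶ μM⁻¹ default), and integrates to completion.  The surface is
    non-decreasing along both axes: more binder or stronger negative
    catalysis can only favor the P1 lineage.
    """
    k2 = 10.0 * k1
    ratios = np.empty((len(q_over_s), len(nc_folds)))
    for i, qs in enumerate(q_over_s):
        for j, fold in enumerate(nc_folds):
            scheme = build_two_product_scheme(
                k1_non=k1, k2_non=k2, k1_bound=k1, k2_bound=k2 / fold,
                K=K, k_on=k_on, S0=S0, Q0=qs * S0,
            )
            traj = simulate_to_completion(scheme)
            ratios[i, j] = product_ratio(traj, at="completion")
    return RatioGrid(
        q_over_s=tuple(q_over_s), nc_folds=tuple(nc_folds), ratios=ratios
    )
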