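"""Seeded random kinetic scenarios for property testing.

Generates schemes whose parameters are drawn log-uniformly over the regimes
the analysis spans: conversion rates 10⁻⁵–10⁻¹ s⁻¹, association constants
10⁻⁴–10⁶ μM⁻¹, initial concentrations 0.1–100 μM, and negative-catalysis
folds 1–10⁴.  Two-product scenarios keep the solution bias k2 = 10·k1
unless overridden.  Sampling is fully deterministic given (seed, index):
each draw uses ``numpy.random.default_rng`` seeded with the pair via
``SeedSequence``, so streams are independent across indices and identical
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import (
    DEFAULT_K_ON,
    KineticScheme,
    build_coupled_scheme,
    build_two_product_scheme,
    build_uniform_binder_scheme,
)

__all__ = ["ScenarioConfig", "sample_scheme", "sample_schemes", "paired_uniform_control"]


def _check_range(name: str, rng: tuple[float, float]) -> None:
    lo, hi = rng
    if not (0 < lo < hi):
        raise ValueError(f"{name} range must satisfy 0 < low < high, got {rng}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Sampling ranges (log-uniform) and seed for the scenario generator.

    ``kind`` selects the scheme family: ``"A"`` (single-product uniform
    binder), ``"two-product"`` or ``"coupled"``.  ``uniform=True`` forces
    bound rates equal to free rates (nc_fold = 1).
    """

    seed: int
    kind: str = "two-product"
    uniform: bool = False
    k_range: tuple[float, float] = (1e-5, 1e-1)
    K_range: tuple[float, float] = (1e-4, 1e6)
    conc_range: tuple[float, float] = (0.1, 100.0)
    nc_fold_range: tuple[float, float] = (1.0, 1e4)
    kf_range: tuple[float, float] = (1e-3, 1.0)
    solution_bias: float = 10.0  # k2_non / k1_non unless overridden

    def __post_init__(self) -> None:
        if self.kind not in ("A", "two-product", "coupled"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        for name in ("k_range", "K_range", "conc_range", "kf_range"):
            _check_range(name, getattr(self, name))
        lo, hi = self.nc_fold_range
        if not (1.0 <= lo < hi):
            raise ValueError(f"nc_fold range must satisfy 1 <= low < high")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_scheme(cfg: ScenarioConfig, index: int = 0) -> KineticScheme:
    """Draw one scheme; deterministic given (cfg.seed, index)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))
    k1 = _log_uniform(rng, *cfg.k_range)
    K = _log_uniform(rng, *cfg.K_range)
    S0 = _log_uniform(rng, *cfg.conc_range)
    Q0 = _log_uniform(rng, *cfg.conc_range)

    if cfg.kind == "A":
        return build_uniform_binder_scheme(k=k1, K=K, k_on=DEFAULT_K_ON, S0=S0, U0=Q0)

    k2 = cfg.solution_bias * k1
    nc = 1.0 if cfg.uniform else _log_uniform(rng, *cfg.nc_fold_range)
    k1_b, k2_b = k1, k2 / nc
    if cfg.kind == "two-product":
        return build_two_product_scheme(
            k1, k2, k1_b, k2_b, K, k_on=DEFAULT_K_ON, S0=S0, Q0=Q0
        )
    k_f = _log_uniform(rng, *cfg.kf_range)
    return build_coupled_scheme(
        k1, k2, k1_b, k2_b, K, k_f=k_f, k_on=DEFAULT_K_ON, S0=S0, Q0=Q0
    )


def sample_schemes(cfg: ScenarioConfig, count: int) -> list[KineticScheme]:
    return [sample_scheme(cfg, i) for i in range(count)]


def paired_uniform_control(scheme: KineticScheme) -> KineticScheme:
    """The matched uniform-binder control: bound rates reset to free rates.

    Preserves species, concentrations, binding constants and the downstream
    rate; only the bound conversions change, so any difference in outcome is
    attributable to negative catalysis alone.
    """
    if scheme.metadata.get("kind") not in ("two-product", "coupled"):
        raise ValueError("control is defined for two-product or coupled schemes")
    k = {(c.reactant, c.product): c.k for c in scheme.conversions}
    kwargs = dict(
        k1_non=k[("S", "P1")],
        k2_non=k[("S", "P2")],
        k1_bound=k[("S", "P1")],
        k2_bound=k[("S", "P2")],
        K=scheme.bindings[0].K_assoc,
        k_on=scheme.bindings[0].k_on,
        S0=scheme["S"].initial_concentration,
        Q0=scheme["Q"].initial_concentration,
    )
    if scheme.metadata["kind"] == "coupled":
        return build_coupled_scheme(k_f=k[("P1", "Pstar")], **kwargs)
    return build_two_product_scheme(**kwargs)
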