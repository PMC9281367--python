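import numpy as np
import pytest

from kinetrap import (
    build_coupled_scheme,
    build_two_product_scheme,
    build_uniform_binder_scheme,
)


@pytest.fixture
def scheme_a():
    """Single-product uniform binder, moderate binding (K = 1e-2 μM⁻¹)."""
    return build_uniform_binder_scheme(k=1e-3, K=1e-2, S0=1.0, U0=1.0)


@pytest.fixture
def two_product_uniform():
    """Two-product scheme with a uniform binder: solution bias 10, no slowing."""
    return build_two_product_scheme(
        k1_non=1e-3, k2_non=1e-2, k1_bound=1e-3, k2_bound=1e-2, K=1e4
    )


@pytest.fixture
def two_product_nc100():
    """Two-product scheme with 100-fold negative catalysis of the P2 route."""
    return build_two_product_scheme(
        k1_non=1e-3, k2_non=1e-2, k1_bound=1e-3, k2_bound=1e-4, K=1e4
    )


@pytest.fixture
def coupled_scheme():
    """Coupled scheme: 1000-fold bound P2 slowing plus downstream P1 → Pstar."""
    return build_coupled_scheme(
        k1_non=1e-3, k2_non=1e-2, k1_bound=1e-3, k2_bound=1e-5,
        K=1e4, k_f=0.1, Q0=2.0,
    )
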