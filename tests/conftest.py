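import numpy as np
import pytest

from bfmnu import CompositeParams, RedistributiveRates


@pytest.fixture
def worked_rates() -> RedistributiveRates:
    """Consistent rate set with k_e = 0.002 and K = 0.005 h^-1."""
    return RedistributiveRates(k_v=0.003, k_n=0.004, k_vn=0.001, k_nv=0.002)


@pytest.fixture
def example_params() -> CompositeParams:
    return CompositeParams(M_i=80.0, M_f=65.0, k_mi=0.001, k_mf=0.001, alpha=0.002, beta=0.005)


def random_consistent_rates(rng: np.random.Generator) -> RedistributiveRates:
    """Random rates satisfying k_v - k_vn = k_n - k_nv = k_e > 0."""
    k_e = 10.0 ** rng.uniform(-4, -2)
    k_vn = 10.0 ** rng.uniform(-4, -2)
    k_nv = 10.0 ** rng.uniform(-4, -2)
    return RedistributiveRates(k_v=k_e + k_vn, k_n=k_e + k_nv, k_vn=k_vn, k_nv=k_nv)


def unchecked_rates(k_v: float, k_n: float, k_vn: float, k_nv: float) -> RedistributiveRates:
    """Build a RedistributiveRates bypassing constructor validation.

    Used only to probe limiting regimes (e.g. zero elimination) that the
    public constructor rightly rejects.
    """
    r = RedistributiveRates.__new__(RedistributiveRates)
    for name, val in zip(("k_v", "k_n", "k_vn", "k_nv"), (k_v, k_n, k_vn, k_nv)):
        object.__setattr__(r, name, val)
    return r
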