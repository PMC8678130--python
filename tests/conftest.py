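import numpy as np
import pytest

from shutterspeed import synth, twosite


@pytest.fixture
def derived_solution() -> twosite.BiexpSolution:
    """Eigen-solution of the reference parameter set (r1_in=1, r1_ex=30,
    k_io=2, v_ex=0.2), validated against the matrix-exponential oracle."""
    params = twosite.TwoSiteParams(r1_in=1.0, r1_ex=30.0, k_io=2.0, v_ex=0.2)
    return twosite.exchange_eigensystem(params)


@pytest.fixture
def dispersion() -> synth.DispersionTruth:
    return synth.default_dispersion_truth()


@pytest.fixture
def invivo_truth() -> dict:
    v_ex, k_io = 0.30, 0.8
    tau_ex = 1.0 / twosite.influx_from_efflux(k_io, v_ex)
    return {"v_ex": v_ex, "k_io": k_io, "tau_ex": tau_ex}


def random_valid_params(rng: np.random.Generator) -> twosite.TwoSiteParams:
    """Log-uniform rates over [1e-2, 1e3] s^-1, v_ex uniform in (0.05, 0.95)."""
    r1_in, r1_ex, k_io = 10.0 ** rng.uniform(-2, 3, size=3)
    v_ex = rng.uniform(0.05, 0.95)
    return twosite.TwoSiteParams(r1_in=r1_in, r1_ex=r1_ex, k_io=k_io,
                                 v_ex=v_ex)
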