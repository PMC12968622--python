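import pytest

from empabridge import PKParameters, reference_fixture
from empabridge.fixtures import load_scenario


@pytest.fixture(scope="session")
def fixture():
    return reference_fixture()


@pytest.fixture(scope="session")
def population(fixture):
    return fixture.population


@pytest.fixture
def simple_params():
    """Hand-picked valid parameter set used across unit tests."""
    return PKParameters(cl_f=10.083, vc_f=30.0, vp_f=60.0, q_f=10.0, ka=1.5, d1=1.5, alag1=0.5)


def random_params(rng, n=1):
    """Random valid parameter sets with plausible PK magnitudes."""
    out = []
    for _ in range(n):
        out.append(
            PKParameters(
                cl_f=rng.uniform(2, 30),
                vc_f=rng.uniform(10, 80),
                vp_f=rng.uniform(30, 200),
                q_f=rng.uniform(5, 80),
                ka=rng.uniform(0.5, 4),
                d1=rng.uniform(0.2, 3),
                alag1=rng.uniform(0.0, 1.0),
            )
        )
    return out if n > 1 else out[0]


# ---------------------------------------------------------------------------
# Shared 100-replicate SSE runs (expensive; session-scoped so the rich- and
# sparse-design checks and the FIM comparison reuse the same results)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def sse_scenario2(population):
    from empabridge.sse import run_sse

    return run_sse(load_scenario("2"), population, n_replicates=100, base_seed=20240201)


@pytest.fixture(scope="session")
def sse_scenario6(population):
    from empabridge.sse import run_sse

    return run_sse(load_scenario("6"), population, n_replicates=100, base_seed=20240202)
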