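import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_dna(rng):
    def make(n: int, seed: int | None = None) -> str:
        r = rng if seed is None else np.random.default_rng(seed)
        return "".join("ACGT"[i] for i in r.integers(0, 4, n))

    return make


@pytest.fixture(scope="session")
def target_fixture():
    """A 1.5-kb walk fixture shared by the simulator tests."""
    from forkpcr.fixtures import make_fixture

    return make_fixture(8000, 1500, ("target",), seed=3)


@pytest.fixture(scope="session")
def target_pools(target_fixture):
    from forkpcr.walking import (
        SimParams,
        simulate_primary,
        simulate_secondary,
        simulate_tertiary,
    )

    fx = target_fixture
    params = SimParams()
    p1 = simulate_primary(fx.genome_records(), fx.fork.pfp, fx.nsp.onsp, params)
    p2 = simulate_secondary(p1, fx.fork.sfp, fx.fork.bp, fx.nsp.mnsp, params)
    p3 = simulate_tertiary(p2, fx.fork.bp, fx.nsp.insp, params)
    return p1, p2, p3
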