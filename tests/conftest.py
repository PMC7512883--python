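import pytest

from linknull import FixtureSpec, generate, toy_g0


@pytest.fixture
def g0():
    """4-node worked example: A-C:1, B-C:2, A-D:3, B-D:1."""
    return toy_g0()


def make_graph(seed: int, n: int = 50, m: int = 3, coupling: float = 0.0,
               discrete: bool = True, closure: float = 0.6):
    """Seeded synthetic graph used across test modules."""
    return generate(
        FixtureSpec(
            n_nodes=n,
            attachment=m,
            coupling=coupling,
            seed=seed,
            discrete=discrete,
            closure=closure,
        )
    )
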