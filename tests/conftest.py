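import hypothesis
import pytest

import argdraw as ad

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[hypothesis.HealthCheck.too_slow])
hypothesis.settings.load_profile("ci")


@pytest.fixture
def t1() -> ad.D3ARG:
    """The toy 5-node / 5-edge ARG with one recombination node."""
    return ad.toy_T1()


@pytest.fixture(scope="session")
def sim_family() -> list[ad.D3ARG]:
    """A reusable family of small simulated ARGs (distinct seeds)."""
    return [
        ad.simulate_arg(ad.SimParams(n_samples=6, genome_length=1000.0,
                                     recombination_rate=6e-4, seed=s))
        for s in range(20)
    ]


def naive_edges_at(arg: ad.D3ARG, p: float) -> set[int]:
    """Independent brute-force interval scan used as the oracle."""
    hits = set()
    for e in arg.edges:
        for left, right in e.intervals:
            if left <= p < right:
                hits.add(e.id)
    return hits


def args_equivalent(a: ad.D3ARG, b: ad.D3ARG) -> bool:
    """Structural equality up to edge-id relabeling."""
    if a.genome_length != b.genome_length:
        return False
    if sorted((n.id, n.time, n.is_sample) for n in a.nodes) != \
            sorted((n.id, n.time, n.is_sample) for n in b.nodes):
        return False
    ea = sorted((e.parent, e.child, e.intervals) for e in a.edges)
    eb = sorted((e.parent, e.child, e.intervals) for e in b.edges)
    if ea != eb:
        return False
    return [(x.left, x.right) for x in a.breakpoints] == \
        [(x.left, x.right) for x in b.breakpoints]
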