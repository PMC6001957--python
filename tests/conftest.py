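import random

import pytest

from ervpipe.cophylogeny import CophylogenyProblem, CostScheme, random_topology


@pytest.fixture
def rng():
    return random.Random(20240917)


def make_random_problem(rng, n_virus, n_host, multi_host_prob=0.2):
    """Random reconciliation instance (shared by oracle-equivalence tests)."""
    hosts = [f"h{i}" for i in range(n_host)]
    viruses = [f"v{i}" for i in range(n_virus)]
    host_tree = random_topology(hosts, rng)
    virus_tree = random_topology(viruses, rng)
    assoc = {v: {rng.choice(hosts)} for v in viruses}
    for v in viruses:
        if rng.random() < multi_host_prob:
            assoc[v].add(rng.choice(hosts))
    return CophylogenyProblem(host_tree, virus_tree, assoc)


def make_random_costs(rng):
    return CostScheme(*[rng.randint(-2, 3) for _ in range(5)])
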