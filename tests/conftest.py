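import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from fedkg.defaults import ckd_hypernym_map, ckd_ruleset, ckd_vocabulary
from fedkg.protocol import CollaborativeProcess, Node
from fedkg.synthetic_cohort import CohortConfig, generate_consortium

settings.register_profile(
    "fedkg",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fedkg")

SALT = "unit-test-salt"


@pytest.fixture(scope="session")
def vocab():
    return ckd_vocabulary()


@pytest.fixture(scope="session")
def hmap(vocab):
    return ckd_hypernym_map(vocab)


@pytest.fixture(scope="session")
def rules():
    return ckd_ruleset()


def build_nodes(stores, vocab, hmap, rules):
    return [Node(s.hospital_id, s, vocab, hmap, rules) for s in stores]


def run_consortium(stores, vocab, hmap, rules, sponsor="H1", salt=SALT):
    nodes = build_nodes(stores, vocab, hmap, rules)
    return nodes, CollaborativeProcess(nodes, sponsor, salt=salt).run()


@pytest.fixture(scope="session")
def small_consortium():
    """60-patient, 3-hospital consortium with every phenotype present."""
    config = CohortConfig(n_patients=60, seed=11)
    stores, truths = generate_consortium(config)
    return config, stores, truths


@pytest.fixture(scope="session")
def small_run(small_consortium, vocab, hmap, rules):
    _, stores, truths = small_consortium
    nodes, outcome = run_consortium(stores, vocab, hmap, rules)
    return nodes, truths, outcome


def date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)
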