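import numpy as np
import pytest

from ppidom.io_formats import DominTable, InteractionSet, ProteinRecord
from ppidom.synthetic_data import (
    SimConfig,
    simulate_annotations,
    simulate_domine,
    simulate_interactions,
    simulate_proteome,
)


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_bundle(sim_cfg):
    """One deterministic synthetic world shared across tests: proteome,
    localization, interactome with generative probabilities, domain catalogue
    and annotation tables."""
    proteome, loc, compartment_of = simulate_proteome(sim_cfg)
    interactions, probs, affinity = simulate_interactions(
        proteome, sim_cfg, compartment_of
    )
    domine = simulate_domine(affinity, sim_cfg)
    annotations = simulate_annotations(proteome, interactions, sim_cfg)
    return {
        "cfg": sim_cfg,
        "proteome": proteome,
        "proteome_map": {p.protein_id: p for p in proteome},
        "localization": loc,
        "compartment_of": compartment_of,
        "interactions": interactions,
        "edge_probs": probs,
        "affinity": affinity,
        "domine": domine,
        **annotations,
    }


@pytest.fixture()
def toy_proteome():
    """The 4-protein worked example: P1={A}, P2={B}, P3={A}, P4={A}."""
    return [
        ProteinRecord("P1", ("A",)),
        ProteinRecord("P2", ("B",)),
        ProteinRecord("P3", ("A",)),
        ProteinRecord("P4", ("A",)),
    ]


@pytest.fixture()
def toy_interactions():
    s = InteractionSet()
    s.add("P1", "P2")
    s.add("P3", "P4")
    return s


def random_toy_instance(rng: np.random.Generator):
    """Random small proteome + interaction set for oracle comparisons
    (<= 10 proteins, <= 5 domains)."""
    n_prot = int(rng.integers(2, 11))
    n_dom = int(rng.integers(1, 6))
    domains = [f"D{k}" for k in range(n_dom)]
    proteome = []
    for i in range(n_prot):
        k = int(rng.integers(0, n_dom + 1))
        doms = tuple(
            sorted(
                {domains[j] for j in rng.choice(n_dom, size=k, replace=True)}
            )
        ) if k else ()
        proteome.append(ProteinRecord(f"P{i}", doms))
    ids = [p.protein_id for p in proteome]
    interactions = InteractionSet()
    n_edges = int(rng.integers(1, max(2, n_prot)))
    for _ in range(n_edges):
        i, j = rng.integers(0, n_prot, size=2)  # self-pairs allowed
        interactions.add(ids[int(i)], ids[int(j)])
    return proteome, interactions
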