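from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from troopnet.data_model import (
    AgeSexClass,
    Individual,
    ObservationEffort,
    Roster,
    SocialNetwork,
)
from troopnet.pipeline import build_networks
from troopnet.synthetic import generate_study_dataset

settings.register_profile("ci", max_examples=25, deadline=None)
settings.load_profile("ci")


def make_individual(id_: str, label: str = "adult_female",
                    is_study_subject: bool = True) -> Individual:
    return Individual(id_, AgeSexClass.from_label(label), is_study_subject)


def make_roster(n: int, label: str = "adult_female") -> Roster:
    return Roster(make_individual(f"N{i}", label) for i in range(n))


def network_from_edges(
    edges: dict[tuple[str, str], float],
    nodes: list[str] | None = None,
    directed: bool = True,
    classes: dict[str, str] | None = None,
) -> SocialNetwork:
    """Build a SocialNetwork directly from a weight mapping (test helper)."""
    g = nx.DiGraph() if directed else nx.Graph()
    node_set = set(nodes or [])
    for (u, v) in edges:
        node_set.update((u, v))
    classes = classes or {}
    for v in sorted(node_set):
        label = classes.get(v, "adult_female")
        age, _, sex = label.rpartition("_")
        g.add_node(v, age_class=age, sex=sex, age_sex=label)
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w)
    return SocialNetwork(g)


def random_network(n: int, p: float, rng: np.random.Generator,
                   directed: bool = True) -> SocialNetwork:
    """Random weighted digraph with uniform(0.5, 5) weights."""
    edges = {}
    names = [f"N{i}" for i in range(n)]
    for u in names:
        for v in names:
            if u != v and rng.random() < p:
                edges[(u, v)] = float(rng.uniform(0.5, 5.0))
    return network_from_edges(edges, nodes=names, directed=directed)


def uniform_effort(roster: Roster, hours: float = 5.0) -> ObservationEffort:
    return ObservationEffort({i.id: hours for i in roster.study_subjects})


@pytest.fixture(scope="session")
def troop_data():
    return generate_study_dataset(seed=11)


@pytest.fixture(scope="session")
def troop_networks(troop_data):
    roster, effort, events = troop_data
    return build_networks(roster, effort, events)
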