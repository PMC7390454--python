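import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ppicore.synthetic_data import (
    PlantedScenario,
    coordinate_table,
    emit_fixture_files,
    generate_background,
    plant_signal,
    synthetic_study,
)


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


@pytest.fixture
def star4():
    """Star with hub H and three leaves."""
    g = nx.Graph()
    g.add_edges_from([("H", "L1"), ("H", "L2"), ("H", "L3")])
    return g


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture
def planted_scenario():
    return PlantedScenario(
        n_nodes=300, er_p=0.04, n_seeds=15, planted_overlap=6, base_seed=11
    )


@pytest.fixture
def planted_network(planted_scenario):
    net, truth = plant_signal(generate_background(planted_scenario), planted_scenario)
    return net, truth


@pytest.fixture
def fixture_dir(tmp_path):
    """A small emitted file set: planted 60-node network + two studies."""
    scen = PlantedScenario(n_nodes=60, er_p=0.08, n_seeds=8, planted_overlap=4, base_seed=1)
    net, truth = plant_signal(generate_background(scen), scen)
    coords = coordinate_table(net.nodes)
    rng = np.random.default_rng(5)
    studies = [
        synthetic_study("GCST1", truth["seeds"], coords, rng),
        synthetic_study(
            "GCST2", rng.choice(sorted(net.nodes), 5, replace=False), coords, rng,
            trait="trait two",
        ),
    ]
    paths = emit_fixture_files(net, studies, tmp_path, seed=2, extra_low_score_edges=10)
    return {"network": net, "truth": truth, "studies": studies, "paths": paths,
            "coords": coords}


def graphs_equal(g1, g2) -> bool:
    return set(g1.nodes) == set(g2.nodes) and (
        {frozenset(e) for e in g1.edges()} == {frozenset(e) for e in g2.edges()}
    )


@pytest.fixture
def toy_string_files(tmp_path):
    """Three-pair links/actions/aliases/HGNC files (scores 650, 700, 999)."""
    links = tmp_path / "links.tsv"
    actions = tmp_path / "actions.tsv"
    aliases = tmp_path / "aliases.tsv"
    hgnc = tmp_path / "hgnc.tsv"
    pd.DataFrame(
        {
            "protein1": ["P1", "P2", "P3"],
            "protein2": ["P2", "P3", "P1"],
            "combined_score": [650, 700, 999],
        }
    ).to_csv(links, sep="\t", index=False)
    pd.DataFrame(
        {
            "item_id_a": ["P1", "P2", "P3"],
            "item_id_b": ["P2", "P3", "P1"],
            "mode": ["binding", "binding", "binding"],
        }
    ).to_csv(actions, sep="\t", index=False)
    pd.DataFrame(
        {"protein_id": ["P1", "P2", "P3"], "alias": ["GENE1", "GENE2", "GENE3"]}
    ).to_csv(aliases, sep="\t", index=False)
    pd.DataFrame({"symbol": ["GENE1", "GENE2", "GENE3"]}).to_csv(hgnc, sep="\t", index=False)
    return {"links_path": links, "actions_path": actions, "aliases_path": aliases, "hgnc_path": hgnc}
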