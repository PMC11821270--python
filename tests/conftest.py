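import textwrap

import networkx as nx
import pytest

from funbench.ontology import OntologyDAG
from funbench.pair_dataset import PairRecord, label_siblings


@pytest.fixture
def chain_dag():
    """R <- A <- B <- C (edges child -> parent)."""
    g = nx.DiGraph()
    g.add_edges_from([("A", "R"), ("B", "A"), ("C", "B")])
    return OntologyDAG(graph=g)


@pytest.fixture
def diamond_dag():
    """Root R with children A, B; C below both."""
    g = nx.DiGraph()
    g.add_edges_from([("A", "R"), ("B", "R"), ("C", "A"), ("C", "B")])
    return OntologyDAG(graph=g)


@pytest.fixture
def obo_file(tmp_path):
    """Minimal OBO: root R, child A, obsolete term X."""
    text = textwrap.dedent(
        """\
        format-version: 1.2
        ontology: toy

        [Term]
        id: R
        name: root

        [Term]
        id: A
        name: child
        is_a: R ! root

        [Term]
        id: X
        name: gone
        is_obsolete: true
        """
    )
    path = tmp_path / "toy.obo"
    path.write_text(text)
    return path


def make_pairs(scores):
    """PairRecords from [(id1, id2, tm, snn)] or [(id1, id2, tm, snn, ident)]."""
    out = []
    for row in scores:
        ident = row[4] if len(row) > 4 else 0.0
        out.append(
            PairRecord(
                id1=row[0], id2=row[1], tm_score=row[2], snn_score=row[3], seq_identity=ident
            )
        )
    return out


@pytest.fixture
def tiny_dataset():
    """Ten pairs, three siblings, labelled by the default gate."""
    pairs = make_pairs(
        [
            ("p0", "p1", 0.9, 0.99),
            ("p0", "p2", 0.8, 0.985),
            ("p1", "p2", 0.7, 0.98),
            ("p0", "p3", 0.6, 0.99),
            ("p1", "p3", 0.9, 0.5),
            ("p2", "p3", 0.3, 0.2),
            ("p0", "p4", 0.2, 0.9),
            ("p1", "p4", 0.5, 0.97),
            ("p2", "p4", 0.4, 0.1),
            ("p3", "p4", 0.1, 0.3),
        ]
    )
    return label_siblings(pairs)
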