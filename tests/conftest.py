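"""Shared fixtures: tiny knowledge graphs, corpus sentences, random worlds."""

from __future__ import annotations

import numpy as np
import pytest

from ddikg.corpus import AnnotatedSentence, Entity, serialize_semeval
from ddikg.kg_subgraph import KnowledgeGraph


def make_sentence(sent_id: str, text: str, drugs: list[str],
                  pairs: list[tuple[int, int, str]] | None = None,
                  ) -> AnnotatedSentence:
    """Build an annotated sentence by locating each drug name in the text.

    Repeated names are matched left to right.  `pairs` holds entity-index
    pairs with labels; omitted pairs default to Negative at candidate time.
    """
    entities = []
    cursor: dict[str, int] = {}
    for i, name in enumerate(drugs):
        start = text.index(name, cursor.get(name, 0))
        cursor[name] = start + len(name)
        entities.append(Entity(id=f"{sent_id}.e{i}", text=name,
                               span=(start, start + len(name))))
    sent = AnnotatedSentence(doc_id=sent_id.rsplit(".s", 1)[0],
                             sent_id=sent_id, text=text, entities=entities)
    for i, j, label in (pairs or []):
        sent.pairs.append((entities[i].id, entities[j].id, label))
    return sent


TABLE1_TEXT = ("If in certain cases, an antidepressant is considered "
               "necessary, it may be advisable to replace tamoxifen with "
               "anastrozole.")


@pytest.fixture
def advise_example_sentence() -> AnnotatedSentence:
    """The antidepressant/tamoxifen/anastrozole sentence with one Advise pair."""
    return make_sentence("d1.s0", TABLE1_TEXT,
                         ["antidepressant", "tamoxifen", "anastrozole"],
                         pairs=[(0, 1, "Advise"), (0, 2, "Negative"),
                                (1, 2, "Negative")])


@pytest.fixture
def rule_example_sentences() -> list[AnnotatedSentence]:
    """Three sentences whose named negative pairs match filtering rules 1-3."""
    s1 = make_sentence(
        "d2.s0",
        "Repeated oral administration of coumaphos in sheep: interactions of "
        "coumaphos with bishydroxycoumarin, trichlorfon, and phenobarbital "
        "sodium.",
        ["coumaphos", "coumaphos", "bishydroxycoumarin", "trichlorfon",
         "phenobarbital sodium"])
    s2 = make_sentence(
        "d2.s1",
        "Other strong inhibitors of CYP3A4 (e.g., itraconazole, "
        "clarithromycin, nefazodone, troleandomycin, ritonavir, nelfinavir) "
        "would be expected to behave similarly.",
        ["itraconazole", "clarithromycin", "nefazodone", "troleandomycin",
         "ritonavir", "nelfinavir"])
    s3 = make_sentence(
        "d2.s2",
        "The concurrent use of tetracycline and penthrane (methoxyflurane) "
        "has been reported to result in fatal renal toxicity.",
        ["tetracycline", "penthrane", "methoxyflurane"])
    return [s1, s2, s3]


@pytest.fixture
def path_kg() -> KnowledgeGraph:
    """DB1 - P1 - DB2 path with typed edges."""
    return KnowledgeGraph(
        node_types={"DB1": "drug", "DB2": "drug", "P1": "protein"},
        edges=[("DB1", "targets", "P1"), ("DB2", "targets", "P1")],
        relations=["targets"])


def random_typed_graph(rng: np.random.Generator, n_nodes: int,
                       edge_prob: float, n_relations: int = 3,
                       ) -> KnowledgeGraph:
    """Erdős–Rényi-style directed typed graph over `n_nodes` drug nodes."""
    names = [f"N{i:03d}" for i in range(n_nodes)]
    edges = []
    rels = [f"r{k}" for k in range(n_relations)]
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < edge_prob:
                edges.append((names[i], rels[rng.integers(n_relations)],
                              names[j]))
    return KnowledgeGraph(node_types={n: "drug" for n in names},
                          edges=sorted(set(edges)), relations=rels)


@pytest.fixture
def corpus_xml_on_disk(tmp_path, advise_example_sentence,
                       rule_example_sentences):
    path = tmp_path / "corpus.xml"
    path.write_text(serialize_semeval([advise_example_sentence]
                                      + rule_example_sentences))
    return path
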