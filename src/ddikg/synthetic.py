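"""Synthetic typed knowledge graph and annotated corpus generator.

Every pipeline stage needs three inputs that real deployments obtain from
licensed resources: a typed KG edge list, a SemEval-dialect XML corpus, and a
drug-name → DrugBank-ID mapping.  This module fabricates all three with a
*controllable* label signal so that recovery and ablation behaviour can be
tested:

* each interaction label owns a 2-hop KG motif (a shared neighbour reached by
  a label-specific relation, or a direct edge for ``Int``), so hop >= 2
  enclosing subgraphs always contain the planted evidence;
* each label owns a bank of trigger-phrase sentence templates;
* ``signal_placement`` decides which channel is informative: ``both``,
  ``text_only`` (motifs planted for random labels), or ``graph_only``
  (templates drawn from the pooled bank, so trigger words are
  label-uninformative by construction).

Background edges use a dedicated ``related_to`` relation that never
participates in a motif, so with zero label noise the planted signal is
unambiguous and a Bayes-optimal classifier reaches 100% accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import CLASSES, AnnotatedSentence, Entity, serialize_semeval
from .kg_subgraph import KnowledgeGraph

__all__ = ["SyntheticWorldConfig", "PairAnnotation", "generate_synthetic_kg",
           "generate_synthetic_corpus", "write_world", "drug_name_generator"]

BACKGROUND_RELATION = "related_to"

#: label → (relation, partner entity type); None ⇒ direct drug–drug edge
MOTIF_RULES: dict[str, tuple[str, str] | None] = {
    "Mechanism": ("targets", "protein"),
    "Effect": ("associated_with", "disease"),
    "Advise": ("participates_in", "pathway"),
    "Int": None,
    "Negative": None,  # no motif is itself the Negative signal
}

TEMPLATE_BANK: dict[str, list[str]] = {
    "Mechanism": [
        "{D1} inhibits the metabolism of {D2}.",
        "{D1} decreases the oral clearance of {D2} by a third.",
        "Plasma levels of {D2} are elevated when {D1} blocks its breakdown.",
    ],
    "Effect": [
        "{D1} potentiates the hypotensive action of {D2}.",
        "Coadministration of {D1} increases the toxicity of {D2}.",
        "{D1} enhances the sedative response to {D2} in most patients.",
    ],
    "Advise": [
        "{D1} should not be combined with {D2}.",
        "Caution is advised if {D1} is administered together with {D2}.",
        "Avoid prescribing {D1} to patients already taking {D2}.",
    ],
    "Int": [
        "An interaction between {D1} and {D2} has been reported.",
        "{D1} is known to interact with {D2}.",
        "The interaction of {D1} with {D2} was established previously.",
    ],
    "Negative": [
        "{D1} was measured before any administration of {D2}.",
        "Patients received {D1} in one arm while {D2} was given separately.",
        "{D1} pharmacokinetics were unaffected in volunteers not taking {D2}.",
    ],
}

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"
_SUFFIXES = ["ine", "ol", "ide", "ax", "um", "il"]


def drug_name_generator(rng: np.random.Generator):
    """Endless unique pronounceable drug names (CV syllables + suffix)."""
    seen: set[str] = set()
    while True:
        syllables = rng.integers(2, 4)
        name = "".join(rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
                       for _ in range(syllables))
        name += _SUFFIXES[rng.integers(0, len(_SUFFIXES))]
        if name not in seen:
            seen.add(name)
            yield name


@dataclass
class SyntheticWorldConfig:
    n_drugs: int = 60
    n_proteins: int = 40
    n_pathways: int = 20
    n_diseases: int = 20
    n_instances: int = 500
    n_background_edges: int = 150
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {c: 0.2 for c in CLASSES})
    signal_placement: str = "both"        # both | text_only | graph_only
    motif_rate: float = 1.0               # P(planting the motif a label calls for)
    noise_rate: float = 0.0               # P(gold label flipped to another class)
    sentences_per_document: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_placement not in ("both", "text_only", "graph_only"):
            raise ValueError(f"bad signal_placement {self.signal_placement!r}")
        for p in (self.motif_rate, self.noise_rate, *self.class_proportions.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for label in CLASSES:
            if not TEMPLATE_BANK[label]:
                raise ValueError(f"no template for label {label}")


@dataclass
class PairAnnotation:
    """Which pair carries which gold label and which planted motif."""
    u: str                     # synthetic drug node ids
    v: str
    label: str                 # gold class (after label noise)
    motif_label: str | None    # motif actually planted in the KG (None: none)


def _entity_ids(cfg: SyntheticWorldConfig) -> dict[str, list[str]]:
    return {
        "drug": [f"SD{i:04d}" for i in range(cfg.n_drugs)],
        "protein": [f"SP{i:04d}" for i in range(cfg.n_proteins)],
        "pathway": [f"SW{i:04d}" for i in range(cfg.n_pathways)],
        "disease": [f"SS{i:04d}" for i in range(cfg.n_diseases)],
    }


def _sample_labels(cfg: SyntheticWorldConfig,
                   rng: np.random.Generator) -> list[str]:
    labels = [c for c in CLASSES if cfg.class_proportions.get(c, 0) > 0]
    probs = np.array([cfg.class_proportions[c] for c in labels], dtype=float)
    probs /= probs.sum()
    drawn = [str(x) for x in rng.choice(labels, size=cfg.n_instances, p=probs)]
    # label noise: flip to a uniformly random *different* class
    for i in range(len(drawn)):
        if cfg.noise_rate > 0 and rng.random() < cfg.noise_rate:
            others = [c for c in CLASSES if c != drawn[i]]
            drawn[i] = others[rng.integers(0, len(others))]
    return drawn


def generate_synthetic_kg(cfg: SyntheticWorldConfig,
                          ) -> tuple[KnowledgeGraph, list[PairAnnotation]]:
    """Background random graph plus per-pair planted motifs.

    Returns the KG and the pair-annotation table recording, for every
    candidate drug pair, its gold label and the motif actually planted.
    """
    rng = np.random.default_rng(cfg.seed)
    ents = _entity_ids(cfg)
    motif_targets = {"protein": ents["protein"], "pathway": ents["pathway"],
                     "disease": ents["disease"]}
    max_pairs = cfg.n_drugs * (cfg.n_drugs - 1) // 2
    if cfg.n_instances > max_pairs:
        raise ValueError(f"{cfg.n_instances} instances need more than the "
                         f"{max_pairs} distinct pairs of {cfg.n_drugs} drugs")

    all_pairs = [(a, b) for i, a in enumerate(ents["drug"])
                 for b in ents["drug"][i + 1:]]
    chosen = rng.choice(len(all_pairs), size=cfg.n_instances, replace=False)
    labels = _sample_labels(cfg, rng)

    node_types = {e: t for t, ids in ents.items() for e in ids}
    edges: set[tuple[str, str, str]] = set()
    annotations: list[PairAnnotation] = []
    for pair_i, label in zip(chosen, labels):
        u, v = all_pairs[pair_i]
        if cfg.signal_placement == "text_only":
            motif_label = str(rng.choice(CLASSES))   # graph is uninformative
        else:
            motif_label = label
        planted: str | None = None
        rule = MOTIF_RULES[motif_label]
        wants_motif = motif_label != "Negative"
        if wants_motif and rng.random() < cfg.motif_rate:
            planted = motif_label
            if rule is None:   # Int: direct interaction edge
                edges.add((u, "interacts_with", v))
            else:
                relation, ent_type = rule
                partner = str(rng.choice(motif_targets[ent_type]))
                edges.add((u, relation, partner))
                edges.add((v, relation, partner))
        annotations.append(PairAnnotation(u=u, v=v, label=label,
                                          motif_label=planted))

    # background edges on the label-neutral relation; every drug gets at least
    # one so no drug node is absent from the edge list on disk
    non_drugs = [e for t, ids in ents.items() if t != "drug" for e in ids]
    background: set[tuple[str, str, str]] = set()
    for d in ents["drug"]:
        background.add((d, BACKGROUND_RELATION, str(rng.choice(non_drugs))))
    while len(background) < cfg.n_background_edges:
        h = str(rng.choice(ents["drug"]))
        t = str(rng.choice(non_drugs))
        background.add((h, BACKGROUND_RELATION, t))
    edges |= background

    relations = sorted({r for _, r, _ in edges}) or [BACKGROUND_RELATION]
    kg = KnowledgeGraph(node_types=node_types, edges=sorted(edges),
                        relations=relations)
    return kg, annotations


def generate_synthetic_corpus(cfg: SyntheticWorldConfig,
                              annotations: list[PairAnnotation],
                              ) -> tuple[list[AnnotatedSentence], dict[str, str]]:
    """Template sentences for the annotated pairs plus a name → ID mapping.

    The corpus seed is derived from the world seed so KG and corpus stay
    jointly deterministic.  Returns the sentences and the drug-name mapping
    (surface name → synthetic drug id).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    names = drug_name_generator(rng)
    ids = _entity_ids(cfg)["drug"]
    name_of = {d: next(names) for d in ids}
    pooled = [t for bank in TEMPLATE_BANK.values() for t in bank]

    sentences: list[AnnotatedSentence] = []
    for i, ann in enumerate(annotations):
        if cfg.signal_placement == "graph_only":
            template = pooled[rng.integers(0, len(pooled))]
        else:
            bank = TEMPLATE_BANK[ann.label]
            template = bank[rng.integers(0, len(bank))]
        n1, n2 = name_of[ann.u], name_of[ann.v]
        text = template.format(D1=n1, D2=n2)
        s1, s2 = text.find(n1), text.find(n2)
        spans = sorted([(s1, s1 + len(n1), n1), (s2, s2 + len(n2), n2)])
        if s1 < 0 or s2 < 0 or spans[0][1] > spans[1][0]:
            raise RuntimeError(f"could not place mentions for template "
                               f"{template!r}")
        sid = f"syn.d{i // cfg.sentences_per_document}.s{i}"
        ent1 = Entity(id=f"{sid}.e0", text=spans[0][2],
                      span=(spans[0][0], spans[0][1]))
        ent2 = Entity(id=f"{sid}.e1", text=spans[1][2],
                      span=(spans[1][0], spans[1][1]))
        sentences.append(AnnotatedSentence(
            doc_id=f"syn.d{i // cfg.sentences_per_document}", sent_id=sid,
            text=text, entities=[ent1, ent2],
            pairs=[(ent1.id, ent2.id, ann.label)]))
    mapping = {name_of[d]: d for d in ids}
    return sentences, mapping


def write_world(cfg: SyntheticWorldConfig, out_dir) -> dict[str, Path]:
    """Generate a full world and write corpus.xml / kg.tsv / mapping.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kg, annotations = generate_synthetic_kg(cfg)
    sentences, mapping = generate_synthetic_corpus(cfg, annotations)

    paths = {"corpus": out / "corpus.xml", "kg": out / "kg.tsv",
             "mapping": out / "mapping.tsv"}
    paths["corpus"].write_text(serialize_semeval(sentences), encoding="utf-8")
    with open(paths["kg"], "w", encoding="utf-8") as fh:
        for h, r, t in kg.edges:
            fh.write(f"{h}\t{kg.node_types[h]}\t{r}\t{t}\t{kg.node_types[t]}\n")
    with open(paths["mapping"], "w", encoding="utf-8") as fh:
        for name in sorted(mapping):
            fh.write(f"{name}\t{mapping[name]}\n")
    return paths
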