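"""Preprocess → subgraph extraction → training → evaluation orchestration.

The functions here wire the library modules into runnable experiments: parse
and filter a corpus, anchor each candidate pair in the knowledge graph, train
the classifier with the multi-focal loss, and produce evaluation reports with
confusion matrices.  The command-line entry points in :mod:`ddikg.cli` are
thin wrappers over these functions.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .autodiff import Adam, stack
from .corpus import (CLASSES, CLASS_INDEX, CandidateInstance, filter_negatives,
                     generate_candidates, map_to_drugbank, parse_semeval)
from .kg_subgraph import (EnclosingSubgraph, KnowledgeGraph,
                          extract_enclosing_subgraph, label_nodes,
                          load_knowledge_graph)
from .loss_metrics import EvaluationReport, class_weights, evaluate, multi_focal_loss
from .model import ModelConfig, PairClassifier
from .text_encoder import TokenSequence, Vocabulary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one experiment needs; serialisable as flat YAML."""

    corpus_xml: str = ""
    kg_tsv: str = ""
    mapping_tsv: str = ""
    output_dir: str = "runs"
    model: ModelConfig = field(default_factory=ModelConfig)
    lr: float = 5e-5
    batch_size: int = 32
    epochs: int = 5
    weight_decay: float = 0.01
    filter_rules: tuple[str, ...] = ("rule1", "rule2", "rule3")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model_keys = {f for f in ModelConfig.__dataclass_fields__}
        model_kwargs = {k: raw.pop(k) for k in list(raw) if k in model_keys}
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in cls.__dataclass_fields__})
        if model_kwargs:
            cfg.model = replace(cfg.model, **model_kwargs)
        return cfg


@dataclass
class Example:
    """One training/evaluation unit: instance + tokens + labelled subgraph."""

    instance: CandidateInstance
    tokens: TokenSequence
    subgraph: EnclosingSubgraph | None

    @property
    def label_index(self) -> int:
        return CLASS_INDEX[self.instance.label]


def preprocess(corpus_xml, mapping, rules=("rule1", "rule2", "rule3"),
               ) -> tuple[list[CandidateInstance], dict]:
    """Parse, generate candidates, filter negatives, and map to DrugBank IDs."""
    sentences = parse_semeval(corpus_xml)
    candidates: list[CandidateInstance] = []
    for sent in sentences:
        candidates.extend(generate_candidates(sent))
    survivors, removed = filter_negatives(candidates, enabled=tuple(rules))
    mapped, dropped = map_to_drugbank(survivors, mapping)
    stats = {"sentences": len(sentences), "generated": len(candidates),
             "removed_by_rule": removed, "dropped_unmapped": dropped,
             "final": len(mapped),
             "label_counts": {c: sum(1 for i in mapped if i.label == c)
                              for c in CLASSES}}
    logger.info("preprocessing: %s", stats)
    return mapped, stats


def extract_subgraphs(instances: list[CandidateInstance], kg: KnowledgeGraph,
                      hop: int, graph_dim: int, seed: int = 0,
                      ) -> dict[tuple[str, str], EnclosingSubgraph]:
    """Labelled enclosing subgraphs for every distinct drug pair (cached)."""
    embeddings = kg.random_node_embeddings(dim=graph_dim, seed=seed)
    cache: dict[tuple[str, str], EnclosingSubgraph] = {}
    for inst in instances:
        key = (inst.drugbank_id1, inst.drugbank_id2)
        if key not in cache:
            sub = extract_enclosing_subgraph(kg, key[0], key[1], hop)
            cache[key] = label_nodes(sub, embeddings)
    return cache


def build_examples(instances: list[CandidateInstance], model: PairClassifier,
                   subgraphs: dict[tuple[str, str], EnclosingSubgraph] | None,
                   ) -> list[Example]:
    examples = []
    for inst in instances:
        sub = None
        if subgraphs is not None:
            sub = subgraphs.get((inst.drugbank_id1, inst.drugbank_id2))
        examples.append(Example(instance=inst, tokens=model.tokenize(inst),
                                subgraph=sub))
    return examples


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)

    def last(self) -> dict:
        return self.epochs[-1]


def train(model: PairClassifier, examples: list[Example], cfg: RunConfig,
          eval_each_epoch: bool = True) -> TrainLog:
    """Mini-batch training with Adam, weight decay, and the multi-focal loss.

    Per-epoch mean loss (and, optionally, training micro/macro F1) is logged
    and returned.  The epoch count is fixed by `cfg.epochs`; no early
    stopping.
    """
    if not examples:
        raise ValueError("empty training set")
    counts = np.bincount([ex.label_index for ex in examples],
                         minlength=len(CLASSES))
    alpha = class_weights(np.maximum(counts, 0) if counts.sum() else counts,
                          weighting=model.cfg.weighting).alpha
    optim = Adam(model.parameters(), lr=cfg.lr,
                 weight_decay=cfg.weight_decay)
    shuffle_rng = np.random.default_rng(cfg.seed + 17)
    log = TrainLog()
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        order = shuffle_rng.permutation(len(examples))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [examples[i] for i in order[start:start + cfg.batch_size]]
            optim.zero_grad()
            probs = stack([model.forward(ex.tokens, ex.subgraph,
                                         training=True).p for ex in batch])
            labels = np.array([ex.label_index for ex in batch])
            loss = multi_focal_loss(probs, labels, alpha,
                                    gamma=model.cfg.gamma,
                                    focal_form=model.cfg.focal_form)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}")
            loss.backward()
            optim.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "loss": float(np.mean(losses)),
                 "seconds": time.perf_counter() - t0}
        if eval_each_epoch:
            report = evaluate_examples(model, examples)
            entry["train_micro_f1"] = report.micro_f1
            entry["train_macro_f1"] = report.macro_f1
        log.epochs.append(entry)
        logger.info("epoch %d: loss %.4f%s", epoch, entry["loss"],
                    f", micro-F1 {entry['train_micro_f1']:.3f}"
                    if eval_each_epoch else "")
    return log


def predict_examples(model: PairClassifier, examples: list[Example],
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (dropout-off) predicted labels and score matrix."""
    scores = np.stack([model.forward(ex.tokens, ex.subgraph,
                                     training=False).p.data
                       for ex in examples])
    return scores.argmax(axis=1), scores


def evaluate_examples(model: PairClassifier, examples: list[Example],
                      classes: str = "positives_only") -> EvaluationReport:
    predicted, scores = predict_examples(model, examples)
    gold = np.array([ex.label_index for ex in examples])
    return evaluate(gold, predicted, scores, classes=classes)


def confusion_matrix(model: PairClassifier, examples: list[Example],
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Raw and row-normalised confusion matrices (gold × predicted)."""
    predicted, _ = predict_examples(model, examples)
    gold = np.array([ex.label_index for ex in examples])
    m = len(CLASSES)
    raw = np.zeros((m, m), dtype=int)
    np.add.at(raw, (gold, predicted), 1)
    rows = raw.sum(axis=1, keepdims=True)
    normed = np.divide(raw, rows, out=np.zeros_like(raw, dtype=float),
                       where=rows > 0)
    return raw, normed


def run_experiment(cfg: RunConfig) -> tuple[PairClassifier, TrainLog,
                                            EvaluationReport]:
    """Full pipeline from file inputs: preprocess, extract, train, evaluate."""
    instances, _ = preprocess(cfg.corpus_xml, cfg.mapping_tsv,
                              rules=cfg.filter_rules)
    kg = load_knowledge_graph(cfg.kg_tsv)
    vocab = Vocabulary.build([i.text for i in instances])
    model = PairClassifier(replace(cfg.model, seed=cfg.seed), vocab,
                           kg.relations)
    subgraphs = None
    if cfg.model.use_subgraph:
        subgraphs = extract_subgraphs(instances, kg, hop=cfg.model.hop,
                                      graph_dim=cfg.model.graph_dim,
                                      seed=cfg.seed)
    examples = build_examples(instances, model, subgraphs)
    log = train(model, examples, cfg)
    report = evaluate_examples(model, examples)
    return model, log, report


def document_folds(instances: list[CandidateInstance], n_folds: int = 5,
                   seed: int = 0) -> list[list[int]]:
    """Cross-validation folds split by *document* (sentence-id prefix), so all
    instances of a document land in the same fold."""
    docs = sorted({inst.sent_id.rsplit(".s", 1)[0] for inst in instances})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    assignment = {docs[j]: i % n_folds for i, j in enumerate(order)}
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for idx, inst in enumerate(instances):
        folds[assignment[inst.sent_id.rsplit(".s", 1)[0]]].append(idx)
    return folds
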