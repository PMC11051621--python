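"""End-to-end drug-pair classifier: text + position + subgraph → class scores.

One forward pass takes a tokenised anonymised sentence and the labelled
enclosing subgraph of its drug pair, produces the contextual embeddings
``e_w``, the drug-relative position embeddings ``e_p`` and the pair vector
``h_dp``, fuses them (method 2 by default) and emits softmax scores over the
five interaction classes.  The two ablation switches zero an entire channel:
``use_position=False`` zeroes ``e_p`` and ``use_subgraph=False`` replaces
``h_dp`` by a zero vector of the same length.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, parameter
from .corpus import CLASSES, CandidateInstance
from .fusion import FusionConfig, FusionHead, PredictionScores, apply_dropout, predict
from .graph_net import GraphNetConfig, PairGraphNetwork
from .kg_subgraph import EnclosingSubgraph
from .text_encoder import (PositionEmbeddings, TinyEncoder, TokenSequence,
                           Vocabulary, tokenize)

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters for the full classifier.

    The defaults mirror the full-scale configuration (hop 3, graph dimension
    75, position dimension 10, window 5, dropout 0.1, focal gamma 2); the
    ``tiny()`` constructor scales the model down for CPU-sized experiments.
    """

    graph_dim: int = 75
    hop: int = 3
    gnn_layers: int = 3
    gnn_hidden: int = 75
    num_bases: int | None = None
    zeta: float = 0.0
    attention_scale: str = "dim"
    d_w: int = 32
    d_p: int = 10
    max_length: int = 390
    fusion_method: int = 2
    window: int = 5
    conv_channels: int = 64
    dropout: float = 0.1
    d_lstm: int = 32
    gamma: float = 2.0
    focal_form: str = "true_class"
    weighting: str = "printed"
    use_position: bool = True
    use_subgraph: bool = True
    seed: int = 0

    @property
    def gnn_input_dim(self) -> int:
        return self.graph_dim + 2 * (self.hop + 1)

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale configuration used by the synthetic experiments."""
        base = dict(graph_dim=16, hop=2, gnn_layers=2, gnn_hidden=16,
                    d_w=32, d_p=8, conv_channels=24, d_lstm=16, max_length=60)
        base.update(overrides)
        return cls(**base)


class PairClassifier:
    """Owns every trainable component and the prediction layer."""

    def __init__(self, cfg: ModelConfig, vocab: Vocabulary,
                 relations: list[str]):
        self.cfg = cfg
        self.vocab = vocab
        self.relations = list(relations)
        rng = np.random.default_rng(cfg.seed)
        self.encoder = TinyEncoder(vocab, d_w=cfg.d_w,
                                   seed=int(rng.integers(0, 2**31)))
        self.positions = PositionEmbeddings(cfg.d_p, cfg.max_length, rng)
        self.graph_net = PairGraphNetwork(
            relations,
            GraphNetConfig(layers=cfg.gnn_layers, hidden_dim=cfg.gnn_hidden,
                           num_bases=cfg.num_bases, zeta=cfg.zeta,
                           input_dim=cfg.gnn_input_dim,
                           attention_scale=cfg.attention_scale),
            rng)
        self.fusion = FusionHead(
            FusionConfig(method=cfg.fusion_method, window=cfg.window,
                         conv_channels=cfg.conv_channels, dropout=cfg.dropout,
                         d_lstm=cfg.d_lstm),
            d_w=cfg.d_w, d_p=cfg.d_p, d_hdp=self.graph_net.output_dim, rng=rng)
        self.W_pred = parameter(rng, (len(CLASSES), self.fusion.output_dim))
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return (self.encoder.parameters() + self.positions.parameters()
                + self.graph_net.parameters() + self.fusion.parameters()
                + [self.W_pred])

    # -- forward -----------------------------------------------------------
    def tokenize(self, inst: CandidateInstance) -> TokenSequence:
        return tokenize(inst.text, inst.d1_span, inst.d2_span, self.vocab,
                        max_length=self.cfg.max_length)

    def forward(self, seq: TokenSequence, sub: EnclosingSubgraph | None,
                training: bool = False) -> PredictionScores:
        n = len(seq.tokens)
        e_w = self.encoder.encode(seq)
        if self.cfg.use_position:
            e_p = self.positions(seq)
        else:
            e_p = Tensor(np.zeros((n, 2 * self.cfg.d_p)))
        if self.cfg.use_subgraph and sub is not None:
            h_dp = self.graph_net(sub).h_dp
        else:
            h_dp = Tensor(np.zeros(self.graph_net.output_dim))
        fused = self.fusion.fuse(e_w, e_p, h_dp,
                                 d1_token=seq.drug1_tokens[0],
                                 d2_token=seq.drug2_tokens[0])
        H = apply_dropout(fused.H, self.cfg.dropout, self._dropout_rng, training)
        return predict(H, self.W_pred)

    __call__ = forward

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"param_{i:04d}"] = p.data
        return arrays

    def save(self, path) -> None:
        meta = {"version": CHECKPOINT_VERSION, "config": asdict(self.cfg),
                "relations": self.relations, "classes": list(CLASSES)}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            __vocab__=np.frombuffer("\n".join(self.vocab.tokens).encode(),
                                    dtype=np.uint8),
            **self.state_arrays())

    @classmethod
    def load(cls, path) -> "PairClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version "
                                 f"{meta['version']}")
            if meta["classes"] != list(CLASSES):
                raise ValueError("checkpoint class order does not match this "
                                 "build")
            vocab = Vocabulary(bytes(data["__vocab__"]).decode().split("\n"))
            model = cls(ModelConfig(**meta["config"]), vocab, meta["relations"])
            for i, p in enumerate(model.parameters()):
                p.data = np.asarray(data[f"param_{i:04d}"], dtype=float)
        return model
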