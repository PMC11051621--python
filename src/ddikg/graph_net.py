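"""Attention-gated relational message passing over an enclosing subgraph.

The network turns an enclosing subgraph (see :mod:`ddikg.kg_subgraph`) into a
fixed-length drug-pair representation ``h_dp``:

* a per-edge attention score ``alpha = tanh(<h_tgt W_J, h_src W_I + r> / d0)``
  computed once from the layer-0 states; edges with ``alpha <= zeta`` are
  pruned by zeroing their gate ``tau``;
* T rounds of relational message passing where each relation's weight matrix
  is a shared basis combination ``W_r = sum_b a_rb V_b`` and incoming messages
  are FiLM-modulated (scale ``gamma``, shift ``beta``) by an affine map of the
  *target* node's current state;
* a layer-aggregated readout: for every layer (including layer 0) the states
  of the two drugs and the mean-pooled subgraph embedding are concatenated.

Messages flow along each stored edge and along a generated inverse relation,
so the relation vocabulary is doubled internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, parameter
from .kg_subgraph import EnclosingSubgraph

__all__ = ["GraphNetConfig", "EdgeAttention", "PairRepresentation",
           "PairGraphNetwork", "inverse_relation"]


def inverse_relation(rel: str) -> str:
    return f"{rel}^-1"


@dataclass
class GraphNetConfig:
    layers: int = 3                    # T message-passing rounds
    hidden_dim: int = 75               # d_h
    num_bases: int | None = None       # B; defaults to |R| (incl. inverses)
    zeta: float = 0.0                  # attention pruning threshold
    input_dim: int = 83                # d_0 = graph_dim + 2(k+1)
    attention_scale: str = "dim"       # "dim" (as modelled) or "sqrt_dim"

    def __post_init__(self) -> None:
        if self.layers < 1:
            raise ValueError("need at least one message-passing layer")
        if not (-1.0 <= self.zeta < 1.0):
            raise ValueError("zeta must lie in [-1, 1)")
        if self.attention_scale not in ("dim", "sqrt_dim"):
            raise ValueError(f"unknown attention_scale {self.attention_scale!r}")


@dataclass
class EdgeAttention:
    """Directed message edges with attention scores and pruning gates."""

    src: np.ndarray                    # member indices, both directions
    tgt: np.ndarray
    rel: np.ndarray                    # indices into the doubled vocabulary
    alpha: Tensor                      # (E,) in [-1, 1]
    tau: Tensor                        # (E,), 0 where alpha <= zeta

    @property
    def n_surviving(self) -> int:
        return int(np.count_nonzero(self.tau.data))


@dataclass
class PairRepresentation:
    """Per-layer node states and readouts plus the aggregated pair vector."""

    layer_states: list[Tensor]         # T+1 entries, each (n, d_t)
    layer_readouts: list[Tensor]       # T+1 entries, each (d_t,)
    h_dp: Tensor                       # concatenation over layers [h_u; h_v; h_G]


class PairGraphNetwork:
    """The message-passing network; owns all trainable graph-side parameters."""

    def __init__(self, relations: list[str], cfg: GraphNetConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.relations = list(relations) + [inverse_relation(r) for r in relations]
        self.rel_index = {r: i for i, r in enumerate(self.relations)}
        R = len(self.relations)
        B = cfg.num_bases if cfg.num_bases is not None else R
        if not (1 <= B <= R):
            raise ValueError(f"num_bases must lie in [1, {R}], got {B}")
        self.num_bases = B

        d0, dh, T = cfg.input_dim, cfg.hidden_dim, cfg.layers
        self.params: dict[str, Tensor] = {}
        p = self.params
        p["W_I"] = parameter(rng, (d0, d0))
        p["W_J"] = parameter(rng, (d0, d0))
        p["rel_emb"] = parameter(rng, (R, d0))
        for t in range(T):
            din = d0 if t == 0 else dh
            p[f"bases_{t}"] = parameter(rng, (B, din, dh))
            p[f"coeffs_{t}"] = parameter(rng, (R, B))
            p[f"W_self_{t}"] = parameter(rng, (din, dh))
            p[f"gate_W_{t}"] = parameter(rng, (din, 2 * dh))
            p[f"gate_b_{t}"] = parameter(rng, (2 * dh,), zero=True)
        for t in range(T + 1):
            din = d0 if t == 0 else dh
            p[f"W_sub_{t}"] = parameter(rng, (din, din))

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=float)

    # -- edge bookkeeping --------------------------------------------------
    def _directed_edges(self, sub: EnclosingSubgraph):
        """Forward plus inverse message edges as member-index arrays."""
        idx = sub.member_index
        src, tgt, rel = [], [], []
        for h, r, t in sub.induced_edges:
            if r not in self.rel_index:
                raise KeyError(f"relation {r!r} has no embedding in this network")
            src.append(idx[h]); tgt.append(idx[t]); rel.append(self.rel_index[r])
            inv = self.rel_index[inverse_relation(r)]
            src.append(idx[t]); tgt.append(idx[h]); rel.append(inv)
        return (np.asarray(src, dtype=np.intp), np.asarray(tgt, dtype=np.intp),
                np.asarray(rel, dtype=np.intp))

    # -- spec operations ---------------------------------------------------
    def compute_edge_attention(self, sub: EnclosingSubgraph,
                               zeta: float | None = None) -> EdgeAttention:
        """Per-edge signal strength from layer-0 states; gate = 0 below zeta."""
        if sub.init_states is None:
            raise ValueError("subgraph has no init_states; call label_nodes first")
        zeta = self.cfg.zeta if zeta is None else zeta
        src, tgt, rel = self._directed_edges(sub)
        h0 = Tensor(sub.init_states)
        d0 = sub.init_states.shape[1]
        scale = float(d0) if self.cfg.attention_scale == "dim" else float(np.sqrt(d0))
        if len(src) == 0:
            empty = Tensor(np.zeros(0))
            return EdgeAttention(src, tgt, rel, empty, empty)
        proj_src = h0.gather_rows(src) @ self.params["W_I"]
        proj_tgt = h0.gather_rows(tgt) @ self.params["W_J"]
        r_emb = self.params["rel_emb"].gather_rows(rel)
        alpha = ((proj_tgt * (proj_src + r_emb)).sum(axis=1) * (1.0 / scale)).tanh()
        mask = (alpha.data > zeta).astype(float)
        tau = alpha * Tensor(mask)
        return EdgeAttention(src, tgt, rel, alpha, tau)

    def film_gates(self, states: Tensor, layer: int) -> tuple[Tensor, Tensor]:
        """Per-node (gamma, beta) from one affine map of the node state."""
        gb = states @ self.params[f"gate_W_{layer}"] + self.params[f"gate_b_{layer}"]
        dh = self.cfg.hidden_dim
        return gb[:, :dh], gb[:, dh:]

    def relation_weight(self, rel: int | str, layer: int) -> Tensor:
        """Basis-decomposed relation weight W_r = sum_b a_rb V_b."""
        r = self.rel_index[rel] if isinstance(rel, str) else rel
        coeffs = self.params[f"coeffs_{layer}"][r]          # (B,)
        bases = self.params[f"bases_{layer}"]               # (B, din, dh)
        return (coeffs.reshape(-1, 1, 1) * bases).sum(axis=0)

    def propagate_layer(self, states: Tensor, attn: EdgeAttention,
                        layer: int) -> Tensor:
        """One message-passing round: h' = ReLU(W_self h + sum of gated messages)."""
        n = states.shape[0]
        gamma, beta = self.film_gates(states, layer)
        self_term = states @ self.params[f"W_self_{layer}"]
        if len(attn.src) == 0:
            return self_term.relu()
        pieces = []
        order = []
        for r in np.unique(attn.rel):
            e = np.flatnonzero(attn.rel == r)
            W_r = self.relation_weight(int(r), layer)
            transformed = states.gather_rows(attn.src[e]) @ W_r
            msg = gamma.gather_rows(attn.tgt[e]) * transformed \
                + beta.gather_rows(attn.tgt[e])
            pieces.append(attn.tau[e].reshape(-1, 1) * msg)
            order.append(attn.tgt[e])
        messages = concat(pieces, axis=0)
        targets = np.concatenate(order)
        b = messages.scatter_rows(targets, n)
        return (self_term + b).relu()

    def readout(self, sub: EnclosingSubgraph,
                layer_states: list[Tensor]) -> PairRepresentation:
        """Layer-aggregated pair representation [h_u; h_v; mean(W_sub h_i)] per layer."""
        iu = sub.member_index[sub.u]
        iv = sub.member_index[sub.v]
        readouts, blocks = [], []
        for t, states in enumerate(layer_states):
            hg = (states @ self.params[f"W_sub_{t}"]).mean(axis=0)
            readouts.append(hg)
            blocks.extend([states[iu], states[iv], hg])
        return PairRepresentation(layer_states=layer_states,
                                  layer_readouts=readouts,
                                  h_dp=concat(blocks, axis=0))

    def forward(self, sub: EnclosingSubgraph,
                attn: EdgeAttention | None = None) -> PairRepresentation:
        if attn is None:
            attn = self.compute_edge_attention(sub)
        states = [Tensor(sub.init_states)]
        for t in range(self.cfg.layers):
            states.append(self.propagate_layer(states[-1], attn, t))
        return self.readout(sub, states)

    __call__ = forward

    @property
    def output_dim(self) -> int:
        """Length of h_dp: 3 * (d_0 + T * d_h)."""
        return 3 * (self.cfg.input_dim + self.cfg.layers * self.cfg.hidden_dim)
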