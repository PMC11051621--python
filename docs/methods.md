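# Methods

## Problem and model

`ddikg` performs sentence-level drug–drug-interaction (DDI) extraction: given
a biomedical sentence with annotated drug mentions, every unordered pair of
mentions becomes a *candidate instance* that is classified into one of five
types — Mechanism (pharmacokinetic), Effect (pharmacodynamic/clinical),
Advise (recommendation), Int (interaction asserted without detail), or
Negative (no interaction).  The classifier fuses two evidence channels:

1. **Text.**  The candidate sentence is anonymised (the two target mentions
   replaced by `DRUG1`/`DRUG2`), WordPiece-tokenised, and encoded into
   contextual embeddings `e_w` (n × d_w).  Each token also receives a
   drug-relative position embedding `e_p = [T1[o1]; T2[o2]]`, where `o1, o2`
   are signed token-unit offsets to the nearest token of each drug span
   (0 inside the span, clamped to ±max_length) and `T1, T2` are learned
   lookup tables.
2. **Knowledge graph.**  The two drugs are anchored in a typed biomedical
   knowledge graph (drugs, proteins, pathways, diseases; typed relations).
   Their k-hop *enclosing subgraph* — the induced graph on
   `(N_k(u) ∩ N_k(v)) ∪ {u, v}` under the undirected view — is extracted,
   and every member node is labelled with the concatenated one-hots of its
   distances to `u` and to `v` (double-radius labelling, length `2(k+1)`),
   appended to a per-node embedding of dimension `graph_dim`.

The graph channel is processed by an attention-gated relational network:

* **Edge attention** (computed once from the layer-0 states):
  `α_ij = tanh(⟨h_j W_J, h_i W_I + r_ij⟩ / d_0)` with one learned vector
  `r` per (possibly inverse) relation.  The gate `τ_ij = α_ij` when
  `α_ij > ζ`, else 0 — edges below the threshold carry no message.
* **FiLM gating**: per layer, one affine map of the edge's *target* node
  state produces a scale `γ` and shift `β` applied to incoming messages.
* **Relational message passing with basis decomposition**:
  `W_r = Σ_b a_rb V_b` (B shared bases per layer), and
  `h_v ← ReLU(W_self h_v + Σ_{u→v} τ_uv (γ_v ⊙ (h_u W_r) + β_v))`.
  Messages flow along stored edges and along generated inverse relations
  (the relation vocabulary is doubled internally).
* **Layer-aggregated readout**: for every layer t (including layer 0) the
  states of the two drugs and the mean-pooled subgraph embedding
  `mean_i(W_sub h_i)` are concatenated, giving the pair vector `h_dp` of
  length `3(d_0 + T·d_h)`.

**Fusion** (three variants; method 2 is the default): the per-token matrix
`[e_w, e_p]` (method 2), a BiLSTM re-encoding of `e_w` concatenated with
`e_p` (method 1), or a token matrix with `h_dp` and the drug-anchored
position rows appended per token (method 3), is passed through a windowed
convolution with GELU and max-pooled over positions.  For methods 1–2 the
pooled text vector is concatenated with `h_dp`; for method 3 the pooled
vector is the final representation.  A linear layer plus softmax yields the
class distribution; training minimises the multi-class focal loss
`−α_y (1 − p_y)^γ log p_y` (γ = 2) averaged over the batch, with class
weights `α` derived from class counts.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `hop` (k) | 3 | enclosing-subgraph radius |
| `graph_dim` | 75 | per-node embedding length (xavier-uniform, gain 2) |
| `gnn_layers` (T) | 3 | message-passing rounds |
| `gnn_hidden` (d_h) | 75 | hidden state length |
| `num_bases` (B) | \|R\| | basis matrices per layer |
| `zeta` (ζ) | 0.0 | attention pruning threshold (−1 disables pruning) |
| `d_p` | 10 | position-embedding dimension per drug channel |
| `max_length` | 390 | token budget; truncation keeps both drug spans |
| `window` | 5 | convolution window (odd) |
| `dropout` | 0.1 | on the fused vector, training only |
| `gamma` (γ) | 2 | focal modulation exponent |
| `batch` / `epochs` / `lr` | 32 / 5 / 5e-5 | full-scale fine-tuning schedule |
| `weight_decay` | 0.01 | decoupled (AdamW-style) decay |

Defaults mirror the full-scale configuration with a pretrained biomedical
transformer (d_w = 768).  `ModelConfig.tiny()` scales the model to CPU
experiments (d_w = 32 one-layer self-attention encoder with learned absolute
positions, graph_dim 16, hop 2, two GNN layers of width 16, conv channels
24, max_length 60); for this from-scratch regime the experiments in this
repository use Adam at lr 5e-3, the standard magnitude for small networks
trained from scratch, while 5e-5 remains the default for transformer
fine-tuning.

## Design choices where the design was open

* **Distances and message directions.**  BFS distances use the undirected
  view of the KG; messages pass in both directions via explicit inverse
  relations — biomedical relations are traversable both ways for
  neighbourhood semantics, and this matches common relational-GCN practice.
* **Endpoints are always retained** in the subgraph even when the other drug
  is unreachable within k hops; their missing distance maps to the outermost
  one-hot bucket k, keeping label length fixed.
* **Attention is computed once from layer-0 states** and reused across
  layers (the module is layer-independent); the FiLM gates are per-layer.
  The attention divisor is the input length `d_0` (a `sqrt_dim` switch is
  available).  `ζ` defaults to 0.0, pruning the tanh-negative half.
* **Decoupled weight decay.**  "Adam with weight decay" is implemented as
  the AdamW rule (decay applied to the weights, not the gradient), the
  standard for transformer fine-tuning.  Coupled L2 at 0.01 visibly
  suppresses the small gradients that reach the deep graph path.
* **Focal-loss form.**  The default is the standard per-true-class focal
  loss; a `printed_sum` option multiplies by `Σα/m` instead (a constant
  rescaling when Σα = 1).  Likewise `weighting: printed` sets α proportional
  to class counts, with `inverse` frequency available as the alternative
  reading for imbalance correction.
* **Metric scope.**  Per the DDI benchmark convention, micro/macro averages
  exclude the Negative class by default (`classes: positives_only`);
  macro F1 is the harmonic mean of macro precision and macro recall, not
  the mean of per-class F1 scores.  AUC/AUPR are one-vs-rest, trapezoidal,
  with tie groups collapsed; the PR curve is anchored at (recall 0,
  precision 1).
* **Filtering rules.**  The negative-instance filters are heuristic
  operationalisations (identical/acronym names; coordinate lists whose
  in-between text is only drug mentions, commas, conjunctions or "e.g.";
  parenthesised synonyms and "such as"/"including" appositions).  Each rule
  can be toggled; gold-positive instances are never filtered.
* **Method 3 token width.**  The per-token concatenation appends `h_dp`
  twice, as specified for that fusion variant (a `duplicate_hdp=False`
  switch de-duplicates); the position block is `[e_p; e_p(d1); e_p(d2)]`
  giving width `6·d_p`.
* **Cross-validation folds** split by document, so all instances of a
  document share a fold.

## Synthetic data: what it emulates and what it does not

The generator fabricates the three inputs a real deployment needs: a typed
KG edge list, a SemEval-dialect XML corpus, and a name → ID mapping.  Each
label owns (a) a 2-hop KG motif — a shared protein via `targets`
(Mechanism), a shared disease via `associated_with` (Effect), a shared
pathway via `participates_in` (Advise), a direct `interacts_with` edge
(Int); Negative pairs receive no motif — and (b) a bank of trigger-phrase
templates.  Background edges use a dedicated `related_to` relation that
never forms a motif, so with zero label noise the planted signal is
unambiguous (Bayes error 0).  `signal_placement` controls which channel is
informative: `both`, `text_only` (motifs planted for random labels), or
`graph_only` (templates drawn from the pooled bank across labels).  Drug
surface names come from a pronounceable-syllable generator and are unique,
so the name-identity filter never fires accidentally.

The synthetic corpus does **not** emulate real biomedical language:
sentences are short single-pair templates, the vocabulary is tiny, entity
mentions never overlap or repeat, and the KG is orders of magnitude smaller
and noise-free relative to a DrugBank-derived graph.  Passing the recovery
and ablation tests therefore demonstrates that the pipeline is wired
correctly and that each channel can carry label information end to end —
not that the model reaches any particular accuracy on real corpora.

## Numerical choices and degenerate inputs

* All arithmetic is float64 on CPU; every random draw is seeded, and a fixed
  seed reproduces losses and metrics bit-identically.
* Softmax is stabilised by max-subtraction; focal-loss probabilities are
  clamped at 1e-12 with a warning.
* Max-pooling resolves ties toward the first maximising position.
* An empty mini-batch, an empty training set, a zero-probability class
  vector, and a non-finite fused vector raise immediately; a subgraph with
  no edges propagates self-terms only.
* Precision/recall with a zero denominator are defined as 0 (flagged in the
  report); classes without positives are skipped in macro AUC/AUPR with a
  warning.
* Checkpoints store all parameter arrays plus config, relation vocabulary,
  class order and a format version; loading verifies the class order.

## Problem sizes used by the shipped experiments

The synthetic study conditions are 500 instances (noise 0, placement
`both`) for end-to-end recovery and 300 instances per placement for the
channel-ablation comparison, with the tiny configuration above, batch 32,
and 10–12 training epochs; subgraph-oracle and metric-oracle checks use 200
random graphs (≤ 60 nodes) and 100 random 50-instance prediction sets.

## Known limitations

* The pretrained-transformer adapter is an interface only; no pretrained
  weights ship with the package, so full-scale corpus results are out of
  reach here.
* Candidate pairs are intra-sentence only, and entity recognition is
  assumed given (gold mentions).
* The filtering rules are surface heuristics; they approximate, not
  reproduce, the filtering statistics of the published corpus tables.
* Mini-batching is per-instance (no padding across subgraphs); throughput
  is adequate for desk-scale experiments only.
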