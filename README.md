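# ddikg

Sentence-level **drug–drug interaction (DDI) extraction** enhanced with
knowledge-graph enclosing-subgraph features.

Adverse drug–drug interactions are a central concern of pharmacovigilance,
and much of the evidence lives in free text.  Given a biomedical sentence
with annotated drug mentions, every unordered pair of mentions is a
candidate instance to be classified into one of five types: **Mechanism**
(pharmacokinetic, "DRUG1 inhibits the metabolism of DRUG2"), **Effect**
(pharmacodynamic/clinical), **Advise** (a recommendation), **Int** (an
interaction asserted without detail), or **Negative** (no interaction).
Text alone often under-determines the label; this package augments the
sentence with structural evidence about the drug pair drawn from a typed
biomedical knowledge graph (drugs, proteins, pathways, diseases).

The package is aimed at researchers reproducing or extending
subgraph-augmented relation-extraction pipelines: it ships the complete
preprocessing, modelling, training, and evaluation stack, plus a synthetic
world generator so everything is runnable and testable without licensed
corpora or databases.

## The model

For a candidate pair (u, v):

* **Enclosing subgraph.**  The induced subgraph on
  `(N_k(u) ∩ N_k(v)) ∪ {u, v}` — the nodes within k hops of *both* drugs —
  is extracted from the knowledge graph.  Each member i carries a
  double-radius label `p_i = one-hot(d(i,u)) ⊕ one-hot(d(i,v))` appended to
  its node embedding.
* **Attention-gated relational network.**  Per edge,
  `α_ij = tanh(⟨h_j W_J, h_i W_I + r_ij⟩ / d_0)`; edges with `α ≤ ζ` are
  gated out (`τ = 0`).  T rounds of relational message passing follow, with
  basis-decomposed relation weights `W_r = Σ_b a_rb V_b`, FiLM gates
  (γ, β) computed from the target node, and
  `h_v ← ReLU(W_self h_v + Σ τ_uv (γ_v ⊙ (h_u W_r) + β_v))`.  Layer-wise
  readouts `[h_u; h_v; mean_i(W_sub h_i)]` concatenate into the pair vector
  `h_dp`.
* **Text channel.**  The anonymised sentence (mentions → `DRUG1`/`DRUG2`)
  is WordPiece-tokenised and contextually encoded (`e_w`); each token gets
  drug-relative position embeddings (`e_p`).  A windowed CNN with GELU and
  max-pooling turns `[e_w, e_p]` into a fixed text vector (fusion method 2;
  a BiLSTM variant and a token-level concatenation variant are included).
* **Prediction.**  `H = [e_text; h_dp]` feeds a linear layer and softmax;
  training minimises the multi-class focal loss `−α_y (1−p_y)^γ log p_y`
  (γ = 2) with count-derived class weights.  Reports cover per-class and
  micro/macro precision/recall/F1 (macro F1 as the harmonic mean of macro P
  and macro R) plus one-vs-rest AUC and AUPR, excluding the Negative class
  from averages by default, following the DDI benchmark convention.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Generate a synthetic world (knowledge graph + annotated corpus + drug-ID
mapping) whose label signal is planted in both channels, then train the
desk-scale model:

```python
import tempfile
from ddikg import RunConfig, ModelConfig, run_experiment
from ddikg.synthetic import SyntheticWorldConfig, write_world

world = write_world(SyntheticWorldConfig(n_instances=200, seed=7),
                    tempfile.mkdtemp())
cfg = RunConfig(corpus_xml=str(world["corpus"]), kg_tsv=str(world["kg"]),
                mapping_tsv=str(world["mapping"]),
                model=ModelConfig.tiny(), lr=5e-3, epochs=8, seed=7)
model, log, report = run_experiment(cfg)
for entry in log.epochs:
    print(f"epoch {entry['epoch']}  loss {entry['loss']:.4f}  "
          f"train micro-F1 {entry['train_micro_f1']:.3f}")
print(f"final micro-F1 {report.micro_f1:.3f}  macro-F1 {report.macro_f1:.3f}")
```

prints

```
epoch 0  loss 0.1858  train micro-F1 0.710
epoch 1  loss 0.0610  train micro-F1 0.973
epoch 2  loss 0.0067  train micro-F1 1.000
...
epoch 7  loss 0.0000  train micro-F1 1.000
final micro-F1 1.000  macro-F1 1.000
```

The loss falls as the model discovers the planted trigger phrases and KG
motifs; because the synthetic world is noise-free and separable, training
accuracy reaches 100%.  The micro/macro F1 here average over the four
positive classes (Negative excluded).

The same pipeline is scriptable from the shell:

```bash
ddikg synth --out world --instances 200 --seed 7
ddikg preprocess --corpus world/corpus.xml --mapping world/mapping.tsv --out cands.tsv
ddikg train --corpus world/corpus.xml --kg world/kg.tsv \
            --mapping world/mapping.tsv --tiny --epochs 8 --lr 5e-3 \
            --seed 7 --out model.npz
ddikg evaluate --checkpoint model.npz --corpus world/corpus.xml \
               --mapping world/mapping.tsv --kg world/kg.tsv --out report.json
```

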