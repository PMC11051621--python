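"""Tokenisation, drug-relative position embeddings, and contextual encoders.

An anonymised candidate sentence (mentions replaced by ``DRUG1``/``DRUG2``) is
segmented by greedy longest-match WordPiece over a fixed vocabulary, with the
two drug placeholders registered as atomic tokens.  Each token then receives

* a contextual embedding ``e_w`` from a pluggable encoder (the tiny trainable
  encoder below, or any implementation of :class:`EncoderContract`), and
* a drug-relative position embedding ``e_p = [table1[off1]; table2[off2]]``
  where ``off`` is the signed token-unit distance to the nearest token of the
  corresponding drug span (0 inside the span), clamped to ±max_length.
"""

from __future__ import annotations

import re
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, parameter

DRUG1, DRUG2 = "DRUG1", "DRUG2"
UNK, PAD = "[UNK]", "[PAD]"
MAX_LENGTH_DEFAULT = 390

_WORD_RE = re.compile(r"\w+|[^\w\s]")


@dataclass
class TokenSequence:
    tokens: list[str]
    spans: list[tuple[int, int]]         # source-char span per token
    drug1_tokens: tuple[int, int]        # half-open token-index span of DRUG1
    drug2_tokens: tuple[int, int]


class Vocabulary:
    """Token vocabulary with WordPiece continuation pieces (## prefix)."""

    def __init__(self, tokens: list[str]):
        base = [PAD, UNK, DRUG1, DRUG2]
        seen = dict.fromkeys(base)
        seen.update(dict.fromkeys(tokens))
        self.tokens = list(seen)
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, tok: str) -> bool:
        return tok in self.index

    def ids(self, tokens: list[str]) -> np.ndarray:
        unk = self.index[UNK]
        return np.array([self.index.get(t, unk) for t in tokens], dtype=np.intp)

    @classmethod
    def build(cls, texts: list[str]) -> "Vocabulary":
        """Whole lowercase words of `texts`, plus single-character pieces so
        greedy WordPiece can always segment an out-of-vocabulary word."""
        words: dict[str, None] = {}
        chars: set[str] = set()
        for text in texts:
            for w in _WORD_RE.findall(text):
                lw = w.lower()
                words.setdefault(lw, None)
                chars.update(lw)
        pieces = sorted(words) + sorted(chars) + [f"##{c}" for c in sorted(chars)]
        return cls(pieces)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            return cls([line.rstrip("\n") for line in fh if line.rstrip("\n")])


def _wordpiece(word: str, vocab: Vocabulary) -> list[str]:
    """Greedy longest-match segmentation; [UNK] when no prefix matches."""
    pieces: list[str] = []
    pos = 0
    while pos < len(word):
        prefix = "##" if pos else ""
        end = len(word)
        while end > pos:
            cand = prefix + word[pos:end]
            if cand in vocab:
                pieces.append(cand)
                break
            end -= 1
        else:
            return [UNK]
        pos = end
    return pieces


def tokenize(text: str, d1_span: tuple[int, int], d2_span: tuple[int, int],
             vocab: Vocabulary, max_length: int = MAX_LENGTH_DEFAULT,
             ) -> TokenSequence:
    """WordPiece-tokenise an anonymised sentence; DRUG1/DRUG2 stay atomic.

    Sequences longer than `max_length` are truncated from whichever end is
    farther from both drug spans; truncating a drug token is an error.
    """
    for span, name in ((d1_span, DRUG1), (d2_span, DRUG2)):
        if text[span[0]:span[1]] != name:
            raise ValueError(f"span {span} does not cover {name} in {text!r}")
    cuts = sorted([(d1_span, DRUG1), (d2_span, DRUG2)])
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    drug_idx: dict[str, tuple[int, int]] = {}
    pos = 0
    for (s, e), name in cuts:
        for m in _WORD_RE.finditer(text, pos, s):
            for piece in _wordpiece(m.group().lower(), vocab):
                tokens.append(piece)
                spans.append((m.start(), m.end()))
        drug_idx[name] = (len(tokens), len(tokens) + 1)
        tokens.append(name)
        spans.append((s, e))
        pos = e
    for m in _WORD_RE.finditer(text, pos):
        for piece in _wordpiece(m.group().lower(), vocab):
            tokens.append(piece)
            spans.append((m.start(), m.end()))

    d1, d2 = drug_idx[DRUG1], drug_idx[DRUG2]
    lo, hi = 0, len(tokens)
    while hi - lo > max_length:
        near = min(d1[0], d2[0])
        far = max(d1[1], d2[1])
        head_gap = near - lo          # tokens before the first drug
        tail_gap = hi - far           # tokens after the last drug
        if head_gap <= 0 and tail_gap <= 0:
            raise ValueError("max_length too small to keep both drug mentions")
        if tail_gap >= head_gap:
            hi -= 1
        else:
            lo += 1
    if lo or hi != len(tokens):
        tokens, spans = tokens[lo:hi], spans[lo:hi]
        d1 = (d1[0] - lo, d1[1] - lo)
        d2 = (d2[0] - lo, d2[1] - lo)
    return TokenSequence(tokens=tokens, spans=spans,
                         drug1_tokens=d1, drug2_tokens=d2)


def token_offsets(n: int, span: tuple[int, int], max_length: int) -> np.ndarray:
    """Signed distance (token units) to the nearest token of `span`; 0 inside."""
    idx = np.arange(n)
    lo, hi = span
    off = np.where(idx < lo, idx - lo, np.where(idx >= hi, idx - (hi - 1), 0))
    return np.clip(off, -max_length, max_length)


class PositionEmbeddings:
    """Two learned lookup tables of shape (2*max_length+1, d_p), one per drug."""

    def __init__(self, d_p: int, max_length: int, rng: np.random.Generator):
        self.d_p, self.max_length = d_p, max_length
        size = 2 * max_length + 1
        self.table1 = parameter(rng, (size, d_p))
        self.table2 = parameter(rng, (size, d_p))

    def parameters(self) -> list[Tensor]:
        return [self.table1, self.table2]

    def __call__(self, seq: TokenSequence) -> Tensor:
        n, L = len(seq.tokens), self.max_length
        off1 = token_offsets(n, seq.drug1_tokens, L) + L
        off2 = token_offsets(n, seq.drug2_tokens, L) + L
        return concat([self.table1.gather_rows(off1),
                       self.table2.gather_rows(off2)], axis=1)


class EncoderContract(ABC):
    """Deterministic mapping from a token sequence to contextual vectors."""

    @property
    @abstractmethod
    def dim(self) -> int:
        """Output embedding dimension d_w."""

    @abstractmethod
    def encode(self, seq: TokenSequence) -> Tensor:
        """(n, d_w) contextual embedding matrix; n must be >= 1."""

    def parameters(self) -> list[Tensor]:
        return []


class TinyEncoder(EncoderContract):
    """A one-layer self-attention + feed-forward encoder (d_w = 32 default).

    Small enough to train on CPU in tests while still context-sensitive:
    permuting distant tokens changes every output row through the attention
    mixing step.
    """

    def __init__(self, vocab: Vocabulary, d_w: int = 32, seed: int = 0,
                 max_positions: int = 512):
        rng = np.random.default_rng(seed)
        self.vocab = vocab
        self._dim = d_w
        self.embedding = parameter(rng, (len(vocab), d_w))
        # internal absolute positions: without them self-attention would be
        # permutation-equivariant and blind to word order
        self.pos_embedding = parameter(rng, (max_positions, d_w))
        self.Wq = parameter(rng, (d_w, d_w))
        self.Wk = parameter(rng, (d_w, d_w))
        self.Wv = parameter(rng, (d_w, d_w))
        self.W1 = parameter(rng, (d_w, 2 * d_w))
        self.b1 = parameter(rng, (2 * d_w,), zero=True)
        self.W2 = parameter(rng, (2 * d_w, d_w))
        self.b2 = parameter(rng, (d_w,), zero=True)

    @property
    def dim(self) -> int:
        return self._dim

    def parameters(self) -> list[Tensor]:
        return [self.embedding, self.pos_embedding, self.Wq, self.Wk,
                self.Wv, self.W1, self.b1, self.W2, self.b2]

    def encode(self, seq: TokenSequence) -> Tensor:
        if not seq.tokens:
            raise ValueError("cannot encode an empty token sequence")
        ids = self.vocab.ids(seq.tokens)
        E = self.embedding.gather_rows(ids) \
            + self.pos_embedding.gather_rows(np.arange(len(ids)))
        scores = (E @ self.Wq) @ (E @ self.Wk).T * (1.0 / np.sqrt(self._dim))
        H = E + scores.softmax(axis=1) @ (E @ self.Wv)
        return H + (H @ self.W1 + self.b1).gelu() @ self.W2 + self.b2


class PretrainedTransformerAdapter(EncoderContract):
    """Adapter contract for a pretrained biomedical transformer (d_w = 768).

    Requires the optional ``transformers`` dependency at run time; it is an
    interface definition and is not exercised by the test suite.
    """

    def __init__(self, model_name: str = "microsoft/BiomedNLP-PubMedBERT-base"
                                         "-uncased-abstract-fulltext"):
        try:
            import transformers  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "PretrainedTransformerAdapter needs the optional 'transformers' "
                "package; install it or use TinyEncoder") from exc
        self.model_name = model_name  # pragma: no cover

    @property
    def dim(self) -> int:  # pragma: no cover
        return 768

    def encode(self, seq: TokenSequence) -> Tensor:  # pragma: no cover
        raise NotImplementedError("adapter is a contract; wire a transformer "
                                  "model here for full-scale runs")
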