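"""Fusing text features, position features, and the drug-pair graph vector.

Three fusion heads produce a fixed-size vector ``H`` from the per-token text
embeddings ``e_w`` (n × d_w), position embeddings ``e_p`` (n × 2 d_p) and the
pair representation ``h_dp``:

* method 1 — BiLSTM over ``e_w``, concatenate with ``e_p``, windowed CNN with
  GELU, max-pool, then append ``h_dp``;
* method 2 (default) — as method 1 but without the BiLSTM: the CNN consumes
  ``[e_w, e_p]`` directly;
* method 3 — ``h_dp`` and the drug-anchored position rows are appended to
  every token *before* the CNN, whose max-pooled output is ``H`` itself.

``H`` feeds a linear prediction layer followed by softmax over the five
interaction classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, parameter

__all__ = ["FusionConfig", "FusedVector", "PredictionScores", "FusionHead",
           "predict", "apply_dropout"]


@dataclass
class FusionConfig:
    method: int = 2
    window: int = 5                 # convolution window (odd)
    conv_channels: int = 64         # d_c
    dropout: float = 0.1
    d_lstm: int = 32                # method 1 only
    duplicate_hdp: bool = True      # method 3 appends h_dp twice per token

    def __post_init__(self) -> None:
        if self.method not in (1, 2, 3):
            raise ValueError(f"fusion method must be 1, 2 or 3, got {self.method}")
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError(f"convolution window must be odd, got {self.window}")


@dataclass
class FusedVector:
    H: Tensor
    method: int
    input_dims: dict[str, int]


@dataclass
class PredictionScores:
    s: Tensor          # (m,) raw scores
    p: Tensor          # (m,) softmax probabilities


def _window_concat(X: Tensor, window: int) -> Tensor:
    """(n, d) → (n, window*d): zero-padded concatenation of the window
    around each position, so one convolution output exists per token."""
    n, d = X.shape
    half = window // 2
    pad = Tensor(np.zeros((half, d)))
    Xp = concat([pad, X, pad], axis=0)
    return concat([Xp[i:i + n] for i in range(window)], axis=1)


def _tile_rows(vec: Tensor, n: int) -> Tensor:
    """Broadcast a (d,) vector to (n, d) differentiably."""
    return Tensor(np.ones((n, 1))) @ vec.reshape(1, -1)


class _LSTM:
    """Single-direction LSTM; gate order (input, forget, cell, output)."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator):
        self.d_h = d_h
        self.Wx = parameter(rng, (d_in, 4 * d_h))
        self.Wh = parameter(rng, (d_h, 4 * d_h))
        self.b = parameter(rng, (4 * d_h,), zero=True)

    def parameters(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]

    def run(self, X: Tensor, reverse: bool = False) -> Tensor:
        n, _ = X.shape
        dh = self.d_h
        h = Tensor(np.zeros((1, dh)))
        c = Tensor(np.zeros((1, dh)))
        outs: list[Tensor] = []
        order = range(n - 1, -1, -1) if reverse else range(n)
        for t in order:
            z = X[t].reshape(1, -1) @ self.Wx + h @ self.Wh + self.b
            i = z[:, :dh].sigmoid()
            f = z[:, dh:2 * dh].sigmoid()
            g = z[:, 2 * dh:3 * dh].tanh()
            o = z[:, 3 * dh:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        if reverse:
            outs.reverse()
        return concat(outs, axis=0)


class FusionHead:
    """Owns the BiLSTM (method 1) and CNN parameters for one fusion method."""

    def __init__(self, cfg: FusionConfig, d_w: int, d_p: int, d_hdp: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.d_w, self.d_p, self.d_hdp = d_w, d_p, d_hdp
        self.lstm_f = self.lstm_b = None
        if cfg.method == 1:
            self.lstm_f = _LSTM(d_w, cfg.d_lstm, rng)
            self.lstm_b = _LSTM(d_w, cfg.d_lstm, rng)
            token_dim = 2 * cfg.d_lstm + 2 * d_p
        elif cfg.method == 2:
            token_dim = d_w + 2 * d_p
        else:
            reps = 2 if cfg.duplicate_hdp else 1
            token_dim = d_w + reps * d_hdp + 6 * d_p
        self.token_dim = token_dim
        self.W_conv = parameter(rng, (cfg.window * token_dim, cfg.conv_channels))
        self.b_conv = parameter(rng, (cfg.conv_channels,), zero=True)

    def parameters(self) -> list[Tensor]:
        params = [self.W_conv, self.b_conv]
        if self.lstm_f is not None:
            params += self.lstm_f.parameters() + self.lstm_b.parameters()
        return params

    @property
    def output_dim(self) -> int:
        if self.cfg.method == 3:
            return self.cfg.conv_channels
        return self.cfg.conv_channels + self.d_hdp

    # -- shared CNN step ---------------------------------------------------
    def _conv_pool(self, tokens: Tensor) -> Tensor:
        Z = _window_concat(tokens, self.cfg.window)
        C = (Z @ self.W_conv + self.b_conv).gelu()
        return C.max(axis=0)

    # -- the three methods -------------------------------------------------
    def fuse_method1(self, e_w: Tensor, e_p: Tensor, h_dp: Tensor) -> FusedVector:
        l = self.lstm_f.run(e_w)
        r = self.lstm_b.run(e_w, reverse=True)
        e_t = concat([l, r, e_p], axis=1)
        H = concat([self._conv_pool(e_t), h_dp], axis=0)
        return FusedVector(H=H, method=1, input_dims=self._dims(e_w, e_p, h_dp))

    def fuse_method2(self, e_w: Tensor, e_p: Tensor, h_dp: Tensor) -> FusedVector:
        e_t = concat([e_w, e_p], axis=1)
        H = concat([self._conv_pool(e_t), h_dp], axis=0)
        return FusedVector(H=H, method=2, input_dims=self._dims(e_w, e_p, h_dp))

    def fuse_method3(self, e_w: Tensor, e_p: Tensor, h_dp: Tensor,
                     d1_token: int, d2_token: int) -> FusedVector:
        n = e_w.shape[0]
        reps = 2 if self.cfg.duplicate_hdp else 1
        hdp_rows = _tile_rows(h_dp, n)
        e_wdp = concat([e_w] + [hdp_rows] * reps, axis=1)
        e_pdp = concat([e_p,
                        _tile_rows(e_p[d1_token], n),
                        _tile_rows(e_p[d2_token], n)], axis=1)
        e = concat([e_wdp, e_pdp], axis=1)
        H = self._conv_pool(e)
        return FusedVector(H=H, method=3, input_dims=self._dims(e_w, e_p, h_dp))

    def fuse(self, e_w: Tensor, e_p: Tensor, h_dp: Tensor,
             d1_token: int = 0, d2_token: int = 0) -> FusedVector:
        if e_w.shape[0] < 1:
            raise ValueError("need at least one token")
        if e_w.shape[0] != e_p.shape[0]:
            raise ValueError(f"sequence length mismatch: e_w has {e_w.shape[0]} "
                             f"rows, e_p has {e_p.shape[0]}")
        if self.cfg.method == 1:
            return self.fuse_method1(e_w, e_p, h_dp)
        if self.cfg.method == 2:
            return self.fuse_method2(e_w, e_p, h_dp)
        return self.fuse_method3(e_w, e_p, h_dp, d1_token, d2_token)

    def _dims(self, e_w, e_p, h_dp) -> dict[str, int]:
        return {"d_w": e_w.shape[1], "d_p2": e_p.shape[1],
                "d_hdp": h_dp.shape[0], "token_dim": self.token_dim}


def apply_dropout(H: Tensor, p: float, rng: np.random.Generator,
                  training: bool) -> Tensor:
    """Inverted dropout on the fused vector; identity when not training."""
    if not training or p <= 0.0:
        return H
    mask = (rng.random(H.shape) >= p) / (1.0 - p)
    return H * Tensor(mask)


def predict(H: Tensor, W_pred: Tensor) -> PredictionScores:
    """Linear scores s = W_pred H and softmax class probabilities."""
    if not np.all(np.isfinite(H.data)):
        raise ValueError("fused vector contains non-finite values")
    s = W_pred @ H
    return PredictionScores(s=s, p=s.softmax(axis=-1))
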