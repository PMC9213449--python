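"""Shared-representation multi-task sequence labeling network.

The trunk follows the transformer -> CNN stack -> bidirectional LSTM
layout of OPUS-TASS-style secondary structure predictors; one output head
per active task sits on top of the shared representation, so every task's
gradient reaches every trunk layer. The ``paper`` preset mirrors the
published layer counts (2 transformer, 5 CNN, 4 biLSTM, dropout 0.25);
internal widths are pragmatic defaults, not normative. The ``tiny``
preset is a CPU desk-scale configuration used by the synthetic-data
experiments and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import ProteinRecord
from .nn import (
    BiLSTM,
    Conv1d,
    Dense,
    Dropout,
    ForwardContext,
    Module,
    Tensor,
    TransformerLayer,
)

TASK_N_CLASSES = {"IF": 2, "BU": 2, "S3": 3, "S8": 8, "SA": 1}
N_FEATURES = 76


@dataclass(frozen=True)
class ModelConfig:
    active_tasks: Tuple[str, ...] = ("IF",)
    preset: str = "tiny"
    n_transformer_layers: int = 1
    n_cnn_layers: int = 2
    n_birnn_layers: int = 1
    dropout: float = 0.25
    d_model: int = 32
    n_heads: int = 2
    d_ff: int = 48
    conv_channels: int = 32
    conv_kernel: int = 5
    lstm_hidden: int = 16
    # data enhancement (random contiguous fragment sampling)
    enhance_prob: float = 0.5
    enhance_min_length: int = 30

    def __post_init__(self) -> None:
        if not self.active_tasks:
            raise ValueError("active_tasks must be non-empty")
        unknown = set(self.active_tasks) - set(TASK_N_CLASSES)
        if unknown:
            raise ValueError(f"unknown task(s): {sorted(unknown)}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def tiny_config(active_tasks: Sequence[str] = ("IF",), **overrides) -> ModelConfig:
    """Desk-scale preset: < 200k parameters, CPU-friendly."""
    return ModelConfig(active_tasks=tuple(active_tasks), preset="tiny",
                       **overrides)


def paper_config(active_tasks: Sequence[str] = ("IF",), **overrides) -> ModelConfig:
    """Published layer counts: 2 transformer + 5 CNN + 4 biLSTM, dropout 0.25."""
    defaults = dict(
        preset="paper",
        n_transformer_layers=2,
        n_cnn_layers=5,
        n_birnn_layers=4,
        dropout=0.25,
        d_model=64,
        n_heads=4,
        d_ff=128,
        conv_channels=64,
        conv_kernel=5,
        lstm_hidden=64,
    )
    defaults.update(overrides)
    return ModelConfig(active_tasks=tuple(active_tasks), **defaults)


def variant_name(active_tasks: Sequence[str]) -> str:
    """Canonical model name: concatenated task codes in IF BU S3 S8 SA order."""
    order = ("IF", "BU", "S3", "S8", "SA")
    return "".join(t for t in order if t in set(active_tasks))


class MultiTaskModel(Module):
    """Trunk shared by all tasks plus one output head per active task."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dim = config.d_model
        self.input_proj = Dense(rng, N_FEATURES, dim, "input")
        self.transformers = [
            TransformerLayer(rng, dim, config.n_heads, config.d_ff,
                             config.dropout, f"tf{i}")
            for i in range(config.n_transformer_layers)
        ]
        self.convs = []
        for i in range(config.n_cnn_layers):
            self.convs.append(
                Conv1d(rng, dim, config.conv_channels, config.conv_kernel,
                       f"conv{i}")
            )
            dim = config.conv_channels
        self.bilstms = []
        for i in range(config.n_birnn_layers):
            self.bilstms.append(BiLSTM(rng, dim, config.lstm_hidden, f"rnn{i}"))
            dim = 2 * config.lstm_hidden
        self.drop = Dropout(config.dropout)
        self.heads = {
            t: Dense(rng, dim, TASK_N_CLASSES[t], f"head_{t}")
            for t in config.active_tasks
        }

    def parameters(self):
        params = super().parameters()
        seen = {id(p) for p in params}
        for head in self.heads.values():
            for p in head.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    # -- forward -----------------------------------------------------------
    def forward(
        self,
        features: np.ndarray,
        lengths: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Dict[str, Tensor]:
        """Per-task per-residue logits (SA: raw values) on a padded batch.

        ``features`` is (B, T, 76); positions at or beyond each protein's
        length are padding and are zeroed between stages, masked as
        attention keys, and excluded from the backward LSTM reversal.
        """
        if features.ndim != 3 or features.shape[2] != N_FEATURES:
            raise ValueError(
                f"features must be (B, T, {N_FEATURES}), got {features.shape}"
            )
        B, T, _ = features.shape
        step_mask = (
            np.arange(T)[None, :] < np.asarray(lengths)[:, None]
        ).astype(float)[:, :, None]
        ctx = ForwardContext(
            lengths=np.asarray(lengths), step_mask=step_mask, train=train,
            rng=rng,
        )
        x = Tensor(features * step_mask)
        x = self.input_proj(x).relu() * ctx.step_mask
        for layer in self.transformers:
            x = layer(x, ctx)
        for conv in self.convs:
            x = self.drop(conv(x).relu(), ctx) * ctx.step_mask
        for rnn in self.bilstms:
            x = self.drop(rnn(x, ctx), ctx)
        return {t: head(x) for t, head in self.heads.items()}

    def predict(
        self, features: np.ndarray, lengths: np.ndarray
    ) -> Dict[str, np.ndarray]:
        """Probability vectors per classification task; raw SA values.

        Classification heads are softmax-normalized per residue; the SA
        head returns one real per residue (B, T).
        """
        logits = self.forward(features, lengths, train=False)
        out = {}
        for t, lg in logits.items():
            if t == "SA":
                out[t] = lg.data[:, :, 0]
            else:
                z = lg.data - lg.data.max(axis=-1, keepdims=True)
                e = np.exp(z)
                out[t] = e / e.sum(axis=-1, keepdims=True)
        return out


def build_model(config: ModelConfig, seed: int = 0) -> MultiTaskModel:
    """Glorot-initialized model with one head per active task."""
    return MultiTaskModel(config, seed=seed)


def pad_batch(
    records: Sequence[ProteinRecord], pad_to: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray, Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Stack records into padded arrays.

    Returns (features (B,T,76), lengths (B,), targets task->(B,T),
    masks task->(B,T)); padded positions carry mask False for every task,
    so the loss machinery needs no padding special case.
    """
    lengths = np.array([r.length for r in records])
    T = int(pad_to or lengths.max())
    if T < lengths.max():
        raise ValueError("pad_to smaller than longest record")
    B = len(records)
    feats = np.zeros((B, T, N_FEATURES))
    targets = {t: np.zeros((B, T)) for t in TASK_N_CLASSES}
    masks = {t: np.zeros((B, T), dtype=bool) for t in TASK_N_CLASSES}
    for b, rec in enumerate(records):
        L = rec.length
        feats[b, :L] = rec.features.values
        for t in TASK_N_CLASSES:
            targets[t][b, :L] = rec.labels[t]
            masks[t][b, :L] = rec.masks[t]
    return feats, lengths, targets, masks


def augment_batch(
    records: Sequence[ProteinRecord],
    config: ModelConfig,
    rng: np.random.Generator,
    enabled: bool = True,
) -> List[ProteinRecord]:
    """Data enhancement: random contiguous fragment sampling.

    Each record is replaced, with probability ``config.enhance_prob``, by
    a random contiguous fragment of length >= ``config.enhance_min_length``
    (labels and masks cropped consistently). Records shorter than the
    minimum pass through unchanged. Deterministic under the caller's rng.
    """
    if not enabled:
        return list(records)
    out: List[ProteinRecord] = []
    for rec in records:
        if rec.length <= config.enhance_min_length or \
                rng.random() >= config.enhance_prob:
            out.append(rec)
            continue
        frag_len = int(rng.integers(config.enhance_min_length, rec.length))
        start = int(rng.integers(0, rec.length - frag_len + 1))
        out.append(rec.crop(start, start + frag_len))
    return out
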