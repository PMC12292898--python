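"""The three scoring networks and their training loop.

* **Diagnosis head** (PD vs healthy) — input FTF (4×97 envelope map):
  1-D convolution–batch-norm–ReLU blocks over the cycle axis with
  max-pooling and dropout (p = 0.3), then an LSTM over the pooled sequence
  and a 2-class softmax.
* **Evaluation head** (UPDRS gait level 0/1/2) — input ETFF (100×97×4
  scalogram volume): 3-D convolution blocks over (scale, time, channel),
  global average pooling, 3-class softmax.  Per-level probabilities are
  required downstream by the threshold-based fusion rules, hence a
  classification (not scalar-regression) output.
* **Balance head** (severe balance impairment, level 2, vs not) — input MF
  (4×6 kinematic summary): the six kinematic features are embedded as
  tokens, weighted by scaled dot-product self-attention (weights exposed
  for inspection), and aggregated into a 2-class softmax.

All heads stay well under 10⁵ parameters and train deterministically from a
seed (Adam, cross-entropy, early stopping on a validation split).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .core import DegenerateLabelsError, EMG_CHANNELS, SchemaError
from .nn import (
    avg_pool,
    Adam,
    BatchNorm,
    Conv1d,
    Conv3d,
    Dropout,
    Linear,
    LSTM,
    Module,
    SelfAttention,
    Tensor,
    cross_entropy,
    max_pool,
)


@dataclass
class HeadConfig:
    head: str = "diagnosis"  # diagnosis | evaluation | balance
    conv_blocks: int = 2
    channels: Tuple[int, ...] = (16, 32)
    kernel: int = 5
    dropout_p: float = 0.3
    lstm_hidden: int = 32
    attention_dim: int = 8
    lr: float = 1e-3
    epochs: int = 60
    batch_size: int = 16
    patience: int = 10
    min_epochs: int = 15  # burn-in before early stopping may trigger
    val_fraction: float = 0.2
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_p < 1:
            raise SchemaError("dropout_p must be in [0, 1)")
        for name in ("conv_blocks", "lstm_hidden", "attention_dim",
                     "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be positive")


def default_head_config(head: str, seed: int = 0) -> "HeadConfig":
    """Per-head default hyperparameters (desk-scale, < 10⁵ parameters)."""
    if head == "diagnosis":
        return HeadConfig(head=head, seed=seed, lr=1e-3, epochs=45)
    if head == "evaluation":
        return HeadConfig(head=head, seed=seed, lr=3e-3, epochs=40)
    if head == "balance":
        return HeadConfig(head=head, seed=seed, lr=1e-2, epochs=150,
                          dropout_p=0.1)
    raise SchemaError(f"unknown head {head!r}")


@dataclass(frozen=True)
class HeadProbabilities:
    p_pd: float
    p_level: np.ndarray  # (3,)
    p_balance_impaired: float

    def __post_init__(self) -> None:
        p = np.asarray(self.p_level, dtype=float)
        if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-6:
            raise SchemaError("p_level must be a 3-vector summing to 1")
        if not (0 <= self.p_pd <= 1 and 0 <= self.p_balance_impaired <= 1):
            raise SchemaError("probabilities must lie in [0, 1]")


class DiagnosisHead(Module):
    """1-D conv stack + LSTM over the 97-point envelope axis → 2 classes."""

    def __init__(self, config: HeadConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        chans = [4] + list(config.channels[:config.conv_blocks])
        self.convs = [Conv1d(chans[i], chans[i + 1], config.kernel, rng)
                      for i in range(config.conv_blocks)]
        self.bns = [BatchNorm(c) for c in chans[1:]]
        self.dropout = Dropout(config.dropout_p, rng)
        self.lstm = LSTM(chans[-1], config.lstm_hidden, rng)
        self.fc = Linear(config.lstm_hidden, 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for conv, bn in zip(self.convs, self.bns):
            x = bn(conv(x)).relu()
            x = max_pool(x, (2,))
        x = self.dropout(x)
        x = x.transpose((0, 2, 1))  # (B, T, C) for the LSTM
        return self.fc(self.lstm(x))


class EvaluationHead(Module):
    """3-D conv stack over the (scale, time, channel) volume → 3 classes.

    The 100×97×4 scalogram volume is average-pooled (default 5×6×1) before
    the convolution blocks: scalogram energy varies smoothly over scale and
    cycle time, so the pooled volume keeps the discriminative structure
    while keeping the network desk-scale.
    """

    def __init__(self, config: HeadConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.input_pool = (5, 6, 1)
        chans = [1, 8, 16][: config.conv_blocks + 1]
        self.convs = [Conv3d(chans[i], chans[i + 1], (3, 3, 2), rng)
                      for i in range(len(chans) - 1)]
        self.bns = [BatchNorm(c) for c in chans[1:]]
        self.pools = [(2, 2, 1), (2, 2, 2)][: len(chans) - 1]
        self.dropout = Dropout(config.dropout_p, rng)
        self.fc = Linear(chans[-1], 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if len(x.shape) == 4:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        x = avg_pool(x, self.input_pool)
        for conv, bn, pk in zip(self.convs, self.bns, self.pools):
            x = bn(conv(x)).relu()
            x = max_pool(x, pk)
        x = self.dropout(x)
        x = x.mean(axis=(2, 3, 4))  # global average pool → (B, C)
        return self.fc(x)


class BalanceHead(Module):
    """Self-attention over the six kinematic feature tokens → 2 classes."""

    def __init__(self, config: HeadConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        d = config.attention_dim
        self.embed = Linear(4, d, rng)
        self.attn = SelfAttention(d, rng)
        self.dropout = Dropout(config.dropout_p, rng)
        self.fc = Linear(6 * d, 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # (B, 4, 6) → six feature tokens of dimension 4
        tokens = x.transpose((0, 2, 1))
        h = self.embed(tokens).tanh()
        h = self.attn(h)
        h = self.dropout(h)
        return self.fc(h.reshape(h.shape[0], 6 * self.config.attention_dim))

    def feature_attention(self) -> Optional[np.ndarray]:
        """Mean attention received by each of the 6 feature tokens."""
        w = self.attn.last_weights
        return None if w is None else w.mean(axis=(0, 1))


def build_diagnosis_head(config: Optional[HeadConfig] = None) -> DiagnosisHead:
    cfg = config or HeadConfig(head="diagnosis")
    model = DiagnosisHead(cfg)
    assert model.n_parameters() < 10 ** 5
    return model


def build_evaluation_head(config: Optional[HeadConfig] = None) -> EvaluationHead:
    cfg = config or HeadConfig(head="evaluation")
    model = EvaluationHead(cfg)
    assert model.n_parameters() < 10 ** 5
    return model


def build_balance_head(config: Optional[HeadConfig] = None) -> BalanceHead:
    cfg = config or HeadConfig(head="balance")
    model = BalanceHead(cfg)
    assert model.n_parameters() < 10 ** 5
    return model


def predict_proba(model: Module, X: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of inputs (model in eval mode)."""
    was_training = model.training
    model.eval()
    logits = model(Tensor(np.asarray(X, dtype=float)))
    probs = logits.softmax(axis=-1).data
    model.train(was_training)
    return probs


def train_head(
    model: Module,
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[HeadConfig] = None,
) -> Dict[str, list]:
    """Train with Adam + cross-entropy; early stopping on a validation split.

    Deterministic given ``config.seed``.  Returns the loss/accuracy history;
    the model is left with the best-validation-loss weights.
    """
    cfg = config or getattr(model, "config", HeadConfig())
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelsError("training set contains a single class")
    weights = None
    if cfg.class_weighting:
        counts = np.bincount(y, minlength=int(y.max()) + 1).astype(float)
        weights = np.where(counts > 0, len(y) / (counts.size * np.maximum(counts, 1)),
                           0.0)

    rng = np.random.default_rng(cfg.seed + 1)
    n = len(y)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n >= 5 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if np.unique(y[tr_idx]).size < 2:  # keep both classes in the training part
        val_idx, tr_idx = perm[:0], perm
        n_val = 0

    opt = Adam(model.parameters(), lr=cfg.lr)
    history: Dict[str, list] = {"loss": [], "val_loss": [], "accuracy": []}
    best_val = np.inf
    best_state = model.state_dict()
    patience_left = cfg.patience
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(tr_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs >= 2 samples
            logits = model(Tensor(X[idx]))
            loss = cross_entropy(logits, y[idx], class_weights=weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history["loss"].append(epoch_loss / max(1, len(order)))
        probs = predict_proba(model, X[tr_idx])
        history["accuracy"].append(float(np.mean(probs.argmax(1) == y[tr_idx])))
        if n_val:
            model.eval()
            vlogits = model(Tensor(X[val_idx]))
            vloss = float(cross_entropy(vlogits, y[val_idx],
                                        class_weights=weights).data)
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_state = model.state_dict()
                patience_left = cfg.patience
            elif epoch >= cfg.min_epochs:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if n_val:
        model.load_state_dict(best_state)
    model.eval()
    return history


def predict_subject(
    models: Dict[str, Module],
    subject_trials: Sequence[Dict[str, np.ndarray]],
) -> HeadProbabilities:
    """Average per-trial head probabilities into one subject-level output.

    ``subject_trials`` holds one dict per trial with keys ``ftf`` (4×97),
    ``etff`` (100×97×4) and ``mf`` (4×6).
    """
    if len(subject_trials) == 0:
        raise SchemaError("subject has no trials")
    ftf = np.stack([t["ftf"] for t in subject_trials])
    etff = np.stack([t["etff"] for t in subject_trials])
    mf = np.stack([t["mf"] for t in subject_trials])
    p_diag = predict_proba(models["diagnosis"], ftf).mean(axis=0)
    p_level = predict_proba(models["evaluation"], etff).mean(axis=0)
    p_bal = predict_proba(models["balance"], mf).mean(axis=0)
    return HeadProbabilities(
        p_pd=float(p_diag[1]),
        p_level=p_level / p_level.sum(),
        p_balance_impaired=float(p_bal[1]),
    )


def occlusion_sensitivity(
    model: Module,
    X: np.ndarray,
    y: np.ndarray,
    channel: str | int,
) -> float:
    """Accuracy drop of the diagnosis head when one FTF channel is zeroed."""
    if isinstance(channel, str):
        if channel not in EMG_CHANNELS:
            raise SchemaError(
                f"unknown channel {channel!r}; expected one of {EMG_CHANNELS}")
        channel = EMG_CHANNELS.index(channel)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    base = float(np.mean(predict_proba(model, X).argmax(1) == y))
    Xo = X.copy()
    Xo[:, channel, :] = 0.0
    occ = float(np.mean(predict_proba(model, Xo).argmax(1) == y))
    return base - occ
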