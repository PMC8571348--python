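"""The convolutional secretability classifier.

One-hot encoded peptides pass through three blocks of (same-padded 1-D
convolution, ReLU, dropout, max pooling).  The variable sequence length is
then collapsed by one of four strategies — global max pooling (default),
k-max pooling, a bidirectional GRU over the block output, or zero-padding /
truncation to a fixed 200 residues — followed by a dense hidden layer and a
single sigmoid output neuron.  Training minimizes class-weighted binary
cross-entropy with Adam; everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..biophys import STANDARD_AA
from ..features import FoldAssignment, SecretabilityDataset
from .autograd import Tensor
from .layers import (
    Adam,
    BiGRU,
    Conv1d,
    Dense,
    Dropout,
    kmax_pool,
    masked_global_max,
    max_pool1d,
)

__all__ = [
    "CNNConfig",
    "SecretabilityCNN",
    "one_hot_encode",
    "decode_one_hot",
    "build_model",
    "train_cnn",
    "ensemble_average",
]

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
POOL_STRATEGIES = ("global_max", "kmax", "bigru", "pad_truncate")


def one_hot_encode(peptide: str) -> np.ndarray:
    """L x 20 one-hot matrix (columns in ``STANDARD_AA`` order).

    Non-standard residues become all-zero rows (the network sees them as
    absence of evidence rather than an error).
    """
    x = np.zeros((len(peptide), 20))
    for i, aa in enumerate(peptide):
        j = _AA_INDEX.get(aa)
        if j is not None:
            x[i, j] = 1.0
    return x


def decode_one_hot(x: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to ``X``."""
    out = []
    for row in np.asarray(x):
        if row.sum() == 0:
            out.append("X")
        else:
            out.append(STANDARD_AA[int(np.argmax(row))])
    return "".join(out)


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training controls."""

    n_filters: tuple[int, int, int] = (16, 16, 16)
    kernel_sizes: tuple[int, int, int] = (7, 7, 7)
    dropout: float = 0.2
    pool_size: int = 2
    pooling: str = "global_max"  # global_max | kmax | bigru | pad_truncate
    kmax_k: int = 5
    gru_hidden: int = 64
    max_len: int = 200  # pad/truncate strategy only
    dense: int = 32
    epochs: int = 12
    batch_size: int = 64
    learning_rate: float = 5e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_filters) != 3 or len(self.kernel_sizes) != 3:
            raise ValueError("the architecture has exactly three convolution blocks")
        if self.pooling not in POOL_STRATEGIES:
            raise ValueError(
                f"unknown pooling strategy {self.pooling!r}; choose from {POOL_STRATEGIES}"
            )


class SecretabilityCNN:
    """Three convolution blocks, a length-collapsing head, dense, sigmoid."""

    def __init__(self, cfg: CNNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
        self.blocks: list[Conv1d] = []
        c_in = 20
        for c_out, k in zip(cfg.n_filters, cfg.kernel_sizes):
            self.blocks.append(Conv1d(c_in, c_out, k, rng))
            c_in = c_out
        self.dropout = Dropout(cfg.dropout)
        self.gru: BiGRU | None = None
        if cfg.pooling == "global_max":
            head_in = c_in
        elif cfg.pooling == "kmax":
            head_in = c_in * cfg.kmax_k
        elif cfg.pooling == "bigru":
            self.gru = BiGRU(c_in, cfg.gru_hidden, rng)
            head_in = 2 * cfg.gru_hidden
        else:  # pad_truncate
            pooled_len = cfg.max_len
            for _ in range(3):
                pooled_len = -(-pooled_len // cfg.pool_size)
            head_in = c_in * pooled_len
        self.dense = Dense(head_in, cfg.dense, rng)
        self.out = Dense(cfg.dense, 1, rng)
        self._train_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))

    @property
    def params(self) -> list[Tensor]:
        params = []
        for blk in self.blocks:
            params += blk.params
        if self.gru is not None:
            params += self.gru.params
        return params + self.dense.params + self.out.params

    # -- forward -------------------------------------------------------------

    @staticmethod
    def _infer_valid(x: np.ndarray) -> np.ndarray:
        """Valid length per sequence = index of the last nonzero row + 1."""
        any_set = np.abs(x).sum(axis=2) > 0
        rev = any_set[:, ::-1]
        has = any_set.any(axis=1)
        last = x.shape[1] - np.argmax(rev, axis=1)
        return np.where(has, last, 0).astype(int)

    def forward(
        self,
        x: np.ndarray | Tensor,
        valid: np.ndarray | None = None,
        train: bool = False,
    ) -> Tensor:
        """Probability tensor of shape (B,) for a (B, L, 20) batch.

        ``valid`` defaults to the position after the last nonzero row, so
        appending all-zero padding rows never changes the output.
        """
        xt = x if isinstance(x, Tensor) else Tensor(x)
        data = xt.data
        if data.ndim != 3 or data.shape[2] != 20:
            raise ValueError("input must have shape (batch, length, 20)")
        if valid is None:
            valid = self._infer_valid(data)
        valid = np.asarray(valid, dtype=int)

        cfg = self.cfg
        if cfg.pooling == "pad_truncate":
            xt = self._pad_truncate(xt)
            valid = np.minimum(valid, cfg.max_len)

        h = xt
        for blk in self.blocks:
            h = blk(h).relu()
            h = self.dropout(h, train, self._train_rng)
            h, valid = max_pool1d(h, valid, cfg.pool_size)

        if cfg.pooling == "global_max":
            z = masked_global_max(h, valid)
        elif cfg.pooling == "kmax":
            z = kmax_pool(h, valid, cfg.kmax_k)
        elif cfg.pooling == "bigru":
            z = self.gru(h, valid)
        else:
            b, length, c = h.shape
            z = h.reshape(b, length * c)
        z = self.dense(z).relu()
        logit = self.out(z)
        return logit.reshape(logit.shape[0]).sigmoid()

    def _pad_truncate(self, xt: Tensor) -> Tensor:
        from .autograd import concat

        b, length, c = xt.shape
        max_len = self.cfg.max_len
        if length >= max_len:
            return xt[:, :max_len, :]
        pad = Tensor(np.zeros((b, max_len - length, c)))
        return concat([xt, pad], axis=1)

    # -- inference helpers ----------------------------------------------------

    def predict_proba(self, peptides: list[str], batch_size: int = 256) -> np.ndarray:
        out = np.empty(len(peptides))
        order = np.argsort([len(p) for p in peptides], kind="stable")
        for lo in range(0, len(order), batch_size):
            idx = order[lo : lo + batch_size]
            x, valid = _pack_batch([peptides[i] for i in idx])
            out[idx] = self.forward(x, valid).data
        return out


def build_model(cfg: CNNConfig) -> SecretabilityCNN:
    return SecretabilityCNN(cfg)


def _pack_batch(peptides: list[str]) -> tuple[np.ndarray, np.ndarray]:
    lens = np.array([len(p) for p in peptides], dtype=int)
    x = np.zeros((len(peptides), int(lens.max()), 20))
    for i, p in enumerate(peptides):
        x[i, : lens[i]] = one_hot_encode(p)
    return x, lens


def _bce_loss(prob: Tensor, y: np.ndarray, weights: np.ndarray) -> Tensor:
    eps = 1e-7
    yt = Tensor(y)
    wt = Tensor(weights)
    p = prob * (1 - 2 * eps) + eps  # clamp away from 0/1
    nll = -(yt * p.log() + (1.0 - yt) * (1.0 - p).log())
    return (wt * nll).sum() * (1.0 / len(y))


def train_single(
    peptides: list[str],
    labels: np.ndarray,
    cfg: CNNConfig,
) -> SecretabilityCNN:
    """Train one model on the given records (class-weighted BCE, Adam)."""
    model = SecretabilityCNN(cfg)
    y = np.asarray(labels, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate single-class training data")
    # inverse-frequency class weights, mean 1
    w_pos = len(y) / (2.0 * n_pos)
    w_neg = len(y) / (2.0 * n_neg)
    weights = np.where(y == 1, w_pos, w_neg)

    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    # batches of similar length keep padding (and wasted compute) small
    order = np.argsort([len(p) for p in peptides], kind="stable")
    batches = [
        order[lo : lo + cfg.batch_size]
        for lo in range(0, len(order), cfg.batch_size)
    ]
    for _ in range(cfg.epochs):
        perm = rng.permutation(len(batches))
        for bi in perm:
            idx = batches[bi]
            x, valid = _pack_batch([peptides[i] for i in idx])
            prob = model.forward(x, valid, train=True)
            loss = _bce_loss(prob, y[idx], weights[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def train_cnn(
    dataset: SecretabilityDataset,
    folds: FoldAssignment,
    cfg: CNNConfig | None = None,
) -> tuple[list[SecretabilityCNN], pd.Series]:
    """One model per fold; returns the models and out-of-fold probabilities."""
    cfg = cfg or CNNConfig()
    oof = pd.Series(
        np.nan, index=pd.Index(dataset.keys, name="fragment_key"), name="cnn_prob"
    )
    models = []
    for fold in range(folds.n_folds):
        tr = folds.train_indices(fold)
        te = folds.test_indices(fold)
        fold_cfg = replace(cfg, seed=cfg.seed * 1000 + fold)
        model = train_single(
            [dataset.peptides[i] for i in tr], dataset.labels[tr], fold_cfg
        )
        models.append(model)
        if te.size:
            oof.iloc[te] = model.predict_proba([dataset.peptides[i] for i in te])
    return models, oof


def ensemble_average(prob_a, prob_b):
    """Arithmetic mean of two aligned probability vectors."""
    a = np.asarray(prob_a, dtype=float)
    b = np.asarray(prob_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("probability vectors must align")
    out = (a + b) / 2.0
    if isinstance(prob_a, pd.Series):
        return pd.Series(out, index=prob_a.index, name="ensemble_avg")
    return out
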