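"""Parallel CNN + BiLSTM classifier with cross-attention feature fusion.

One expression profile is treated as an ordered gene sequence
``X = {x1, ..., xn}`` (ordered by descending training-set variance, frozen
into the model). Two branches encode it in parallel:

* a spatial branch — three stacked 1-D convolutions (ReLU, with max-pooling
  after the first two) over the raw sequence;
* a temporal branch — a bidirectional LSTM over non-overlapping windows of
  the same sequence, forward and backward states concatenated.

Both branches are linearly projected to a shared ``L x d`` token grid, then
fused by cross-attention:

    Fcg = softmax(Fc @ Fg.T / sqrt(d)) @ (Fc + Fg)

(the ``scale="d"`` option divides by ``d`` instead). The fused tokens are
mean-pooled, passed through a fully connected layer and a softmax over the
``k`` subtype classes; training minimises mean cross-entropy against the
consensus pseudo-labels with adaptive-moment updates and early stopping on
validation loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from . import _autodiff as ad
from ._autodiff import Tensor
from .io import ExpressionMatrix


# ---------------------------------------------------------------------------
# Eq.-level fusion API (numpy, mirrors the in-graph computation)
# ---------------------------------------------------------------------------


@dataclass
class FusionTensors:
    Fc: np.ndarray
    Fg: np.ndarray
    attention: np.ndarray
    Fcg: np.ndarray
    d: int


def _row_softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_fusion(Fc: np.ndarray, Fg: np.ndarray, scale: str = "sqrt_d") -> FusionTensors:
    """Cross-attention fusion of two L x d branch feature matrices.

    ``attention = row-softmax(Fc @ Fg.T / s)`` with ``s = sqrt(d)`` by default
    (``scale="d"`` uses the feature dimension itself), and
    ``Fcg = attention @ (Fc + Fg)``.
    """
    Fc = np.asarray(Fc, dtype=float)
    Fg = np.asarray(Fg, dtype=float)
    if Fc.shape != Fg.shape:
        raise ValueError(f"branch shapes differ: {Fc.shape} vs {Fg.shape}")
    if Fc.ndim != 2:
        raise ValueError("cross_fusion expects 2-D L x d matrices")
    d = Fc.shape[1]
    denom = np.sqrt(d) if scale == "sqrt_d" else float(d)
    attention = _row_softmax(Fc @ Fg.T / denom)
    Fcg = attention @ (Fc + Fg)
    return FusionTensors(Fc=Fc, Fg=Fg, attention=attention, Fcg=Fcg, d=d)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ClassifierConfig:
    """Architecture and training hyperparameters (all overridable)."""

    window: int = 4              # token width; must equal the total pooling factor
    conv_channels: tuple = (32, 64, 64)
    kernel: int = 3
    lstm_hidden: int = 32        # per direction
    d: int = 64                  # shared fusion feature dimension
    dropout: float = 0.2
    scale: str = "sqrt_d"        # attention scale: "sqrt_d" or "d"
    variant: str = "fusion"      # "fusion" | "cnn" | "bilstm"
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.scale not in ("sqrt_d", "d"):
            raise ValueError("scale must be 'sqrt_d' or 'd'")
        if self.variant not in ("fusion", "cnn", "bilstm"):
            raise ValueError("variant must be fusion, cnn or bilstm")
        if self.window != 4:
            raise ValueError(
                "window must be 4: the spatial branch pools by 2 twice, and the "
                "two branches must share the token length L = n/window"
            )


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def _glorot(rng, shape):
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    if len(shape) == 3:  # conv (C_out, C_in, K)
        fan_in = shape[1] * shape[2]
        fan_out = shape[0] * shape[2]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Network:
    """Parameter container + forward pass. n_genes is padded to a multiple of
    ``window`` with zeros so L = n_pad / window is shared by both branches."""

    def __init__(self, n_genes: int, k: int, cfg: ClassifierConfig, rng):
        self.cfg = cfg
        self.k = k
        self.n_genes = n_genes
        w = cfg.window
        self.n_pad = int(np.ceil(n_genes / w)) * w
        self.L = self.n_pad // w
        c1, c2, c3 = cfg.conv_channels
        K = cfg.kernel
        H = cfg.lstm_hidden
        d = cfg.d

        def P(shape, zero=False):
            data = np.zeros(shape) if zero else _glorot(rng, shape)
            return Tensor(data, requires_grad=True)

        self.params = {}
        p = self.params
        # spatial branch: conv(1->c1), pool2, conv(c1->c2), pool2, conv(c2->c3)
        p["cw1"], p["cb1"] = P((c1, 1, K)), P((c1,), zero=True)
        p["cw2"], p["cb2"] = P((c2, c1, K)), P((c2,), zero=True)
        p["cw3"], p["cb3"] = P((c3, c2, K)), P((c3,), zero=True)
        p["proj_c_w"], p["proj_c_b"] = P((c3, d)), P((d,), zero=True)
        # temporal branch: BiLSTM over (L, window)-tokens
        for direction in ("f", "b"):
            p[f"Wx_{direction}"] = P((w, 4 * H))
            p[f"Wh_{direction}"] = P((H, 4 * H))
            bias = np.zeros(4 * H)
            bias[H : 2 * H] = 1.0  # forget-gate bias
            p[f"bias_{direction}"] = Tensor(bias, requires_grad=True)
        p["proj_g_w"], p["proj_g_b"] = P((2 * H, d)), P((d,), zero=True)
        # head
        p["fc_w"], p["fc_b"] = P((d, k)), P((k,), zero=True)

    def parameters(self):
        return list(self.params.values())

    # -- branches ------------------------------------------------------------

    def _pad(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] == self.n_pad:
            return X
        out = np.zeros((X.shape[0], self.n_pad))
        out[:, : X.shape[1]] = X
        return out

    def _conv_branch(self, x: Tensor) -> Tensor:
        p = self.params
        pad = self.cfg.kernel // 2
        h = x.conv1d(p["cw1"], p["cb1"], padding=pad).relu().maxpool1d(2)
        h = h.conv1d(p["cw2"], p["cb2"], padding=pad).relu().maxpool1d(2)
        h = h.conv1d(p["cw3"], p["cb3"], padding=pad).relu()  # (B, c3, L)
        h = h.transpose(0, 2, 1)  # (B, L, c3)
        return h @ p["proj_c_w"] + p["proj_c_b"]  # (B, L, d)

    def _lstm_pass(self, tokens: Tensor, direction: str) -> Tensor:
        p = self.params
        H = self.cfg.lstm_hidden
        B = tokens.shape[0]
        order = range(self.L) if direction == "f" else range(self.L - 1, -1, -1)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = [None] * self.L
        Wx, Wh, bias = p[f"Wx_{direction}"], p[f"Wh_{direction}"], p[f"bias_{direction}"]
        xW = tokens @ Wx + bias  # (B, L, 4H): input projection for every step at once
        for t in order:
            gates = xW[:, t, :] + h @ Wh
            i = gates[:, 0 * H : 1 * H].sigmoid()
            f = gates[:, 1 * H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h
        return ad.stack(outs, axis=1)  # (B, L, H)

    def _lstm_branch(self, tokens: Tensor) -> Tensor:
        p = self.params
        fwd = self._lstm_pass(tokens, "f")
        bwd = self._lstm_pass(tokens, "b")
        h = ad.concat([fwd, bwd], axis=2)  # (B, L, 2H)
        return h @ p["proj_g_w"] + p["proj_g_b"]  # (B, L, d)

    # -- full forward ----------------------------------------------------------

    def forward(self, X: np.ndarray, dropout_rng=None):
        """X: (B, n_genes) -> logits Tensor (B, k)."""
        cfg = self.cfg
        Xp = self._pad(np.asarray(X, float))
        B = Xp.shape[0]
        need_c = cfg.variant in ("fusion", "cnn")
        need_g = cfg.variant in ("fusion", "bilstm")

        Fc = Fg = None
        if need_c:
            Fc = self._conv_branch(Tensor(Xp[:, None, :]))
        if need_g:
            tokens = Tensor(Xp.reshape(B, self.L, cfg.window))
            Fg = self._lstm_branch(tokens)

        if cfg.variant == "fusion":
            denom = np.sqrt(cfg.d) if cfg.scale == "sqrt_d" else float(cfg.d)
            scores = (Fc @ Fg.transpose(0, 2, 1)) / denom  # (B, L, L)
            attention = scores.softmax(axis=-1)
            fused = attention @ (Fc + Fg)  # (B, L, d)
        elif cfg.variant == "cnn":
            fused = Fc
        else:
            fused = Fg

        pooled = fused.mean(axis=1)  # (B, d)
        if dropout_rng is not None and cfg.dropout > 0:
            mask = (dropout_rng.random(pooled.shape) >= cfg.dropout) / (1 - cfg.dropout)
            pooled = pooled * Tensor(mask)
        return pooled @ self.params["fc_w"] + self.params["fc_b"]

    def fusion_tensors(self, x: np.ndarray) -> FusionTensors:
        """Branch features and fused tokens for one sample (no dropout)."""
        Xp = self._pad(np.asarray(x, float).reshape(1, -1))
        Fc = self._conv_branch(Tensor(Xp[:, None, :])).data[0]
        tokens = Tensor(Xp.reshape(1, self.L, self.cfg.window))
        Fg = self._lstm_branch(tokens).data[0]
        return cross_fusion(Fc, Fg, scale=self.cfg.scale)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class CrossFusionClassifier:
    """Subtype classifier trained against consensus pseudo-labels.

    Parameters
    ----------
    X : ExpressionMatrix
        Training cohort (genes x samples).
    labels : sequence of int
        Pseudo-label per sample, values in ``[0, k)``; every class must be
        present with at least 2 samples.
    config : ClassifierConfig, optional
    """

    def __init__(self, X: ExpressionMatrix, labels, config: Optional[ClassifierConfig] = None):
        self.X = X
        self.labels = np.asarray(labels, dtype=int)
        if self.labels.size != X.n_samples:
            raise ValueError("labels length must equal n_samples")
        self.config = config or ClassifierConfig()
        self.k = int(self.labels.max()) + 1
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts == 0).any():
            missing = np.where(counts == 0)[0].tolist()
            raise ValueError(f"class(es) {missing} absent from training labels")
        if (counts < 2).any():
            raise ValueError("every class needs at least 2 training samples")
        # gene order: descending training-set variance, frozen into the model
        var = X.values.var(axis=1)
        order = np.argsort(-var, kind="stable")
        self.gene_order = [X.gene_ids[i] for i in order]

    def _design(self, X: ExpressionMatrix) -> np.ndarray:
        return X.subset_genes(self.gene_order).samples_matrix()

    def fit(self) -> "ClassifierResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        M = self._design(self.X)
        y = self.labels

        idx_train, idx_val = train_test_split(
            np.arange(y.size),
            test_size=cfg.val_fraction,
            stratify=y,
            random_state=int(rng.integers(2**31 - 1)),
        )
        net = _Network(len(self.gene_order), self.k, cfg, rng)
        opt = ad.Adam(net.parameters(), lr=cfg.lr)
        drop_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
        shuffle_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))

        history = []
        best_val = np.inf
        best_state = None
        best_epoch = 0
        for epoch in range(cfg.max_epochs):
            perm = shuffle_rng.permutation(idx_train)
            tr_losses, tr_correct = [], 0
            for start in range(0, perm.size, cfg.batch_size):
                batch = perm[start : start + cfg.batch_size]
                logits = net.forward(M[batch], dropout_rng=drop_rng)
                loss = ad.cross_entropy(logits, y[batch])
                opt.zero_grad()
                loss.backward()
                opt.step()
                tr_losses.append(float(loss.data) * batch.size)
                tr_correct += int((logits.data.argmax(axis=1) == y[batch]).sum())
            val_logits = net.forward(M[idx_val])
            val_loss = float(ad.cross_entropy(val_logits, y[idx_val]).data)
            val_acc = float((val_logits.data.argmax(axis=1) == y[idx_val]).mean())
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": sum(tr_losses) / perm.size,
                    "train_acc": tr_correct / perm.size,
                    "val_loss": val_loss,
                    "val_acc": val_acc,
                }
            )
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_epoch = epoch
                best_state = {k2: p.data.copy() for k2, p in net.params.items()}
            elif epoch - best_epoch >= cfg.patience:
                break
        if best_state is not None:
            for k2, p in net.params.items():
                p.data = best_state[k2]
        return ClassifierResults(
            model=self,
            network=net,
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
            classes=self.k,
        )


@dataclass
class ClassifierResults:
    model: CrossFusionClassifier
    network: _Network
    history: pd.DataFrame
    best_epoch: int
    classes: int

    # -- inference -----------------------------------------------------------

    def predict_proba(self, X: ExpressionMatrix, batch_size: int = 256) -> np.ndarray:
        M = self.model._design(X)
        out = []
        for start in range(0, M.shape[0], batch_size):
            logits = self.network.forward(M[start : start + batch_size])
            out.append(_row_softmax(logits.data))
        return np.vstack(out)

    def predict(self, X: ExpressionMatrix) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def fusion_tensors(self, X: ExpressionMatrix, sample_id: str) -> FusionTensors:
        col = X.sample_ids.index(sample_id)
        x = X.subset_genes(self.model.gene_order).values[:, col]
        return self.network.fusion_tensors(x)

    def evaluate(self, X: ExpressionMatrix, y) -> dict:
        """Accuracy and per-class one-vs-rest ROC AUC on a labelled set."""
        y = np.asarray(y, dtype=int)
        probs = self.predict_proba(X)
        acc = float((probs.argmax(axis=1) == y).mean())
        if np.unique(y).size < 2:
            raise ValueError("AUC undefined on a single-class test set")
        aucs = {}
        for c in range(self.classes):
            mask = y == c
            if mask.all() or not mask.any():
                aucs[c] = float("nan")
                continue
            aucs[c] = float(roc_auc_score(mask.astype(int), probs[:, c]))
        return {"accuracy": acc, "auc_per_class": aucs}

    def summary(self) -> str:
        cfg = self.model.config
        last = self.history.iloc[-1]
        lines = [
            "Cross-fusion attention classifier (CNN + BiLSTM branches)",
            f"  variant: {cfg.variant}    classes: {self.classes}"
            f"    genes: {len(self.model.gene_order)}",
            f"  tokens L: {self.network.L}    feature dim d: {cfg.d}"
            f"    attention scale: {cfg.scale}",
            f"  epochs run: {len(self.history)} (best @ {self.best_epoch})",
            f"  final train acc: {last['train_acc']:.3f}    val acc: {last['val_acc']:.3f}",
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.model.config)
        cfg["conv_channels"] = list(cfg["conv_channels"])
        meta = {
            "config": cfg,
            "k": self.classes,
            "gene_order": self.model.gene_order,
            "best_epoch": self.best_epoch,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=1))
        np.savez(directory / "weights.npz", **{k: p.data for k, p in self.network.params.items()})
        self.history.to_csv(directory / "history.tsv", sep="\t", index=False)

    @staticmethod
    def load(directory) -> "ClassifierResults":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        cfg_d = dict(meta["config"])
        cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
        cfg = ClassifierConfig(**cfg_d)
        weights = np.load(directory / "weights.npz")
        k = meta["k"]
        gene_order = meta["gene_order"]
        dummy = ExpressionMatrix(
            gene_order, [f"_s{i}" for i in range(2 * k)], np.zeros((len(gene_order), 2 * k))
        )
        model = CrossFusionClassifier(
            dummy, np.repeat(np.arange(k), 2), config=cfg
        )
        model.gene_order = gene_order
        net = _Network(len(gene_order), k, cfg, np.random.default_rng(0))
        for name, p in net.params.items():
            p.data = weights[name]
        history = pd.read_csv(directory / "history.tsv", sep="\t")
        return ClassifierResults(
            model=model, network=net, history=history,
            best_epoch=meta["best_epoch"], classes=k,
        )


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------


def ablate(
    X_train: ExpressionMatrix,
    y_train,
    X_test: ExpressionMatrix,
    y_test,
    seeds: Sequence[int] = (0,),
    config: Optional[ClassifierConfig] = None,
) -> pd.DataFrame:
    """Train the three variants (CNN-only, BiLSTM-only, full fusion) under
    identical data, seeds and budget; one row per variant with mean train and
    test accuracy over the seeds."""
    base = asdict(config or ClassifierConfig())
    base["conv_channels"] = tuple(base["conv_channels"])
    rows = []
    for variant in ("cnn", "bilstm", "fusion"):
        train_accs, test_accs = [], []
        for seed in seeds:
            cfg = ClassifierConfig(**{**base, "variant": variant, "seed": int(seed)})
            res = CrossFusionClassifier(X_train, y_train, config=cfg).fit()
            train_accs.append(
                float((res.predict(X_train) == np.asarray(y_train)).mean())
            )
            test_accs.append(float((res.predict(X_test) == np.asarray(y_test)).mean()))
        rows.append(
            {
                "variant": variant,
                "train_acc": float(np.mean(train_accs)),
                "test_acc": float(np.mean(test_accs)),
                "n_seeds": len(seeds),
            }
        )
    return pd.DataFrame(rows)
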