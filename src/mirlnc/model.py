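"""The CNN + IndRNN interaction classifier.

Architecture: token embedding -> two (conv1d, ReLU, max-pool) blocks ->
two IndRNN layers with batch normalization on the input projection ->
time readout -> dropout(0.5) -> dense -> sigmoid probability of
interaction.  Trained with binary cross-entropy; the per-neuron
recurrent weights are clipped after every optimizer step so long-range
gradients stay bounded.

Exposed statsmodels-style: ``CnnIndRnnModel(batch, config).fit()``
returns a :class:`CnnIndRnnResults` holding the trained parameters,
per-epoch history and a ``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .dataset import EncodedPairBatch


class ModelConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training configuration.

    Defaults follow the published setup (dropout 0.5, batch size 128,
    learning rate 0.01, 50 epochs); conv/IndRNN widths are configurable and
    searchable by the optimizer module.
    """

    vocab_size: int = 6
    embed_dim: int = 32
    conv_blocks: tuple[tuple[int, int, int], ...] = ((32, 8, 4), (64, 8, 4))
    conv_strides: tuple[int, ...] = (1, 1)
    indrnn_units: tuple[int, ...] = (64, 64)
    recurrent_clip: float | None = None  # None -> 2**(1/T) at build time
    use_batchnorm: bool = True
    readout: str = "mean"  # "mean" | "last"
    dropout: float = 0.5
    optimizer: str = "sgd"  # "sgd" | "momentum" | "adam"
    learning_rate: float = 0.01
    lr_decay_epoch: int | None = None  # multiply lr by lr_decay_factor from this epoch
    lr_decay_factor: float = 0.1
    batch_size: int = 128
    epochs: int = 50
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ModelConfigError("dropout must be in [0, 1)")
        if len(self.conv_blocks) != 2 or len(self.indrnn_units) != 2:
            raise ModelConfigError("architecture uses two conv blocks and two IndRNN layers")
        if len(self.conv_strides) != len(self.conv_blocks) or any(s < 1 for s in self.conv_strides):
            raise ModelConfigError("conv_strides must give a positive stride per conv block")
        if self.readout not in ("mean", "last"):
            raise ModelConfigError("readout must be 'mean' or 'last'")
        if self.optimizer not in ("sgd", "momentum", "adam"):
            raise ModelConfigError(f"unknown optimizer {self.optimizer!r}")


def _post_conv_length(L: int, conv_blocks, conv_strides=(1, 1)) -> int:
    for (_, kernel, pool), stride in zip(conv_blocks, conv_strides):
        L = ((L - kernel) // stride + 1) // pool
        if L < 1:
            raise ModelConfigError("input too short for the conv/pool stack")
    return L


def build_network(config: ModelConfig, input_len: int) -> nn.Sequential:
    """Instantiate the layer stack for a given padded input width."""
    rng = np.random.default_rng(config.seed)
    dtype = np.dtype(config.dtype).type
    t_post = _post_conv_length(input_len, config.conv_blocks, config.conv_strides)
    clip = config.recurrent_clip if config.recurrent_clip is not None else 2.0 ** (1.0 / t_post)
    layers: list[nn.Layer] = [nn.Embedding(config.vocab_size, config.embed_dim, rng, dtype)]
    c_in = config.embed_dim
    for (filters, kernel, pool), stride in zip(config.conv_blocks, config.conv_strides):
        # pool before ReLU: identical to ReLU-then-pool (max commutes with a
        # monotone map) but the nonlinearity runs on the pooled tensor
        layers += [nn.Conv1D(c_in, filters, kernel, rng, stride=stride, dtype=dtype),
                   nn.MaxPool1D(pool), nn.ReLU()]
        c_in = filters
    for units in config.indrnn_units:
        layers.append(nn.IndRNN(c_in, units, rng, recurrent_clip=clip, use_bn=config.use_batchnorm, dtype=dtype))
        c_in = units
    layers.append(nn.MeanOverTime() if config.readout == "mean" else nn.LastStep())
    layers.append(nn.Dropout(config.dropout, rng))
    layers.append(nn.Dense(c_in, 1, rng, dtype))
    return nn.Sequential(layers)


def _make_optimizer(config: ModelConfig):
    if config.optimizer == "adam":
        return nn.Adam(config.learning_rate)
    if config.optimizer == "momentum":
        return nn.SGD(config.learning_rate, momentum=0.9)
    return nn.SGD(config.learning_rate)


class CnnIndRnnModel:
    """Binary interaction classifier over encoded (miRNA, lncRNA) pairs."""

    def __init__(self, batch: EncodedPairBatch, config: ModelConfig | None = None):
        self.batch = batch
        self.config = config or ModelConfig()
        self.network = build_network(self.config, batch.max_len)
        self._rng = np.random.default_rng(np.random.SeedSequence((self.config.seed, 1)))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sequences, config: ModelConfig | None = None,
                       max_len: int | None = None) -> "CnnIndRnnModel":
        """Build from a pairs DataFrame with mirna_id/lncrna_id/label columns."""
        from .dataset import encode_pairs
        from .records import InteractionPair

        pairs = [InteractionPair(r.mirna_id, r.lncrna_id, int(r.label)) for r in df.itertuples()]
        return cls(encode_pairs(pairs, sequences, max_len=max_len), config)

    def predict_probs(self, tokens: np.ndarray) -> np.ndarray:
        """Interaction probabilities; dropout disabled, deterministic."""
        logits = self.network.forward(tokens, train=False)
        return nn.sigmoid(logits[:, 0])

    def _snapshot_params(self) -> list[np.ndarray]:
        state = [p.copy() for _, _, p in self.network.parameters()]
        for bn in self.network.batchnorms():
            state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def _restore_params(self, state: list[np.ndarray]) -> None:
        params = [p for _, _, p in self.network.parameters()]
        for p, saved in zip(params, state):
            p[...] = saved
        rest = state[len(params):]
        for i, bn in enumerate(self.network.batchnorms()):
            bn.running_mean = rest[2 * i].copy()
            bn.running_var = rest[2 * i + 1].copy()

    def fit(
        self,
        epochs: int | None = None,
        verbose: bool = False,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
        restore_best: bool = False,
        track_train_accuracy: bool = True,
        calibration_sample: int | None = None,
    ) -> "CnnIndRnnResults":
        """Minimize binary cross-entropy by mini-batch gradient descent.

        Recurrent weights are re-clipped after every optimizer step.  Raises
        on non-finite loss (divergence) with the offending epoch/batch.
        ``validation`` is an optional (tokens, labels) hold-out whose
        accuracy is recorded per epoch; with ``restore_best`` the parameters
        (and batch-norm statistics) of the best validation epoch are kept.
        ``calibration_sample`` caps the number of training rows used to
        re-estimate batch-norm inference statistics each epoch.
        """
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        opt = _make_optimizer(cfg)
        tokens, labels = self.batch.tokens, self.batch.labels
        n = tokens.shape[0]
        if calibration_sample is not None and calibration_sample < n:
            calib_rows = self._rng.choice(n, size=calibration_sample, replace=False)
        else:
            calib_rows = np.arange(n)
        best_val, best_state = -np.inf, None
        history: list[dict] = []
        for epoch in range(n_epochs):
            if cfg.lr_decay_epoch is not None and epoch == cfg.lr_decay_epoch:
                opt.lr *= cfg.lr_decay_factor
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self.network.forward(tokens[idx], train=True)
                probs = nn.sigmoid(logits[:, 0])
                loss, dlogit = nn.bce_loss(probs, labels[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}, batch {start // cfg.batch_size}"
                    )
                self.network.backward(dlogit[:, None])
                opt.step(self.network)
                for layer in self.network.layers:
                    if isinstance(layer, nn.IndRNN):
                        layer.clip_recurrent()
                losses.append(loss)
            # refresh BN inference statistics on (a sample of) the training set
            self.network.calibrate(tokens[calib_rows], chunk_size=cfg.batch_size)
            row = {"epoch": epoch + 1, "loss": float(np.mean(losses))}
            if track_train_accuracy:
                train_probs = self.predict_probs(tokens)
                row["train_accuracy"] = float(((train_probs > 0.5).astype(int) == labels).mean())
            if validation is not None:
                va_probs = self.predict_probs(validation[0])
                va = float(((va_probs > 0.5).astype(int) == validation[1]).mean())
                row["val_accuracy"] = va
                if restore_best and va > best_val:
                    best_val, best_state = va, self._snapshot_params()
            history.append(row)
            if verbose:
                print(f"epoch {epoch + 1}: " + " ".join(f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
        if restore_best and best_state is not None:
            self._restore_params(best_state)
        cols = ["epoch", "loss"]
        if track_train_accuracy:
            cols.append("train_accuracy")
        if validation is not None:
            cols.append("val_accuracy")
        return CnnIndRnnResults(self, pd.DataFrame(history, columns=cols))


@dataclass
class CnnIndRnnResults:
    """Fitted classifier: parameters, training history, prediction, summary."""

    model: CnnIndRnnModel
    history: pd.DataFrame

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    @property
    def n_parameters(self) -> int:
        return self.model.network.n_parameters()

    def predict(self, batch: EncodedPairBatch | np.ndarray) -> np.ndarray:
        tokens = batch.tokens if isinstance(batch, EncodedPairBatch) else batch
        if tokens.shape[1] != self.model.batch.max_len:
            raise ValueError(
                f"batch width {tokens.shape[1]} != trained width {self.model.batch.max_len}"
            )
        return self.model.predict_probs(tokens)

    def summary(self) -> str:
        cfg = self.config
        buf = io.StringIO()
        buf.write("CNN+IndRNN interaction classifier\n")
        buf.write("=" * 48 + "\n")
        rows = [
            ("input width (tokens)", self.model.batch.max_len),
            ("embedding dim", cfg.embed_dim),
            ("conv blocks (filters,kernel,pool)", cfg.conv_blocks),
            ("IndRNN units", cfg.indrnn_units),
            ("readout", cfg.readout),
            ("dropout", cfg.dropout),
            ("optimizer / lr", f"{cfg.optimizer} / {cfg.learning_rate}"),
            ("parameters", self.n_parameters),
            ("epochs run", len(self.history)),
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            rows.append(("final train loss", f"{last['loss']:.4f}"))
            if "train_accuracy" in self.history:
                rows.append(("final train accuracy", f"{last['train_accuracy']:.4f}"))
            if "val_accuracy" in self.history:
                rows.append(("final validation accuracy", f"{last['val_accuracy']:.4f}"))
        for k, v in rows:
            buf.write(f"{k:<36}{v}\n")
        return buf.getvalue()
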