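"""Deep-learning ROM: convolutional autoencoder + feedforward latent map.

The surrogate approximates u(t; mu) ~ f_D(phi(t, mu)) where the decoder
f_D spans a nonlinear trial manifold of dimension n (ideally close to the
intrinsic dimension n_mu + 1) and the feedforward network phi maps the
normalized (t, mu) to the latent coordinates.  An encoder is used during
training only, to tie the latent coordinates to compressed snapshots via
the two-term loss

    L = omega_h / 2 ||u - u_tilde||^2
      + (1 - omega_h) / 2 ||u_n_tilde - u_n||^2

averaged over samples.  Evaluation never touches the encoder and never
time-steps: the model is queried independently at any (t, mu).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .fom import SnapshotSet
from .nn import (
    Adam,
    Conv2D,
    ConvTranspose2D,
    Dense,
    ELU,
    Flatten,
    Reshape,
    Sequential,
)


@dataclass
class Normalization:
    """Min-max statistics mapping snapshots and (t, mu) inputs to [0, 1]."""

    u_min: float
    u_max: float
    tin_min: np.ndarray
    tin_max: np.ndarray

    def __post_init__(self) -> None:
        if not self.u_max > self.u_min:
            raise ValueError("constant snapshot matrix: u_max must exceed u_min")

    def scale_u(self, u: np.ndarray) -> np.ndarray:
        return (u - self.u_min) / (self.u_max - self.u_min)

    def unscale_u(self, u: np.ndarray) -> np.ndarray:
        return u * (self.u_max - self.u_min) + self.u_min

    def scale_tin(self, tin: np.ndarray) -> np.ndarray:
        span = np.where(self.tin_max > self.tin_min,
                        self.tin_max - self.tin_min, 1.0)
        return (tin - self.tin_min) / span


@dataclass
class DLROMArchitecture:
    """Network hyperparameters.

    The encoder applies ``len(conv_channels)`` strided convolutions and a
    dense layer to the latent dimension n; the decoder mirrors it with
    transposed convolutions.  The snapshot side length must be divisible
    by stride ** len(conv_channels).
    """

    n: int = 3
    conv_channels: tuple[int, ...] = (8, 16, 32, 64)
    kernel: int = 5
    stride: int = 2
    dfnn_hidden: tuple[int, ...] = (50, 50, 50, 50)


@dataclass
class TrainConfig:
    """Optimization settings (Adam, random 8:2 train/validation split,
    early stopping on the validation loss)."""

    lr: float = 1e-4
    batch_size: int = 40
    max_epochs: int = 2000
    patience: int = 500
    omega_h: float = 0.5
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega_h <= 1.0:
            raise ValueError("omega_h must lie in [0, 1]")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


@dataclass
class DLDataset:
    """Tensorized snapshots: scaled s x s images plus scaled (t, mu) inputs."""

    X: np.ndarray  # (Ns, 1, s, s)
    tin: np.ndarray  # (Ns, n_mu + 1), scaled to [0, 1]
    mask: np.ndarray  # (s, s) bool, True on real (unpadded) cells
    norm: Normalization
    n_nodes: int
    side: int


def pad_side(n_nodes: int) -> tuple[int, int]:
    """Square side s = ceil(sqrt(N)) and number of zero-padded cells."""
    s = int(np.ceil(np.sqrt(n_nodes)))
    return s, s * s - n_nodes


def prepare_dataset(snapshots: SnapshotSet) -> DLDataset:
    """Scale snapshots to [0, 1], reshape columns to zero-padded squares.

    The pad mask is retained so padded cells can be excluded from the
    reconstruction loss, and the (t, mu) labels are min-max scaled per
    component.
    """
    S = snapshots.S
    n_nodes, ns = S.shape
    s, n_pad = pad_side(n_nodes)
    u_min, u_max = float(S.min()), float(S.max())
    tin = np.column_stack([snapshots.times, snapshots.params])
    norm = Normalization(
        u_min=u_min,
        u_max=u_max,
        tin_min=tin.min(axis=0),
        tin_max=tin.max(axis=0),
    )
    Xflat = np.zeros((ns, s * s))
    Xflat[:, :n_nodes] = norm.scale_u(S).T
    mask = np.zeros(s * s, dtype=bool)
    mask[:n_nodes] = True
    return DLDataset(
        X=Xflat.reshape(ns, 1, s, s),
        tin=norm.scale_tin(tin),
        mask=mask.reshape(s, s),
        norm=norm,
        n_nodes=n_nodes,
        side=s,
    )


def dlrom_loss(
    u: np.ndarray,
    u_tilde: np.ndarray,
    un: np.ndarray,
    un_tilde: np.ndarray,
    omega_h: float,
    mask: np.ndarray | None = None,
) -> float:
    """Per-batch loss: omega_h/2 |u - u_tilde|^2 + (1-omega_h)/2
    |un_tilde - un|^2, averaged over the batch."""
    du = u - u_tilde
    if mask is not None:
        du = du * mask
    B = u.shape[0]
    recon = 0.5 * omega_h * (du**2).sum() / B
    code = 0.5 * (1.0 - omega_h) * ((un_tilde - un) ** 2).sum() / B
    return float(recon + code)


def _build_networks(arch: DLROMArchitecture, side: int, n_in: int,
                    rng: np.random.Generator):
    """(encoder, dfnn, decoder) Sequentials for a given image side."""
    L = len(arch.conv_channels)
    if side % arch.stride**L != 0:
        raise ValueError(
            f"side {side} not divisible by stride^{L}; "
            "reduce conv depth or change the grid"
        )
    sf = side // arch.stride**L
    c_last = arch.conv_channels[-1]

    enc_layers: list = []
    prev = 1
    for c in arch.conv_channels:
        enc_layers += [Conv2D(prev, c, arch.kernel, arch.stride, rng), ELU()]
        prev = c
    enc_layers += [Flatten(), Dense(c_last * sf * sf, arch.n, rng)]

    dfnn_layers: list = []
    prev = n_in
    for h in arch.dfnn_hidden:
        dfnn_layers += [Dense(prev, h, rng), ELU()]
        prev = h
    dfnn_layers.append(Dense(prev, arch.n, rng))

    dec_layers: list = [
        Dense(arch.n, c_last * sf * sf, rng),
        ELU(),
        Reshape((c_last, sf, sf)),
    ]
    rev = list(arch.conv_channels[::-1])
    for c_in, c_out in zip(rev, rev[1:] + [1]):
        dec_layers.append(ConvTranspose2D(c_in, c_out, arch.kernel,
                                          arch.stride, rng))
        if c_out != 1:
            dec_layers.append(ELU())
    return Sequential(enc_layers), Sequential(dfnn_layers), Sequential(dec_layers)


@dataclass
class TrainedDLROM:
    """Trained weights plus the metadata needed to evaluate the surrogate."""

    arch: DLROMArchitecture
    encoder: Sequential
    dfnn: Sequential
    decoder: Sequential
    norm: Normalization
    mask: np.ndarray
    n_nodes: int
    side: int
    history: list = field(default_factory=list)
    seed: int = 0
    param_box: np.ndarray | None = None

    def _tin(self, t: np.ndarray, mu: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        mu = np.asarray(mu, dtype=float)
        if mu.ndim == 1:
            mu = np.tile(mu, (len(t), 1))
        if len(mu) != len(t):
            raise ValueError("t and mu sample counts differ")
        return self.norm.scale_tin(np.column_stack([t, mu]))

    def predict(self, t: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """Evaluate u(t; mu) for a batch of (t, mu); shape (n_samples, N).

        Only the feedforward network and the decoder are evaluated; each
        query is independent of any other (no internal state).
        """
        tin = self._tin(t, mu)
        if np.any(tin < -1e-6) or np.any(tin > 1 + 1e-6):
            warnings.warn("query outside the training (t, mu) range",
                          stacklevel=2)
        un = self.dfnn.forward(tin)
        img = self.decoder.forward(un)
        flat = img.reshape(len(tin), -1)[:, : self.n_nodes]
        return self.norm.unscale_u(flat)

    def encode(self, u: np.ndarray) -> np.ndarray:
        """Latent codes of full-order states (diagnostics only); (B, n)."""
        u = np.atleast_2d(np.asarray(u, dtype=float))
        ns = u.shape[0]
        flat = np.zeros((ns, self.side * self.side))
        flat[:, : self.n_nodes] = self.norm.scale_u(u)
        return self.encoder.forward(flat.reshape(ns, 1, self.side, self.side))

    def latent(self, t: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """Latent coordinates phi(t, mu); (B, n)."""
        return self.dfnn.forward(self._tin(t, mu))

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        weights = {}
        for name, net in (("enc", self.encoder), ("dfnn", self.dfnn),
                          ("dec", self.decoder)):
            for i, p in enumerate(net.params):
                weights[f"{name}_{i}"] = p
        np.savez(d / "weights.npz", mask=self.mask, **weights)
        meta = {
            "arch": {
                "n": self.arch.n,
                "conv_channels": list(self.arch.conv_channels),
                "kernel": self.arch.kernel,
                "stride": self.arch.stride,
                "dfnn_hidden": list(self.arch.dfnn_hidden),
            },
            "norm": {
                "u_min": self.norm.u_min,
                "u_max": self.norm.u_max,
                "tin_min": self.norm.tin_min.tolist(),
                "tin_max": self.norm.tin_max.tolist(),
            },
            "n_nodes": self.n_nodes,
            "side": self.side,
            "seed": self.seed,
            "n_inputs": int(len(self.norm.tin_min)),
            "param_box": None
            if self.param_box is None
            else np.asarray(self.param_box).tolist(),
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
        if self.history:
            hdr = "epoch,train_loss,val_loss"
            rows = [f"{e},{tr:.17e},{vl:.17e}" for e, tr, vl in self.history]
            (d / "history.csv").write_text("\n".join([hdr] + rows) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedDLROM":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        arch = DLROMArchitecture(
            n=meta["arch"]["n"],
            conv_channels=tuple(meta["arch"]["conv_channels"]),
            kernel=meta["arch"]["kernel"],
            stride=meta["arch"]["stride"],
            dfnn_hidden=tuple(meta["arch"]["dfnn_hidden"]),
        )
        norm = Normalization(
            u_min=meta["norm"]["u_min"],
            u_max=meta["norm"]["u_max"],
            tin_min=np.asarray(meta["norm"]["tin_min"]),
            tin_max=np.asarray(meta["norm"]["tin_max"]),
        )
        rng = np.random.default_rng(0)
        enc, dfnn, dec = _build_networks(arch, meta["side"], meta["n_inputs"],
                                         rng)
        data = np.load(d / "weights.npz")
        for name, net in (("enc", enc), ("dfnn", dfnn), ("dec", dec)):
            net.set_weights([data[f"{name}_{i}"]
                             for i in range(len(net.params))])
        history = []
        hist_file = d / "history.csv"
        if hist_file.exists():
            for line in hist_file.read_text().strip().splitlines()[1:]:
                e, tr, vl = line.split(",")
                history.append((int(e), float(tr), float(vl)))
        return cls(
            arch=arch,
            encoder=enc,
            dfnn=dfnn,
            decoder=dec,
            norm=norm,
            mask=data["mask"],
            n_nodes=meta["n_nodes"],
            side=meta["side"],
            history=history,
            seed=meta["seed"],
            param_box=None
            if meta.get("param_box") is None
            else np.asarray(meta["param_box"]),
        )


def train(dataset: DLDataset, arch: DLROMArchitecture,
          config: TrainConfig) -> TrainedDLROM:
    """Minimize the two-term loss with Adam and early stopping.

    The sample set is split 8:2 (configurable) into training and
    validation at the individual (t, mu) level; the best-validation
    weights are checkpointed and restored at the end.  Everything is
    driven by a single seeded generator, so repeated runs are bitwise
    identical.
    """
    rng = np.random.default_rng(config.seed)
    ns = dataset.X.shape[0]
    perm = rng.permutation(ns)
    n_val = max(1, int(round(config.val_fraction * ns)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    enc, dfnn, dec = _build_networks(arch, dataset.side,
                                     dataset.tin.shape[1], rng)
    params = enc.params + dfnn.params + dec.params
    opt = Adam(params, lr=config.lr)
    mask = dataset.mask[None, None, :, :].astype(float)
    omega = config.omega_h

    def eval_loss(idx: np.ndarray) -> float:
        total = 0.0
        for lo in range(0, len(idx), 256):
            sel = idx[lo : lo + 256]
            X = dataset.X[sel]
            un_t = enc.forward(X)
            un = dfnn.forward(dataset.tin[sel])
            u_t = dec.forward(un)
            total += dlrom_loss(X, u_t, un, un_t, omega, mask) * len(sel)
        return total / len(idx)

    history: list[tuple[int, float, float]] = []
    best_val = np.inf
    best_weights = None
    best_epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(tr_idx)
        train_loss = 0.0
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo : lo + config.batch_size]
            B = len(sel)
            X = dataset.X[sel]
            un_tilde = enc.forward(X)
            un = dfnn.forward(dataset.tin[sel])
            u_tilde = dec.forward(un)
            loss = dlrom_loss(X, u_tilde, un, un_tilde, omega, mask)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; history={history!r}"
                )
            train_loss += loss * B
            enc.zero_grad()
            dfnn.zero_grad()
            dec.zero_grad()
            d_u_tilde = omega * (u_tilde - X) * mask / B
            d_un_dec = dec.backward(d_u_tilde)
            d_un = d_un_dec + (1.0 - omega) * (un - un_tilde) / B
            dfnn.backward(d_un)
            d_un_tilde = (1.0 - omega) * (un_tilde - un) / B
            enc.backward(d_un_tilde)
            opt.step(enc.grads + dfnn.grads + dec.grads)
        train_loss /= len(order)
        val_loss = eval_loss(val_idx)
        history.append((epoch, train_loss, val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_weights = (enc.get_weights(), dfnn.get_weights(),
                            dec.get_weights())
        elif epoch - best_epoch >= config.patience:
            break
    if best_weights is not None:
        enc.set_weights(best_weights[0])
        dfnn.set_weights(best_weights[1])
        dec.set_weights(best_weights[2])
    return TrainedDLROM(
        arch=arch,
        encoder=enc,
        dfnn=dfnn,
        decoder=dec,
        norm=dataset.norm,
        mask=dataset.mask,
        n_nodes=dataset.n_nodes,
        side=dataset.side,
        history=history,
        seed=config.seed,
    )


class DLROM(BaseEstimator):
    """scikit-learn style estimator wrapping dataset preparation, network
    construction and training.

    ``fit`` consumes a SnapshotSet; ``predict(t, mu)`` evaluates the
    surrogate at arbitrary (t, mu) without time-stepping.
    """

    def __init__(
        self,
        n: int = 3,
        conv_channels: tuple[int, ...] = (8, 16, 32, 64),
        kernel: int = 5,
        stride: int = 2,
        dfnn_hidden: tuple[int, ...] = (50, 50, 50, 50),
        omega_h: float = 0.5,
        lr: float = 1e-4,
        batch_size: int = 40,
        max_epochs: int = 2000,
        patience: int = 500,
        val_fraction: float = 0.2,
        seed: int = 0,
    ) -> None:
        self.n = n
        self.conv_channels = conv_channels
        self.kernel = kernel
        self.stride = stride
        self.dfnn_hidden = dfnn_hidden
        self.omega_h = omega_h
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    def fit(self, snapshots: SnapshotSet, param_box: np.ndarray | None = None):
        dataset = prepare_dataset(snapshots)
        arch = DLROMArchitecture(
            n=self.n,
            conv_channels=tuple(self.conv_channels),
            kernel=self.kernel,
            stride=self.stride,
            dfnn_hidden=tuple(self.dfnn_hidden),
        )
        config = TrainConfig(
            lr=self.lr,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            omega_h=self.omega_h,
            val_fraction=self.val_fraction,
            seed=self.seed,
        )
        self.model_ = train(dataset, arch, config)
        self.model_.param_box = param_box
        self.history_ = self.model_.history
        return self

    def predict(self, t: np.ndarray, mu: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit must be called before predict")
        return self.model_.predict(t, mu)

    def encode(self, u: np.ndarray) -> np.ndarray:
        return self.model_.encode(u)
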