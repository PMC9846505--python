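"""SADLN: self-attention adversarial autoencoder for multi-omics integration.

The model integrates M omics blocks into one N x d_k latent matrix Z. Per
block, an independent affine sub-network maps the D_m input features to d
dimensions; the M outputs are concatenated (d_k = M * d), batch-normalized,
passed through a GELU, mixed across samples by scaled dot-product
self-attention, batch-normalized again and mapped by a fully-connected
layer to Gaussian latent heads (mean and log-variance). A decoder
reconstructs every block from Z, and a discriminator — trained
adversarially against the encoder — pushes the latent distribution toward
a standard normal prior, so the total generator objective is

    L = lambda1 * L_decoder + lambda2 * L_adversarial.

Usage follows the Model/Results convention::

    model = SADLN(dataset)               # or SADLN(dataset, epochs=200, seed=2)
    res = model.fit()
    latent = res.transform()             # inference-mode Z = mu, full-set attention
    print(res.summary())
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .data import OmicsDataset
from .layers import Adam, Affine, BatchNorm, SelfAttention, gelu, gelu_grad, softmax

__all__ = [
    "ArchitectureConfig",
    "LatentRepresentation",
    "SADLN",
    "SADLNResults",
    "DivergenceError",
    "LEARNING_RATE_GRID",
    "sub_network_forward",
    "concat_features",
    "self_attention",
    "decoder_loss",
    "discriminator_losses",
    "total_loss",
    "model_summary",
]

#: learning rates the method was tuned over; the single default is the first.
LEARNING_RATE_GRID = (1e-4, 2e-4, 3e-4, 4e-4, 5e-4, 1e-5, 2e-5, 3e-5, 4e-5, 5e-5)

_EPS = 1e-7  # discriminator output clamp


class DivergenceError(FloatingPointError):
    """Raised when a training loss becomes non-finite."""


@dataclass
class ArchitectureConfig:
    """Hyperparameters of the network.

    ``latent_dim`` is always M * per_omics_width; lambda1 weighs the
    reconstruction loss and lambda2 the adversarial regularizer.
    """

    block_input_dims: tuple[int, ...]
    per_omics_width: int = 25
    learning_rate: float = 1e-4
    epochs: int = 600
    batch_size: int = 64
    seed: int = 2
    lambda1: float = 1.0
    lambda2: float = 1e-4
    use_attention: bool = True

    def __post_init__(self) -> None:
        if not self.block_input_dims:
            raise ValueError("need at least one omics block")
        if not (0 <= self.lambda1 <= 1 and 0 <= self.lambda2 <= 1):
            raise ValueError("lambda1 and lambda2 must lie in [0, 1]")

    @property
    def n_blocks(self) -> int:
        return len(self.block_input_dims)

    @property
    def latent_dim(self) -> int:
        return self.n_blocks * self.per_omics_width


@dataclass
class LatentRepresentation:
    """Integrated representation: Z (= mu in inference mode) with its heads."""

    Z: np.ndarray
    mu: np.ndarray
    log_var: np.ndarray
    sample_ids: list[str]

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.Z, index=self.sample_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# functional forms (used by the network and directly testable)

def sub_network_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-omics sub-network: the row-wise affine map y = x w + b."""
    return np.asarray(x) @ np.asarray(w) + np.asarray(b)


def concat_features(y_list: list[np.ndarray]) -> np.ndarray:
    """Column-wise concatenation of the per-omics outputs, in block order."""
    rows = {y.shape[0] for y in y_list}
    if len(rows) != 1:
        raise ValueError(f"row-count mismatch across blocks: {sorted(rows)}")
    return np.concatenate(y_list, axis=1)


def self_attention(
    yp: np.ndarray, w_k: np.ndarray, w_q: np.ndarray, w_v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product self-attention across samples.

    Returns (Z, weights): weights row i is softmax_j((q_i . k_j)/sqrt(d_k))
    and Z row i the weight-averaged value rows.
    """
    d_k = yp.shape[1]
    q, k, v = yp @ w_q, yp @ w_k, yp @ w_v
    scores = q @ k.T / np.sqrt(d_k)
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite attention projections")
    w = softmax(scores, axis=1)
    return w @ v, w


def decoder_loss(x_blocks: list[np.ndarray], xhat_blocks: list[np.ndarray]) -> float:
    """Reconstruction loss: mean over blocks of the squared Frobenius
    distance, averaged over the samples in the batch."""
    if len(x_blocks) != len(xhat_blocks):
        raise ValueError("block count mismatch")
    n = x_blocks[0].shape[0]
    m = len(x_blocks)
    total = 0.0
    for x, xh in zip(x_blocks, xhat_blocks):
        if x.shape != xh.shape:
            raise ValueError(f"shape mismatch {x.shape} vs {xh.shape}")
        total += float(np.sum((x - xh) ** 2))
    return total / (m * n)


def discriminator_losses(d_prior: np.ndarray, d_gen: np.ndarray) -> tuple[float, float]:
    """Binary cross-entropy losses of the adversarial game.

    d_loss trains the discriminator to score prior draws 1 and encoded
    samples 0; g_loss is the non-saturating generator objective pushing
    encoded samples toward score 1. Outputs are clamped away from {0, 1}.
    """
    if d_prior.size == 0 or d_gen.size == 0:
        raise ValueError("empty discriminator batch")
    p = np.clip(d_prior, _EPS, 1 - _EPS)
    g = np.clip(d_gen, _EPS, 1 - _EPS)
    d_loss = float(-np.mean(np.log(p)) - np.mean(np.log(1 - g)))
    g_loss = float(-np.mean(np.log(g)))
    return d_loss, g_loss


def total_loss(l_dec: float, l_adv: float, lambda1: float, lambda2: float) -> float:
    """Generator-side objective lambda1 * L_decoder + lambda2 * L_adversarial."""
    return lambda1 * l_dec + lambda2 * l_adv


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# the network


class _Network:
    """All trainable parameters; forward/backward per component."""

    def __init__(self, config: ArchitectureConfig, rng: np.random.Generator):
        self.config = config
        d, dk = config.per_omics_width, config.latent_dim
        self.subs = [Affine(dm, d, rng) for dm in config.block_input_dims]
        self.bn1 = BatchNorm(dk)
        self.attn = SelfAttention(dk, rng) if config.use_attention else None
        self.bn2 = BatchNorm(dk)
        self.fc = Affine(dk, dk, rng)
        self.mean_head = Affine(dk, dk, rng)
        self.logvar_head = Affine(dk, dk, rng)
        self.dec_fc = Affine(dk, dk, rng)
        self.dec_bn = BatchNorm(dk)
        self.dec_heads = [Affine(dk, dm, rng) for dm in config.block_input_dims]
        self.disc = Affine(dk, 1, rng)
        self._enc_gelu_in: np.ndarray | None = None
        self._dec_gelu_in: np.ndarray | None = None

    # -- parameter bookkeeping -------------------------------------------
    def _encoder_layers(self):
        layers = [*self.subs, self.bn1, self.bn2, self.fc, self.mean_head, self.logvar_head]
        if self.attn is not None:
            layers.insert(len(self.subs) + 1, self.attn)
        return layers

    def _decoder_layers(self):
        return [self.dec_fc, self.dec_bn, *self.dec_heads]

    def encoder_params(self):
        return [p for layer in self._encoder_layers() for p in layer.params]

    def encoder_grads(self):
        return [g for layer in self._encoder_layers() for g in layer.grads]

    def decoder_params(self):
        return [p for layer in self._decoder_layers() for p in layer.params]

    def decoder_grads(self):
        return [g for layer in self._decoder_layers() for g in layer.grads]

    def zero_grads(self) -> None:
        for layer in [*self._encoder_layers(), *self._decoder_layers(), self.disc]:
            for g in layer.grads:
                g[...] = 0.0

    # -- forward / backward ----------------------------------------------
    def encode(self, xs: list[np.ndarray], train: bool) -> tuple[np.ndarray, np.ndarray]:
        ys = [sub.forward(x, train) for sub, x in zip(self.subs, xs)]
        y = concat_features(ys)
        h = self.bn1.forward(y, train)
        self._enc_gelu_in = h if train else None
        a = gelu(h)
        if self.attn is not None:
            a = self.attn.forward(a, train)
        h2 = self.bn2.forward(a, train)
        h3 = self.fc.forward(h2, train)
        mu = self.mean_head.forward(h3, train)
        log_var = self.logvar_head.forward(h3, train)
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(log_var))):
            raise DivergenceError("non-finite encoder activations")
        return mu, log_var

    def encode_backward(self, dmu: np.ndarray, dlogvar: np.ndarray) -> None:
        dh3 = self.mean_head.backward(dmu) + self.logvar_head.backward(dlogvar)
        dh2 = self.fc.backward(dh3)
        da = self.bn2.backward(dh2)
        if self.attn is not None:
            da = self.attn.backward(da)
        dh = da * gelu_grad(self._enc_gelu_in)
        dy = self.bn1.backward(dh)
        start = 0
        d = self.config.per_omics_width
        for sub in self.subs:
            sub.backward(dy[:, start : start + d])
            start += d

    def decode(self, z: np.ndarray, train: bool) -> list[np.ndarray]:
        t = self.dec_fc.forward(z, train)
        tb = self.dec_bn.forward(t, train)
        self._dec_gelu_in = tb if train else None
        tg = gelu(tb)
        self._dec_gelu_out = tg if train else None
        return [head.forward(tg, train) for head in self.dec_heads]

    def decode_backward(self, gouts: list[np.ndarray]) -> np.ndarray:
        dtg = sum(head.backward(g) for head, g in zip(self.dec_heads, gouts))
        dtb = dtg * gelu_grad(self._dec_gelu_in)
        dt = self.dec_bn.backward(dtb)
        return self.dec_fc.backward(dt)

    def discriminate(self, z: np.ndarray, train: bool) -> np.ndarray:
        return _sigmoid(self.disc.forward(z, train))[:, 0]

    def discriminate_backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.disc.backward(np.asarray(dlogits).reshape(-1, 1))

    # -- serialization ----------------------------------------------------
    def _named_layers(self):
        names = {f"sub{i}": s for i, s in enumerate(self.subs)}
        names.update(bn1=self.bn1, bn2=self.bn2, fc=self.fc, mean=self.mean_head, logvar=self.logvar_head)
        if self.attn is not None:
            names["attn"] = self.attn
        names.update(dec_fc=self.dec_fc, dec_bn=self.dec_bn, disc=self.disc)
        names.update({f"dec_head{i}": h for i, h in enumerate(self.dec_heads)})
        return names

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, layer in self._named_layers().items():
            for i, p in enumerate(layer.params):
                state[f"{name}.p{i}"] = p
            if isinstance(layer, BatchNorm):
                state[f"{name}.running_mean"] = layer.running_mean
                state[f"{name}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._named_layers().items():
            for i, p in enumerate(layer.params):
                p[...] = state[f"{name}.p{i}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(state[f"{name}.running_mean"])
                layer.running_var = np.array(state[f"{name}.running_var"])


def model_summary(network: _Network) -> dict:
    """Structured layer accounting plus parameter totals.

    Rows are counted the way the architecture table prints them: the
    encoder's input, concatenation, two batch-norms, activation, attention,
    fully-connected and the two latent heads plus output (10 rows with
    attention); decoder input/fully-connected/batch-norm/activation/output
    (5); discriminator input/fully-connected/sigmoid/output (4).
    """
    cfg = network.config
    dk = cfg.latent_dim
    enc = [
        ("Input", " + ".join(str(d) for d in cfg.block_input_dims)),
        ("Concatenate (sub-networks)", " + ".join(str(cfg.per_omics_width) for _ in cfg.block_input_dims)),
        ("Batch normalization", dk),
        ("Activation (GELU)", dk),
    ]
    if cfg.use_attention:
        enc.append(("Attention", dk))
    enc += [
        ("Batch normalization", dk),
        ("Fully-connected", dk),
        ("Fully-connected, Mean", dk),
        ("Fully-connected, Var", dk),
        ("Output", dk),
    ]
    dec = [
        ("Input", dk),
        ("Fully-connected", dk),
        ("Batch normalization", dk),
        ("Activation (GELU)", dk),
        ("Output", " + ".join(str(d) for d in cfg.block_input_dims)),
    ]
    disc = [("Input", dk), ("Fully-connected", 1), ("Sigmoid", 1), ("Output", 1)]
    n_enc = sum(p.size for p in network.encoder_params())
    n_dec = sum(p.size for p in network.decoder_params())
    n_disc = sum(p.size for p in network.disc.params)
    return {
        "encoder": enc,
        "decoder": dec,
        "discriminator": disc,
        "encoder_layers": len(enc),
        "decoder_layers": len(dec),
        "discriminator_layers": len(disc),
        "total_layers": len(enc) + len(dec) + len(disc),
        "encoder_parameters": n_enc,
        "decoder_parameters": n_dec,
        "discriminator_parameters": n_disc,
        "total_parameters": n_enc + n_dec + n_disc,
    }


# ---------------------------------------------------------------------------
# Model / Results


class SADLN:
    """Adversarial autoencoder model over an aligned multi-omics dataset.

    Parameters
    ----------
    dataset : OmicsDataset
        Row-aligned omics blocks. Standardize features first (see
        :func:`sadln.data.zscore_blocks`) unless they are already scaled.
    config : ArchitectureConfig, optional
        Full hyperparameter set; built from the dataset's block widths when
        omitted. Keyword overrides (``epochs=200``, ``lambda2=0`` ...) are
        applied on top.
    """

    def __init__(self, dataset: OmicsDataset, config: ArchitectureConfig | None = None, **overrides):
        if config is None:
            config = ArchitectureConfig(block_input_dims=tuple(dataset.block_widths))
        if overrides:
            cfg = asdict(config)
            cfg.update(overrides)
            cfg["block_input_dims"] = tuple(cfg["block_input_dims"])
            config = ArchitectureConfig(**cfg)
        if tuple(dataset.block_widths) != tuple(config.block_input_dims):
            raise ValueError(
                f"dataset block widths {dataset.block_widths} do not match "
                f"config {config.block_input_dims}"
            )
        self.dataset = dataset
        self.config = config

    def fit(self) -> "SADLNResults":
        """Train with the alternating adversarial schedule.

        Per minibatch: (1) generator step — encoder and decoder updated
        jointly on lambda1 * reconstruction + lambda2 * the non-saturating
        adversarial loss (latent sampled by the reparameterization trick,
        discriminator frozen), so the lambda trade-off acts on the summed
        gradient before Adam's normalization; (2) discriminator step on
        fresh prior draws versus the detached latent batch.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net = _Network(cfg, rng)
        xs_full = self.dataset.as_matrices()
        n = self.dataset.n_samples
        m = len(xs_full)
        dk = cfg.latent_dim

        opt_gen = Adam(net.encoder_params() + net.decoder_params(), cfg.learning_rate)
        opt_disc = Adam(net.disc.params, cfg.learning_rate)

        trace_rows = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            sums = np.zeros(3)
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xs = [x[idx] for x in xs_full]
                b = len(idx)

                # generator step: lambda1 * L_dec + lambda2 * g_loss
                net.zero_grads()
                mu, log_var = net.encode(xs, train=True)
                eps = rng.standard_normal(mu.shape)
                std = np.exp(0.5 * log_var)
                z = mu + std * eps
                xhat = net.decode(z, train=True)
                l_dec = decoder_loss(xs, xhat)
                gouts = [cfg.lambda1 * 2.0 * (xh - x) / (m * b) for x, xh in zip(xs, xhat)]
                dz = net.decode_backward(gouts)
                p_gen = net.discriminate(z, train=True)
                g_loss = float(-np.mean(np.log(np.clip(p_gen, _EPS, 1 - _EPS))))
                dz = dz + net.discriminate_backward(cfg.lambda2 * (p_gen - 1.0) / b)
                net.disc.grads[0][...] = 0.0  # discriminator frozen in this step
                net.disc.grads[1][...] = 0.0
                net.encode_backward(dz, dz * eps * 0.5 * std)
                opt_gen.step(net.encoder_grads() + net.decoder_grads())

                # discriminator step: fresh prior draws vs detached z
                net.zero_grads()
                z_prior = rng.standard_normal((b, dk))
                p_prior = net.discriminate(z_prior, train=True)
                net.discriminate_backward((p_prior - 1.0) / b)
                p_fake = net.discriminate(z, train=True)
                net.discriminate_backward(p_fake / b)
                d_loss, _ = discriminator_losses(p_prior, p_fake)
                opt_disc.step(net.disc.grads)

                if not np.isfinite([l_dec, d_loss, g_loss]).all():
                    raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
                sums += (l_dec, d_loss, g_loss)
                n_batches += 1

            means = sums / n_batches
            trace_rows.append(
                {
                    "epoch": epoch + 1,
                    "decoder_loss": means[0],
                    "discriminator_loss": means[1],
                    "generator_loss": means[2],
                    "total_loss": total_loss(means[0], means[2], cfg.lambda1, cfg.lambda2),
                }
            )

        trace = pd.DataFrame(
            trace_rows,
            columns=["epoch", "decoder_loss", "discriminator_loss", "generator_loss", "total_loss"],
        )
        return SADLNResults(net, cfg, trace, dataset=self.dataset)


class SADLNResults:
    """Fitted model: parameters, training trace, and the latent transform."""

    def __init__(self, network: _Network, config: ArchitectureConfig, trace: pd.DataFrame, dataset: OmicsDataset | None = None):
        self._network = network
        self.config = config
        self.trace = trace
        self.dataset = dataset

    def transform(self, dataset: OmicsDataset | None = None) -> LatentRepresentation:
        """Inference-mode integrated representation.

        Deterministic: Z = mu, batch statistics come from the running
        averages, and attention (when on) is computed over the full sample
        set in a single pass so Z does not depend on batching.
        """
        data = dataset if dataset is not None else self.dataset
        if data is None:
            raise ValueError("no dataset bound; pass one explicitly")
        mu, log_var = self._network.encode(data.as_matrices(), train=False)
        return LatentRepresentation(Z=mu, mu=mu, log_var=log_var, sample_ids=list(data.sample_ids))

    def summary(self) -> str:
        """Plain-text layer table with parameter counts and final losses."""
        info = model_summary(self._network)
        buf = io.StringIO()
        buf.write("SADLN integration model\n")
        buf.write("=" * 60 + "\n")
        for comp in ("encoder", "decoder", "discriminator"):
            buf.write(f"{comp.capitalize()} ({info[f'{comp}_layers']} layers, "
                      f"{info[f'{comp}_parameters']:,} parameters)\n")
            for name, width in info[comp]:
                buf.write(f"  {name:<30} {width}\n")
        buf.write("-" * 60 + "\n")
        buf.write(f"Total layers: {info['total_layers']}   "
                  f"Total parameters: {info['total_parameters']:,}\n")
        if len(self.trace):
            last = self.trace.iloc[-1]
            buf.write(
                f"Final losses (epoch {int(last['epoch'])}): "
                f"decoder {last['decoder_loss']:.4f}, "
                f"discriminator {last['discriminator_loss']:.4f}, "
                f"generator {last['generator_loss']:.4f}, "
                f"total {last['total_loss']:.4f}\n"
            )
        return buf.getvalue()

    def layer_counts(self) -> dict:
        return model_summary(self._network)

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file checkpoint: all tensors, running stats, config, trace."""
        state = self._network.state_dict()
        meta = {"config": asdict(self.config), "trace": self.trace.to_dict(orient="list")}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path: str, dataset: OmicsDataset | None = None) -> "SADLNResults":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        cfg_d = meta["config"]
        cfg_d["block_input_dims"] = tuple(cfg_d["block_input_dims"])
        config = ArchitectureConfig(**cfg_d)
        net = _Network(config, np.random.default_rng(config.seed))
        net.load_state_dict(state)
        trace = pd.DataFrame(meta["trace"])
        return cls(net, config, trace, dataset=dataset)
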