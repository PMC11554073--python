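"""Variational autoencoders for segmentation slice stacks.

Two VAEs produce the deep imaging features: VAE 1 encodes the lesion channels
(core + edema) and VAE 2 the brain-mask channel, each into a 48-dimensional
latent space. A stack is deterministically average-pooled to a coarse grid,
flattened, and passed through a dense encoder that outputs the posterior mean
and log-variance; the decoder mirrors the encoder and reconstructs the pooled
occupancy map. Training maximises the evidence lower bound (binary
cross-entropy reconstruction + KL divergence to the standard-normal prior).

Feature extraction is deterministic: the posterior mean ``mu`` is the
feature vector, tagged with its group (pre/post × lesion/mask).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, DenseStack, sigmoid
from .volumes import SliceStack

GROUPS = ("pre_lesion", "post_lesion", "pre_mask", "post_mask")
LOGVAR_CLIP = 8.0


@dataclass
class VaeConfig:
    latent_dim: int = 48
    input_channels: int = 2  # 2 for the lesion VAE, 1 for the mask VAE
    input_shape: tuple[int, int, int] = (24, 64, 64)  # slices, H, W
    pool: tuple[int, int, int] = (2, 4, 4)  # average-pooling factors
    hidden_widths: tuple[int, ...] = (256,)
    kl_weight: float = 1.0
    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def pooled_shape(self) -> tuple[int, int, int]:
        for s, p in zip(self.input_shape, self.pool):
            if s % p != 0:
                raise ValueError(
                    f"input shape {self.input_shape} not divisible by pooling {self.pool}")
        return tuple(s // p for s, p in zip(self.input_shape, self.pool))

    def flat_dim(self) -> int:
        return int(np.prod(self.pooled_shape())) * self.input_channels


def elbo_loss(x: np.ndarray, recon_logits: np.ndarray, mu: np.ndarray,
              logvar: np.ndarray, kl_weight: float = 1.0):
    """Negative evidence lower bound and its two terms.

    Reconstruction: mean binary cross-entropy between ``x`` (targets in
    [0,1]) and ``sigmoid(recon_logits)``, averaged over every element.
    KL: summed over latent dimensions, averaged over the batch.
    """
    x = np.asarray(x, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(recon_logits).all()
            and np.isfinite(mu).all() and np.isfinite(logvar).all()):
        raise ValueError("non-finite inputs to elbo_loss")
    if x.shape != recon_logits.shape:
        raise ValueError("x and recon_logits shapes disagree")
    # numerically stable BCE-with-logits: max(l,0) - l*x + log(1+exp(-|l|))
    l = recon_logits
    rec = float(np.mean(np.maximum(l, 0) - l * x + np.log1p(np.exp(-np.abs(l)))))
    mu2 = np.atleast_2d(mu)
    lv2 = np.atleast_2d(logvar)
    kl = float(np.mean(-0.5 * np.sum(1 + lv2 - mu2 ** 2 - np.exp(lv2), axis=1)))
    return rec + kl_weight * kl, rec, kl


class Vae:
    """Dense VAE over pooled slice stacks; see module docstring."""

    def __init__(self, config: VaeConfig):
        self.config = config
        config.pooled_shape()  # validate divisibility
        d = config.flat_dim()
        rng = np.random.default_rng(config.seed)
        widths = list(config.hidden_widths)
        self.encoder = DenseStack([d, *widths, 2 * config.latent_dim], rng)
        self.decoder = DenseStack([config.latent_dim, *widths[::-1], d], rng)

    def n_params(self) -> int:
        return self.encoder.n_params() + self.decoder.n_params()

    # -- data plumbing ---------------------------------------------------
    def _pool_flatten(self, x: np.ndarray) -> np.ndarray:
        """(B, S, H, W, C) binary stack -> (B, flat) pooled occupancy."""
        cfg = self.config
        b = x.shape[0]
        if x.shape[1:] != (*cfg.input_shape, cfg.input_channels):
            raise ValueError(
                f"stack shape {x.shape[1:]} does not match VAE input "
                f"{(*cfg.input_shape, cfg.input_channels)}")
        ps, ph, pw = cfg.pool
        s, h, w = cfg.input_shape
        x = x.reshape(b, s // ps, ps, h // ph, ph, w // pw, pw, cfg.input_channels)
        x = x.mean(axis=(2, 4, 6))
        return x.reshape(b, -1)

    def encode(self, x_flat: np.ndarray):
        out, cache = self.encoder.forward(x_flat, train=False)
        mu = out[:, :self.config.latent_dim]
        logvar = np.clip(out[:, self.config.latent_dim:], -LOGVAR_CLIP, LOGVAR_CLIP)
        return mu, logvar

    def reconstruct_logits(self, x: np.ndarray) -> np.ndarray:
        """Deterministic (mu-path) reconstruction logits on the pooled grid."""
        mu, _ = self.encode(self._pool_flatten(np.asarray(x, dtype=float)))
        logits, _ = self.decoder.forward(mu, train=False)
        return logits

    # -- training --------------------------------------------------------
    def _step(self, xf: np.ndarray, rng: np.random.Generator, opt: Adam):
        cfg = self.config
        out, enc_cache = self.encoder.forward(xf, train=True, rng=rng)
        mu = out[:, :cfg.latent_dim]
        raw_lv = out[:, cfg.latent_dim:]
        logvar = np.clip(raw_lv, -LOGVAR_CLIP, LOGVAR_CLIP)
        eps = rng.standard_normal(mu.shape)
        z = mu + eps * np.exp(0.5 * logvar)
        logits, dec_cache = self.decoder.forward(z, train=True, rng=rng)

        _, rec, kl = elbo_loss(xf, logits, mu, logvar, cfg.kl_weight)
        # Training objective is the per-image negative ELBO: reconstruction
        # log-likelihood summed over voxels, KL summed over latent dims
        # (mean-BCE training would let the KL term collapse the posterior).
        d = xf.shape[1]
        total = d * rec + cfg.kl_weight * kl
        if not np.isfinite(total):
            raise FloatingPointError(
                f"VAE training diverged (loss={total}, rec={rec}, kl={kl})")

        b = xf.shape[0]
        dlogits = (sigmoid(logits) - xf) / b
        dz, dec_grads = self.decoder.backward(dec_cache, dlogits)
        dmu = dz + cfg.kl_weight * mu / b
        dlv = (dz * eps * 0.5 * np.exp(0.5 * logvar)
               + cfg.kl_weight * (-0.5) * (1.0 - np.exp(logvar)) / b)
        dlv = dlv * (np.abs(raw_lv) < LOGVAR_CLIP)  # clip gate
        _, enc_grads = self.encoder.backward(enc_cache, np.concatenate([dmu, dlv], axis=1))
        opt.step(enc_grads + dec_grads)
        return total

    def channel_input(self, stack: SliceStack) -> np.ndarray:
        return stack.lesion if self.config.input_channels == 2 else stack.brain_mask


def build_vae(config: VaeConfig) -> Vae:
    """Construct a VAE from its config (parameter count on ``n_params()``)."""
    return Vae(config)


def pretrain(vae: Vae, stacks: list[SliceStack], epochs: int | None = None,
             seed: int | None = None) -> list[float]:
    """Train the VAE on slice stacks; returns per-epoch mean loss history."""
    if not stacks:
        raise ValueError("empty pretraining dataset")
    cfg = vae.config
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    # pool each stack individually: full-resolution stacks are never held in
    # one array (a large corpus would not fit in memory otherwise)
    xf = np.concatenate([
        vae._pool_flatten(vae.channel_input(s)[None].astype(np.float32))
        for s in stacks])
    opt = Adam(vae.encoder.params + vae.decoder.params, lr=cfg.learning_rate)
    history: list[float] = []
    n = xf.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            batch = xf[order[i:i + cfg.batch_size]]
            losses.append(vae._step(batch, rng, opt))
        history.append(float(np.mean(losses)))
    return history


def extract_latent(vae: Vae, stack: SliceStack, group: str) -> "LatentFeatures":
    """Deterministic latent features (posterior mean) for one stack."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    x = vae.channel_input(stack)[None].astype(float)
    mu, logvar = vae.encode(vae._pool_flatten(x))
    return LatentFeatures(mu=mu[0], logvar=logvar[0], group=group)


@dataclass
class LatentFeatures:
    mu: np.ndarray
    logvar: np.ndarray
    group: str


@dataclass
class MriFeatureVector:
    values: np.ndarray
    names: list[str]
    groups: list[str]


def assemble_mri_features(pre: SliceStack, post: SliceStack, vae1: Vae, vae2: Vae,
                          augment_scalars: bool = False) -> MriFeatureVector:
    """Concatenate the four 48-dim latent blocks for one patient.

    Order: pre_lesion, post_lesion, pre_mask, post_mask (192 features). With
    ``augment_scalars`` four voxel-count summaries (pre/post core and edema
    areas within the window) are appended, giving 196.
    """
    if pre is None or post is None:
        raise ValueError("both pre- and postoperative stacks are required")
    blocks = [
        extract_latent(vae1, pre, "pre_lesion"),
        extract_latent(vae1, post, "post_lesion"),
        extract_latent(vae2, pre, "pre_mask"),
        extract_latent(vae2, post, "post_mask"),
    ]
    values = np.concatenate([b.mu for b in blocks])
    names, groups = [], []
    for b in blocks:
        names.extend(f"{b.group}_{i:02d}" for i in range(len(b.mu)))
        groups.extend([b.group] * len(b.mu))
    if augment_scalars:
        scalars = {
            "pre_core_area": pre.lesion[..., 0].sum(),
            "post_core_area": post.lesion[..., 0].sum(),
            "pre_edema_area": pre.lesion[..., 1].sum(),
            "post_edema_area": post.lesion[..., 1].sum(),
        }
        values = np.concatenate([values, np.array(list(scalars.values()), dtype=float)])
        for k in scalars:
            names.append(k)
            groups.append("pre_lesion" if k.startswith("pre") else "post_lesion")
    return MriFeatureVector(values=values, names=names, groups=groups)


# -- checkpointing --------------------------------------------------------

def save_checkpoint(vae: Vae, path) -> None:
    cfg = asdict(vae.config)
    arrays = {}
    for tag, stack in (("enc", vae.encoder), ("dec", vae.decoder)):
        for i, W in enumerate(stack.W):
            arrays[f"{tag}_W{i}"] = W
        for i, b in enumerate(stack.b):
            arrays[f"{tag}_b{i}"] = b
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> Vae:
    data = np.load(path, allow_pickle=False)
    cfg_d = json.loads(str(data["config"]))
    for key in ("input_shape", "pool", "hidden_widths"):
        cfg_d[key] = tuple(cfg_d[key])
    vae = Vae(VaeConfig(**cfg_d))
    for tag, stack in (("enc", vae.encoder), ("dec", vae.decoder)):
        for i in range(len(stack.W)):
            stack.W[i] = data[f"{tag}_W{i}"]
            stack.b[i] = data[f"{tag}_b{i}"]
    return vae
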