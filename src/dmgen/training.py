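"""Three-phase training of the hybrid VAE / WGAN-GP and sample generation.

Each batch runs, in order: (1) one encoder+decoder update minimizing
reconstruction + kld_weight * KLD; (2) n_critic critic updates, each on fresh
prior noise passed through the decoder, minimizing the Wasserstein critic
loss with gradient penalty; (3) one decoder update minimizing the adversarial
loss on fresh noise. The critic is untouched during phase 1 and the encoder
during phases 2-3.

A master seed derives independent per-epoch streams so runs reproduce
bit-for-bit in single-threaded mode.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .dataset import MatrixDataset, ScalerState, apply_scale, fit_scaler, invert_scale
from .losses import (
    generator_adversarial_loss,
    gradient_penalty,
    kld_loss,
    reconstruction_loss,
)
from .nets import Critic, Decoder, Encoder, ModelConfig, build_networks, reparameterize
from .nn import Adam, Tensor, no_grad


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    lambda_gp: float = 10.0
    n_critic: int = 5
    epochs: int = 100
    batch_size: int = 64
    #: None = automatic: 1 / input_side^2, which makes the VAE objective equal
    #: to the classical summed ELBO (pixel-sum reconstruction + KLD) up to a
    #: constant factor; a unit weight on a pixel-MEAN reconstruction would let
    #: the KLD dominate and collapse the latent code.
    kld_weight: float | None = None
    adv_weight: float = 1.0
    recon_loss_kind: str = "mse"
    seed: int = 0
    checkpoint_every: int = 10

    def __post_init__(self):
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        for name in ("learning_rate", "lambda_gp", "epochs", "batch_size",
                     "adv_weight", "checkpoint_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kld_weight is not None and self.kld_weight <= 0:
            raise ValueError("kld_weight must be positive (or None for automatic)")

    def resolve_kld_weight(self, input_side: int) -> float:
        if self.kld_weight is not None:
            return self.kld_weight
        return 1.0 / (input_side * input_side)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LossRecord:
    epoch: int
    reconstruction_loss: float
    kld_loss: float
    critic_loss: float
    generator_adv_loss: float

    def check_finite(self) -> "LossRecord":
        vals = [self.reconstruction_loss, self.kld_loss, self.critic_loss,
                self.generator_adv_loss]
        if not np.all(np.isfinite(vals)):
            raise RuntimeError(f"non-finite loss at epoch {self.epoch}: {vals}")
        return self


class TrainState:
    """Networks, optimizers and counters for one training run."""

    def __init__(self, model_config: ModelConfig, train_config: TrainConfig,
                 scaler: ScalerState):
        self.model_config = model_config
        self.train_config = train_config
        self.scaler = scaler
        self.encoder, self.decoder, self.critic = build_networks(model_config)
        betas = (train_config.adam_beta1, train_config.adam_beta2)
        lr = train_config.learning_rate
        self.enc_opt = Adam(self.encoder.parameters(), lr, betas)
        self.dec_opt = Adam(self.decoder.parameters(), lr, betas)
        self.cri_opt = Adam(self.critic.parameters(), lr, betas)
        self.update_counts = {"vae": 0, "critic": 0, "generator_adv": 0}


def _sample_latent(rng: np.random.Generator, batch: int, latent_dim: int) -> np.ndarray:
    return rng.standard_normal((batch, latent_dim))


def train_step(state: TrainState, batch: np.ndarray,
               rng: np.random.Generator) -> LossRecord:
    """One three-phase update on a scaled [0, 1] batch of shape (B, 1, S, S)."""
    cfg = state.train_config
    b = batch.shape[0]
    latent_dim = state.model_config.latent_dim

    # phase 1: VAE update (encoder + decoder)
    state.enc_opt.zero_grad()
    state.dec_opt.zero_grad()
    x = Tensor(batch)
    lat = state.encoder(x)
    z = reparameterize(lat, rng)
    x_hat = state.decoder(z)
    recon = reconstruction_loss(x, x_hat, cfg.recon_loss_kind)
    kld = kld_loss(lat)
    kw = cfg.resolve_kld_weight(state.model_config.input_side)
    (recon + kld * kw).backward()
    state.enc_opt.step()
    state.dec_opt.step()
    state.update_counts["vae"] += 1

    # phase 2: n_critic critic updates on fresh prior noise
    critic_losses = []
    for _ in range(cfg.n_critic):
        state.cri_opt.zero_grad()
        with no_grad():
            fake = state.decoder(Tensor(_sample_latent(rng, b, latent_dim))).data
        f_fake = state.critic(Tensor(fake))
        f_real = state.critic(x)
        wass = f_fake.mean() - f_real.mean()
        wass.backward()
        pen = gradient_penalty(state.critic, batch, fake, rng,
                               accumulate_param_grads=True,
                               lambda_gp=cfg.lambda_gp)
        state.cri_opt.step()
        critic_losses.append(float(wass.data) + cfg.lambda_gp * pen)
        state.update_counts["critic"] += 1

    # phase 3: one adversarial decoder update on fresh noise
    state.dec_opt.zero_grad()
    state.critic.zero_grad()
    fake = state.decoder(Tensor(_sample_latent(rng, b, latent_dim)))
    adv = generator_adversarial_loss(state.critic, fake)
    (adv * cfg.adv_weight).backward()
    state.dec_opt.step()
    state.critic.zero_grad()
    state.update_counts["generator_adv"] += 1

    return LossRecord(
        epoch=-1,
        reconstruction_loss=float(recon.data),
        kld_loss=float(kld.data),
        critic_loss=float(np.mean(critic_losses)),
        generator_adv_loss=float(adv.data),
    ).check_finite()


def train(dataset: MatrixDataset, model_config: ModelConfig,
          train_config: TrainConfig, out_dir: str | None = None,
          progress: bool = False) -> tuple[TrainState, pd.DataFrame]:
    """Train on a dataset of Å-scale matrices; returns state and loss table.

    Writes ``losses.csv`` and ``ckpt_epoch_*.h5`` under ``out_dir`` when given
    (checkpoints every ``checkpoint_every`` epochs and at the final epoch).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if dataset.n_residues != model_config.input_side:
        raise ValueError(
            f"dataset matrices are {dataset.n_residues}x{dataset.n_residues} but "
            f"model input_side is {model_config.input_side}")
    scaler = dataset.scaler or fit_scaler(dataset.matrices)
    scaled = apply_scale(dataset.matrices, scaler)[:, None, :, :]

    state = TrainState(model_config, train_config, scaler)
    master = np.random.SeedSequence(train_config.seed)
    records: list[LossRecord] = []
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    for epoch in range(1, train_config.epochs + 1):
        rng = np.random.default_rng(master.spawn(1)[0])
        order = rng.permutation(len(scaled))
        epoch_losses = []
        for start in range(0, len(scaled), train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            if len(idx) < 2:
                continue        # batch statistics need at least 2 samples
            epoch_losses.append(train_step(state, scaled[idx], rng))
        rec = LossRecord(
            epoch=epoch,
            reconstruction_loss=float(np.mean([r.reconstruction_loss for r in epoch_losses])),
            kld_loss=float(np.mean([r.kld_loss for r in epoch_losses])),
            critic_loss=float(np.mean([r.critic_loss for r in epoch_losses])),
            generator_adv_loss=float(np.mean([r.generator_adv_loss for r in epoch_losses])),
        ).check_finite()
        records.append(rec)
        if progress:
            print(f"epoch {epoch}: recon={rec.reconstruction_loss:.5f} "
                  f"kld={rec.kld_loss:.3f} critic={rec.critic_loss:.3f}", flush=True)
        if out_dir and (epoch % train_config.checkpoint_every == 0
                        or epoch == train_config.epochs):
            save_checkpoint(os.path.join(out_dir, f"ckpt_epoch_{epoch:04d}.h5"), state)
    table = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if out_dir:
        table.to_csv(os.path.join(out_dir, "losses.csv"), index=False)
    return state, table


def save_checkpoint(path, state: TrainState) -> None:
    """All network parameters plus model config and scaler, one HDF5 file."""
    with h5py.File(path, "w") as f:
        for group, net in (("encoder", state.encoder), ("decoder", state.decoder),
                           ("critic", state.critic)):
            g = f.create_group(group)
            for name, arr in net.state_dict().items():
                g.create_dataset(name, data=arr)
        f.attrs["model_config"] = json.dumps(state.model_config.to_dict())
        f.attrs["train_config"] = json.dumps(state.train_config.to_dict())
        f.attrs["max_distance"] = state.scaler.max_distance


def load_checkpoint(path) -> TrainState:
    with h5py.File(path, "r") as f:
        if "max_distance" not in f.attrs:
            raise ValueError(f"checkpoint {path!r} lacks the scaler state")
        model_config = ModelConfig.from_dict(json.loads(f.attrs["model_config"]))
        train_config = TrainConfig(**json.loads(f.attrs["train_config"]))
        scaler = ScalerState(float(f.attrs["max_distance"]))
        state = TrainState(model_config, train_config, scaler)
        for group, net in (("encoder", state.encoder), ("decoder", state.decoder),
                           ("critic", state.critic)):
            net.load_state_dict({k: np.asarray(v) for k, v in f[group].items()})
    return state


def generate(state_or_path, count: int, seed: int, batch_size: int = 64) -> np.ndarray:
    """Draw prior noise, decode, and invert scaling back to Å.

    Returns (count, N, N) matrices; no symmetrization is applied, so the
    asymmetry score measures a genuine model property. Deterministic per seed
    (for a fixed batch_size: batch normalization uses batch statistics at
    sampling time, since running averages of short runs are unrepresentative —
    a common practice for generators trained with batch normalization).
    """
    state = (state_or_path if isinstance(state_or_path, TrainState)
             else load_checkpoint(state_or_path))
    rng = np.random.default_rng(seed)
    state.decoder.train()
    outs = []
    with no_grad():
        for start in range(0, count, batch_size):
            b = min(batch_size, count - start)
            z = _sample_latent(rng, b, state.model_config.latent_dim)
            outs.append(state.decoder(Tensor(z)).data[:, 0])
    scaled = np.concatenate(outs, axis=0)
    return invert_scale(scaled, state.scaler)
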