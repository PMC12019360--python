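"""Encoder, decoder and critic networks for distance-matrix generation.

The reference configuration consumes 1 x 128 x 128 matrices scaled to [0, 1].
The encoder halves the spatial side four times (channels 32-64-128-256, 4x4
kernels, stride 2, padding 1) with optional residual blocks after the second
and third convolutions, then two parallel fully connected heads emit the
latent mean and log-variance (latent dimension 512). The decoder mirrors it
with transposed convolutions and residual blocks after its second and third
up-samplings; the final transposed convolution has no normalization and a
logistic output keeps values in [0, 1]. The critic ladder is 64-128-256-512
filters with strides 2, 2, 4, 2 (instance normalization on layers 2-4,
dropout on layers 1-4) followed by a valid convolution to one scalar.

All encoder/decoder convolutions use batch normalization and a leaky
rectifier; weights are drawn from N(0, 0.02), seeded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


class ConfigurationError(ValueError):
    """Architecture cannot be built for the requested input size."""


@dataclass(frozen=True)
class ModelConfig:
    input_side: int = 128
    latent_dim: int = 512
    use_residual_blocks: bool = True
    base_filters: int = 32          # encoder ladder starts here; critic at 2x
    leaky_slope: float = 0.2
    critic_dropout: float = 0.1
    init_seed: int = 0

    def __post_init__(self):
        s = self.input_side
        if s < 16 or (s & (s - 1)) != 0:
            raise ConfigurationError("input_side must be a power of two >= 16")
        if self.latent_dim < 1:
            raise ConfigurationError("latent_dim must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class GaussianLatent:
    """Latent posterior parameters: mean and log-variance, (batch, latent)."""

    mu: Tensor
    log_var: Tensor


class ResidualBlock(nn.Module):
    """conv-norm-activation-conv-norm, skip addition, then activation.

    Output spatial side and channel count equal the input's. With the two
    convolutions' weights zeroed the block reduces to the activation of its
    input (skip-path integrity).
    """

    def __init__(self, channels: int, slope: float, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, 1, 1, rng)
        self.bn1 = nn.BatchNorm2d(channels)
        self.act = nn.LeakyReLU(slope)
        self.conv2 = nn.Conv2d(channels, channels, 3, 1, 1, rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x):
        h = self.act(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        return self.act(x + h)


def _check_batch(x: Tensor | np.ndarray, side: int) -> Tensor:
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=np.float64))
    if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != side or x.shape[3] != side:
        raise ValueError(f"expected batch of shape (B, 1, {side}, {side}), got {x.shape}")
    return x


class Encoder(nn.Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        bf = config.base_filters
        s = config.leaky_slope
        layers = [
            nn.Conv2d(1, bf, 4, 2, 1, rng), nn.BatchNorm2d(bf), nn.LeakyReLU(s),
            nn.Conv2d(bf, 2 * bf, 4, 2, 1, rng), nn.BatchNorm2d(2 * bf), nn.LeakyReLU(s),
        ]
        if config.use_residual_blocks:
            layers.append(ResidualBlock(2 * bf, s, rng))
        layers += [nn.Conv2d(2 * bf, 4 * bf, 4, 2, 1, rng),
                   nn.BatchNorm2d(4 * bf), nn.LeakyReLU(s)]
        if config.use_residual_blocks:
            layers.append(ResidualBlock(4 * bf, s, rng))
        layers += [nn.Conv2d(4 * bf, 8 * bf, 4, 2, 1, rng),
                   nn.BatchNorm2d(8 * bf), nn.LeakyReLU(s)]
        self.ladder = nn.Sequential(*layers)
        self.feature_side = config.input_side // 16
        flat = 8 * bf * self.feature_side ** 2
        self.fc_mu = nn.Linear(flat, config.latent_dim, rng)
        self.fc_log_var = nn.Linear(flat, config.latent_dim, rng)
        # zero-initialized heads: the posterior starts exactly at the prior,
        # so the KLD rises from zero as the encoder learns to use the latent
        for head in (self.fc_mu, self.fc_log_var):
            head.weight.data[:] = 0.0

    def forward(self, x) -> GaussianLatent:
        x = _check_batch(x, self.config.input_side)
        h = self.ladder(x)
        h = h.reshape(h.shape[0], int(np.prod(h.shape[1:])))
        return GaussianLatent(self.fc_mu(h), self.fc_log_var(h))


class Decoder(nn.Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        bf = config.base_filters
        s = config.leaky_slope
        self.feature_side = config.input_side // 16
        self.fc = nn.Linear(config.latent_dim, 8 * bf * self.feature_side ** 2, rng)
        self.fc_bn = nn.BatchNorm2d(8 * bf)
        self.act = nn.LeakyReLU(s)
        layers = [
            nn.ConvTranspose2d(8 * bf, 4 * bf, 4, 2, 1, rng),
            nn.BatchNorm2d(4 * bf), nn.LeakyReLU(s),
            nn.ConvTranspose2d(4 * bf, 2 * bf, 4, 2, 1, rng),
            nn.BatchNorm2d(2 * bf), nn.LeakyReLU(s),
        ]
        if config.use_residual_blocks:
            layers.append(ResidualBlock(2 * bf, s, rng))
        layers += [nn.ConvTranspose2d(2 * bf, bf, 4, 2, 1, rng),
                   nn.BatchNorm2d(bf), nn.LeakyReLU(s)]
        if config.use_residual_blocks:
            layers.append(ResidualBlock(bf, s, rng))
        layers += [nn.ConvTranspose2d(bf, 1, 4, 2, 1, rng), nn.Sigmoid()]
        self.ladder = nn.Sequential(*layers)

    def forward(self, z) -> Tensor:
        if not isinstance(z, Tensor):
            z = Tensor(np.asarray(z, dtype=np.float64))
        if z.ndim != 2 or z.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"expected latent batch (B, {self.config.latent_dim}), got {z.shape}")
        h = self.fc(z)
        bf8 = 8 * self.config.base_filters
        h = h.reshape(z.shape[0], bf8, self.feature_side, self.feature_side)
        h = self.act(self.fc_bn(h))
        return self.ladder(h)


class Critic(nn.Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        bc = 2 * config.base_filters
        s = config.leaky_slope
        p = config.critic_dropout
        side = config.input_side
        strides = [2, 2, 4, 2]
        for st in strides:
            side = (side + 2 - 4) // st + 1
            if side < 1:
                raise ConfigurationError(
                    f"input side {config.input_side} too small for the critic ladder")
        self.final_kernel = min(4, side)
        if side - self.final_kernel < 0:
            raise ConfigurationError("critic final kernel does not fit")
        layers = [
            nn.Conv2d(1, bc, 4, 2, 1, rng), nn.LeakyReLU(s), nn.Dropout(p, rng),
            nn.Conv2d(bc, 2 * bc, 4, 2, 1, rng), nn.InstanceNorm2d(2 * bc),
            nn.LeakyReLU(s), nn.Dropout(p, rng),
            nn.Conv2d(2 * bc, 4 * bc, 4, 4, 1, rng), nn.InstanceNorm2d(4 * bc),
            nn.LeakyReLU(s), nn.Dropout(p, rng),
            nn.Conv2d(4 * bc, 8 * bc, 4, 2, 1, rng), nn.InstanceNorm2d(8 * bc),
            nn.LeakyReLU(s), nn.Dropout(p, rng),
            nn.Conv2d(8 * bc, 1, self.final_kernel, 1, 0, rng),
        ]
        self.ladder = nn.Sequential(*layers)

    def forward(self, x) -> Tensor:
        x = _check_batch(x, self.config.input_side)
        out = self.ladder(x)
        return out.mean(axis=(2, 3)).reshape(x.shape[0])


def build_networks(config: ModelConfig) -> tuple[Encoder, Decoder, Critic]:
    """Build the three networks with seeded N(0, 0.02) initialization."""
    rng = np.random.default_rng(config.init_seed)
    return Encoder(config, rng), Decoder(config, rng), Critic(config, rng)


def reparameterize(lat: GaussianLatent, seed_or_rng) -> Tensor:
    """z = mu + exp(log_var / 2) * eps with standard-normal eps, seeded."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    eps = rng.standard_normal(lat.mu.shape)
    return lat.mu + (lat.log_var * 0.5).exp() * Tensor(eps)


def encode(x, encoder: Encoder) -> GaussianLatent:
    return encoder(x)


def decode(z, decoder: Decoder) -> Tensor:
    return decoder(z)


def criticize(x, critic: Critic) -> Tensor:
    return critic(x)


def shape_trace(config: ModelConfig) -> dict:
    """Spatial sides and channel counts along each ladder, for conformance checks."""
    s = config.input_side
    bf = config.base_filters
    enc_sides, enc_channels = [], []
    side = s
    for ch in (bf, 2 * bf, 4 * bf, 8 * bf):
        side //= 2
        enc_sides.append(side)
        enc_channels.append(ch)
    bc = 2 * bf
    critic_sides = []
    side = s
    for st in (2, 2, 4, 2):
        side = (side + 2 - 4) // st + 1
        critic_sides.append(side)
    critic_sides.append(side - min(4, side) + 1)
    dec_sides = [s // 16 * (2 ** k) for k in range(1, 5)]
    return {
        "encoder_sides": enc_sides,
        "encoder_channels": enc_channels,
        "decoder_sides": dec_sides,
        "critic_sides": critic_sides,
        "critic_channels": [bc, 2 * bc, 4 * bc, 8 * bc, 1],
    }
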