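"""Training losses: VAE reconstruction + KLD, WGAN-GP critic and generator.

The critic loss is mean f(fake) - mean f(real) + lambda_gp * GP where GP is
the gradient penalty mean((||grad_x f(x~)||_2 - 1)^2) on per-sample uniform
interpolates x~ between real and fake batches.

The penalty's parameter gradient is a second-order quantity; it is computed
as a central-difference directional derivative: with g_b = grad_x f(x_b) and
v_b = (2/B) (||g_b|| - 1) g_b / ||g_b||, d(GP)/d(theta) equals
sum_b d/d(theta) [v_b . g_b], and v . grad_x f(x) is evaluated as
(f(x + a v) - f(x - a v)) / (2a), whose parameter gradient needs only two
ordinary backward passes. Dropout masks are frozen across the three critic
evaluations so all passes see the same network.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, freeze_dropout, no_grad
from .nets import GaussianLatent

_FD_STEP = 1e-4


def kld_loss(lat: GaussianLatent) -> Tensor:
    """Batch mean of KL(N(mu, sigma^2) || N(0, I)), summed over latent dims.

    Closed form: -1/2 sum_d (1 + log_var - mu^2 - exp(log_var)); always >= 0.
    """
    inner = (1.0 + lat.log_var - lat.mu * lat.mu - lat.log_var.exp()).sum(axis=1)
    return inner.sum() * (-0.5 / lat.mu.shape[0])


def reconstruction_loss(x, x_hat, kind: str = "mse") -> Tensor:
    """Reconstruction term between scaled batches; 0 iff x == x_hat.

    kind="mse": mean squared error (default). kind="bce": mean binary
    cross-entropy, applicable because both tensors live in [0, 1].
    """
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=np.float64))
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    if kind == "mse":
        return ((x - x_hat) ** 2.0).mean()
    if kind == "bce":
        eps = 1e-7
        xh = x_hat * (1 - 2 * eps) + eps
        return -(x * xh.log() + (1.0 - x) * (1.0 - xh).log()).mean()
    raise ValueError(f"unknown reconstruction loss kind {kind!r}")


def _input_gradient(critic, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample input gradient of the critic and its L2 norms.

    Parameter gradients are not touched: parameter tensors are temporarily
    flagged as not requiring gradients.
    """
    params = list(critic.parameters()) if hasattr(critic, "parameters") else []
    flags = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
    try:
        xt = Tensor(x, requires_grad=True)
        out = critic(xt)
        out.sum().backward()
        g = xt.grad if xt.grad is not None else np.zeros_like(x)
    finally:
        for p, f in zip(params, flags):
            p.requires_grad = f
    b = x.shape[0]
    norms = np.sqrt((g.reshape(b, -1) ** 2).sum(axis=1) + 1e-24)
    return g, norms


def gradient_penalty(critic, real, fake, seed_or_rng=0,
                     accumulate_param_grads: bool = False,
                     lambda_gp: float = 1.0) -> float:
    """WGAN-GP penalty mean((||grad_x f(x~)|| - 1)^2) on random interpolates.

    With ``accumulate_param_grads`` the lambda_gp-scaled parameter gradient of
    the penalty is added into the critic parameters' ``grad`` fields (used by
    the training step); the returned value is always the unscaled penalty.
    """
    real = np.asarray(real, dtype=np.float64)
    fake = np.asarray(fake, dtype=np.float64)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must have the same shape")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    b = real.shape[0]
    eps = rng.uniform(size=(b,) + (1,) * (real.ndim - 1))
    x = eps * real + (1.0 - eps) * fake

    freeze = hasattr(critic, "modules")
    if freeze:
        freeze_dropout(critic, False)   # draw fresh masks on the first pass
    g, norms = _input_gradient(critic, x)
    if freeze:
        freeze_dropout(critic, True)    # reuse those masks for the FD passes
    try:
        penalty = float(np.mean((norms - 1.0) ** 2))
        if accumulate_param_grads:
            v = (2.0 / b) * ((norms - 1.0) / norms).reshape((b,) + (1,) * (real.ndim - 1)) * g
            vmax = np.abs(v).max()
            alpha = _FD_STEP / (vmax + 1e-30)
            for sign in (1.0, -1.0):
                out = critic(Tensor(x + sign * alpha * v))
                scale = lambda_gp * sign / (2.0 * alpha)
                (out.sum() * scale).backward()
    finally:
        if freeze:
            freeze_dropout(critic, False)
    return penalty


def critic_loss(critic, real, fake, lambda_gp: float = 10.0, seed_or_rng=0) -> float:
    """mean f(fake) - mean f(real) + lambda_gp * gradient penalty (value only)."""
    with no_grad():
        fr = critic(Tensor(np.asarray(real, dtype=np.float64))).data.mean()
        ff = critic(Tensor(np.asarray(fake, dtype=np.float64))).data.mean()
    pen = gradient_penalty(critic, real, fake, seed_or_rng)
    return float(ff - fr + lambda_gp * pen)


def generator_adversarial_loss(critic, fake) -> Tensor:
    """-mean f(fake); minimized by the decoder in the adversarial phase."""
    if not isinstance(fake, Tensor):
        fake = Tensor(np.asarray(fake, dtype=np.float64))
    return -critic(fake).mean()
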