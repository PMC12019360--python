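"""Loss closed forms and gradient-penalty correctness."""

import numpy as np
import pytest

from dmgen import nn
from dmgen.losses import (
    critic_loss,
    generator_adversarial_loss,
    gradient_penalty,
    kld_loss,
    reconstruction_loss,
)
from dmgen.nets import GaussianLatent, ModelConfig, build_networks
from dmgen.nn import Tensor


class LinearCritic(nn.Module):
    """f(x) = w . x with ||w|| = gradient_norm everywhere."""

    def __init__(self, n_inputs, gradient_norm):
        super().__init__()
        w = np.full(n_inputs, gradient_norm / np.sqrt(n_inputs))
        self.weight = Tensor(w.reshape(n_inputs, 1), requires_grad=True)

    def forward(self, x):
        flat = x.reshape(x.shape[0], int(np.prod(x.shape[1:])))
        return (flat @ self.weight).reshape(x.shape[0])


class ConstantCritic(nn.Module):
    def __init__(self, value=0.0):
        super().__init__()
        self.value = value

    def forward(self, x):
        return Tensor(np.full(x.shape[0], self.value))


def latent(mu, log_var):
    return GaussianLatent(Tensor(np.atleast_2d(mu)), Tensor(np.atleast_2d(log_var)))


@pytest.mark.parametrize("mu,log_var,expected", [
    (0.0, 0.0, 0.0),
    (1.0, 0.0, 0.5),
    (0.0, np.log(4.0), 0.5 * (4 - np.log(4) - 1)),
])
def test_kld_closed_forms(mu, log_var, expected):
    assert np.isclose(kld_loss(latent([mu], [log_var])).data, expected)


def test_kld_nonnegative_and_batch_mean(rng):
    mu = rng.normal(size=(6, 4))
    lv = rng.normal(size=(6, 4))
    val = kld_loss(GaussianLatent(Tensor(mu), Tensor(lv))).data
    per_sample = (-0.5 * (1 + lv - mu ** 2 - np.exp(lv))).sum(axis=1)
    assert val >= 0.0
    assert np.isclose(val, per_sample.mean())


def test_reconstruction_loss_closed_forms(rng):
    x = rng.random((3, 1, 4, 4))
    assert reconstruction_loss(x, Tensor(x.copy())).data == 0.0
    assert np.isclose(
        reconstruction_loss(np.zeros((2, 4)), Tensor(np.full((2, 4), 0.5))).data,
        0.25)
    # permutation invariance of the batch mean
    perm = x[[2, 0, 1]]
    xh = rng.random((3, 1, 4, 4))
    assert np.isclose(reconstruction_loss(x, Tensor(xh)).data,
                      reconstruction_loss(perm, Tensor(xh[[2, 0, 1]])).data)
    with pytest.raises(ValueError):
        reconstruction_loss(x, Tensor(np.zeros((3, 1, 4, 5))))


def test_bce_reconstruction_positive_unless_equal(rng):
    x = (rng.random((2, 1, 4, 4)) > 0.5).astype(float)
    assert reconstruction_loss(x, Tensor(x * 0.999 + 0.0005), "bce").data < \
        reconstruction_loss(x, Tensor(np.full_like(x, 0.5)), "bce").data


@pytest.mark.parametrize("norm,expected", [(1.0, 0.0), (2.0, 1.0)])
def test_gradient_penalty_linear_critic(rng, norm, expected):
    real = rng.random((4, 1, 8, 8))
    fake = rng.random((4, 1, 8, 8))
    pen = gradient_penalty(LinearCritic(64, norm), real, fake, 0)
    assert np.isclose(pen, expected, atol=1e-9)


def test_gradient_penalty_constant_critic_and_lambda_weighting(rng):
    real = rng.random((4, 1, 8, 8))
    fake = rng.random((4, 1, 8, 8))
    assert np.isclose(gradient_penalty(ConstantCritic(), real, fake, 0), 1.0)
    # reference config: lambda_gp = 10 makes the weighted term 10
    assert np.isclose(critic_loss(ConstantCritic(), real, fake, 10.0, 0), 10.0)
    # gradient-norm-2 linear critic: weighted term lambda * (2 - 1)^2
    lc = LinearCritic(64, 2.0)
    loss = critic_loss(lc, real, real.copy(), 10.0, 0)
    assert np.isclose(loss, 10.0)


def test_critic_loss_cancels_for_identical_batches(rng):
    real = rng.random((4, 1, 8, 8))
    assert np.isclose(critic_loss(LinearCritic(64, 1.0), real, real.copy(), 10.0, 0),
                      0.0, atol=1e-9)


def test_critic_loss_decreases_after_one_gradient_step(rng):
    """One Adam step on separated point clouds lowers the critic loss."""
    cfg = ModelConfig(input_side=32, latent_dim=8, base_filters=4,
                      init_seed=0, critic_dropout=0.0)
    _, _, critic = build_networks(cfg)
    real = np.clip(rng.normal(0.8, 0.05, size=(8, 1, 32, 32)), 0, 1)
    fake = np.clip(rng.normal(0.2, 0.05, size=(8, 1, 32, 32)), 0, 1)
    opt = nn.Adam(critic.parameters(), lr=1e-3)

    def loss_value():
        return critic_loss(critic, real, fake, 10.0, 123)

    before = loss_value()
    opt.zero_grad()
    f_fake = critic(Tensor(fake))
    f_real = critic(Tensor(real))
    (f_fake.mean() - f_real.mean()).backward()
    gradient_penalty(critic, real, fake, 123, accumulate_param_grads=True,
                     lambda_gp=10.0)
    opt.step()
    assert loss_value() < before


def test_gp_parameter_gradients_match_numerical(rng):
    """Central-difference GP gradients agree with direct numerical ones."""
    cfg = ModelConfig(input_side=32, latent_dim=8, base_filters=4,
                      init_seed=0, critic_dropout=0.0)
    _, _, critic = build_networks(cfg)
    for p in critic.parameters():
        if p.data.ndim == 4:
            p.data = p.data * 12.0     # push gradient norms to O(1)
    real = rng.random((3, 1, 32, 32))
    fake = rng.random((3, 1, 32, 32))
    critic.zero_grad()
    gradient_penalty(critic, real, fake, 5, accumulate_param_grads=True)
    params = list(critic.parameters())
    check_rng = np.random.default_rng(1)
    checked = 0
    for _ in range(12):
        p = params[int(check_rng.integers(len(params)))]
        idx = tuple(int(check_rng.integers(s)) for s in p.data.shape)
        eps = 1e-6
        p.data[idx] += eps
        up = gradient_penalty(critic, real, fake, 5)
        p.data[idx] -= 2 * eps
        dn = gradient_penalty(critic, real, fake, 5)
        p.data[idx] += eps
        num = (up - dn) / (2 * eps)
        ana = p.grad[idx]
        if max(abs(num), abs(ana)) > 1e-3:
            assert abs(num - ana) / max(abs(num), abs(ana)) < 0.05
            checked += 1
    assert checked >= 3


def test_generator_adversarial_loss(rng):
    fake = rng.random((4, 1, 8, 8))
    assert generator_adversarial_loss(ConstantCritic(0.0), fake).data == 0.0
    assert generator_adversarial_loss(ConstantCritic(5.0), fake).data == -5.0


def test_generator_adv_gradient_is_negative_critic_gradient(rng):
    """d(-mean f)/d(fake) equals -(1/B) grad f, by finite differences."""
    critic = LinearCritic(16, 1.5)
    fake = Tensor(rng.random((2, 1, 4, 4)), requires_grad=True)
    loss = generator_adversarial_loss(critic, fake)
    loss.backward()
    g = fake.grad.copy()
    eps = 1e-6
    for idx in [(0, 0, 1, 2), (1, 0, 3, 0), (0, 0, 0, 0)]:
        fake.data[idx] += eps
        lp = generator_adversarial_loss(critic, Tensor(fake.data)).data
        fake.data[idx] -= 2 * eps
        lm = generator_adversarial_loss(critic, Tensor(fake.data)).data
        fake.data[idx] += eps
        assert np.isclose(g[idx], (lp - lm) / (2 * eps), atol=1e-8)
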