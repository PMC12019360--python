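"""Scikit-learn style estimator facade over the hybrid VAE / WGAN-GP.

``HybridVAEWGAN`` follows the sklearn estimator protocol (get_params /
set_params, fit, trailing-underscore fitted attributes) so it composes with
pipelines and model selection. ``fit`` consumes a stack of Å-scale distance
matrices, ``sample`` draws new matrices from the prior, ``transform`` maps
matrices to latent means and ``inverse_transform`` decodes latent vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dataset import MatrixDataset, apply_scale, fit_scaler, invert_scale
from .losses import reconstruction_loss
from .nets import ModelConfig
from .nn import Tensor, no_grad
from .training import TrainConfig, TrainState, generate, train


class HybridVAEWGAN(BaseEstimator):
    """Generative model of Cα distance matrices.

    A convolutional variational autoencoder provides probabilistic latent
    representations; a Wasserstein critic with gradient penalty sharpens the
    decoder's samples. Residual blocks in encoder and decoder are switchable
    for ablation.

    Parameters mirror the reference configuration: latent dimension 512,
    Adam(lr 1e-4, betas 0.5/0.999), gradient-penalty coefficient 10, five
    critic updates per generator update, batch size 64.
    """

    def __init__(self, latent_dim: int = 512, base_filters: int = 32,
                 use_residual_blocks: bool = True, leaky_slope: float = 0.2,
                 critic_dropout: float = 0.1, learning_rate: float = 1e-4,
                 adam_beta1: float = 0.5, adam_beta2: float = 0.999,
                 lambda_gp: float = 10.0, n_critic: int = 5, epochs: int = 100,
                 batch_size: int = 64, kld_weight: float | None = None,
                 adv_weight: float = 1.0, recon_loss_kind: str = "mse",
                 checkpoint_every: int = 10, random_state: int = 0):
        self.latent_dim = latent_dim
        self.base_filters = base_filters
        self.use_residual_blocks = use_residual_blocks
        self.leaky_slope = leaky_slope
        self.critic_dropout = critic_dropout
        self.learning_rate = learning_rate
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.lambda_gp = lambda_gp
        self.n_critic = n_critic
        self.epochs = epochs
        self.batch_size = batch_size
        self.kld_weight = kld_weight
        self.adv_weight = adv_weight
        self.recon_loss_kind = recon_loss_kind
        self.checkpoint_every = checkpoint_every
        self.random_state = random_state

    # -- config assembly ---------------------------------------------------
    def _model_config(self, input_side: int) -> ModelConfig:
        return ModelConfig(
            input_side=input_side, latent_dim=self.latent_dim,
            use_residual_blocks=self.use_residual_blocks,
            base_filters=self.base_filters, leaky_slope=self.leaky_slope,
            critic_dropout=self.critic_dropout, init_seed=self.random_state,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, adam_beta1=self.adam_beta1,
            adam_beta2=self.adam_beta2, lambda_gp=self.lambda_gp,
            n_critic=self.n_critic, epochs=self.epochs,
            batch_size=self.batch_size, kld_weight=self.kld_weight,
            adv_weight=self.adv_weight, recon_loss_kind=self.recon_loss_kind,
            seed=self.random_state, checkpoint_every=self.checkpoint_every,
        )

    @staticmethod
    def _as_stack(X) -> np.ndarray:
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
            raise ValueError("X must be a (n_samples, N, N) stack of matrices")
        if not np.all(np.isfinite(arr)) or arr.min() < 0:
            raise ValueError("distance matrices must be finite and nonnegative")
        return arr

    # -- estimator API -------------------------------------------------------
    def fit(self, X, y=None, out_dir: str | None = None):
        """Fit on (n_samples, N, N) Å-scale distance matrices."""
        arr = self._as_stack(X)
        dataset = MatrixDataset(arr, [f"sample_{i}" for i in range(len(arr))],
                                fit_scaler(arr))
        state, losses = train(dataset, self._model_config(arr.shape[1]),
                              self._train_config(), out_dir=out_dir)
        self.state_: TrainState = state
        self.scaler_ = state.scaler
        self.losses_: pd.DataFrame = losses
        self.input_side_ = arr.shape[1]
        self.n_features_in_ = arr.shape[1] * arr.shape[2]
        return self

    def sample(self, n_samples: int = 1, random_state: int | None = None) -> np.ndarray:
        """Generate (n_samples, N, N) matrices in Å from prior noise."""
        check_is_fitted(self, "state_")
        seed = self.random_state if random_state is None else random_state
        return generate(self.state_, n_samples, seed)

    def transform(self, X) -> np.ndarray:
        """Latent posterior means, shape (n_samples, latent_dim)."""
        check_is_fitted(self, "state_")
        arr = self._as_stack(X)
        scaled = apply_scale(arr, self.scaler_)[:, None]
        self.state_.encoder.eval()
        try:
            with no_grad():
                lat = self.state_.encoder(Tensor(scaled))
        finally:
            self.state_.encoder.train()
        return lat.mu.data.copy()

    def inverse_transform(self, Z) -> np.ndarray:
        """Decode latent vectors back to Å-scale matrices."""
        check_is_fitted(self, "state_")
        z = np.asarray(Z, dtype=np.float64)
        self.state_.decoder.eval()
        try:
            with no_grad():
                out = self.state_.decoder(Tensor(z)).data[:, 0]
        finally:
            self.state_.decoder.train()
        return invert_scale(out, self.scaler_)

    def score(self, X, y=None) -> float:
        """Negative mean-squared reconstruction error in scaled units."""
        check_is_fitted(self, "state_")
        arr = self._as_stack(X)
        scaled = apply_scale(arr, self.scaler_)[:, None]
        recon = self.inverse_transform(self.transform(arr))
        recon_scaled = apply_scale(recon, self.scaler_)[:, None]
        return -float(reconstruction_loss(scaled, Tensor(recon_scaled)).data)
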