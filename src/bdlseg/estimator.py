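"""Scikit-learn-style estimator facade over the U-Net trainer.

:class:`UNetSegmenter` exposes the segmentation model as a fit/predict
estimator so it composes with sklearn tooling (``get_params``/``set_params``,
``clone``, pipelines). ``X`` is an array of shape ``(n_cases, 4, S, S, S)``
(T1, contrast-enhanced T1, T2, FLAIR channels) and ``y`` an array of binary
masks ``(n_cases, S, S, S)``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import evaluate_case
from .network import NetworkConfig, predict_case
from .training import TrainConfig, train_model

__all__ = ["UNetSegmenter"]


class UNetSegmenter(BaseEstimator):
    """3D U-Net binary segmenter trained with a Dice-based loss.

    Parameters
    ----------
    base_filters, depth, leaky_slope : architecture hyperparameters (filters
        double per level; instance norm + leaky ReLU throughout).
    loss_mode : ``"soft-dice"`` or ``"bdl"`` (balanced Dice loss, which
        multiplies the loss of lesion-free cases by ``beta``).
    beta, epsilon : loss hyperparameters.
    initial_lr, lr_halving_period, max_epochs, batch_size : Adam schedule;
        the learning rate halves every ``lr_halving_period`` epochs.
    threshold : probability cut for :meth:`predict`.
    seed : controls weight initialization and batch shuffling.
    init_state : optional state dict for transfer learning.

    Attributes
    ----------
    model_ : the trained network.
    history_ : per-epoch training/validation losses and learning rates.
    input_size_ : cubic edge length inferred from the training data.
    """

    def __init__(
        self,
        base_filters: int = 8,
        depth: int = 3,
        leaky_slope: float = 0.01,
        loss_mode: str = "soft-dice",
        beta: float = 100.0,
        epsilon: float = 1e-5,
        initial_lr: float = 1e-4,
        lr_halving_period: int = 30,
        max_epochs: int = 50,
        batch_size: int = 4,
        threshold: float = 0.5,
        seed: int = 0,
        init_state: dict | None = None,
    ) -> None:
        self.base_filters = base_filters
        self.depth = depth
        self.leaky_slope = leaky_slope
        self.loss_mode = loss_mode
        self.beta = beta
        self.epsilon = epsilon
        self.initial_lr = initial_lr
        self.lr_halving_period = lr_halving_period
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.seed = seed
        self.init_state = init_state

    def _validate(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 5 or X.shape[1] != 4:
            raise ValueError(
                f"X must have shape (n_cases, 4, S, S, S), got {X.shape}"
            )
        if not (X.shape[2] == X.shape[3] == X.shape[4]):
            raise ValueError("volumes must be cubic")
        if y is not None:
            y = np.asarray(y)
            if y.shape != (X.shape[0],) + X.shape[2:]:
                raise ValueError(
                    f"y shape {y.shape} does not match X {X.shape}"
                )
            if not np.isin(np.unique(y), (0, 1)).all():
                raise ValueError("y must be binary masks")
        return X, y

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (volumes, masks); optional validation data feeds history_."""
        X, y = self._validate(X, y)
        size = X.shape[2]
        net_cfg = NetworkConfig(
            input_channels=4,
            base_filters=self.base_filters,
            depth=self.depth,
            leaky_slope=self.leaky_slope,
            input_size=size,
            seed=self.seed,
        )
        train_cfg = TrainConfig(
            initial_lr=self.initial_lr,
            lr_halving_period=self.lr_halving_period,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            loss_mode=self.loss_mode,
            beta=self.beta,
            epsilon=self.epsilon,
            seed=self.seed,
            init_weights=self.init_state,
        )
        cases = list(zip(X, y))
        val_cases = []
        if X_val is not None:
            X_val, y_val = self._validate(X_val, y_val)
            val_cases = list(zip(X_val, y_val))
        self.model_, self.history_ = train_model(
            cases, val_cases, net_cfg, train_cfg
        )
        self.input_size_ = size
        self.network_config_ = net_cfg
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-voxel foreground probabilities, shape (n_cases, S, S, S)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("UNetSegmenter is not fitted")
        X, _ = self._validate(X)
        return np.stack([predict_case(self.model_, v) for v in X])

    def predict(self, X) -> np.ndarray:
        """Binary masks obtained by thresholding the probability maps."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean Dice over cases (binarized at the estimator threshold)."""
        X, y = self._validate(X, y)
        proba = self.predict_proba(X)
        return float(
            np.mean(
                [evaluate_case(p, t, self.threshold).dice for p, t in zip(proba, y)]
            )
        )
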