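"""Scikit-learn style estimator facade.

``FractalSegmenter`` wraps the architecture builders and the training
pipeline as a ``fit``/``predict`` estimator so that model selection,
pipelines and cross-validation tooling from scikit-learn compose with
the segmentation models.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data_io import ImageSlice, SamplePair
from .metrics import BinaryMask, dice
from .models import ArchitectureConfig, build_model
from .pipeline import TrainConfig, predict_proba as _predict_proba, train as _train

__all__ = ["FractalSegmenter"]


class FractalSegmenter(BaseEstimator):
    """Binary semantic segmentation with a (fractal) U-Net.

    Parameters
    ----------
    architecture : {'unet', 'fractalspinet', 'att_fractalspinet', 'con_fractalunet'}
        Which encoder–decoder variant to build.
    stage_widths : tuple of int
        Channels per resolution level, length ``depth + 1``.
    fractal_order : int
        Expansion order C of the fractal blocks (2^C − 1 conv units each).
    dropout : float
        Dropout rate at the two deepest levels.
    epochs, batch_size, learning_rate : training regimen.
    validation_fraction : float
        Share of the training images held out for the per-epoch
        validation curve and best-checkpoint selection.
    threshold : float
        Probability cut for ``predict``.
    seed : int
        Seeds weight init, dropout, shuffling.

    Attributes
    ----------
    model_ : SegmentationModel
        The trained network (best-validation-loss parameters).
    history_ : TrainHistory
        Per-epoch loss/accuracy curves.
    n_parameters_ : int
        Trainable parameter count.
    """

    def __init__(
        self,
        architecture: str = "unet",
        depth: int = 3,
        stage_widths: tuple[int, ...] = (8, 16, 32, 64),
        fractal_order: int = 2,
        dropout: float = 0.5,
        epochs: int = 30,
        batch_size: int = 8,
        learning_rate: float = 0.001,
        validation_fraction: float = 0.1,
        threshold: float = 0.5,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.architecture = architecture
        self.depth = depth
        self.stage_widths = stage_widths
        self.fractal_order = fractal_order
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.seed = seed
        self.verbose = verbose

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_images(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4 and X.shape[-1] == 1:
            X = X[..., 0]
        if X.ndim != 3:
            raise ValueError(f"expected (n, H, W) images, got shape {X.shape}")
        return X

    def _to_pairs(self, X, y=None) -> list[SamplePair]:
        X = self._as_images(X)
        if y is None:
            y = np.zeros_like(X, dtype=np.uint8)
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"mask shape {y.shape} != image shape {X.shape}")
        yb = (y > 0.5).astype(np.uint8)
        return [
            SamplePair(
                image=ImageSlice(X[i], identifier=f"sample_{i:05d}"),
                csa_mask=BinaryMask(yb[i]),
                lesion_mask=BinaryMask(np.zeros_like(yb[i])),
            )
            for i in range(len(X))
        ]

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        """Train on images X (n, H, W) and binary masks y (n, H, W)."""
        X = self._as_images(X)
        h, w = X.shape[1:]
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ValueError(
                f"image size {h}x{w} must be divisible by 2^depth = {2 ** self.depth}"
            )
        cfg = ArchitectureConfig(
            arch_name=self.architecture,
            input_size=(h, w, 1),
            depth=self.depth,
            stage_widths=tuple(self.stage_widths),
            fractal_order=self.fractal_order,
            dropout_rate=self.dropout,
            attention=(self.architecture == "att_fractalspinet"),
            seed=self.seed,
        )
        model = build_model(cfg)
        pairs = self._to_pairs(X, y)
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(pairs))
        n_val = round(self.validation_fraction * len(pairs))
        val = [pairs[i] for i in order[:n_val]]
        tr = [pairs[i] for i in order[n_val:]]
        tc = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            dropout=self.dropout,
            seed=self.seed,
            target="csa",
        )
        history, best_state, _final = _train(model, tr, tc, val_pairs=val or None,
                                             verbose=self.verbose)
        model.load_state_dict(best_state)
        self.model_ = model
        self.history_ = history
        self.n_parameters_ = model.num_parameters()
        self.n_features_in_ = h * w
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel foreground probabilities, shape (n, H, W)."""
        check_is_fitted(self, "model_")
        pairs = self._to_pairs(X)
        return _predict_proba(self.model_, pairs, batch_size=self.batch_size)

    def predict(self, X) -> np.ndarray:
        """Binary masks (n, H, W) at the configured threshold."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean Dice similarity coefficient over the batch, in [0, 1]."""
        preds = self.predict(X)
        y = (np.asarray(y) > 0.5).astype(np.uint8)
        scores = [
            dice(BinaryMask(p), BinaryMask(t)) / 100.0 for p, t in zip(preds, y)
        ]
        return float(np.mean(scores))
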