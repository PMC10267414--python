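"""scikit-learn style estimator facade over the segmentation pipeline.

:class:`RetinalLayerSegmenter` wraps network construction, the training
loop, and prediction behind the familiar ``fit`` / ``predict`` /
``get_params`` surface, so the model composes with sklearn model selection
utilities.  X is an array of grayscale images ``(n_samples, H, W)`` with
values in [0, 1]; y is the matching stack of integer label masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dataio import AugmentationConfig
from .evaluation import confusion, compute_metrics
from .network import NetworkConfig
from .phantom import AnnotatedBScan
from .training import TrainConfig, train_fold


class RetinalLayerSegmenter(BaseEstimator):
    """Multi-scale attention segmentation network as an sklearn estimator.

    Parameters mirror the network and training configuration; all are
    plain constructor arguments so ``get_params`` / ``set_params`` and
    cloning work as usual.

    Attributes (after ``fit``)
    --------------------------
    model_ : the trained network (best-on-validation weights)
    state_ : per-epoch training history
    n_classes_ : number of classes
    """

    def __init__(self, n_classes=9, stage_widths=(16, 32, 64, 128),
                 stage_depths=(3, 3, 9, 3), attention_variant="de_cbam",
                 upsample_mode="bilinear", learning_rate=0.002,
                 max_epochs=300, batch_size=4, steplr_step=50,
                 steplr_gamma=0.5, val_fraction=0.2, augment=False,
                 random_state=0):
        self.n_classes = n_classes
        self.stage_widths = stage_widths
        self.stage_depths = stage_depths
        self.attention_variant = attention_variant
        self.upsample_mode = upsample_mode
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.steplr_step = steplr_step
        self.steplr_gamma = steplr_gamma
        self.val_fraction = val_fraction
        self.augment = augment
        self.random_state = random_state

    def _configs(self):
        net = NetworkConfig(n_classes=self.n_classes,
                            stage_widths=tuple(self.stage_widths),
                            stage_depths=tuple(self.stage_depths),
                            attention_variant=self.attention_variant,
                            upsample_mode=self.upsample_mode,
                            seed=self.random_state)
        aug = AugmentationConfig(seed=self.random_state) if self.augment else None
        train = TrainConfig(learning_rate=self.learning_rate,
                            max_epochs=self.max_epochs,
                            batch_size=self.batch_size,
                            steplr_step=self.steplr_step,
                            steplr_gamma=self.steplr_gamma,
                            seed=self.random_state,
                            augmentation=aug)
        return net, train

    @staticmethod
    def _to_samples(X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X must be (n, H, W) images with matching masks")
        return [AnnotatedBScan(image=img, mask=mask.astype(np.int64))
                for img, mask in zip(X, y)]

    def fit(self, X, y):
        """Train on image/mask stacks; an internal tail split of
        ``val_fraction`` drives best-epoch selection."""
        samples = self._to_samples(X, y)
        n_val = max(1, int(round(len(samples) * self.val_fraction)))
        if len(samples) - n_val < 1:
            raise ValueError("not enough samples for a train/val split")
        net_cfg, train_cfg = self._configs()
        self.model_, self.state_ = train_fold(samples[:-n_val], samples[-n_val:],
                                              net_cfg, train_cfg)
        self.n_classes_ = self.n_classes
        return self

    def predict(self, X):
        """Label masks, shape (n, H, W)."""
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        """Softmax class probabilities, shape (n, C, H, W)."""
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def score(self, X, y):
        """Mean foreground Dice pooled over the given images."""
        check_is_fitted(self, "model_")
        pred = self.predict(X)
        total = None
        for p, t in zip(pred, np.asarray(y)):
            c = confusion(p, t, self.n_classes)
            total = c if total is None else total + c
        fg = compute_metrics(total).dice[1:]
        fg = fg[~np.isnan(fg)]
        return float(fg.mean()) if fg.size else 0.0
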