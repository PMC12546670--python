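"""Scikit-learn style estimator wrapping the fusion network.

``MSIFusionClassifier`` follows the sklearn contract (``fit`` /
``predict`` / ``predict_proba`` / ``get_params`` / ``set_params``, fitted
attributes with trailing underscores) so it composes with pipelines and
model selection.  The multimodal design matrix ``X`` is a dict with keys
``'spectra'`` (N x L float) and/or ``'images'`` (N x 3 x H x W float32,
already normalized by :func:`msifusion.images.prepare_model_input`); a
``(spectra, images)`` tuple is also accepted.  Unimodal modes need only
their own key.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .model import ModelSpec, MSIFusionNet, SpectralBranchConfig, build_model
from .nn import autodiff as ad

__all__ = ["MSIFusionClassifier", "as_multimodal_X", "subset_X"]


def as_multimodal_X(X):
    """Normalize X to a dict with 'spectra'/'images' keys."""
    if isinstance(X, dict):
        out = dict(X)
    elif isinstance(X, (tuple, list)) and len(X) == 2:
        out = {"spectra": X[0], "images": X[1]}
    elif isinstance(X, np.ndarray):
        out = {"spectra": X} if X.ndim == 2 else {"images": X}
    else:
        raise ValueError("X must be a dict, a (spectra, images) pair, or an array")
    sizes = {k: len(v) for k, v in out.items() if v is not None}
    if len(set(sizes.values())) > 1:
        raise ValueError(f"unpaired modalities: sample counts differ ({sizes})")
    return out


def subset_X(X, idx):
    X = as_multimodal_X(X)
    return {k: (None if v is None else np.asarray(v)[idx]) for k, v in X.items()}


class MSIFusionClassifier(BaseEstimator, ClassifierMixin):
    """Two-branch spectral/image classifier with cross-modal attention.

    Parameters
    ----------
    mode : 'fusion' | 'spectral' | 'image'
        Which branches are active.
    attention : bool
        Branch attention (CBAM + SE) and cross-modal attention fusion on or
        off (the ablation axis).
    backbone : str
        Registered 2-D backbone name ('shufflenet_v2', 'vgg16', 'tiny').
    epochs, lr, batch_size
        Adam training schedule (defaults follow the full-scale protocol:
        200 epochs at learning rate 1e-4, batch 32).
    random_state : int
        Seeds weight initialization and batch shuffling; a fixed seed makes
        fit/predict bit-reproducible.
    """

    def __init__(self, mode="fusion", attention=True, backbone="shufflenet_v2",
                 epochs=200, lr=1e-4, batch_size=32, cma_scale="sqrt",
                 tie_shared_fc=True, random_state=None):
        self.mode = mode
        self.attention = attention
        self.backbone = backbone
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.cma_scale = cma_scale
        self.tie_shared_fc = tie_shared_fc
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _make_spec(self, input_length, num_classes):
        return ModelSpec(
            mode=self.mode, backbone=self.backbone, num_classes=num_classes,
            spectral=SpectralBranchConfig(input_length=input_length or 480),
            use_branch_attention=self.attention,
            use_cma=self.attention and self.mode == "fusion",
            cma_scale=self.cma_scale, tie_shared_fc=self.tie_shared_fc)

    def _batches(self, X, n, rng=None, shuffle=False):
        order = np.arange(n)
        if shuffle:
            rng.shuffle(order)
        for lo in range(0, n, self.batch_size):
            idx = order[lo:lo + self.batch_size]
            sp = X.get("spectra")
            im = X.get("images")
            yield idx, \
                None if sp is None else ad.Tensor(np.asarray(sp)[idx]), \
                None if im is None else ad.Tensor(np.asarray(im)[idx])

    def _check_X(self, X):
        X = as_multimodal_X(X)
        if self.mode in ("fusion", "spectral") and X.get("spectra") is None:
            raise ValueError(f"mode {self.mode!r} requires X['spectra']")
        if self.mode in ("fusion", "image") and X.get("images") is None:
            raise ValueError(f"mode {self.mode!r} requires X['images']")
        return X

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, init_weights=None, monitor=None):
        """Train with Adam on the cross-entropy loss.

        ``init_weights`` (a state dict) warm-starts the parameters, e.g.
        from the best cross-validation fold.  ``monitor=(X_mon, y_mon)``
        records held-out accuracy per epoch in ``history_`` without
        influencing training or selection.
        """
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n = len(y)
        L = None
        if X.get("spectra") is not None:
            X["spectra"] = np.asarray(X["spectra"], np.float32)
            L = X["spectra"].shape[1]
            self.n_features_in_ = L
        seed = 0 if self.random_state is None else int(self.random_state)
        spec = self._make_spec(L, len(self.classes_))
        self.model_ = build_model(spec, seed=seed)
        if init_weights is not None:
            self.model_.load_state_dict(init_weights)
        opt = nn.Adam(self.model_.parameters(), lr=self.lr)
        rng = np.random.default_rng(seed + 1)
        history = []
        for epoch in range(self.epochs):
            self.model_.train()
            losses, correct = [], 0
            for idx, sp, im in self._batches(X, n, rng, shuffle=True):
                logits = self.model_.forward_logits(sp, im)
                loss = nn.cross_entropy(logits, y_enc[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                correct += int((logits.data.argmax(1) == y_enc[idx]).sum())
            rec = {"epoch": epoch, "loss": float(np.mean(losses)),
                   "train_accuracy": correct / n}
            if monitor is not None:
                rec["monitor_accuracy"] = self.score(*monitor)
            history.append(rec)
        self.history_ = history
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = self._check_X(X)
        n = len(next(v for v in X.values() if v is not None))
        self.model_.eval()
        out = np.empty((n, len(self.classes_)), np.float64)
        for idx, sp, im in self._batches(X, n):
            out[idx] = self.model_.forward(sp, im).data
        return out

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def transform(self, X):
        """The 64-d fused (or branch) features, for embedding/visualization."""
        check_is_fitted(self, "model_")
        X = self._check_X(X)
        n = len(next(v for v in X.values() if v is not None))
        self.model_.eval()
        feats = []
        for _, sp, im in self._batches(X, n):
            feats.append(self.model_.features(sp, im))
        return np.concatenate(feats, axis=0)

    def get_weights(self):
        check_is_fitted(self, "model_")
        return self.model_.state_dict()
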