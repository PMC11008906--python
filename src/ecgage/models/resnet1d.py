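"""1-D residual convolutional age-group classifier, implemented in numpy.

The network is a one-dimensional residual convolutional classifier with a
single input channel: a strided convolutional stem, a stack of residual
blocks (basic two-convolution blocks, or 1-k-1 bottleneck blocks; with
``block="bottleneck"`` and ``n_blocks=16`` the stack reproduces the
50-convolution bottleneck arrangement), global average pooling and a
linear head.  Forward and backward passes are written explicitly, which
makes the input gradient — the saliency map substrate — directly
available.

Training follows the protocol used for the raw-signal path: AdamW with
decoupled weight decay, focal or cross-entropy loss with optional
inverse-frequency class weights, a reduce-on-plateau schedule dividing the
learning rate by 10 after 2 consecutive non-improving epochs, and early
stopping after 3 consecutive non-improving epochs.  Validation is
monitored at crop level when a validation set is supplied.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided
from sklearn.base import BaseEstimator, ClassifierMixin

from .losses import focal_loss, focal_loss_grad_logits


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Conv1d:
    """Same-padded 1-D convolution via im2col; stride >= 1."""

    def __init__(self, cin, cout, k, stride, rng):
        scale = np.sqrt(2.0 / (cin * k))
        self.W = rng.standard_normal((cout, cin, k)) * scale
        self.b = np.zeros(cout)
        self.k, self.stride = k, stride
        self.pad = k // 2

    def forward(self, x):
        n, c, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        L_out = (L + 2 * self.pad - self.k) // self.stride + 1
        s0, s1, s2 = xp.strides
        cols = as_strided(
            xp,
            shape=(n, c, L_out, self.k),
            strides=(s0, s1, s2 * self.stride, s2),
        )
        self._cols = cols
        self._in_shape = x.shape
        y = np.einsum("nclk,ock->nol", cols, self.W, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, dy):
        n, c, L = self._in_shape
        L_out = dy.shape[2]
        self.dW = np.einsum("nol,nclk->ock", dy, self._cols, optimize=True)
        self.db = dy.sum(axis=(0, 2))
        # gradient to input: scatter-add over kernel taps
        dxp = np.zeros((n, c, L + 2 * self.pad))
        dcols = np.einsum("nol,ock->nclk", dy, self.W, optimize=True)
        for ki in range(self.k):
            dxp[:, :, ki : ki + self.stride * L_out : self.stride] += dcols[:, :, :, ki]
        self._cols = None
        return dxp[:, :, self.pad : self.pad + L]

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _ResBlock:
    """Basic residual block: conv-relu-conv plus a (possibly projected) skip."""

    def __init__(self, cin, cout, k, stride, rng, bottleneck=False):
        self.bottleneck = bottleneck
        if bottleneck:
            cmid = max(1, cout // 4)
            self.convs = [
                _Conv1d(cin, cmid, 1, 1, rng),
                _Conv1d(cmid, cmid, k, stride, rng),
                _Conv1d(cmid, cout, 1, 1, rng),
            ]
        else:
            self.convs = [
                _Conv1d(cin, cout, k, stride, rng),
                _Conv1d(cout, cout, k, 1, rng),
            ]
        self.relus = [_ReLU() for _ in self.convs[:-1]]
        self.out_relu = _ReLU()
        self.proj = None
        if cin != cout or stride != 1:
            self.proj = _Conv1d(cin, cout, 1, stride, rng)

    def forward(self, x):
        h = x
        for conv, relu in zip(self.convs[:-1], self.relus):
            h = relu.forward(conv.forward(h))
        h = self.convs[-1].forward(h)
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.out_relu.forward(h + skip)

    def backward(self, dy):
        dy = self.out_relu.backward(dy)
        dskip = self.proj.backward(dy) if self.proj is not None else dy
        dh = self.convs[-1].backward(dy)
        for conv, relu in zip(reversed(self.convs[:-1]), reversed(self.relus)):
            dh = conv.backward(relu.backward(dh))
        return dh + dskip

    def modules(self):
        mods = list(self.convs)
        if self.proj is not None:
            mods.append(self.proj)
        return mods


class _Net:
    def __init__(self, n_classes, width, n_blocks, kernel_size, block, seed):
        rng = np.random.default_rng(seed)
        bottleneck = block == "bottleneck"
        self.stem = _Conv1d(1, width, 7, 2, rng)
        self.stem_relu = _ReLU()
        self.blocks = []
        cin = width
        for i in range(n_blocks):
            stride = 2 if i == 0 else 1
            self.blocks.append(_ResBlock(cin, width, kernel_size, stride, rng, bottleneck))
            cin = width
        self.Wd = rng.standard_normal((width, n_classes)) * np.sqrt(1.0 / width)
        self.bd = np.zeros(n_classes)

    def forward(self, x):
        h = self.stem_relu.forward(self.stem.forward(x))
        for blk in self.blocks:
            h = blk.forward(h)
        self._gap_len = h.shape[2]
        self._gap_in = h
        pooled = h.mean(axis=2)
        self._pooled = pooled
        return pooled @ self.Wd + self.bd

    def backward(self, dlogits):
        self.dWd = self._pooled.T @ dlogits
        self.dbd = dlogits.sum(axis=0)
        dpooled = dlogits @ self.Wd.T
        dh = np.repeat(dpooled[:, :, None], self._gap_len, axis=2) / self._gap_len
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        return self.stem.backward(self.stem_relu.backward(dh))

    def conv_modules(self):
        mods = [self.stem]
        for blk in self.blocks:
            mods.extend(blk.modules())
        return mods

    def parameters(self):
        """List of (array-holder, attr, grad-attr, decay) tuples."""
        out = []
        for m in self.conv_modules():
            out.append((m, "W", "dW", True))
            out.append((m, "b", "db", False))
        out.append((self, "Wd", "dWd", True))
        out.append((self, "bd", "dbd", False))
        return out


class _AdamW:
    def __init__(self, params, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(obj, name)) for obj, name, _, _ in params]
        self.v = [np.zeros_like(getattr(obj, name)) for obj, name, _, _ in params]

    def step(self):
        self.t += 1
        for i, (obj, name, gname, decay) in enumerate(self.params):
            g = getattr(obj, gname)
            w = getattr(obj, name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            w -= self.lr * mh / (np.sqrt(vh) + self.eps)
            if decay:
                w -= self.lr * self.wd * w


class RawSignalAgeClassifier(BaseEstimator, ClassifierMixin):
    """Residual 1-D convolutional classifier over fixed-length ECG crops.

    The compact default (``width=16, n_blocks=2, block="basic"``) is a
    width- and depth-reduced variant suitable for desk-scale experiments;
    ``block="bottleneck", n_blocks=16, width=64`` reproduces the full
    50-convolution arrangement.
    """

    def __init__(
        self,
        width: int = 16,
        n_blocks: int = 2,
        block: str = "basic",
        kernel_size: int = 3,
        loss: str = "focal",
        gamma: float = 2.0,
        learning_rate: float = 3e-3,
        weight_decay: float = 1e-2,
        batch_size: int = 32,
        epochs: int = 20,
        early_stop_patience: int = 3,
        plateau_patience: int = 2,
        class_weights: bool = True,
        seed: int = 0,
    ):
        self.width = width
        self.n_blocks = n_blocks
        self.block = block
        self.kernel_size = kernel_size
        self.loss = loss
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.early_stop_patience = early_stop_patience
        self.plateau_patience = plateau_patience
        self.class_weights = class_weights
        self.seed = seed

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._as_batch(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_to_idx[c] for c in y])
        if self.class_weights:
            counts = np.bincount(yi, minlength=len(self.classes_)).astype(float)
            w = 1.0 / counts
            self.class_weights_ = w / w.mean()
        else:
            self.class_weights_ = None
        gamma = self.gamma if self.loss == "focal" else 0.0

        rng = np.random.default_rng(self.seed)
        self.net_ = _Net(
            len(self.classes_), self.width, self.n_blocks, self.kernel_size,
            self.block, seed=int(rng.integers(2**31 - 1)),
        )
        opt = _AdamW(self.net_.parameters(), self.learning_rate, self.weight_decay)

        if X_val is not None:
            X_val = self._as_batch(X_val)
            yv = np.array([class_to_idx[c] for c in np.asarray(y_val)])

        self.training_log_ = []
        best = np.inf
        plateau_count = 0
        stop_count = 0
        n = len(X)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.net_.forward(X[idx])
                probs = _softmax(logits)
                losses.append(focal_loss(probs, yi[idx], gamma, self.class_weights_))
                dlogits = focal_loss_grad_logits(probs, yi[idx], gamma, self.class_weights_)
                self.net_.backward(dlogits)
                opt.step()
            train_loss = float(np.mean(losses))
            if X_val is not None:
                val_probs = self._forward_proba(X_val)
                monitored = focal_loss(val_probs, yv, gamma, self.class_weights_)
            else:
                monitored = train_loss
            self.training_log_.append(
                {"epoch": epoch, "train_loss": train_loss,
                 "monitored_loss": float(monitored), "lr": opt.lr}
            )
            if monitored < best - 1e-12:
                best = monitored
                plateau_count = 0
                stop_count = 0
            else:
                plateau_count += 1
                stop_count += 1
                if plateau_count >= self.plateau_patience:
                    opt.lr /= 10.0
                    plateau_count = 0
                if stop_count >= self.early_stop_patience:
                    break
        self.n_features_in_ = X.shape[2]
        return self

    # -------------------------------------------------------------- predict

    @staticmethod
    def _as_batch(X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, None, :]
        if X.ndim != 3 or X.shape[1] != 1:
            raise ValueError("expected (n_crops, crop_len) or (n_crops, 1, crop_len)")
        return X

    def _forward_proba(self, X, batch=256):
        out = []
        for start in range(0, len(X), batch):
            out.append(_softmax(self.net_.forward(X[start : start + batch])))
        return np.vstack(out)

    def predict_proba(self, X):
        return self._forward_proba(self._as_batch(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def input_gradient(self, X, target_class) -> np.ndarray:
        """Gradient of the target-class pre-softmax score w.r.t. the input,
        per crop.  ``target_class`` is a label or an array of labels."""
        X = self._as_batch(X)
        targets = np.broadcast_to(np.asarray(target_class), (len(X),))
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        ti = np.array([class_to_idx[t] for t in targets])
        grads = np.empty((len(X), X.shape[2]))
        batch = 256
        for start in range(0, len(X), batch):
            xb = X[start : start + batch]
            logits = self.net_.forward(xb)
            dlogits = np.zeros_like(logits)
            dlogits[np.arange(len(xb)), ti[start : start + batch]] = 1.0
            dx = self.net_.backward(dlogits)
            grads[start : start + batch] = dx[:, 0, :]
        return grads

    def randomized_copy(self, seed: int = 0) -> "RawSignalAgeClassifier":
        """Same architecture with freshly randomized weights (for attribution
        sanity checks)."""
        clone = RawSignalAgeClassifier(**self.get_params())
        clone.classes_ = self.classes_
        clone.net_ = _Net(
            len(self.classes_), self.width, self.n_blocks, self.kernel_size,
            self.block, seed=seed,
        )
        clone.training_log_ = []
        return clone


def predict_subject(model, crops: np.ndarray) -> np.ndarray:
    """Subject-level probability vector: arithmetic mean of per-crop
    probability vectors (>= 1 crop required)."""
    crops = np.asarray(crops, dtype=float)
    if len(crops) < 1:
        raise ValueError("need at least one crop")
    return model.predict_proba(crops).mean(axis=0)
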