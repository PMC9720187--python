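"""Small convolutional network for searchlight-image decoding.

The CNN stream classifies each n1 x n1 searchlight image directly instead
of a flattened vector.  The network is input -> convolution (3 x 3 kernel,
8 filters, padding preserving the n1 x n1 size) -> relu -> 2 x 2 max
pooling -> dense layer with one unit per class -> softmax.  It is written
directly on numpy, trains full-batch with Adam, and is fully seeded so runs
reproduce bit-for-bit on any CPU.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W) -> (N, H*W, k*k) patches under same-padding."""
    n, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    s = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    return s.reshape(n, h * w, k * k)


class ConvNetClassifier(BaseEstimator, ClassifierMixin):
    """Seeded numpy CNN matching the searchlight image geometry.

    Parameters
    ----------
    kernel_size : int
        Side of the square convolution kernel (same-padding), default 3.
    n_filters : int
        Convolution filters, default 8.
    epochs : int
        Full-batch Adam steps, default 150.
    lr : float
        Adam learning rate, default 0.01.
    random_state : int
        Seed for weight initialisation.
    """

    def __init__(self, kernel_size: int = 3, n_filters: int = 8,
                 epochs: int = 150, lr: float = 0.01, random_state: int = 0):
        self.kernel_size = kernel_size
        self.n_filters = n_filters
        self.epochs = epochs
        self.lr = lr
        self.random_state = random_state

    def fit(self, X, y):
        """Train on (N, n1, n1) images with integer class labels."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"expected (N, n1, n1) images, got shape {X.shape}")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("training labels contain a single class")
        n, n1, _ = X.shape
        k, f = self.kernel_size, self.n_filters
        pool = n1 // 2  # 2x2 max pool, stride 2, trailing row/col dropped
        rng = np.random.default_rng(self.random_state)

        W1 = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(k * k, f))
        b1 = np.zeros(f)
        W2 = rng.normal(0.0, np.sqrt(2.0 / (pool * pool * f)),
                        size=(pool * pool * f, n_classes))
        b2 = np.zeros(n_classes)
        params = [W1, b1, W2, b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        cols = _im2col(X, k)  # (n, n1*n1, k*k)
        onehot = np.eye(n_classes)[y_idx]
        for step in range(1, self.epochs + 1):
            # forward
            conv = cols @ W1 + b1                      # (n, n1*n1, f)
            conv = conv.reshape(n, n1, n1, f)
            relu = np.maximum(conv, 0.0)
            blocks = relu[:, :2 * pool, :2 * pool, :].reshape(
                n, pool, 2, pool, 2, f)
            pooled = blocks.max(axis=(2, 4))           # (n, pool, pool, f)
            flat = pooled.reshape(n, -1)
            logits = flat @ W2 + b2
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            # backward (mean cross-entropy)
            dlogits = (p - onehot) / n
            gW2 = flat.T @ dlogits
            gb2 = dlogits.sum(axis=0)
            dflat = dlogits @ W2.T
            dpooled = dflat.reshape(n, pool, pool, f)
            # route gradient to the argmax of each 2x2 block
            dblocks = np.zeros_like(blocks)
            mask = blocks == pooled[:, :, None, :, None, :]
            counts = mask.sum(axis=(2, 4), keepdims=True)
            dblocks = mask * (dpooled[:, :, None, :, None, :] / counts)
            drelu = np.zeros_like(relu)
            drelu[:, :2 * pool, :2 * pool, :] = dblocks.reshape(
                n, 2 * pool, 2 * pool, f)
            dconv = drelu * (conv > 0)
            dconv = dconv.reshape(n, n1 * n1, f)
            gW1 = np.einsum("npk,npf->kf", cols, dconv)
            gb1 = dconv.sum(axis=(0, 1))
            grads = [gW1, gb1, gW2, gb2]
            for i, (prm, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1 ** step)
                vhat = v[i] / (1 - beta2 ** step)
                prm -= self.lr * mhat / (np.sqrt(vhat) + eps)

        self.W1_, self.b1_, self.W2_, self.b2_ = params
        self.n1_ = n1
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        n, n1 = X.shape[0], self.n1_
        pool = n1 // 2
        cols = _im2col(X, self.kernel_size)
        conv = (cols @ self.W1_ + self.b1_).reshape(n, n1, n1, self.n_filters)
        relu = np.maximum(conv, 0.0)
        pooled = relu[:, :2 * pool, :2 * pool, :].reshape(
            n, pool, 2, pool, 2, self.n_filters).max(axis=(2, 4))
        return pooled.reshape(n, -1) @ self.W2_ + self.b2_

    def predict_proba(self, X):
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def cnn_decode(train_images, train_y, test_images, random_state: int = 0,
               **params) -> np.ndarray:
    """Train the CNN on one fold's images and predict the test fold."""
    clf = ConvNetClassifier(random_state=random_state, **params)
    clf.fit(train_images, train_y)
    return clf.predict(test_images)
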