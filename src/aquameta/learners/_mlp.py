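"""Minimal fully-connected network with manual backprop.

Kept dependency-free (numpy only) because the deployment environment has no
deep-learning framework.  Parameters live in a flat list of arrays, with
flatten/unflatten helpers so meta-learning code can treat the whole network
as a single parameter vector.
"""

from __future__ import annotations

import numpy as np

__all__ = ["init_params", "forward", "loss_grad", "flatten", "unflatten",
           "adam_train"]


def init_params(sizes: list[int], rng: np.random.Generator) -> list[np.ndarray]:
    """He-initialized weights/biases for layer sizes [n_in, h1, ..., n_out]."""
    params = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        params.append(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        params.append(np.zeros(n_out))
    return params


def forward(params: list[np.ndarray], X: np.ndarray) -> np.ndarray:
    a = X
    n_layers = len(params) // 2
    for layer in range(n_layers):
        W, b = params[2 * layer], params[2 * layer + 1]
        a = a @ W + b
        if layer < n_layers - 1:
            a = np.maximum(a, 0.0)
    return a


def loss_grad(params, X, Y, mask=None):
    """Mean squared error over observed entries and its parameter gradient.

    ``Y`` is (n, n_out); ``mask`` a boolean (n, n_out) array selecting the
    observed (row, output) pairs (all observed when None).
    """
    n_layers = len(params) // 2
    activations = [X]
    a = X
    for layer in range(n_layers):
        W, b = params[2 * layer], params[2 * layer + 1]
        z = a @ W + b
        a = np.maximum(z, 0.0) if layer < n_layers - 1 else z
        activations.append(a)
    pred = activations[-1]

    resid = pred - Y
    if mask is not None:
        resid = np.where(mask, resid, 0.0)
        n_obs = max(int(mask.sum()), 1)
    else:
        n_obs = resid.size
    loss = float(np.sum(resid ** 2) / n_obs)

    grads = [None] * len(params)
    delta = 2.0 * resid / n_obs
    for layer in range(n_layers - 1, -1, -1):
        a_prev = activations[layer]
        grads[2 * layer] = a_prev.T @ delta
        grads[2 * layer + 1] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ params[2 * layer].T) * (activations[layer] > 0)
    return loss, grads


def flatten(params: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([p.ravel() for p in params])


def unflatten(vec: np.ndarray, shapes: list[tuple]) -> list[np.ndarray]:
    out, i = [], 0
    for shape in shapes:
        size = int(np.prod(shape))
        out.append(vec[i:i + size].reshape(shape))
        i += size
    return out


def adam_train(params, X, Y, mask=None, *, epochs=200, batch_size=128, lr=1e-3,
               rng=None, X_val=None, Y_val=None, mask_val=None, patience=20,
               trainable=None):
    """Adam minibatch training; returns (params, history).

    ``trainable``: optional per-array booleans — frozen arrays keep their
    exact initial values (bitwise), used by head-only fine-tuning.
    Early stopping restores the best parameters seen on the validation set.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    params = [p.copy() for p in params]
    if trainable is None:
        trainable = [True] * len(params)
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = len(X)
    best_val = np.inf
    best_params = None
    bad_epochs = 0
    history = []

    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = loss_grad(params, X[idx], Y[idx],
                                    None if mask is None else mask[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("training loss diverged to non-finite value")
            t += 1
            for j, g in enumerate(grads):
                if not trainable[j]:
                    continue
                m[j] = beta1 * m[j] + (1 - beta1) * g
                v[j] = beta2 * v[j] + (1 - beta2) * g * g
                mhat = m[j] / (1 - beta1 ** t)
                vhat = v[j] / (1 - beta2 ** t)
                params[j] = params[j] - lr * mhat / (np.sqrt(vhat) + eps)
        if X_val is not None and len(X_val):
            val_loss, _ = loss_grad(params, X_val, Y_val, mask_val)
            history.append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = [p.copy() for p in params]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= patience:
                    break
    if best_params is not None:
        params = best_params
    return params, history
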