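"""Minimal dense neural network with explicit forward/backward passes.

Two gradient paths are exposed, because the package needs both:

* gradients with respect to the *weights*, for training the displacement
  surrogate;
* vector-Jacobian products with respect to the *inputs*, for the inverse
  estimators, which freeze the weights and optimise a subset of the inputs
  through the network.

Hidden activations are ``tanh`` so that input-gradients are smooth, which the
gradient-based estimators rely on.  All arithmetic is float64 NumPy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully connected ``n_in -> hidden... -> n_out`` network, tanh hidden units."""

    def __init__(self, layer_sizes: tuple[int, ...], seed: int | None = 0):
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output layer sizes")
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            # Xavier/Glorot scaling, appropriate for tanh units
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [np.asarray(p, dtype=float) for p in params[:n]]
        self.biases = [np.asarray(p, dtype=float) for p in params[n:]]

    def forward(self, x: np.ndarray, cache: bool = False):
        """Evaluate the network on a batch ``x`` of shape (n, n_in).

        With ``cache=True`` also returns the per-layer activations needed by
        the backward passes.  Arithmetic follows the dtype of the weights.
        """
        h = np.asarray(x, dtype=self.weights[0].dtype)
        acts = [h]
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w
            h += b
            if i < last:
                np.tanh(h, out=h)
            if cache:
                acts.append(h)
        return (h, acts) if cache else h

    def vjp_inputs(self, acts: list[np.ndarray], cotangent: np.ndarray) -> np.ndarray:
        """Backpropagate an output cotangent to the inputs.

        ``acts`` is the cache from ``forward(..., cache=True)``; the return
        value is ``cotangent @ J`` with ``J`` the (n, n_out, n_in) Jacobian,
        i.e. shape (n, n_in).  Weights are read, never written.
        """
        g = np.asarray(cotangent, dtype=self.weights[0].dtype)
        for i in range(len(self.weights) - 1, -1, -1):
            g = g @ self.weights[i].T
            if i > 0:
                g = g * (1.0 - acts[i] ** 2)
        return g

    def grads(self, acts: list[np.ndarray], cotangent: np.ndarray) -> list[np.ndarray]:
        """Parameter gradients (same layout as ``parameters``) for a summed
        scalar loss whose per-sample output gradient is ``cotangent``."""
        g = np.asarray(cotangent, dtype=self.weights[0].dtype)
        w_grads: list[np.ndarray] = [None] * len(self.weights)  # type: ignore
        b_grads: list[np.ndarray] = [None] * len(self.biases)   # type: ignore
        for i in range(len(self.weights) - 1, -1, -1):
            w_grads[i] = acts[i].T @ g
            b_grads[i] = g.sum(axis=0)
            if i > 0:
                g = (g @ self.weights[i].T) * (1.0 - acts[i] ** 2)
        return w_grads + b_grads

    def weight_hash(self) -> str:
        """Stable digest of all parameters; used to prove weight freezing."""
        import hashlib

        h = hashlib.sha256()
        for p in self.parameters:
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()


class Adam:
    """Adam optimiser over a list of arrays (or a single array)."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.single = isinstance(params, np.ndarray)
        plist = [params] if self.single else list(params)
        self.m = [np.zeros_like(p) for p in plist]
        self.v = [np.zeros_like(p) for p in plist]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr: float, mask=None):
        """One update in place.  ``mask`` (broadcastable boolean) freezes entries."""
        plist = [params] if self.single else list(params)
        glist = [grads] if self.single else list(grads)
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for i, (p, g) in enumerate(zip(plist, glist)):
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            update = lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)
            if mask is not None:
                update = np.where(mask, update, 0.0)
            p -= update
        return params
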