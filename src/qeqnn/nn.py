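"""Small feed-forward networks with hand-derived analytic gradients.

Each per-element network has two hidden tanh layers (15 nodes each by
default) and a linear output.  Besides the forward pass, the class provides

* ``input_grad`` -- the Jacobian dy/dx needed for analytic forces,
* ``vjp`` -- the gradient of ``sum(vy * y) + sum(Vg * dy/dx)`` with respect
  to the flattened parameters.  The second term is the mixed second
  derivative (double backprop) required when the training loss contains
  forces, which depend on dy/dx.

Everything is vectorized over samples; no autodiff framework is used.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

__all__ = ["MLP"]


class MLP:
    """d -> H1 -> H2 -> 1 network, tanh hidden activations, linear output."""

    def __init__(self, n_input: int, hidden: Tuple[int, int] = (15, 15), seed: int = 0):
        self.n_input = n_input
        self.hidden = tuple(hidden)
        self.seed = seed
        rng = np.random.default_rng(seed)
        h1, h2 = self.hidden
        # Xavier-style initialization
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(n_input), (n_input, h1))
        self.b1 = np.zeros(h1)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(h1), (h1, h2))
        self.b2 = np.zeros(h2)
        self.w3 = rng.normal(0.0, 1.0 / np.sqrt(h2), h2)
        self.b3 = 0.0

    # -- parameter flattening ---------------------------------------------
    @property
    def n_params(self) -> int:
        h1, h2 = self.hidden
        return self.n_input * h1 + h1 + h1 * h2 + h2 + h2 + 1

    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2, self.w3, [self.b3]]
        )

    def set_params(self, theta: np.ndarray) -> None:
        h1, h2 = self.hidden
        d = self.n_input
        ofs = 0
        self.W1 = theta[ofs : ofs + d * h1].reshape(d, h1).copy()
        ofs += d * h1
        self.b1 = theta[ofs : ofs + h1].copy()
        ofs += h1
        self.W2 = theta[ofs : ofs + h1 * h2].reshape(h1, h2).copy()
        ofs += h1 * h2
        self.b2 = theta[ofs : ofs + h2].copy()
        ofs += h2
        self.w3 = theta[ofs : ofs + h2].copy()
        ofs += h2
        self.b3 = float(theta[ofs])

    def copy(self) -> "MLP":
        new = MLP(self.n_input, self.hidden, self.seed)
        new.set_params(self.get_params())
        return new

    # -- evaluation ---------------------------------------------------------
    def _hidden_states(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        h1 = np.tanh(X @ self.W1 + self.b1)
        h2 = np.tanh(h1 @ self.W2 + self.b2)
        return h1, h2

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        _, h2 = self._hidden_states(X)
        return h2 @ self.w3 + self.b3

    def forward_with_input_grad(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Returns (y (n,), dy/dx (n, d))."""
        X = np.atleast_2d(X)
        h1, h2 = self._hidden_states(X)
        y = h2 @ self.w3 + self.b3
        s2 = (1.0 - h2 * h2) * self.w3  # (n, h2)
        s1 = (1.0 - h1 * h1) * (s2 @ self.W2.T)  # (n, h1)
        g = s1 @ self.W1.T  # (n, d)
        return y, g

    def input_grad(self, X: np.ndarray) -> np.ndarray:
        return self.forward_with_input_grad(X)[1]

    # -- gradients with respect to parameters -------------------------------
    def vjp(
        self,
        X: np.ndarray,
        vy: Optional[np.ndarray] = None,
        Vg: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Gradient of sum_n [vy_n y_n + Vg_n . (dy/dx)_n] w.r.t. parameters.

        ``vy`` has shape (n,) and ``Vg`` shape (n, d); either may be None.
        """
        X = np.atleast_2d(X)
        n = X.shape[0]
        h1, h2 = self._hidden_states(X)
        t1 = 1.0 - h1 * h1
        t2 = 1.0 - h2 * h2
        gW1 = np.zeros_like(self.W1)
        gb1 = np.zeros_like(self.b1)
        gW2 = np.zeros_like(self.W2)
        gb2 = np.zeros_like(self.b2)
        gw3 = np.zeros_like(self.w3)
        gb3 = 0.0

        if vy is not None:
            # plain backprop of sum vy*y
            gw3 += h2.T @ vy
            gb3 += float(vy.sum())
            d2 = (vy[:, None] * self.w3) * t2  # (n, h2)
            gW2 += h1.T @ d2
            gb2 += d2.sum(axis=0)
            d1 = (d2 @ self.W2.T) * t1
            gW1 += X.T @ d1
            gb1 += d1.sum(axis=0)

        if Vg is not None:
            # double backprop of sum Vg . dy/dx where
            # dy/dx = W1 [t1 o (W2 (t2 o w3))]
            s2 = t2 * self.w3  # (n, h2)
            W2s2 = s2 @ self.W2.T  # (n, h1)
            s1 = t1 * W2s2  # (n, h1)
            u1 = Vg @ self.W1  # (n, h1)
            a1 = u1 * t1  # (n, h1)
            u2 = a1 @ self.W2  # (n, h2)
            # explicit appearances
            gW1 += Vg.T @ s1
            gW2 += a1.T @ s2
            gw3 += (u2 * t2).sum(axis=0)
            # through h2: c2 = d(.)/dh2 = -2 u2 o h2 o w3
            c2 = -2.0 * u2 * h2 * self.w3
            d2 = c2 * t2
            gW2 += h1.T @ d2
            gb2 += d2.sum(axis=0)
            # through h1: two paths (a1 factor and z2)
            c1 = -2.0 * u1 * h1 * W2s2 + d2 @ self.W2.T
            d1 = c1 * t1
            gW1 += X.T @ d1
            gb1 += d1.sum(axis=0)

        return np.concatenate(
            [gW1.ravel(), gb1, gW2.ravel(), gb2, gw3, [gb3]]
        )
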