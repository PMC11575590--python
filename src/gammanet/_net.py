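"""Dense feed-forward networks on numpy with exact derivatives.

The Gibbs-excess model needs three capabilities that no single numpy routine
provides together:

* forward-mode (Taylor) propagation of first and second derivatives of the
  network output with respect to one input coordinate (the mole fraction) --
  used at prediction time for activity coefficients and for the Gibbs-Duhem
  checker;
* reverse-mode gradients of both the output *and* its first input-derivative
  with respect to every weight -- used during training, because the fitted
  observable (ln gamma) contains dg/dx1;
* a decoupled-weight-decay Adam update (AdamW).

All passes are batched: inputs are (n, d) arrays, derivatives are propagated
alongside values.  The SiLU activation is smooth, so every derivative used
here exists classically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import ShapeMismatch

__all__ = ["MLP", "AdamW", "silu", "silu_d1", "silu_d2"]


def silu(z: np.ndarray) -> np.ndarray:
    """SiLU (swish) activation x * sigmoid(x)."""
    return z * expit(z)


def silu_d1(z: np.ndarray) -> np.ndarray:
    """First derivative of SiLU: s + z*s*(1-s) with s = sigmoid(z)."""
    s = expit(z)
    return s * (1.0 + z * (1.0 - s))


def silu_d2(z: np.ndarray) -> np.ndarray:
    """Second derivative of SiLU: s(1-s) * (2 + z(1-2s))."""
    s = expit(z)
    return s * (1.0 - s) * (2.0 + z * (1.0 - 2.0 * s))


@dataclass
class MLP:
    """A fully connected network, SiLU on every layer except the last.

    ``weights[k]`` has shape (out_k, in_k); ``biases[k]`` shape (out_k,).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    # ------------------------------------------------------------------ setup

    @classmethod
    def create(cls, sizes: list[int], rng: np.random.Generator) -> "MLP":
        """Uniform fan-in initialization U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            weights.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
            biases.append(rng.uniform(-bound, bound, size=fan_out))
        return cls(weights, biases)

    @property
    def sizes(self) -> list[int]:
        return [self.weights[0].shape[1]] + [w.shape[0] for w in self.weights]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    def copy(self) -> "MLP":
        return MLP([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.weights[0].shape[1]:
            raise ShapeMismatch(
                f"expected input width {self.weights[0].shape[1]}, got {x.shape[1]}"
            )
        return x

    # --------------------------------------------------------------- forwards

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Plain value pass; x is (n, d_in), returns (n, d_out)."""
        a = self._check_input(x)
        last = self.n_layers - 1
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w.T + b
            a = z if k == last else silu(z)
        return a

    def forward2(
        self, x: np.ndarray, dx: np.ndarray, d2x: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Second-order forward mode along one scalar direction.

        ``dx``/``d2x`` are the first/second derivatives of the input with
        respect to the scalar of interest; returns (y, dy, d2y).
        """
        a = self._check_input(x)
        ad = np.broadcast_to(np.asarray(dx, dtype=float), a.shape).copy()
        ae = np.broadcast_to(np.asarray(d2x, dtype=float), a.shape).copy()
        last = self.n_layers - 1
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w.T + b
            zd = ad @ w.T
            ze = ae @ w.T
            if k == last:
                a, ad, ae = z, zd, ze
            else:
                f1 = silu_d1(z)
                a = silu(z)
                ae = silu_d2(z) * zd * zd + f1 * ze
                ad = f1 * zd
        return a, ad, ae

    def forward_tape(
        self, x: np.ndarray, dx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, list]:
        """First-order dual pass recording a tape for :meth:`backward_tape`."""
        a = self._check_input(x)
        ad = np.broadcast_to(np.asarray(dx, dtype=float), a.shape).copy()
        last = self.n_layers - 1
        tape = []
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w.T + b
            zd = ad @ w.T
            tape.append((a, ad, z, zd))
            if k == last:
                a, ad = z, zd
            else:
                f1 = silu_d1(z)
                a = silu(z)
                ad = f1 * zd

        return a, ad, tape

    def backward_tape(
        self, tape: list, gy: np.ndarray, gdy: np.ndarray
    ) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
        """Reverse pass through a taped dual forward.

        ``gy``/``gdy`` are adjoints of the output value and of its first
        x-derivative.  Returns (param_grads in :meth:`parameters` order,
        input value adjoint, input derivative adjoint).
        """
        last = self.n_layers - 1
        g_v = np.asarray(gy, dtype=float)
        g_d = np.asarray(gdy, dtype=float)
        grads: list[np.ndarray] = [None] * (2 * self.n_layers)
        for k in range(last, -1, -1):
            a, ad, z, zd = tape[k]
            if k == last:
                gz_v, gz_d = g_v, g_d
            else:
                f1 = silu_d1(z)
                gz_v = g_v * f1 + g_d * silu_d2(z) * zd
                gz_d = g_d * f1
            grads[2 * k] = gz_v.T @ a + gz_d.T @ ad
            grads[2 * k + 1] = gz_v.sum(axis=0)
            w = self.weights[k]
            g_v = gz_v @ w
            g_d = gz_d @ w
        return grads, g_v, g_d

    # ------------------------------------------------------------ persistence

    def to_dict(self) -> dict:
        return {
            "sizes": self.sizes,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        return cls(
            [np.asarray(w, dtype=float) for w in d["weights"]],
            [np.asarray(b, dtype=float) for b in d["biases"]],
        )


@dataclass
class AdamW:
    """Adam with decoupled weight decay, applied to a flat parameter list.

    The decay term is subtracted directly from the parameters (``w -= lr *
    weight_decay * w``) rather than added to the gradient, which is the
    behaviour that distinguishes AdamW from L2-regularised Adam.
    """

    params: list[np.ndarray]
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.01
    _m: list[np.ndarray] = field(default_factory=list)
    _v: list[np.ndarray] = field(default_factory=list)
    _t: int = 0

    def __post_init__(self) -> None:
        self._m = [np.zeros_like(p) for p in self.params]
        self._v = [np.zeros_like(p) for p in self.params]

    def step(self, grads: list[np.ndarray]) -> None:
        b1, b2 = self.betas
        self._t += 1
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, g, m, v in zip(self.params, grads, self._m, self._v):
            p -= self.lr * self.weight_decay * p
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
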