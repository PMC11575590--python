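"""The hard-constraint Gibbs-excess network.

The model maps two component embeddings E1, E2, a temperature T and a mole
fraction x1 to the molar Gibbs excess energy of the binary liquid mixture:

    g^E(x1, T) = x1*(1-x1) * d_cos(f_theta(E1), f_theta(E2)) * R * T * g_NN

where

* ``f_theta`` (one hidden layer) refines each standardized raw embedding to a
  compact component embedding h_i;
* ``d_cos`` is the cosine distance between h_1 and h_2 -- zero when the two
  components are identical, which pins g^E of a pseudo-binary mixture of a
  component with itself to zero for *any* network weights;
* ``g_NN = f_phi(f_alpha(c_1) + f_alpha(c_2))`` is a deep set over the two
  refined embeddings c_i = concat(h_i, T*, x_i), each stream carrying its own
  mole fraction (x1 and 1-x1), so the sum aggregation makes g^E exactly
  permutation invariant;
* the prefactor x1*(1-x1) pins g^E to zero at both pure-component limits.

Activity coefficients follow by exact differentiation of g^E in the thermo
module; because they are derivatives of one smooth scalar function, they
satisfy the Gibbs-Duhem equation by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._net import MLP
from .embeddings import ComponentRecord, ScalerSet
from .errors import NonFiniteDerivative, ShapeMismatch, ZeroVector

__all__ = [
    "GAS_CONSTANT",
    "MixtureQuery",
    "GibbsExcessNet",
    "cosine_distance",
    "NeuralGeFunction",
]

#: Ideal gas constant, J/(mol K).
GAS_CONSTANT = 8.31446

_NORM_EPS = 1e-12


@dataclass(frozen=True)
class MixtureQuery:
    """One state point: an ordered component pair, T (K) and x1.

    Pressure is deliberately absent -- its influence on liquid-phase activity
    coefficients is small and is neglected by the model.
    """

    comp1: ComponentRecord
    comp2: ComponentRecord
    T: float
    x1: float

    def __post_init__(self):
        if not 0.0 <= self.x1 <= 1.0:
            raise ValueError(f"x1 must lie in [0, 1], got {self.x1}")
        if self.T <= 0:
            raise ValueError(f"T must be positive (Kelvin), got {self.T}")

    def swapped(self) -> "MixtureQuery":
        return MixtureQuery(self.comp2, self.comp1, self.T, 1.0 - self.x1)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """d = 1 - u.v/(|u||v|); 0 for identical, 1 orthogonal, 2 antipodal.

    Raises :class:`ZeroVector` if either norm is below 1e-12: a zero
    component embedding is a pathological parameterization, not a mixture.
    Bitwise-identical inputs return exactly 0.0.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < _NORM_EPS or nv < _NORM_EPS:
        raise ZeroVector("cosine distance undefined for (near-)zero vector")
    if u.shape == v.shape and np.array_equal(u, v):
        return 0.0
    cos = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(1.0 - cos)


@dataclass
class GibbsExcessNet:
    """All parameters of the hard-constraint model plus its fitted scalers.

    Network shapes, with D the raw embedding width and H the hidden width
    (default 96):

    * theta: D -> H -> H (one hidden layer)
    * alpha: H+2 -> H -> H -> H (two hidden layers; +2 for T* and x_i)
    * phi:   H -> H -> 1 (one hidden layer)

    Activation is SiLU everywhere except the output layers.
    """

    theta: MLP
    alpha: MLP
    phi: MLP
    scalers: ScalerSet
    backend_id: str = "unspecified"
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        h = self.theta.sizes[-1]
        if self.alpha.sizes[0] != h + 2:
            raise ShapeMismatch(
                f"alpha input width {self.alpha.sizes[0]} != theta output {h} + 2"
            )
        if self.phi.sizes[-1] != 1:
            raise ShapeMismatch("phi output must be scalar")

    # ---------------------------------------------------------------- setup

    @classmethod
    def create(
        cls,
        embedding_dim: int = 384,
        hidden: int = 96,
        scalers: ScalerSet | None = None,
        backend_id: str = "unspecified",
        seed: int = 0,
        config: dict | None = None,
    ) -> "GibbsExcessNet":
        rng = np.random.default_rng(seed)
        return cls(
            theta=MLP.create([embedding_dim, hidden, hidden], rng),
            alpha=MLP.create([hidden + 2, hidden, hidden, hidden], rng),
            phi=MLP.create([hidden, hidden, 1], rng),
            scalers=scalers or ScalerSet.identity(embedding_dim),
            backend_id=backend_id,
            config=dict(config or {}),
        )

    @property
    def hidden(self) -> int:
        return self.theta.sizes[-1]

    @property
    def embedding_dim(self) -> int:
        return self.theta.sizes[0]

    def parameters(self) -> list[np.ndarray]:
        return self.theta.parameters() + self.alpha.parameters() + self.phi.parameters()

    def copy(self) -> "GibbsExcessNet":
        return GibbsExcessNet(
            self.theta.copy(),
            self.alpha.copy(),
            self.phi.copy(),
            self.scalers,
            self.backend_id,
            dict(self.config),
        )

    # ------------------------------------------------------- building blocks

    def theta_embed(self, E: np.ndarray) -> np.ndarray:
        """f_theta applied to the standardized raw embedding(s)."""
        z = self.scalers.transform_embedding(np.atleast_2d(np.asarray(E, dtype=float)))
        return self.theta.forward(z)

    def mixture_embedding(self, c1_in: np.ndarray, c2_in: np.ndarray) -> np.ndarray:
        """C_mix = f_alpha(c1) + f_alpha(c2); symmetric under input exchange
        by commutativity of the two-term sum."""
        return self.alpha.forward(c1_in) + self.alpha.forward(c2_in)

    # ---------------------------------------------------------- the forward

    def _prepare(self, E1, E2, T, x1):
        E1 = np.atleast_2d(np.asarray(E1, dtype=float))
        E2 = np.atleast_2d(np.asarray(E2, dtype=float))
        T = np.broadcast_to(np.asarray(T, dtype=float).ravel(), (max(E1.shape[0], 1),))
        x1 = np.asarray(x1, dtype=float).ravel()
        if E1.shape != E2.shape:
            raise ShapeMismatch("E1 and E2 must have identical shapes")
        if x1.shape[0] != E1.shape[0]:
            if x1.shape[0] == 1:
                x1 = np.broadcast_to(x1, (E1.shape[0],)).copy()
            else:
                raise ShapeMismatch("x1 length must match number of rows")
        return E1, E2, np.asarray(T, dtype=float), x1

    def _cosine_batch(self, h1: np.ndarray, h2: np.ndarray, same: np.ndarray):
        """Row-wise cosine distance with the identical-component shortcut.

        ``same`` marks rows whose *raw* embeddings are bitwise equal; those
        get d = 0 exactly (the analytic gradient there is 0 as well).
        """
        n1 = np.linalg.norm(h1, axis=1)
        n2 = np.linalg.norm(h2, axis=1)
        if np.any(n1 < _NORM_EPS) or np.any(n2 < _NORM_EPS):
            raise ZeroVector("f_theta produced a (near-)zero component embedding")
        cos = np.clip(np.sum(h1 * h2, axis=1) / (n1 * n2), -1.0, 1.0)
        d = 1.0 - cos
        d[same] = 0.0
        return d, cos, n1, n2

    def ge_bar_derivatives(self, E1, E2, T, x1):
        """Dimensionless g^E/(RT) and its first two x1-derivatives.

        All arguments broadcast row-wise; returns three (n,) arrays.  This is
        the exact-differentiation path (second-order forward mode), used for
        activity coefficients and the Gibbs-Duhem checker alike.
        """
        E1, E2, T, x1 = self._prepare(E1, E2, T, x1)
        n = E1.shape[0]
        same = np.all(E1 == E2, axis=1)

        z = self.scalers.transform_embedding(np.vstack([E1, E2]))
        h = self.theta.forward(z)
        h1, h2 = h[:n], h[n:]
        d, _, _, _ = self._cosine_batch(h1, h2, same)

        ts = np.broadcast_to(self.scalers.transform_temperature(T), (n,))
        c1 = np.column_stack([h1, ts, x1])
        c2 = np.column_stack([h2, ts, 1.0 - x1])
        width = c1.shape[1]
        dc1 = np.zeros(width)
        dc1[-1] = 1.0
        dc2 = np.zeros(width)
        dc2[-1] = -1.0

        a1, a1d, a1e = self.alpha.forward2(c1, dc1, 0.0)
        a2, a2d, a2e = self.alpha.forward2(c2, dc2, 0.0)
        nn, nnd, nne = self.phi.forward2(a1 + a2, a1d + a2d, a1e + a2e)
        nn, nnd, nne = nn[:, 0], nnd[:, 0], nne[:, 0]

        q = x1 * (1.0 - x1)
        qp = 1.0 - 2.0 * x1
        g = q * d * nn
        g1 = d * (qp * nn + q * nnd)
        g2 = d * (-2.0 * nn + 2.0 * qp * nnd + q * nne)
        if not (np.all(np.isfinite(g)) and np.all(np.isfinite(g1)) and np.all(np.isfinite(g2))):
            raise NonFiniteDerivative("non-finite g^E or derivative")
        return g, g1, g2

    def g_excess_nn(self, query: MixtureQuery) -> float:
        """The unconstrained scalar g_NN = f_phi(C_mix) for one query."""
        E1, E2, T, x1 = self._prepare(
            query.comp1.embedding, query.comp2.embedding, query.T, query.x1
        )
        z = self.scalers.transform_embedding(np.vstack([E1, E2]))
        h = self.theta.forward(z)
        ts = np.broadcast_to(self.scalers.transform_temperature(T), (1,))
        c1 = np.column_stack([h[:1], ts, x1])
        c2 = np.column_stack([h[1:], ts, 1.0 - x1])
        return float(self.phi.forward(self.mixture_embedding(c1, c2))[0, 0])

    def g_excess(self, query: MixtureQuery) -> float:
        """Molar Gibbs excess energy in J/mol at one state point."""
        g, _, _ = self.ge_bar_derivatives(
            query.comp1.embedding, query.comp2.embedding, query.T, query.x1
        )
        return float(g[0] * GAS_CONSTANT * query.T)

    def ln_gamma(self, E1, E2, T, x1):
        """(ln gamma_1, ln gamma_2) arrays from exact differentiation."""
        _, _, T_, x1_ = self._prepare(E1, E2, T, x1)
        g, g1, _ = self.ge_bar_derivatives(E1, E2, T, x1)
        return g + (1.0 - x1_) * g1, g - x1_ * g1

    def ge_function(self, comp1: ComponentRecord, comp2: ComponentRecord) -> "NeuralGeFunction":
        """Bind a component pair into a (x1, T) -> g^E/(RT) callable that the
        thermo module's checkers accept."""
        return NeuralGeFunction(self, comp1, comp2)

    # ---------------------------------------------- training forward/backward

    def forward_training(self, E1, E2, T, x1) -> dict:
        """Taped forward pass returning ln gamma and everything the backward
        pass needs.  Used only by the training loop."""
        E1, E2, T, x1 = self._prepare(E1, E2, T, x1)
        n = E1.shape[0]
        same = np.all(E1 == E2, axis=1)

        z = self.scalers.transform_embedding(np.vstack([E1, E2]))
        h, _, theta_tape = self.theta.forward_tape(z, 0.0)
        h1, h2 = h[:n], h[n:]
        d, cos, n1, n2 = self._cosine_batch(h1, h2, same)

        ts = np.broadcast_to(self.scalers.transform_temperature(T), (n,))
        c = np.vstack(
            [np.column_stack([h1, ts, x1]), np.column_stack([h2, ts, 1.0 - x1])]
        )
        dc = np.zeros_like(c)
        dc[:n, -1] = 1.0
        dc[n:, -1] = -1.0
        a, ad, alpha_tape = self.alpha.forward_tape(c, dc)
        cmix = a[:n] + a[n:]
        cmixd = ad[:n] + ad[n:]
        nn, nnd, phi_tape = self.phi.forward_tape(cmix, cmixd)
        nn, nnd = nn[:, 0], nnd[:, 0]

        q = x1 * (1.0 - x1)
        qp = 1.0 - 2.0 * x1
        g = q * d * nn
        g1 = d * (qp * nn + q * nnd)
        return {
            "n": n,
            "x1": x1,
            "q": q,
            "qp": qp,
            "d": d,
            "cos": cos,
            "norm1": n1,
            "norm2": n2,
            "h1": h1,
            "h2": h2,
            "same": same,
            "nn": nn,
            "nnd": nnd,
            "theta_tape": theta_tape,
            "alpha_tape": alpha_tape,
            "phi_tape": phi_tape,
            "ln_gamma_1": g + (1.0 - x1) * g1,
            "ln_gamma_2": g - x1 * g1,
        }

    def backward_training(self, cache: dict, g_ln1, g_ln2) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter, given the loss
        adjoints of ln gamma_1 and ln gamma_2 (arrays of shape (n,))."""
        n = cache["n"]
        x1, q, qp = cache["x1"], cache["q"], cache["qp"]
        d, nn, nnd = cache["d"], cache["nn"], cache["nnd"]

        g_g = np.asarray(g_ln1) + np.asarray(g_ln2)
        g_g1 = np.asarray(g_ln1) * (1.0 - x1) - np.asarray(g_ln2) * x1

        g_nn = (g_g * q + g_g1 * qp) * d
        g_nnd = g_g1 * q * d
        g_d = g_g * q * nn + g_g1 * (qp * nn + q * nnd)

        phi_grads, g_cmix, g_cmixd = self.phi.backward_tape(
            cache["phi_tape"], g_nn[:, None], g_nnd[:, None]
        )
        alpha_grads, g_c, _ = self.alpha.backward_tape(
            cache["alpha_tape"], np.vstack([g_cmix, g_cmix]), np.vstack([g_cmixd, g_cmixd])
        )

        hwidth = self.hidden
        g_h = np.vstack([g_c[:n, :hwidth], g_c[n:, :hwidth]])
        # cosine-distance pullback onto h1, h2; exactly zero where u == v
        h1, h2 = cache["h1"], cache["h2"]
        n1, n2, cos = cache["norm1"], cache["norm2"], cache["cos"]
        gd = np.where(cache["same"], 0.0, g_d)[:, None]
        inv12 = 1.0 / (n1 * n2)[:, None]
        g_h[:n] += gd * (h2 * inv12 - cos[:, None] * h1 / (n1**2)[:, None]) * -1.0
        g_h[n:] += gd * (h1 * inv12 - cos[:, None] * h2 / (n2**2)[:, None]) * -1.0

        theta_grads, _, _ = self.theta.backward_tape(
            cache["theta_tape"], g_h, np.zeros_like(g_h)
        )
        return theta_grads + alpha_grads + phi_grads

    # ------------------------------------------------------------ persistence

    def to_dict(self) -> dict:
        return {
            "format": "gammanet-checkpoint-v1",
            "hidden": self.hidden,
            "embedding_dim": self.embedding_dim,
            "activation": "silu",
            "backend_id": self.backend_id,
            "theta": self.theta.to_dict(),
            "alpha": self.alpha.to_dict(),
            "phi": self.phi.to_dict(),
            "scalers": self.scalers.to_dict(),
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GibbsExcessNet":
        return cls(
            MLP.from_dict(d["theta"]),
            MLP.from_dict(d["alpha"]),
            MLP.from_dict(d["phi"]),
            ScalerSet.from_dict(d["scalers"]),
            d.get("backend_id", "unspecified"),
            d.get("config", {}),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "GibbsExcessNet":
        return cls.from_dict(json.loads(Path(path).read_text()))


class NeuralGeFunction:
    """Adapter exposing a component pair of a :class:`GibbsExcessNet` as a
    dimensionless g^E/(RT) function of (x1, T) with exact derivatives."""

    def __init__(self, model: GibbsExcessNet, comp1: ComponentRecord, comp2: ComponentRecord):
        self.model = model
        self.comp1 = comp1
        self.comp2 = comp2

    def _tiled(self, x1):
        x1 = np.asarray(x1, dtype=float).ravel()
        m = x1.shape[0]
        return (
            np.tile(self.comp1.embedding, (m, 1)),
            np.tile(self.comp2.embedding, (m, 1)),
            x1,
        )

    def __call__(self, x1, T):
        e1, e2, x1v = self._tiled(x1)
        g, _, _ = self.model.ge_bar_derivatives(e1, e2, T, x1v)
        return g if np.ndim(x1) else float(g[0])

    def derivatives(self, x1, T):
        e1, e2, x1v = self._tiled(x1)
        g, g1, g2 = self.model.ge_bar_derivatives(e1, e2, T, x1v)
        if np.ndim(x1):
            return g, g1, g2
        return float(g[0]), float(g1[0]), float(g2[0])
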