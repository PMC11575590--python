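"""Second-order dual numbers for exact differentiation of analytic g^E
models (Margules, NRTL) with respect to x1.

A ``Dual2`` carries (value, first derivative, second derivative) along a
single scalar direction and overloads the arithmetic the analytic models
need.  Entries are numpy arrays so whole composition grids differentiate in
one pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dual2"]


class Dual2:
    __slots__ = ("v", "d", "e")

    def __init__(self, v, d=0.0, e=0.0):
        self.v = np.asarray(v, dtype=float)
        self.d = np.broadcast_to(np.asarray(d, dtype=float), self.v.shape)
        self.e = np.broadcast_to(np.asarray(e, dtype=float), self.v.shape)

    @classmethod
    def variable(cls, x) -> "Dual2":
        """The differentiation variable itself: d/dx = 1, d2/dx2 = 0."""
        return cls(x, np.ones_like(np.asarray(x, dtype=float)), 0.0)

    @staticmethod
    def _lift(other) -> "Dual2":
        return other if isinstance(other, Dual2) else Dual2(other)

    def __add__(self, o):
        o = self._lift(o)
        return Dual2(self.v + o.v, self.d + o.d, self.e + o.e)

    __radd__ = __add__

    def __neg__(self):
        return Dual2(-self.v, -self.d, -self.e)

    def __sub__(self, o):
        return self + (-self._lift(o))

    def __rsub__(self, o):
        return self._lift(o) + (-self)

    def __mul__(self, o):
        o = self._lift(o)
        return Dual2(
            self.v * o.v,
            self.d * o.v + self.v * o.d,
            self.e * o.v + 2.0 * self.d * o.d + self.v * o.e,
        )

    __rmul__ = __mul__

    def __truediv__(self, o):
        o = self._lift(o)
        inv = 1.0 / o.v
        v = self.v * inv
        d = (self.d - v * o.d) * inv
        e = (self.e - 2.0 * d * o.d - v * o.e) * inv
        return Dual2(v, d, e)

    def __rtruediv__(self, o):
        return self._lift(o) / self

    def exp(self) -> "Dual2":
        ev = np.exp(self.v)
        return Dual2(ev, ev * self.d, ev * (self.e + self.d * self.d))

    def unpack(self):
        return self.v, np.asarray(self.d), np.asarray(self.e)
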