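"""Isothermal vapor-liquid phase diagrams (p-x-y) from activity
coefficients, via direct inversion of extended Raoult's law with an
ideal-gas vapor phase:

    p(x1) = x1 gamma_1 p_1^S + (1 - x1) gamma_2 p_2^S
    y1(x1) = x1 gamma_1 p_1^S / p(x1)

An azeotrope is an interior crossing of y1(x1) = x1, located by bisection on
the continuous model and classified by comparing the azeotropic pressure
with the pure-component vapor pressures (a pressure maximum is a low-boiling
azeotrope, a minimum a high-boiling one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["PxyDiagram", "Azeotrope", "bubble_point", "pxy_diagram", "detect_azeotrope"]


@dataclass(frozen=True)
class Azeotrope:
    x1: float
    p: float  # kPa
    kind: str  # "low-boiling" (pressure maximum) or "high-boiling"


@dataclass
class PxyDiagram:
    """Isothermal phase diagram on an x1 grid.  ``lngamma_fn`` (optional) is
    the generating (x1 -> (ln gamma_1, ln gamma_2)) callable, retained so
    azeotrope refinement can work on the continuous model."""

    T: float
    x1: np.ndarray
    p: np.ndarray
    y1: np.ndarray
    ln_gamma_1: np.ndarray
    ln_gamma_2: np.ndarray
    p_sat_1: float
    p_sat_2: float
    lngamma_fn: object = None


def bubble_point(x1, T, ln_g1, ln_g2, p_sat_1, p_sat_2):
    """Bubble pressure (kPa) and vapor composition y1 at given liquid state.
    Vectorizes over x1 and the ln gammas."""
    x1 = np.asarray(x1, dtype=float)
    part1 = x1 * np.exp(np.asarray(ln_g1, dtype=float)) * p_sat_1
    part2 = (1.0 - x1) * np.exp(np.asarray(ln_g2, dtype=float)) * p_sat_2
    p = part1 + part2
    y1 = part1 / p
    if np.ndim(x1):
        return p, y1
    return float(p), float(y1)


def pxy_diagram(lngamma_fn, T, p_sat_1, p_sat_2, n_grid: int = 101) -> PxyDiagram:
    """Compute the isothermal p-x-y diagram on a uniform x1 grid.

    ``lngamma_fn(x1_array, T) -> (ln_gamma_1, ln_gamma_2)``.  Endpoint
    pressures equal the pure vapor pressures because ln gamma vanishes at the
    respective limits.
    """
    x1 = np.linspace(0.0, 1.0, n_grid)
    ln1, ln2 = lngamma_fn(x1, T)
    p, y1 = bubble_point(x1, T, ln1, ln2, p_sat_1, p_sat_2)
    return PxyDiagram(T, x1, p, y1, np.asarray(ln1), np.asarray(ln2), p_sat_1, p_sat_2, lngamma_fn)


def detect_azeotrope(diagram: PxyDiagram, xtol: float = 1e-6) -> Azeotrope | None:
    """Locate an interior y1 = x1 crossing, if any.

    The grid provides the bracketing interval; when the diagram retains its
    generating callable the root is refined by bisection on the continuous
    model, otherwise by linear interpolation on the grid.
    """
    x, y = diagram.x1, diagram.y1
    f = y - x
    interior = slice(1, len(x) - 1)
    sign = np.sign(f[interior])
    idx = np.flatnonzero(np.diff(sign) != 0)
    cross = [i + 1 for i in idx if sign[i] != 0]
    if not cross:
        return None
    i = cross[0]
    a, b = x[i], x[i + 1]

    if diagram.lngamma_fn is not None:

        def resid(xx):
            ln1, ln2 = diagram.lngamma_fn(np.array([xx]), diagram.T)
            _, yy = bubble_point(
                np.array([xx]), diagram.T, ln1, ln2, diagram.p_sat_1, diagram.p_sat_2
            )
            return float(yy[0] - xx)

        x_az = brentq(resid, a, b, xtol=xtol)
        ln1, ln2 = diagram.lngamma_fn(np.array([x_az]), diagram.T)
        p_az, _ = bubble_point(
            np.array([x_az]), diagram.T, ln1, ln2, diagram.p_sat_1, diagram.p_sat_2
        )
        p_az = float(p_az[0])
    else:
        w = f[i] / (f[i] - f[i + 1])
        x_az = float(a + w * (b - a))
        p_az = float(diagram.p[i] + w * (diagram.p[i + 1] - diagram.p[i]))

    kind = "low-boiling" if p_az > max(diagram.p_sat_1, diagram.p_sat_2) else "high-boiling"
    return Azeotrope(float(x_az), p_az, kind)
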