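"""Activity coefficients by exact differentiation of g^E, and the
thermodynamic-consistency checkers.

With gbar = g^E/(RT), the binary relations are

    ln gamma_1 = gbar + (1 - x1) * d(gbar)/dx1
    ln gamma_2 = gbar -      x1  * d(gbar)/dx1

Because both are derivatives of one smooth scalar function, the isothermal,
isobaric Gibbs-Duhem equation

    x1 * d(ln gamma_1)/dx1 + (1 - x1) * d(ln gamma_2)/dx1 = 0

holds identically; the checkers here quantify the (purely numerical)
residual, and also serve as negative controls for externally supplied,
possibly inconsistent, ln gamma curves.

Any object with a ``derivatives(x1, T) -> (gbar, d1, d2)`` method works as a
``GeFunction``: the analytic Margules/NRTL models and the neural model share
every checker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .errors import NonFiniteDerivative
from .model import GAS_CONSTANT, GibbsExcessNet, MixtureQuery

__all__ = [
    "GeFunction",
    "GammaPrediction",
    "activity_coefficients",
    "infinite_dilution",
    "gibbs_duhem_residual",
    "gibbs_duhem_residual_curves",
    "permutation_check",
    "consistency_report",
]


@runtime_checkable
class GeFunction(Protocol):
    """Dimensionless g^E/(RT) as a function of (x1, T), with exact first and
    second x1-derivatives."""

    def __call__(self, x1, T): ...

    def derivatives(self, x1, T): ...


@dataclass
class GammaPrediction:
    """g^E (J/mol) and both logarithmic activity coefficients at one or more
    state points (fields are scalars or aligned arrays)."""

    gE: np.ndarray
    ln_gamma_1: np.ndarray
    ln_gamma_2: np.ndarray
    T: np.ndarray
    x1: np.ndarray


def _check_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise NonFiniteDerivative("g^E differentiation produced NaN/Inf")


def activity_coefficients(ge: GeFunction, x1, T) -> GammaPrediction:
    """Exact-differentiation route from g^E to ln gamma_i.

    At the endpoints the same smooth differentiation path is used (one-sided
    limits exist because the model is smooth on a neighborhood of [0, 1]);
    the structure of the relations forces ln gamma_1(x1=1) = 0 and
    ln gamma_2(x1=0) = 0 exactly.
    """
    x1a = np.asarray(x1, dtype=float)
    g, g1, _ = ge.derivatives(x1a, T)
    g = np.asarray(g, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    _check_finite(g, g1)
    ln1 = g + (1.0 - x1a) * g1
    ln2 = g - x1a * g1
    return GammaPrediction(
        gE=g * GAS_CONSTANT * np.asarray(T, dtype=float),
        ln_gamma_1=ln1,
        ln_gamma_2=ln2,
        T=np.asarray(T, dtype=float),
        x1=x1a,
    )


def infinite_dilution(ge: GeFunction, component: int, T) -> float:
    """ln gamma_i at infinite dilution: component 1 evaluated at x1 = 0,
    component 2 at x1 = 1."""
    if component not in (1, 2):
        raise ValueError("component must be 1 or 2")
    x = 0.0 if component == 1 else 1.0
    pred = activity_coefficients(ge, x, T)
    return float(pred.ln_gamma_1 if component == 1 else pred.ln_gamma_2)


def gibbs_duhem_residual(ge: GeFunction, x1, T):
    """r = x1*d(ln gamma_1)/dx1 + (1-x1)*d(ln gamma_2)/dx1 at constant T, p.

    Uses the exact second derivative of gbar: d(ln gamma_1)/dx1 =
    (1-x1)*gbar'' and d(ln gamma_2)/dx1 = -x1*gbar''.  For any
    twice-differentiable g^E the two terms cancel; the returned value is the
    numerical residual of that cancellation.
    """
    x1a = np.asarray(x1, dtype=float)
    _, _, g2 = ge.derivatives(x1a, T)
    g2 = np.asarray(g2, dtype=float)
    _check_finite(g2)
    r = x1a * ((1.0 - x1a) * g2) + (1.0 - x1a) * (-x1a * g2)
    return r if np.ndim(x1) else float(r)


def gibbs_duhem_residual_curves(ln_gamma_1, ln_gamma_2, x1, h: float = 1e-6):
    """Gibbs-Duhem residual for two independently supplied ln gamma curves.

    ``ln_gamma_1``/``ln_gamma_2`` are callables of x1.  Derivatives are taken
    by central differences since arbitrary external curves carry no exact
    derivative; this is the negative-control checker for curves that were
    *not* derived from one g^E function.
    """
    x1a = np.asarray(x1, dtype=float)
    d1 = (ln_gamma_1(x1a + h) - ln_gamma_1(x1a - h)) / (2.0 * h)
    d2 = (ln_gamma_2(x1a + h) - ln_gamma_2(x1a - h)) / (2.0 * h)
    r = x1a * d1 + (1.0 - x1a) * d2
    return r if np.ndim(x1) else float(r)


def permutation_check(model: GibbsExcessNet, query: MixtureQuery) -> float:
    """Max absolute change of {ln gamma_1, ln gamma_2} under swapping the
    component order (and correspondingly x1 -> 1-x1).  The deep-set
    architecture makes this zero up to floating-point commutativity."""
    ln1, ln2 = model.ln_gamma(
        query.comp1.embedding, query.comp2.embedding, query.T, query.x1
    )
    swapped = query.swapped()
    ln1s, ln2s = model.ln_gamma(
        swapped.comp1.embedding, swapped.comp2.embedding, swapped.T, swapped.x1
    )
    return float(max(abs(ln1[0] - ln2s[0]), abs(ln2[0] - ln1s[0])))


def consistency_report(
    model: GibbsExcessNet,
    comp1,
    comp2,
    T: float = 298.15,
    n_grid: int = 99,
    tolerances: dict | None = None,
) -> pd.DataFrame:
    """Machine-readable consistency table for one component pair.

    Rows: pure-component limits, identical-component (pseudo-binary) zeros,
    Gibbs-Duhem residual, permutation equivariance.  Columns: criterion,
    grid, max violation, tolerance, passed.
    """
    tol = {
        "pure_component_limits": 1e-12,
        "identical_components": 1e-10,
        "gibbs_duhem": 1e-6,
        "permutation": 1e-10,
    }
    tol.update(tolerances or {})
    grid = np.linspace(0.01, 0.99, n_grid)

    ge = model.ge_function(comp1, comp2)
    pred = activity_coefficients(ge, np.array([0.0, 1.0]), T)
    v_pure = max(abs(float(pred.ln_gamma_2[0])), abs(float(pred.ln_gamma_1[1])))

    ge_same = model.ge_function(comp1, comp1)
    pred_same = activity_coefficients(ge_same, grid, T)
    v_same = float(
        np.max(np.maximum(np.abs(pred_same.ln_gamma_1), np.abs(pred_same.ln_gamma_2)))
    )

    v_gd = float(np.max(np.abs(gibbs_duhem_residual(ge, grid, T))))

    v_perm = max(
        permutation_check(model, MixtureQuery(comp1, comp2, T, float(x)))
        for x in (0.1, 0.5, 0.9)
    )

    rows = [
        ("pure_component_limits", "x1 in {0,1}", v_pure),
        ("identical_components", f"{n_grid}-point x1 grid", v_same),
        ("gibbs_duhem", f"{n_grid}-point x1 grid", v_gd),
        ("permutation", "x1 in {0.1,0.5,0.9}", v_perm),
    ]
    return pd.DataFrame(
        [
            {
                "criterion": name,
                "grid": grid_desc,
                "max_violation": val,
                "tolerance": tol[name],
                "passed": bool(val <= tol[name]),
            }
            for name, grid_desc, val in rows
        ]
    )
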