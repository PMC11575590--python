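"""Thermodynamically consistent synthetic data from analytic g^E models.

The generator emulates the observable a VLE-derived training table carries
-- ln gamma_i(T, x1) curves with measurement noise -- using two classic
binary g^E models:

* two-parameter Margules with an optional A_ij(T) = a_ij + b_ij/T
  temperature dependence, so the standardized-temperature input of the
  network is actually exercised;
* NRTL with constant tau_12, tau_21 and non-randomness alpha.

Component identities are plain tags ("SYN_000", ...) routed to the
hash-fallback embedding backend, which keeps the chemistry toolkit out of
the minimal test path.  Ground-truth parameters are emitted alongside the
dataset so parameter-recovery experiments have an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._dual import Dual2
from .dataio import GammaRecord, gamma_records_to_frame, write_gamma_csv

__all__ = [
    "margules_ln_gamma",
    "nrtl_ln_gamma",
    "MargulesGe",
    "NrtlGe",
    "SyntheticSystem",
    "generate_dataset",
    "write_dataset",
]


# ------------------------------------------------------------- closed forms


def margules_ln_gamma(A12: float, A21: float, x1):
    """Two-parameter Margules activity coefficients (closed form):

    ln gamma_1 = (1-x1)^2 [A12 + 2(A21-A12) x1]
    ln gamma_2 = x1^2     [A21 + 2(A12-A21)(1-x1)]
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = 1.0 - x1
    ln1 = x2**2 * (A12 + 2.0 * (A21 - A12) * x1)
    ln2 = x1**2 * (A21 + 2.0 * (A12 - A21) * x2)
    return ln1, ln2


def nrtl_ln_gamma(tau12: float, tau21: float, alpha: float, x1):
    """NRTL activity coefficients with G_ij = exp(-alpha * tau_ij)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = 1.0 - x1
    G12 = np.exp(-alpha * tau12)
    G21 = np.exp(-alpha * tau21)
    f21 = G21 / (x1 + x2 * G21)
    f12 = G12 / (x2 + x1 * G12)
    ln1 = x2**2 * (tau21 * f21**2 + tau12 * f12 / (x2 + x1 * G12))
    ln2 = x1**2 * (tau12 * f12**2 + tau21 * f21 / (x1 + x2 * G21))
    return ln1, ln2


# ----------------------------------------------------- GeFunction interfaces


@dataclass(frozen=True)
class MargulesGe:
    """gbar(x1, T) = x1 x2 (A21(T) x1 + A12(T) x2), A_ij(T) = a_ij + b_ij/T.

    Exact derivatives come from second-order dual numbers, independent of
    the closed-form ln gamma expressions above (the two routes cross-check
    each other in the consistency tests).
    """

    a12: float
    a21: float
    b12: float = 0.0
    b21: float = 0.0

    def coefficients(self, T: float) -> tuple[float, float]:
        return self.a12 + self.b12 / T, self.a21 + self.b21 / T

    def _gbar(self, x1, T):
        A12, A21 = self.coefficients(T)
        x2 = 1.0 - x1
        return x1 * x2 * (A21 * x1 + A12 * x2)

    def __call__(self, x1, T):
        return self._gbar(np.asarray(x1, dtype=float), T)

    def derivatives(self, x1, T):
        return self._gbar(Dual2.variable(x1), T).unpack()

    def ln_gamma(self, x1, T):
        A12, A21 = self.coefficients(T)
        return margules_ln_gamma(A12, A21, x1)


@dataclass(frozen=True)
class NrtlGe:
    """gbar(x1, T) = x1 x2 [tau21 G21/(x1+x2 G21) + tau12 G12/(x2+x1 G12)],
    parameters taken temperature-independent."""

    tau12: float
    tau21: float
    alpha: float

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("NRTL alpha must lie in (0, 1]")

    def _gbar(self, x1, T):
        G12 = np.exp(-self.alpha * self.tau12)
        G21 = np.exp(-self.alpha * self.tau21)
        x2 = 1.0 - x1
        return x1 * x2 * (self.tau21 * G21 / (x1 + x2 * G21) + self.tau12 * G12 / (x2 + x1 * G12))

    def __call__(self, x1, T):
        return self._gbar(np.asarray(x1, dtype=float), T)

    def derivatives(self, x1, T):
        return self._gbar(Dual2.variable(x1), T).unpack()

    def ln_gamma(self, x1, T):
        return nrtl_ln_gamma(self.tau12, self.tau21, self.alpha, x1)


@dataclass(frozen=True)
class SyntheticSystem:
    """One synthetic binary system: two component tags plus the analytic
    ground truth that generated its labels."""

    comp1: str
    comp2: str
    model_kind: str  # "margules2" | "nrtl"
    ge: MargulesGe | NrtlGe

    def parameters(self) -> dict:
        return {k: float(v) for k, v in vars(self.ge).items()}


# ----------------------------------------------------------------- generator


def generate_dataset(
    n_systems: int = 20,
    points_per_system: int = 15,
    T_range: tuple[float, float] = (290.0, 360.0),
    noise_sd: float = 0.02,
    seed: int = 0,
    model_kind: str = "margules2",
    include_endpoints: bool = False,
    a_range: tuple[float, float] = (-0.5, 2.0),
    b_range: tuple[float, float] = (-60.0, 60.0),
    tau_range: tuple[float, float] = (-0.5, 1.5),
    alpha_range: tuple[float, float] = (0.2, 0.47),
) -> tuple[list[GammaRecord], list[SyntheticSystem]]:
    """Sample systems and noisy ln gamma labels.

    Each system pairs two fresh component tags; x1 is drawn uniformly on the
    open interval (0, 1) and T uniformly on ``T_range``; i.i.d. Gaussian
    noise of sd ``noise_sd`` is added to both labels.  With
    ``include_endpoints`` every system additionally emits the two one-sided
    infinite-dilution records at x1 = 0 and x1 = 1 (noise-free composition,
    noisy label).  Fully determined by ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    systems: list[SyntheticSystem] = []
    records: list[GammaRecord] = []

    for k in range(n_systems):
        c1, c2 = f"SYN_{2 * k:03d}", f"SYN_{2 * k + 1:03d}"
        if model_kind == "margules2":
            ge = MargulesGe(
                a12=rng.uniform(*a_range),
                a21=rng.uniform(*a_range),
                b12=rng.uniform(*b_range),
                b21=rng.uniform(*b_range),
            )
        elif model_kind == "nrtl":
            ge = NrtlGe(
                tau12=rng.uniform(*tau_range),
                tau21=rng.uniform(*tau_range),
                alpha=rng.uniform(*alpha_range),
            )
        else:
            raise ValueError(f"unknown model_kind {model_kind!r}")
        system = SyntheticSystem(c1, c2, model_kind, ge)
        systems.append(system)

        x1 = rng.uniform(0.0, 1.0, size=points_per_system)
        # keep strictly interior: endpoints are emitted separately
        x1 = np.clip(x1, 1e-3, 1.0 - 1e-3)
        T = rng.uniform(*T_range, size=points_per_system)
        ln1, ln2 = np.empty_like(x1), np.empty_like(x1)
        for j in range(points_per_system):
            a, b = ge.ln_gamma(x1[j], T[j])
            ln1[j], ln2[j] = float(a), float(b)
        ln1 += rng.normal(0.0, noise_sd, size=points_per_system) if noise_sd else 0.0
        ln2 += rng.normal(0.0, noise_sd, size=points_per_system) if noise_sd else 0.0
        for j in range(points_per_system):
            records.append(
                GammaRecord(c1, c2, float(T[j]), float(x1[j]), float(ln1[j]), float(ln2[j]), "synthetic")
            )

        if include_endpoints:
            for x_end, comp_idx in ((0.0, 1), (1.0, 2)):
                T_end = float(rng.uniform(*T_range))
                g1, g2 = ge.ln_gamma(x_end, T_end)
                label = float(g1 if comp_idx == 1 else g2)
                label += float(rng.normal(0.0, noise_sd)) if noise_sd else 0.0
                records.append(
                    GammaRecord(
                        c1,
                        c2,
                        T_end,
                        x_end,
                        label if comp_idx == 1 else None,
                        label if comp_idx == 2 else None,
                        "infinite_dilution",
                    )
                )

    return records, systems


def write_dataset(records, systems, out_dir) -> tuple[Path, Path]:
    """Write the gamma CSV plus a JSON truth sidecar; returns both paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_path = out / "synthetic_gamma.csv"
    truth_path = out / "synthetic_truth.json"
    write_gamma_csv(gamma_records_to_frame(records), data_path)
    truth_path.write_text(
        json.dumps(
            [
                {
                    "comp1": s.comp1,
                    "comp2": s.comp2,
                    "model_kind": s.model_kind,
                    "parameters": s.parameters(),
                }
                for s in systems
            ],
            indent=1,
        )
    )
    return data_path, truth_path
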