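"""Tabular dataset I/O, extended Raoult's law, and preprocessing filters.

Canonical internal units throughout: Kelvin, kPa, natural log of activity
coefficients.  Antoine parameter files must declare their unit conventions
explicitly (temperature unit, pressure unit, logarithm base); nothing is
guessed.

The gamma CSV schema -- the interoperability surface for training data --
is: ``smiles_1, smiles_2, T_K, x_1, ln_gamma_1, ln_gamma_2, source`` where
either (but not both) ln column may be blank.  One-sided records are
first-class: infinite-dilution data have exactly this shape, with x_1 at 0
or 1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InvalidSmiles,
    NonPositivePressure,
    RangeWarning,
    SchemaError,
)

__all__ = [
    "VleRecord",
    "AntoineParams",
    "GammaRecord",
    "FilterReport",
    "GAMMA_COLUMNS",
    "VLE_COLUMNS",
    "antoine_vapor_pressure",
    "read_antoine_csv",
    "vle_to_gamma",
    "apply_filters",
    "read_gamma_csv",
    "write_gamma_csv",
    "gamma_records_to_frame",
]

log = logging.getLogger(__name__)

GAMMA_COLUMNS = ["smiles_1", "smiles_2", "T_K", "x_1", "ln_gamma_1", "ln_gamma_2", "source"]
VLE_COLUMNS = ["smiles_1", "smiles_2", "T_K", "p_kPa", "x_1", "y_1"]

#: 10 bar in kPa -- VLE points above this total pressure are excluded
#: because the ideal-gas vapor phase assumption breaks down.
PRESSURE_CUTOFF_KPA = 1000.0

_P_TO_KPA = {"kPa": 1.0, "Pa": 1e-3, "hPa": 0.1, "bar": 100.0, "mmHg": 0.101325 * 1000 / 760}


@dataclass(frozen=True)
class VleRecord:
    """One isothermal VLE measurement: liquid/vapor composition of component
    1 and total pressure."""

    smiles_1: str
    smiles_2: str
    T: float  # K
    p: float  # kPa
    x1: float
    y1: float

    def __post_init__(self):
        if not (0.0 <= self.x1 <= 1.0 and 0.0 <= self.y1 <= 1.0):
            raise ValueError("mole fractions must lie in [0, 1]")
        if self.p <= 0 or self.T <= 0:
            raise ValueError("T and p must be positive")


@dataclass(frozen=True)
class AntoineParams:
    """Antoine vapor-pressure correlation with explicit unit conventions:
    log_base^(A - B/(C + T')) evaluated with T' in ``T_unit``, yielding
    pressure in ``p_unit``."""

    A: float
    B: float
    C: float
    T_unit: str = "K"  # "K" or "C"
    p_unit: str = "kPa"
    log_base: str = "10"  # "10" or "e"
    T_min: float = -np.inf
    T_max: float = np.inf


@dataclass(frozen=True)
class GammaRecord:
    """One training observable: ln gamma of one or both components at a
    state point.  ``source`` tags provenance (vle | infinite_dilution |
    synthetic)."""

    smiles_1: str
    smiles_2: str
    T: float
    x1: float
    ln_gamma_1: float | None = None
    ln_gamma_2: float | None = None
    source: str = "vle"

    def __post_init__(self):
        if self.ln_gamma_1 is None and self.ln_gamma_2 is None:
            raise ValueError("at least one ln gamma must be present")
        if not 0.0 <= self.x1 <= 1.0:
            raise ValueError("x1 must lie in [0, 1]")


@dataclass
class FilterReport:
    """Per-reason drop counts from :func:`apply_filters`."""

    n_input: int = 0
    n_kept: int = 0
    dropped: dict = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


# ------------------------------------------------------------------- Antoine


def antoine_vapor_pressure(params: AntoineParams, T: float) -> float:
    """Pure-component saturation pressure in kPa at T (Kelvin)."""
    t = T - 273.15 if params.T_unit == "C" else T
    if not params.T_min <= T <= params.T_max:
        warnings.warn(
            f"T={T} K outside Antoine validity [{params.T_min}, {params.T_max}] K",
            RangeWarning,
            stacklevel=2,
        )
    exponent = params.A - params.B / (params.C + t)
    base = math.e if params.log_base == "e" else 10.0
    p = base**exponent * _P_TO_KPA[params.p_unit]
    if not (p > 0 and math.isfinite(p)):
        raise NonPositivePressure(f"Antoine evaluation gave p={p} kPa at T={T} K")
    return p


def read_antoine_csv(path) -> dict[str, AntoineParams]:
    """Read an Antoine parameter table keyed by SMILES.  Columns: smiles, A,
    B, C, T_unit, p_unit, log_base, T_min, T_max (unit columns mandatory)."""
    df = pd.read_csv(path)
    required = {"smiles", "A", "B", "C", "T_unit", "p_unit", "log_base"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"Antoine file missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[row["smiles"]] = AntoineParams(
            A=float(row["A"]),
            B=float(row["B"]),
            C=float(row["C"]),
            T_unit=str(row["T_unit"]),
            p_unit=str(row["p_unit"]),
            log_base=str(row["log_base"]),
            T_min=float(row.get("T_min", -np.inf)) if "T_min" in df.columns else -np.inf,
            T_max=float(row.get("T_max", np.inf)) if "T_max" in df.columns else np.inf,
        )
    return out


# ----------------------------------------------------------- Raoult inversion


def vle_to_gamma(rec: VleRecord, p_sat_1: float, p_sat_2: float) -> GammaRecord:
    """Extended Raoult's law, ideal-gas vapor phase:
    gamma_i = y_i * p / (x_i * p_sat_i).

    A composition endpoint (x_i = 0) leaves that component's gamma undefined
    and yields a one-sided record.  Non-positive gammas signal inconsistent
    raw data and raise; batch callers drop such rows with a log entry.
    """
    x2 = 1.0 - rec.x1
    y2 = 1.0 - rec.y1
    ln1 = ln2 = None
    if rec.x1 > 0.0:
        g1 = rec.y1 * rec.p / (rec.x1 * p_sat_1)
        if g1 <= 0:
            raise ValueError(f"non-positive gamma_1 = {g1}")
        ln1 = math.log(g1)
    if x2 > 0.0:
        g2 = y2 * rec.p / (x2 * p_sat_2)
        if g2 <= 0:
            raise ValueError(f"non-positive gamma_2 = {g2}")
        ln2 = math.log(g2)
    return GammaRecord(rec.smiles_1, rec.smiles_2, rec.T, rec.x1, ln1, ln2, source="vle")


# -------------------------------------------------------------------- filters


def apply_filters(df: pd.DataFrame, canonicalizer=None) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the preprocessing exclusions to a VLE table.

    Drops, in order: rows flagged by a boolean/int ``quality`` column when
    present (poor-quality data), rows with total pressure above 10 bar, and
    rows whose SMILES cannot be canonicalized.  ``canonicalizer`` defaults to
    the rdkit-backed one; pass a custom callable to filter synthetic tags.
    """
    if canonicalizer is None:
        from .embeddings import canonicalize_smiles as canonicalizer  # noqa: PLC0415

    report = FilterReport(n_input=len(df))
    keep = pd.Series(True, index=df.index)

    if "quality" in df.columns:
        bad_quality = ~df["quality"].astype(bool)
        report.dropped["poor_quality"] = int(bad_quality[keep].sum())
        keep &= ~bad_quality

    high_p = df["p_kPa"] > PRESSURE_CUTOFF_KPA
    report.dropped["pressure>10bar"] = int(high_p[keep].sum())
    keep &= ~high_p

    bad_smiles = pd.Series(False, index=df.index)
    cache: dict[str, bool] = {}
    for idx in df.index[keep]:
        for col in ("smiles_1", "smiles_2"):
            s = df.at[idx, col]
            ok = cache.get(s)
            if ok is None:
                try:
                    canonicalizer(s)
                    ok = True
                except InvalidSmiles:
                    ok = False
                cache[s] = ok
            if not ok:
                bad_smiles.at[idx] = True
                log.warning("dropping row %s: unparsable SMILES %r", idx, s)
    report.dropped["invalid_smiles"] = int(bad_smiles[keep].sum())
    keep &= ~bad_smiles

    kept = df[keep].copy()
    report.n_kept = len(kept)
    report.dropped = {k: v for k, v in report.dropped.items() if v}
    return kept, report


# ------------------------------------------------------------------ gamma CSV


def gamma_records_to_frame(records: list[GammaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "smiles_1": r.smiles_1,
                "smiles_2": r.smiles_2,
                "T_K": r.T,
                "x_1": r.x1,
                "ln_gamma_1": np.nan if r.ln_gamma_1 is None else r.ln_gamma_1,
                "ln_gamma_2": np.nan if r.ln_gamma_2 is None else r.ln_gamma_2,
                "source": r.source,
            }
            for r in records
        ],
        columns=GAMMA_COLUMNS,
    )


def write_gamma_csv(records, path) -> None:
    """Write GammaRecords (or an equivalent DataFrame) to the gamma schema.
    Floats use repr-precision so a write -> read round trip is lossless."""
    df = records if isinstance(records, pd.DataFrame) else gamma_records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.17g")


def read_gamma_csv(path) -> list[GammaRecord]:
    """Read and validate a gamma CSV into records.

    Raises :class:`SchemaError` for a missing required column or for a data
    row carrying neither ln gamma value (position reported 1-based, header
    excluded).
    """
    df = pd.read_csv(Path(path))
    required = set(GAMMA_COLUMNS) - {"source"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"gamma CSV missing required columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "vle"
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        ln1 = None if pd.isna(row.ln_gamma_1) else float(row.ln_gamma_1)
        ln2 = None if pd.isna(row.ln_gamma_2) else float(row.ln_gamma_2)
        if ln1 is None and ln2 is None:
            raise SchemaError(f"row {i + 1}: both ln_gamma columns are empty")
        records.append(
            GammaRecord(
                str(row.smiles_1),
                str(row.smiles_2),
                float(row.T_K),
                float(row.x_1),
                ln1,
                ln2,
                str(row.source),
            )
        )
    return records
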