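"""Component embeddings: SMILES canonicalization, pluggable embedding
backends, and feature standardization.

Two backends implement the same interface:

* ``HashEmbeddingBackend`` ("hash-fallback") -- a deterministic pseudo-random
  unit vector keyed on the component string.  It carries no chemistry but is
  reproducible offline, which makes the full pipeline testable without any
  download; it is the package default.
* ``ChemBertaBackend`` ("chemberta2-77M-MTR") -- the CLS-token embedding of
  the last layer of the pretrained ChemBERTa-2 77M-MTR model (384 dims, max
  512 tokens).  Requires the optional ``transformers`` dependency and the
  published checkpoint; construction raises :class:`BackendUnavailable` when
  those are missing so callers can fall back *explicitly*.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BackendUnavailable,
    DegenerateColumnWarning,
    InvalidSmiles,
    ShapeMismatch,
)

__all__ = [
    "ComponentRecord",
    "ScalerSet",
    "HashEmbeddingBackend",
    "ChemBertaBackend",
    "EmbeddingCache",
    "canonicalize_smiles",
    "embed_component",
    "get_backend",
    "fit_scalers",
    "standardize",
    "unstandardize",
]


# --------------------------------------------------------------------- types


@dataclass(frozen=True)
class ComponentRecord:
    """A component identifier plus its raw embedding vector."""

    smiles: str
    embedding: np.ndarray
    backend_id: str

    def __post_init__(self):
        object.__setattr__(
            self, "embedding", np.asarray(self.embedding, dtype=float)
        )


@dataclass
class ScalerSet:
    """Per-dimension standardization statistics for embeddings and T.

    Fitted on the training split only; serialized inside every checkpoint so
    inference applies exactly the transform seen during training.  Std uses
    the population convention (ddof=0); zero-variance entries are replaced by
    1 and recorded in ``degenerate_dims`` / ``degenerate_temperature``.
    """

    embedding_mean: np.ndarray
    embedding_std: np.ndarray
    temperature_mean: float
    temperature_std: float
    degenerate_dims: list = field(default_factory=list)
    degenerate_temperature: bool = False

    @classmethod
    def identity(cls, dim: int) -> "ScalerSet":
        return cls(np.zeros(dim), np.ones(dim), 0.0, 1.0)

    def transform_embedding(self, e: np.ndarray) -> np.ndarray:
        e = np.asarray(e, dtype=float)
        if e.shape[-1] != self.embedding_mean.shape[0]:
            raise ShapeMismatch(
                f"embedding width {e.shape[-1]} != scaler width "
                f"{self.embedding_mean.shape[0]}"
            )
        return (e - self.embedding_mean) / self.embedding_std

    def transform_temperature(self, t):
        return (np.asarray(t, dtype=float) - self.temperature_mean) / self.temperature_std

    def to_dict(self) -> dict:
        return {
            "embedding_mean": self.embedding_mean.tolist(),
            "embedding_std": self.embedding_std.tolist(),
            "temperature_mean": float(self.temperature_mean),
            "temperature_std": float(self.temperature_std),
            "degenerate_dims": list(self.degenerate_dims),
            "degenerate_temperature": bool(self.degenerate_temperature),
            "std_convention": "population",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerSet":
        return cls(
            np.asarray(d["embedding_mean"], dtype=float),
            np.asarray(d["embedding_std"], dtype=float),
            float(d["temperature_mean"]),
            float(d["temperature_std"]),
            list(d.get("degenerate_dims", [])),
            bool(d.get("degenerate_temperature", False)),
        )


# ----------------------------------------------------------- canonicalization


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical SMILES form, raising :class:`InvalidSmiles` for
    unparsable input.  Idempotent: canon(canon(s)) == canon(s)."""
    if not smiles:
        raise InvalidSmiles("empty SMILES string")
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmiles(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


# ------------------------------------------------------------------ backends


class HashEmbeddingBackend:
    """Deterministic pseudo-embedding: a seeded unit-norm Gaussian vector
    keyed on (seed, component string) via SHA-256.

    Identical strings always map to bitwise-identical vectors; distinct
    strings collide with probability ~2**-64.  Accepts arbitrary component
    tags (not only valid SMILES), which lets synthetic datasets bypass the
    chemistry toolkit entirely.
    """

    def __init__(self, dim: int = 384, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = int(dim)
        self.seed = int(seed)

    @property
    def backend_id(self) -> str:
        return f"hash-fallback-d{self.dim}-s{self.seed}"

    def embed(self, smiles: str) -> np.ndarray:
        digest = hashlib.sha256(f"{self.seed}:{smiles}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        v = rng.standard_normal(self.dim)
        return v / np.linalg.norm(v)


class ChemBertaBackend:
    """CLS-token embedding from the pretrained ChemBERTa-2 77M-MTR model.

    Optional: needs ``transformers`` plus the published checkpoint.  The
    tokenizer is used as published (no local patches), so embeddings may
    differ from pipelines that modify it.
    """

    DIM = 384
    MAX_TOKENS = 512
    MODEL_NAME = "DeepChem/ChemBERTa-77M-MTR"

    def __init__(self, model_name: str | None = None):
        try:
            from transformers import AutoModel, AutoTokenizer  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional path
            raise BackendUnavailable(
                "the 'transformers' package is not installed; use the "
                "hash-fallback backend or install the optional dependency"
            ) from exc
        name = model_name or self.MODEL_NAME
        try:  # pragma: no cover - requires network/checkpoint
            self._tokenizer = AutoTokenizer.from_pretrained(name)
            self._model = AutoModel.from_pretrained(name)
        except Exception as exc:  # pragma: no cover
            raise BackendUnavailable(f"could not load {name}: {exc}") from exc
        self.dim = self.DIM

    @property
    def backend_id(self) -> str:
        return "chemberta2-77M-MTR"

    def embed(self, smiles: str) -> np.ndarray:  # pragma: no cover - optional
        import torch

        tokens = self._tokenizer(
            smiles, return_tensors="pt", truncation=True, max_length=self.MAX_TOKENS
        )
        with torch.no_grad():
            out = self._model(**tokens)
        return out.last_hidden_state[0, 0].numpy().astype(float)


def get_backend(name: str, **kwargs):
    """Construct a backend by config name ('hash-fallback' or
    'chemberta2-77M-MTR')."""
    if name == "hash-fallback":
        return HashEmbeddingBackend(
            dim=kwargs.get("dim", 384), seed=kwargs.get("seed", 0)
        )
    if name == "chemberta2-77M-MTR":
        return ChemBertaBackend(kwargs.get("model_name"))
    raise ValueError(f"unknown backend {name!r}")


class EmbeddingCache:
    """Embed each unique component once, keyed on (string, backend id)."""

    def __init__(self, backend):
        self.backend = backend
        self._store: dict[str, ComponentRecord] = {}

    def get(self, smiles: str) -> ComponentRecord:
        rec = self._store.get(smiles)
        if rec is None:
            rec = ComponentRecord(smiles, self.backend.embed(smiles), self.backend.backend_id)
            self._store[smiles] = rec
        return rec

    def __len__(self) -> int:
        return len(self._store)


def embed_component(smiles: str, backend) -> ComponentRecord:
    """Embed one component with the given backend."""
    return ComponentRecord(smiles, backend.embed(smiles), backend.backend_id)


# -------------------------------------------------------------------- scalers


def fit_scalers(embeddings: np.ndarray, temperatures: np.ndarray) -> ScalerSet:
    """Fit standardization statistics on training-split features.

    ``embeddings`` is (n, D) -- every embedding row occurring in the training
    records; ``temperatures`` is (n_T,).  Mole fractions are never scaled.
    """
    emb = np.atleast_2d(np.asarray(embeddings, dtype=float))
    t = np.asarray(temperatures, dtype=float).ravel()
    if emb.shape[0] < 2 or t.size < 2:
        raise ValueError("need at least 2 records to fit scalers")

    mean = emb.mean(axis=0)
    std = emb.std(axis=0)  # population convention, ddof=0
    degenerate = np.flatnonzero(std == 0.0).tolist()
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} zero-variance embedding dims; std set to 1",
            DegenerateColumnWarning,
            stacklevel=2,
        )
        std = std.copy()
        std[degenerate] = 1.0

    t_mean = float(t.mean())
    t_std = float(t.std())
    degenerate_t = t_std == 0.0
    if degenerate_t:
        warnings.warn(
            "temperature column has zero variance; std set to 1",
            DegenerateColumnWarning,
            stacklevel=2,
        )
        t_std = 1.0
    return ScalerSet(mean, std, t_mean, t_std, degenerate, degenerate_t)


def standardize(x, mean, std):
    """z = (x - mean) / std, broadcasting over leading axes."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if mean.ndim and x.shape[-1:] != mean.shape:
        raise ShapeMismatch(f"cannot standardize shape {x.shape} with mean shape {mean.shape}")
    return (x - mean) / np.asarray(std, dtype=float)


def unstandardize(z, mean, std):
    """Inverse of :func:`standardize`."""
    return np.asarray(z, dtype=float) * np.asarray(std, dtype=float) + np.asarray(
        mean, dtype=float
    )
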