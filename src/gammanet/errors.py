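"""Exception and warning types shared across the package."""


class GammanetError(Exception):
    """Base class for all package-specific errors."""


class InvalidSmiles(GammanetError):
    """A SMILES string could not be parsed / canonicalized."""


class BackendUnavailable(GammanetError):
    """The requested embedding backend cannot be constructed (e.g. the
    optional transformer dependency is not installed)."""


class ShapeMismatch(GammanetError):
    """An array does not have the shape a network layer or scaler expects."""


class ZeroVector(GammanetError):
    """Cosine distance requested for a vector with near-zero norm."""


class NonFiniteDerivative(GammanetError):
    """A derivative of the Gibbs excess energy came out NaN/Inf."""


class SchemaError(GammanetError):
    """A tabular file is missing required columns or violates row invariants."""


class TooFewSystems(GammanetError):
    """Not enough distinct systems to form a train/val/test partition."""


class DivergedLoss(GammanetError):
    """Training loss became non-finite."""


class NonPositivePressure(GammanetError):
    """Antoine evaluation produced a non-positive vapor pressure."""


class DegenerateColumnWarning(UserWarning):
    """A feature column had zero variance; its std was replaced by 1."""


class RangeWarning(UserWarning):
    """Antoine parameters evaluated outside their stated validity range."""
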