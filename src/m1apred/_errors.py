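"""Exception hierarchy shared across the package."""


class M1APredError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(M1APredError):
    """Malformed FASTA input."""


class AlphabetError(M1APredError):
    """A sequence contains a symbol outside {A, C, G, U} (after T->U)."""


class DuplicateIdError(M1APredError):
    """Two records in one file share an identifier."""


class WindowError(M1APredError):
    """A window violates the length or center-adenosine convention."""


class ParameterError(M1APredError):
    """An operation received an out-of-range or inconsistent parameter."""


class SamplingError(M1APredError):
    """Negative sampling was asked for more records than the pool holds."""


class ContaminationError(M1APredError):
    """Identical sequences appear in both the positive and negative class."""


class TrainingError(M1APredError):
    """The classifier cannot be trained on the given data."""


class EvaluationError(M1APredError):
    """A validation protocol cannot run on the given dataset."""


class ModelIOError(M1APredError):
    """A model file is missing, truncated, or from an incompatible version."""


class CompatibilityError(M1APredError):
    """A model was applied to data that does not match its encoder settings."""
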