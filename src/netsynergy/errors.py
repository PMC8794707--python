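"""Exception hierarchy.

Every error raised by the package derives from :class:`NetsynergyError`,
so callers can catch one base class at pipeline boundaries.
"""


class NetsynergyError(Exception):
    """Base class for all package errors."""


# --- knowledge base -------------------------------------------------------

class EmptyNetworkError(NetsynergyError):
    """An interaction stream contained no usable rows."""


class UnknownInteractionTypeError(NetsynergyError):
    """An interaction-type token is missing from the dialect table."""

    def __init__(self, token: str, row: int):
        self.token = token
        self.row = row
        super().__init__(f"unknown interaction type {token!r} at row {row}")


class ConflictingActionError(NetsynergyError):
    """The same protein appears with both activating and inhibiting action."""


class EmptyProfileError(NetsynergyError):
    """A drug profile declares no targets."""


class DisjointCharacterisationError(NetsynergyError):
    """No disease effector maps onto the network."""


# --- expression -----------------------------------------------------------

class UnmappedTranscriptError(NetsynergyError):
    """Differential-expression records lack a protein mapping."""

    def __init__(self, transcript_ids):
        self.transcript_ids = list(transcript_ids)
        super().__init__(
            "unmapped transcripts: " + ", ".join(self.transcript_ids)
        )


# --- MoA sampling ---------------------------------------------------------

class MissingTargetProteinError(NetsynergyError):
    """A stimulus or clamp protein is absent from the network."""


class EmptyTrainingSetError(NetsynergyError):
    """Accuracy evaluation requires at least one training pair."""


class NoCompliantSolutionError(NetsynergyError):
    """The sampling budget was exhausted without an accepted solution."""

    def __init__(self, best_accuracy: float):
        self.best_accuracy = best_accuracy
        super().__init__(
            f"no compliant solution found; best accuracy reached "
            f"{best_accuracy:.3f}"
        )


class EmptyEnsembleError(NetsynergyError):
    """Aggregation requires a non-empty ensemble."""


# --- relationship scoring -------------------------------------------------

class EmptySetError(NetsynergyError):
    """A protein set is empty or has no member mapped to the network."""


class DegenerateTrainingSetError(NetsynergyError):
    """Scorer training data contains a single class."""


class InsufficientNullError(NetsynergyError):
    """Too few null samples requested for empirical calibration."""


class InvalidScoreError(NetsynergyError):
    """A relationship score lies outside [0, 100]."""


# --- synergy pipeline -----------------------------------------------------

class MissingEntityError(NetsynergyError):
    """A score matrix lacks a required entity row."""


class ShapeMismatchError(NetsynergyError):
    """Two score matrices do not share the same rows/columns."""


class ConfigurationError(NetsynergyError):
    """A pipeline configuration is incomplete or inconsistent."""


class PipelineStageError(NetsynergyError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


# --- synthetic data -------------------------------------------------------

class InvalidSpecError(NetsynergyError):
    """A synthetic-data specification is infeasible."""


class UnknownMotiveError(NetsynergyError):
    """A motive name is not present in the disease characterisation."""
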