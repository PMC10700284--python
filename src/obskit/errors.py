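"""Exception hierarchy shared across obskit modules."""


class ObskitError(Exception):
    """Base class for all obskit errors."""


class SchemaError(ObskitError):
    """A keystroke schema (KSF) violates its invariants or cannot be read."""


class SessionValidationError(ObskitError):
    """A session record violates its invariants or its JSON is malformed."""


class RecorderError(ObskitError):
    """The event recorder was driven outside its contract."""


class PhysioError(ObskitError):
    """A physiological recording or feature computation is invalid."""


class NoBeatsError(PhysioError):
    """Fewer than two pulse peaks could be located in a PPG series."""


class AgreementError(ObskitError):
    """An interobserver-agreement computation received incompatible inputs."""


class StorageError(ObskitError):
    """A project-store operation failed (collision, missing layout, ...)."""
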