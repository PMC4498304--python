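"""Exception hierarchy for pocketdyn."""


class PocketdynError(Exception):
    """Base class for all pocketdyn errors."""


class FormatError(PocketdynError):
    """Input file is readable but not valid for the expected format."""


class SelectionError(PocketdynError):
    """A residue/atom selection matched nothing."""


class PairingError(PocketdynError):
    """Two coordinate sets that must be paired atom-by-atom do not match."""


class DegenerateFitError(PocketdynError):
    """Superposition requested on fewer than three or collinear fit points."""


class InsufficientDataError(PocketdynError):
    """Not enough conformations for the requested statistic."""


class UnknownElementError(PocketdynError):
    """No van der Waals radius / mass tabulated for an element."""


class ConfigError(PocketdynError):
    """Invalid configuration for a generator or pipeline."""


class StageError(PocketdynError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
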