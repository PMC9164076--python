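"""Exception hierarchy shared across the pipeline.

Every error raised by netpharm derives from :class:`NetPharmError`, so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class NetPharmError(Exception):
    """Base class for all netpharm errors."""


class MalformedRecordError(NetPharmError):
    """A single input record could not be interpreted (e.g. empty gene symbol)."""


class IncompleteRecordError(MalformedRecordError):
    """A record is missing a required field; the message names the field."""


class SchemaError(NetPharmError):
    """A tabular input lacks a required column; the message names the column."""


class FormatError(NetPharmError):
    """A file violates its format (bad GMT line, non-numeric score...)."""


class StructureError(NetPharmError):
    """A graph construction request violates layer constraints."""


class InvalidAnnotationError(NetPharmError):
    """Pathway annotation counts are inconsistent (hit count above background)."""


class ConfigError(NetPharmError):
    """A run or generator configuration is infeasible or unparseable."""


class NoResultError(NetPharmError):
    """An operation that must select something was given nothing to select."""


class PipelineStageError(NetPharmError):
    """A pipeline stage aborted; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
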