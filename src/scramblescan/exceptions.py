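"""Exception hierarchy."""


class ScrambleScanError(Exception):
    """Base class for all package errors."""


class ParameterError(ScrambleScanError, ValueError):
    """A configuration value is outside its documented domain.

    The message names the offending field.
    """


class InputError(ScrambleScanError, ValueError):
    """An input record is malformed or degenerate (e.g. empty sequence)."""


class IntegrityError(ScrambleScanError, ValueError):
    """Cross-references between records are inconsistent.

    Raised e.g. for coordinates outside a scaffold, an unknown scaffold id in
    a support table, or a transcript assigned to two gene families.
    """


class PipelineError(ScrambleScanError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
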