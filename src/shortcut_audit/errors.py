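"""Exception hierarchy for the audit pipeline.

``ValidationError`` and ``SchemaError`` map to CLI exit code 2;
anything else escaping the pipeline maps to exit code 1.
"""


class AuditError(Exception):
    """Base class for all package errors."""


class ValidationError(AuditError):
    """Input data violates an invariant (shape, range, degenerate classes)."""


class FormatError(AuditError):
    """A file's payload does not match its declared format."""


class SchemaError(AuditError):
    """A required column or key is missing from a table/config."""
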