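"""Exception hierarchy shared across the pipeline stages."""


class P53ccError(Exception):
    """Base class for all package errors."""


class SchemaError(P53ccError):
    """An input table is structurally invalid (missing columns, duplicates)."""


class ParseError(P53ccError):
    """A field value could not be parsed (names the offending row)."""


class InputError(P53ccError):
    """Semantically inconsistent input (e.g. conflicting cancer-type labels)."""


class UndefinedCorrelationError(P53ccError):
    """Pearson correlation requested on a zero-variance vector."""


class EnumerationLimitError(P53ccError):
    """Exhaustive enumeration would exceed the configured guard."""
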