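"""Exception hierarchy shared across the package."""


class AstigvecError(Exception):
    """Base class for all package-specific errors."""


class UndefinedAxisError(AstigvecError, ValueError):
    """An axis-dependent operation was asked of a zero-cylinder astigmatism."""


class SingularConversionError(AstigvecError, ZeroDivisionError):
    """Vertex-distance conversion hit the pole 1 - d*F == 0."""


class MissingFieldError(AstigvecError, KeyError):
    """A required measurement is absent from an eye record."""

    def __init__(self, field: str, eye_id: str | None = None):
        self.field = field
        self.eye_id = eye_id
        where = f" (eye {eye_id})" if eye_id else ""
        super().__init__(f"missing required field '{field}'{where}")

    def __str__(self) -> str:  # KeyError would re-quote the message
        return self.args[0]


class EmptyCohortError(AstigvecError, ValueError):
    """An operation that needs at least one eye received an empty cohort."""


class PairingError(AstigvecError, ValueError):
    """Paired samples of unequal length."""


class SchemaError(AstigvecError, ValueError):
    """A cohort CSV does not match the expected column schema."""


class CohortReadError(AstigvecError, ValueError):
    """One or more rows of a cohort CSV failed validation.

    Carries ``row_errors``, a list of ``(line_number, eye_id, message)``
    tuples so callers can report every bad row at once.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "; ".join(
            f"line {ln} (eye {eid or '?'}): {msg}" for ln, eid, msg in self.row_errors
        )
        super().__init__(f"{len(self.row_errors)} invalid row(s): {lines}")
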