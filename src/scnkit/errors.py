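"""Exception hierarchy shared across the package."""

from __future__ import annotations


class ScnError(Exception):
    """Base class for all scnkit errors."""


class FormatError(ScnError):
    """A file does not have the expected tabular layout (missing columns, bad header)."""


class ValidationError(ScnError):
    """Input data violates an invariant.

    Collects *every* violation found, not just the first, so that a defective
    clinical table can be fixed in one pass.
    """

    def __init__(self, errors: list[str] | str):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class ConfigError(ScnError):
    """A simulation or pipeline configuration is internally inconsistent."""


class ConvergenceError(ScnError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message if residual is None else f"{message} (residual={residual:.3e})")
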