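"""Exception hierarchy.

The one distinction that matters throughout the engine is *blocked* versus
*error*: a :class:`Blocked` condition is transient and user-fixable (missing
credential, unreachable resource, a file that has not appeared yet) and maps
to the resumable ``blocked`` task state, while every other failure is a real
error.  Code that catches ``Blocked`` must never convert it to an error state.
"""

from __future__ import annotations


class BenchworkError(Exception):
    """Base class for every error raised by benchwork."""


class ConfigurationError(BenchworkError):
    """A registry/config cross-reference is broken (e.g. dangling backend id)."""


class ValidationError(BenchworkError):
    """A document failed schema or semantic validation.

    ``diagnostics`` holds one human-readable message per offending item
    (per job for workflow requests, per field for configs).
    """

    def __init__(self, message: str, diagnostics: list[str] | None = None):
        super().__init__(message)
        self.diagnostics: list[str] = list(diagnostics or [])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.diagnostics:
            return base + "\n  " + "\n  ".join(self.diagnostics)
        return base


class NotFoundError(BenchworkError):
    """A referenced entity (user, workflow, path) does not exist."""


class PatternError(BenchworkError):
    """A file-type glob pattern is malformed."""


class RenderError(BenchworkError):
    """A command template could not be rendered (unbound mandatory param)."""


class TransferError(BenchworkError):
    """A storage copy failed or was rejected."""


class ContractViolation(BenchworkError):
    """An internal invariant was broken (e.g. illegal status transition).

    This is a bug surface, not a user error.
    """


class SchemaMismatch(BenchworkError):
    """A persisted store or snapshot has an unrecognized schema version."""


class AuthenticationError(BenchworkError):
    """Wrong vault password or tampered ciphertext."""


class Blocked(BenchworkError):
    """Transient, user-fixable fault: the affected task goes *blocked*, never *error*."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class CredentialMissing(Blocked):
    """No decrypted credential is cached for a backend that requires one."""


class BackendUnreachable(Blocked):
    """A storage or compute backend cannot currently be reached."""
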