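"""Package-wide exception types."""


class DiazoloadError(Exception):
    """Base class for all errors raised by diazoload."""


class ConfigurationError(DiazoloadError):
    """A configuration problem: missing column mapping, unknown station,
    invalid basin definition, or a path that does not exist."""


class ValidationError(DiazoloadError):
    """Input data failed validation.

    Carries a list of ``(row, message)`` pairs in :attr:`issues` so callers
    can report every offending row, not just the first.
    """

    def __init__(self, message: str, issues=None):
        super().__init__(message)
        self.issues = list(issues or [])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.issues:
            detail = "; ".join(f"row {r}: {m}" for r, m in self.issues[:20])
            more = "" if len(self.issues) <= 20 else f" (+{len(self.issues) - 20} more)"
            return f"{base}: {detail}{more}"
        return base
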