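"""Exception hierarchy shared across the package."""


class DesceaError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DesceaError, ValueError):
    """A scalar input violates its domain (e.g. non-positive mean).

    The message always names the offending field.
    """


class InfeasibleMomentsError(DesceaError, ValueError):
    """Summary moments admit no distribution in the requested family
    (e.g. beta variance >= mean*(1-mean))."""


class EmptyInputError(DesceaError, ValueError):
    """An operation that needs at least one record received none."""


class ConfigValidationError(DesceaError, ValueError):
    """A run configuration failed validation.

    Carries ``issues``: a list of ``(key, message)`` pairs covering every
    offending key, so callers can report all problems at once.
    """

    def __init__(self, issues: list[tuple[str, str]]):
        self.issues = list(issues)
        lines = "; ".join(f"{key}: {msg}" for key, msg in self.issues)
        super().__init__(f"invalid configuration ({len(self.issues)} issue(s)): {lines}")
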