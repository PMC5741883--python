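"""Exception hierarchy for the chilling-requirement pipeline."""


class PeonychillError(Exception):
    """Base class for all package errors."""


class ChillDataError(PeonychillError, ValueError):
    """Invalid temperature records (non-finite, out of range, unordered)."""


class GapError(ChillDataError):
    """Missing hours inside an accumulation window."""

    def __init__(self, missing_hours):
        self.missing_hours = list(missing_hours)
        preview = ", ".join(str(h) for h in self.missing_hours[:5])
        more = "" if len(self.missing_hours) <= 5 else f" (+{len(self.missing_hours) - 5} more)"
        super().__init__(f"{len(self.missing_hours)} missing hour(s) in window: {preview}{more}")


class WindowRangeError(ChillDataError):
    """Accumulation window lies (partly) outside the series span."""


class StartDateNotFoundError(PeonychillError, LookupError):
    """No date satisfies the chill start rule in the given series."""


class ConfigError(PeonychillError, ValueError):
    """Invalid run, rule or generator configuration."""


class EstimationError(PeonychillError, ValueError):
    """CR bracket or fulfillment estimation is impossible from the data."""


class UnitMismatchError(PeonychillError, ValueError):
    """Comparing or intersecting quantities from different chill models."""


class UndefinedDelayError(EstimationError):
    """At least one winter never accumulates the requested chill amount."""


class DegenerateProfileError(PeonychillError, ValueError):
    """Expression profiles too flat for any lagged correlation."""
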