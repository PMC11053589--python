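"""Exception hierarchy shared across the package."""


class GaitFuseError(Exception):
    """Base class for all package-specific errors."""


class NotStationaryError(GaitFuseError):
    """A window expected to be stationary failed a stillness check.

    Parameters
    ----------
    check : str
        Name of the violated check (e.g. ``"gyro_rate_sd"``, ``"accel_norm"``).
    value, threshold : float
        Observed statistic and the limit it exceeded.
    """

    def __init__(self, check: str, value: float, threshold: float):
        self.check = check
        self.value = value
        self.threshold = threshold
        super().__init__(
            f"stationarity check {check!r} failed: {value:.6g} exceeds {threshold:.6g}"
        )


class AlignmentUnreliableError(GaitFuseError):
    """Cross-correlation peak too weak to trust the estimated time offset."""

    def __init__(self, best_correlation: float, threshold: float = 0.5):
        self.best_correlation = best_correlation
        self.threshold = threshold
        super().__init__(
            f"alignment unreliable: peak correlation {best_correlation:.3f} "
            f"below {threshold:.3f}"
        )


class IntegrationError(GaitFuseError):
    """ODE integration produced a non-finite state."""

    def __init__(self, message: str, time: float | None = None):
        self.time = time
        super().__init__(message if time is None else f"{message} at t={time:.6g} s")


class SchemaError(GaitFuseError):
    """Invalid measurement schema or endpoint definition conflict."""


class RecordValidationError(GaitFuseError):
    """A record in an insertion batch violates the endpoint schema."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"record {index}: {message}")


class FilterError(GaitFuseError):
    """Malformed or schema-incompatible query-string filter."""


class UnsupportedOperatorError(FilterError):
    """Operator not supported for the column's type (e.g. gt/lt on text)."""
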