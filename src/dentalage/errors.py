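"""Exception hierarchy shared across the package."""


class DentalAgeError(Exception):
    """Base class for all package-specific errors."""


class InvalidRecordError(DentalAgeError):
    """A child record violates a basic invariant (e.g. radiograph before birth)."""


class ValidationError(DentalAgeError):
    """One or more cohort rows failed validation.

    ``problems`` is a list of ``(row_number, column, message)`` tuples; row
    numbers are 1-based and count the header as row 1.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"row {r}, {c}: {m}" for r, c, m in self.problems[:10])
        more = "" if len(self.problems) <= 10 else f" (+{len(self.problems) - 10} more)"
        super().__init__(f"{len(self.problems)} invalid cell(s): {lines}{more}")


class ConfigError(DentalAgeError):
    """A score table, conversion table, model, or generator config is invalid."""


class OutOfRangeError(DentalAgeError):
    """A value falls outside the studied range (e.g. age not in [3, 11))."""


class UnscorableToothError(DentalAgeError):
    """Both a left mandibular tooth and its contralateral are absent/unreadable."""

    def __init__(self, child_id, tooth):
        self.child_id = child_id
        self.tooth = tooth
        super().__init__(
            f"tooth {tooth} unscorable for child {child_id!r}: "
            f"left and contralateral both absent"
        )


class OutOfTableError(DentalAgeError):
    """A maturity score or age falls outside the conversion table's knots."""


class NonInvertibleError(DentalAgeError):
    """An age lies at or beyond a prediction model's asymptotes."""


class InsufficientDataError(DentalAgeError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(DentalAgeError):
    """Data with zero variance where variance is required (SST=0, constant ranks...)."""
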