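"""Error taxonomy for chip data validation and analysis.

Every malformed input raises a named error from this hierarchy; nothing is
silently coerced.
"""


class ChipDataError(ValueError):
    """Base class for all panelqc data errors."""


class LayoutError(ChipDataError):
    """Chip layout violates its invariants (duplicate wells, bad indices)."""


class FormatError(ChipDataError):
    """A file or token does not match the documented format."""


class RangeError(ChipDataError):
    """A numeric value lies outside its physically admissible range."""


class ConsistencyError(ChipDataError):
    """Cross-references between tables disagree (well/assay vs layout)."""


class ConfigError(ChipDataError):
    """A configuration value violates a Config invariant."""


class FitError(ChipDataError):
    """A regression/fit has too few or degenerate points."""


class UndefinedMetricError(ChipDataError):
    """A metric's denominator is empty; the value does not exist."""


class PartialReportError(ChipDataError):
    """A composite report is missing constituent analyses.

    ``missing`` lists the absent field names.
    """

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing report constituents: {', '.join(self.missing)}")


class NormalizationError(ChipDataError):
    """A required normalization factor was not detected in the sample."""


class DegenerateProfileError(ChipDataError):
    """A profile row cannot be processed (all-missing or zero variance)."""
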