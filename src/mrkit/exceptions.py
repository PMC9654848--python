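"""Exception hierarchy for mrkit.

Everything derives from :class:`MrkitError` so callers can catch the whole
family with one clause; the finer-grained classes distinguish user
configuration mistakes from data problems and statistical preconditions.
"""


class MrkitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MrkitError):
    """A user-supplied configuration is inconsistent or incomplete
    (missing mandatory column, finite clumping window without positions,
    unknown outcome label, invalid simulation ranges)."""


class SumstatsError(MrkitError):
    """Summary-statistic rows violated their invariants and the caller
    asked for strict parsing."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


class DegenerateFrequencyError(MrkitError, ValueError):
    """Effect-allele frequency of exactly 0 or 1 makes the Z-score
    conversion (and the explained-variance formula) undefined."""


class UnsupportedAlleleError(MrkitError, ValueError):
    """An allele outside {A, C, G, T} was encountered where strand logic
    is required."""


class InvalidStandardizationError(MrkitError, ValueError):
    """A per-SNP explained variance >= 1, impossible for a standardized
    trait; the exposure betas are not on a standardized scale."""


class InsufficientInstrumentsError(MrkitError, ValueError):
    """Fewer instruments than the estimator's minimum (2 for IVW, 3 for
    MR-Egger and the weighted median, 4 for MR-PRESSO)."""


class InsufficientSampleError(MrkitError, ValueError):
    """Exposure sample size too small for the F-statistic (n <= 2)."""


class PipelineAbort(MrkitError, RuntimeError):
    """A pipeline stage depleted the instrument set below the minimum
    needed downstream; the message names the stage."""
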