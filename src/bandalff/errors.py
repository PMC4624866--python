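"""Exception hierarchy shared across the pipeline stages."""


class BandAlffError(Exception):
    """Base class for all package errors."""


class DomainError(BandAlffError, ValueError):
    """An argument lies outside the operation's domain (bad count, negative scale...)."""


class FormatError(BandAlffError, ValueError):
    """A file or array does not have the expected structure (wrong dimensionality, grid mismatch)."""


class DegenerateInputError(BandAlffError, ValueError):
    """Input carries no usable variation (constant series, zero-variance design, zero global mean)."""


class InvalidBandError(BandAlffError, ValueError):
    """A frequency band lies outside (0, Nyquist] or covers no spectral bin."""


class EmptyBandError(InvalidBandError):
    """A band contains no frequency bin at the given resolution."""


class CollinearityError(BandAlffError, ValueError):
    """Covariate matrix is rank deficient."""


class UnattainableAlphaError(BandAlffError, ValueError):
    """Requested family-wise alpha cannot be met by any cluster-extent threshold."""


class ConfigError(BandAlffError, ValueError):
    """Run configuration failed validation; message names the offending field."""
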