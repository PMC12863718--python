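"""Exception hierarchy shared across the pipeline stages."""


class Tric4Error(Exception):
    """Base class for all package-specific errors."""


# -- haplotype calling ------------------------------------------------------

class MissingSiteError(Tric4Error):
    """A required variant site is absent from the input."""


class AlleleMismatchError(Tric4Error):
    """An observed allele is neither the configured ref nor alt."""


class PhasingError(Tric4Error):
    """Genotype cannot be resolved into haplotypes without phase information."""


class NoDataError(Tric4Error):
    """An operation received an empty input where data is required."""


class LabelParseError(Tric4Error):
    """A genotype label cannot be decomposed into two chromosome labels."""


# -- coverage / copy number -------------------------------------------------

class WindowMismatchError(Tric4Error):
    """Coverage records do not line up with the window definitions."""


class NormalizationError(Tric4Error):
    """Flank coverage is unusable as a normalization baseline."""


class DomainError(Tric4Error):
    """A numeric input lies outside the operation's domain."""


class InconsistentCallError(Tric4Error):
    """Copy-number evidence is internally contradictory."""


# -- association ------------------------------------------------------------

class DegenerateTableError(Tric4Error):
    """Contingency table has fewer than two informative rows or columns."""


class LabelError(Tric4Error):
    """A queried label does not exist in the table."""


# -- survival ---------------------------------------------------------------

class MissingDataError(Tric4Error):
    """A subject lacks required time/event or covariate data."""


class EmptyFrameError(Tric4Error):
    """Filtering removed every subject."""


class ConvergenceError(Tric4Error):
    """Model fitting failed to converge."""


# -- expression -------------------------------------------------------------

class LibrarySizeError(Tric4Error):
    """A sample has zero library size."""


class DesignError(Tric4Error):
    """The design matrix is rank-deficient."""


# -- simulation -------------------------------------------------------------

class ConfigError(Tric4Error):
    """A simulation configuration value is invalid."""
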