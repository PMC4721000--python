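"""Exception and warning types raised across the pipeline."""

from __future__ import annotations


class OncogramError(Exception):
    """Base class for all package errors."""


class InvalidInputError(OncogramError, ValueError):
    """An input value violates a precondition (e.g. total cell count 0)."""


class InvalidPairingError(OncogramError, ValueError):
    """Treated and untreated fractions belong to different patients."""


class DegenerateBaselineError(OncogramError, ValueError):
    """Untreated death fraction is zero; the ratio is undefined."""


class InsufficientCohortError(OncogramError, ValueError):
    """Fewer than the minimum number of ratios to compute percentiles."""


class UncodableCaseError(OncogramError, ValueError):
    """No clinical evaluation could be attributed to a regimen."""


class FixtureIntegrityError(OncogramError, RuntimeError):
    """Bundled study fixture failed checksum or invariant validation."""


class ReproductionMismatchError(OncogramError, RuntimeError):
    """Internally inconsistent reproduction of the study analysis."""


class ConfigError(OncogramError, ValueError):
    """Simulation or run configuration is invalid or uncalibratable."""


class UnmappedRegimenWarning(UserWarning):
    """A received component combination matches no tested condition."""
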