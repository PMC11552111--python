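"""Exception hierarchy for the imscore pipeline.

Every stage raises a subclass of :class:`ImscoreError` so the CLI can tag
failures with the stage that produced them.
"""


class ImscoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ImscoreError):
    """Invalid configuration value (probability out of range, n <= 0, ...)."""


class MissingDataError(ImscoreError):
    """A required covariate or metadata field is absent; nothing is imputed."""


class ValidationError(ImscoreError):
    """An input object violates its invariants (negative dose, bad panel, ...)."""


class PlacementError(ImscoreError):
    """A reference ROI cannot be placed (structure absent or too small)."""


class GeometryError(ImscoreError):
    """Phantom geometry is inconsistent (lesion does not fit, radii too small)."""


class ScoreInapplicableError(ValidationError):
    """Requested score cannot be computed for this modality.

    The Deauville score needs liver and mediastinal blood-pool references,
    which a head-only PET/MR acquisition does not provide.
    """


class ReconstructionError(ImscoreError):
    """Printed marginals and anchor metric do not yield a consistent 2x2 table."""


class ConvergenceError(ImscoreError):
    """An iterative fit failed to converge (outside the monotone-likelihood case,
    which is flagged on the fit object rather than raised)."""
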