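"""Exception hierarchy for the alignment pipeline.

Each failure mode the pipeline can hit in batch processing maps to a
distinct exception so the CLI can log per-case failures and continue.
"""


class HeadAlignError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HeadAlignError):
    """Invalid parameter combination (e.g. a landmark outside the grid)."""


class VolumeIOError(HeadAlignError):
    """Unreadable file or inconsistent series geometry."""


class LandmarkNotFoundError(HeadAlignError):
    """A landmark label is empty or detection found the wrong number of
    components -- the machine analogue of the failure modes seen on
    deformed or absent anatomy (fractures, labyrinthectomy, infants)."""


class DegenerateGeometryError(HeadAlignError):
    """Landmark geometry does not determine a unique rotation
    (coincident or collinear points, gimbal-adjacent decomposition)."""


class DegenerateStatisticsError(HeadAlignError):
    """A statistical test is undefined on the given sample
    (all-zero paired differences, constant sample, zero between-subject
    variance)."""
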