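"""Exception hierarchy for epiget.

All errors raised by the package derive from :class:`EpigetError` so callers
can catch package failures with a single except clause; the subclasses keep
the distinct failure modes (degenerate markers, partitions too small to
correlate, numerically singular eigenproblems, exhausted simulation pools,
out-of-domain centering parameters) separately catchable.
"""


class EpigetError(Exception):
    """Base class for all epiget errors."""


class InvalidInputError(EpigetError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateMarkerError(EpigetError):
    """A marker has zero variance within a phenotype partition."""

    def __init__(self, marker_id: str, partition: str):
        self.marker_id = marker_id
        self.partition = partition
        super().__init__(
            f"marker {marker_id!r} has zero variance among {partition}; "
            "drop it upstream or pass drop_degenerate=True"
        )


class PartitionTooSmallError(EpigetError):
    """Fewer than two cases or two controls."""


class NumericalRankError(EpigetError):
    """The weighted correlation sum d*S1 + (n-d)*S0 is numerically singular.

    Usually caused by duplicated or perfectly collinear markers; filter the
    marker set and retry.
    """


class SingularFitError(EpigetError):
    """A regression design matrix is collinear."""


class InsufficientCasesError(EpigetError):
    """The simulation pool hit its cap before enough cases/controls accrued."""

    def __init__(self, needed_cases, got_cases, needed_controls, got_controls,
                 pool_size, prevalence):
        self.prevalence = prevalence
        super().__init__(
            f"pool cap reached at {pool_size} subjects with achieved prevalence "
            f"{prevalence:.4g}: collected {got_cases}/{needed_cases} cases and "
            f"{got_controls}/{needed_controls} controls"
        )


class AngleDomainError(EpigetError):
    """p is too large relative to n1+n2 for the centering angles to exist."""
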