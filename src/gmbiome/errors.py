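"""Exception hierarchy shared across the package.

Every error raised deliberately by gmbiome derives from :class:`GmbiomeError`
so callers can catch the package's failures without masking programming bugs.
"""


class GmbiomeError(Exception):
    """Base class for all errors raised by gmbiome."""


class InvalidArgumentError(GmbiomeError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(GmbiomeError, ValueError):
    """Input is structurally valid but statistically degenerate (e.g. a
    zero-variance column, a constant covariate gradient)."""


class FitFailureError(GmbiomeError, RuntimeError):
    """A numerical fit failed to converge or is not identifiable."""


class CollinearityError(FitFailureError):
    """A design matrix is rank deficient; carries the aliased term names."""

    def __init__(self, aliased, message=None):
        self.aliased = list(aliased)
        super().__init__(
            message or f"rank-deficient design; aliased terms: {self.aliased}"
        )


class MissingLeafError(GmbiomeError, KeyError):
    """Taxa referenced by a community are absent from the phylogeny."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"taxa absent from tree: {self.missing}")


class EmptyResultError(GmbiomeError, ValueError):
    """An operation removed every sample (or every feature)."""
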