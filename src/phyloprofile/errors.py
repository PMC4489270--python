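"""Exception hierarchy for the profiling pipeline."""


class PhyloProfileError(Exception):
    """Base class for all errors raised by this package."""


class BlastParseError(PhyloProfileError):
    """A BLAST tabular line could not be parsed."""


class MatrixError(PhyloProfileError):
    """A score matrix violates a structural contract."""


class NormalizationError(PhyloProfileError):
    """A protein cannot be normalized (missing or zero self-score)."""


class DegenerateProfileError(PhyloProfileError):
    """A profile or null distribution has zero variance."""
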