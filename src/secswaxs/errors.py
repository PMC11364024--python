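"""Exception hierarchy.

Every stage raises a subclass of :class:`SecSwaxsError` so pipeline callers
can attribute a failure to a stage without string matching.
"""


class SecSwaxsError(Exception):
    """Base class for all package errors."""


class ParseError(SecSwaxsError):
    """Malformed input file (``.dat``, PDB, traces CSV)."""


class GridError(SecSwaxsError):
    """q grids differ where an exact match is required."""


class SelectionError(SecSwaxsError):
    """Frame selection failed (all frames rejected, bad buffer window)."""


class MergeError(SecSwaxsError):
    """SAXS/WAXS overlap window insufficient or disjoint."""


class AlignmentError(SecSwaxsError):
    """No usable elution peak found during trace alignment."""


class GuinierError(SecSwaxsError):
    """No valid Guinier window in the curve."""


class IFTError(SecSwaxsError):
    """Indirect Fourier transform system is ill-conditioned."""


class SequenceError(SecSwaxsError):
    """Amino-acid sequence contains an unknown residue code."""


class IllConditionedError(SecSwaxsError):
    """UV/dRI channel pair cannot separate the two species."""


class StoichiometryError(SecSwaxsError):
    """No integer stoichiometry reproduces the observed I0.

    Carries the full misfit table in ``misfits`` for diagnostics.
    """

    def __init__(self, message, misfits=None):
        super().__init__(message)
        self.misfits = misfits


class FitError(SecSwaxsError):
    """Profile fitting impossible (degenerate sigma, empty window)."""


class SizeError(SecSwaxsError):
    """Too many scattering centers for the O(n^2) Debye sum."""


class GenerationError(SecSwaxsError):
    """Self-avoiding-walk chain generation failed; reports the seed."""
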