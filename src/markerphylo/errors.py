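"""Exception hierarchy.

All package errors derive from :class:`MarkerPhyloError` so callers (and the
CLI) can distinguish bad input (exit code 2) from a run that is well-formed
but unsatisfiable (exit code 3).
"""


class MarkerPhyloError(Exception):
    """Base class for all package errors."""


class InputError(MarkerPhyloError):
    """Malformed or invalid user input (bad file, bad argument)."""


class FormatError(InputError):
    """A structured file (HMMER3, FASTA, checkpoint) could not be parsed."""


class ValidationError(MarkerPhyloError):
    """An in-memory object violates its invariants."""


class CheckpointMismatchError(MarkerPhyloError):
    """Checkpoint was produced under different search parameters."""


class UnsatisfiableRunError(MarkerPhyloError):
    """The run is well-formed but cannot produce a result (e.g. no markers)."""
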