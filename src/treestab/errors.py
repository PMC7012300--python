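"""Exception hierarchy.

Every error raised by this package derives from :class:`TreestabError`, so
callers (and the CLI) can catch one type. The finer-grained classes mirror
the distinct failure modes of the pipeline: malformed input files, ragged
alignments, unusable distance data, bad arguments, unknown labels, and the
deliberately undefined stability of two-leaf clades.
"""


class TreestabError(Exception):
    """Base class for all errors raised by treestab."""


class FormatError(TreestabError):
    """A file violates its format contract (duplicate labels, bad characters, ...)."""


class AlignmentError(TreestabError):
    """Sequences that should form an alignment have unequal lengths."""


class DataError(TreestabError):
    """Data is structurally valid but unusable (e.g. zero comparable sites)."""


class InputError(TreestabError, ValueError):
    """An argument violates an operation's precondition."""


class LabelLookupError(TreestabError, KeyError):
    """A requested sequence/leaf label does not exist in the target object."""


class StabilityUndefinedError(TreestabError):
    """Stability (Ps) is undefined for clades of fewer than three sequences.

    A two-leaf rooted subtree has a single possible topology, so its modal
    bootstrap frequency is trivially 100% and carries no information.
    """
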