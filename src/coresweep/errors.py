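"""Exception hierarchy shared across the package.

Every error raised on user input derives from :class:`CoresweepError`, so
callers (and the CLI) can catch one type.  The subclasses distinguish the
three failure families the pipeline meets in practice: malformed files,
table/tree disagreement, and mathematically undefined requests.
"""


class CoresweepError(Exception):
    """Base class for all package errors."""


class FormatError(CoresweepError):
    """A file does not conform to the expected format."""


class CongruenceError(CoresweepError):
    """Feature table and phylogeny disagree (taxa missing from the tree)."""


class UndefinedValueError(CoresweepError):
    """A metric was requested on input for which it is mathematically undefined
    (e.g. Shannon entropy of an empty sample)."""


class ParameterError(CoresweepError):
    """A parameter is outside its valid domain."""
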