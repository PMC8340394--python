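"""Exception hierarchy for dtlor."""


class DtlorError(Exception):
    """Base class for all dtlor errors."""


class ParseError(DtlorError):
    """A newick string could not be parsed into a valid rooted tree."""


class InputError(DtlorError):
    """An association table or instance is inconsistent with its trees."""


class NotBinaryError(DtlorError):
    """A binary-only solver was handed a multifurcating tree.

    Multifurcating gene trees are handled by :mod:`dtlor.nonbinary`.
    """


class ArityCapError(DtlorError):
    """A multifurcation exceeds the configured resolution cap."""


class GuardError(DtlorError):
    """A brute-force oracle was asked for an instance above its size guard."""
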