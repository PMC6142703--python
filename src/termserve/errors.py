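"""Exception hierarchy shared across the engine.

Every error a caller is expected to handle derives from
:class:`TermserveError`; the CLI maps these to exit code 1 with a
one-line message.
"""


class TermserveError(Exception):
    """Base class for all engine errors."""


# -- code system / store ----------------------------------------------------

class CycleError(TermserveError):
    """The is-a graph contains a cycle; ``cycle`` names one offending path."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("is-a cycle detected: " + " -> ".join(self.cycle))


class SystemNotFound(TermserveError):
    pass


class CodeNotFound(TermserveError):
    pass


class ClosureNotFound(TermserveError):
    pass


class DanglingReferenceError(TermserveError):
    """Relationships referencing concepts absent from the record."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(
            "relationships reference unknown concepts: %s" % ", ".join(self.offenders)
        )


# -- RF2 --------------------------------------------------------------------

class MissingCoreFile(TermserveError):
    pass


class ParseError(TermserveError):
    def __init__(self, message, file=None, line=None):
        self.file = file
        self.line = line
        loc = f" ({file}:{line})" if file else ""
        super().__init__(message + loc)


# -- ECL --------------------------------------------------------------------

class EclSyntaxError(TermserveError):
    def __init__(self, message, position):
        self.position = position
        super().__init__(f"{message} at position {position}")


class UnsupportedEclFeature(TermserveError):
    pass


# -- OWL --------------------------------------------------------------------

class UnsupportedAxiomError(TermserveError):
    pass


class MissingIriError(TermserveError):
    pass


class ImportResolutionError(TermserveError):
    pass


# -- value sets -------------------------------------------------------------

class UnsupportedImplicitValueSet(TermserveError):
    pass


class ImportCycleError(TermserveError):
    pass


class ValueSetNotFound(TermserveError):
    pass


# -- syndication ------------------------------------------------------------

class FeedParseError(TermserveError):
    pass


class ContentUnavailable(TermserveError):
    pass


class IntegrityError(TermserveError):
    pass


class IncompatibleIndexError(TermserveError):
    pass
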