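"""Exception types shared across foldsense modules."""


class FoldsenseError(Exception):
    """Base class for all foldsense errors."""


class ParameterError(FoldsenseError, ValueError):
    """A parameter violates a documented precondition."""


class UndefinedIndexError(FoldsenseError, ValueError):
    """A FRET index is undefined (zero donor signal)."""


class ConvergenceError(FoldsenseError, RuntimeError):
    """An iterative procedure failed to converge."""


class MissingAtomsError(FoldsenseError, KeyError):
    """A structure lacks atoms required by an operation."""
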