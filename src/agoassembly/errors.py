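"""Exception hierarchy shared across the toolkit."""


class AgoAssemblyError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(AgoAssemblyError, ValueError):
    """Input violates a structural precondition (alphabet, length, ids...)."""


class FormatError(AgoAssemblyError):
    """A file failed to parse; message names the file (and line when known)."""


class DesignInfeasibleError(AgoAssemblyError):
    """No candidate satisfies the design rules; carries per-candidate reports."""

    def __init__(self, message, reports=None):
        super().__init__(message)
        self.reports = reports or []


class InfeasiblePairError(AgoAssemblyError):
    """No primer length combination balances the pair; carries best |dTm|."""

    def __init__(self, message, best_delta_tm=None):
        super().__init__(message)
        self.best_delta_tm = best_delta_tm
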