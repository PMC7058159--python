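"""Exception hierarchy shared across the package."""


class CanarySeqError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(CanarySeqError):
    """Invalid alignment content (ragged rows, bad characters, duplicate ids)."""


class NewickError(CanarySeqError):
    """Malformed Newick input or invalid tree structure."""


class TreeError(CanarySeqError):
    """Invalid tree operation (unknown leaf, too few leaves, leaf-set mismatch)."""


class SaturationError(CanarySeqError):
    """Observed divergence beyond the domain of a distance correction."""


class EngineError(CanarySeqError):
    """Failure of an external tree-inference engine; carries diagnostics."""

    def __init__(self, message: str, *, command: str | None = None,
                 stdout: str = "", stderr: str = ""):
        super().__init__(message)
        self.command = command
        self.stdout = stdout
        self.stderr = stderr
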