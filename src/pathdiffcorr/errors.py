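"""Exception hierarchy shared across the package."""


class PathDiffCorrError(Exception):
    """Base class for all package errors."""


class FormatError(PathDiffCorrError):
    """An input file violates its expected tabular/XML format."""


class ValidationError(PathDiffCorrError):
    """An input is well-formed but violates a semantic constraint."""


class DegenerateFitError(PathDiffCorrError):
    """Least-squares line is undefined (constant x or too few points)."""


class ChunkExecutionError(PathDiffCorrError):
    """A worker chunk failed; carries the chunk index and the failing item key."""

    def __init__(self, chunk_index: int, item_key, cause: str):
        self.chunk_index = chunk_index
        self.item_key = item_key
        self.cause = cause
        super().__init__(
            f"chunk {chunk_index} failed on item {item_key!r}: {cause}"
        )

    def __reduce__(self):
        return (self.__class__, (self.chunk_index, self.item_key, self.cause))
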