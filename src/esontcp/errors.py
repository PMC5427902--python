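"""Exception types shared across the package."""


class EsontcpError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(EsontcpError):
    """A structure contains no voxels (empty mask or empty dose map)."""


class DVHParseError(EsontcpError):
    """A DVH text file is malformed; the message names the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GridMismatchError(EsontcpError):
    """A mask and a voxel dose map are not defined on the same grid."""


class ModelConfigError(EsontcpError):
    """An NTCP model is missing required parameters or is misconfigured."""
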