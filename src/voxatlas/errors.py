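"""Exception hierarchy.

Everything raised on bad data inherits from :class:`VoxatlasError` so the
command-line layer can map it to a non-zero exit status distinct from usage
errors.
"""


class VoxatlasError(Exception):
    """Base class for all voxatlas data and contract errors."""


class GridMismatchError(VoxatlasError, ValueError):
    """Two volumes were combined that do not share dims and spacing."""


class DataError(VoxatlasError, ValueError):
    """Input data violates a precondition (missing file, bad values, ...)."""
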