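"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors are handled by the argument
parser (exit 2); :class:`InputError`/:class:`FormatError`/:class:`SchemaError`
map to exit 3; :class:`ExtractionError` maps to exit 4.
"""

from __future__ import annotations


class TfccMorphError(Exception):
    """Base class for all package-specific errors."""


class InputError(TfccMorphError):
    """A required input (file, table, column) is missing or unreadable."""


class FormatError(TfccMorphError):
    """A file exists but its contents violate the expected format."""


class SchemaError(TfccMorphError):
    """Label codes or column names do not match the declared schema."""


class GeometryError(TfccMorphError):
    """Degenerate or infeasible geometry (collinear points, patch too large)."""


class ZeroVarianceError(TfccMorphError):
    """A statistic is undefined because the data carry no variance."""


class CollinearityError(TfccMorphError):
    """Predictor matrix is rank deficient."""

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        super().__init__(
            "predictor matrix is rank deficient; dependent columns: "
            + ", ".join(self.columns)
        )


class ExtractionError(TfccMorphError):
    """The footprint pipeline produced an empty result at some stage."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(f"extraction failed at stage '{stage}'"
                         + (f": {message}" if message else ""))
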