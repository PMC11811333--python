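"""Error taxonomy.

Every user-facing failure mode carries a category name that the CLI prints
verbatim, so shell users (and scripts parsing stderr) can tell a bad contour
from a bad DICOM series without reading a traceback.
"""


class TumorSegError(Exception):
    """Base class for all package errors."""

    category = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.category}: {super().__str__()}"


class DataQualityError(TumorSegError):
    """Non-finite voxels or otherwise unusable image data."""

    category = "data-quality error"


class ParameterError(TumorSegError):
    """Invalid numeric parameter (weights, scales, iteration counts)."""

    category = "parameter error"


class GridError(TumorSegError):
    """Mismatched shapes/spacings between fields that must share a grid."""

    category = "grid error"


class EmptyFrontError(TumorSegError):
    """A level-set field with no sign change (empty or full interior)."""

    category = "empty or full front"


class ContourError(TumorSegError):
    """Degenerate or self-intersecting initial contour."""

    category = "contour error"


class SeedError(TumorSegError):
    """Initial contour rasterizes to an empty seed region."""

    category = "seed error"


class GeometryError(TumorSegError):
    """Contour or mask geometry incompatible with the image volume."""

    category = "geometry error"


class SeriesError(TumorSegError):
    """Inconsistent DICOM series (mixed UIDs, missing geometry tags)."""

    category = "series error"


class StatsError(TumorSegError):
    """Region statistics requested over an empty interior or exterior."""

    category = "stats error"


class SpecError(TumorSegError):
    """Invalid phantom specification (radius nesting, negative noise...)."""

    category = "spec error"


class FeatureError(TumorSegError):
    """Tumor features requested for an empty mask."""

    category = "feature error"


class SampleSizeError(TumorSegError):
    """Too few measurement pairs for an agreement analysis."""

    category = "sample-size error"
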