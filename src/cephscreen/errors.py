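"""Exception types shared across the package."""


class CephscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CephscreenError, ValueError):
    """A generator specification violates its invariants."""


class DegenerateGeometryError(CephscreenError, ValueError):
    """Coincident points or zero-length line where geometry is required."""


class OutOfBoundsError(CephscreenError, ValueError):
    """A requested coordinate or object lies outside the voxel grid."""


class InvalidRangeError(CephscreenError, ValueError):
    """An empty or inverted craniocaudal measurement range."""


class MissingLandmarkError(CephscreenError, KeyError):
    """A mandatory anatomical landmark is absent."""

    def __init__(self, name: str):
        self.landmark = name
        super().__init__(f"missing mandatory landmark: {name!r}")


class DegenerateSampleError(CephscreenError, ValueError):
    """A sample is constant / too small for the requested statistic."""


class DegenerateTableError(CephscreenError, ValueError):
    """A contingency table with a zero margin."""


class DegenerateLabelsError(CephscreenError, ValueError):
    """Binary labels with one class absent."""


class SchemaError(CephscreenError, KeyError):
    """A required column is missing from a cohort table."""


class CollinearityError(CephscreenError, ValueError):
    """Exactly collinear design columns in a regression."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design column {column!r} is collinear with the others")


class CycleError(CephscreenError, RuntimeError):
    """Stepwise selection failed to terminate within the step limit."""


class MissingCellError(CephscreenError, ValueError):
    """Incomplete subjects-by-raters measurement table."""


class UnattainableTargetError(CephscreenError, ValueError):
    """A sensitivity/specificity target is unreachable on the empirical curve."""
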