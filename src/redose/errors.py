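"""Exception hierarchy for the toolkit.

Every error a caller can sensibly catch derives from :class:`RedoseError`,
so pipeline drivers can distinguish toolkit failures from programming bugs.
"""


class RedoseError(Exception):
    """Base class for all toolkit errors."""


class GeometryError(RedoseError):
    """Grids or masks on incompatible geometries were combined."""


class TransformError(RedoseError):
    """A spatial transform is invalid (e.g. non-invertible affine)."""


class ContractError(RedoseError):
    """A dose-kind contract was violated (e.g. resampling an EQD2 grid)."""


class ParameterError(RedoseError):
    """A radiobiological or algorithmic parameter is out of range."""


class MalformedContourError(RedoseError):
    """A planar contour has fewer than 3 vertices or inconsistent slices."""


class StructureNotFoundError(RedoseError):
    """A named structure referenced by config or a constraint is missing."""

    def __init__(self, name: str, available: list[str] | None = None):
        self.name = name
        self.available = list(available or [])
        msg = f"structure {name!r} not found"
        if self.available:
            msg += f"; available: {', '.join(sorted(self.available))}"
        super().__init__(msg)


class FormatError(RedoseError):
    """A file is not in a supported dialect of its format."""
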