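"""Three-dimensional airway morphometry on binary voxel masks.

Measures the airway parameters used for screening: the three sagittal
diameters (IPAS on the B-Go line, MPAS at the uvula tip parallel to B-Go,
SPAS halfway between uvula tip and posterior nasal spine parallel to B-Go),
axial cross-sectional areas at those levels, the minimal axial area ``A_min``
and the airway volume ``V_PAS`` between the posterior-nasal-spine and hyoid
planes, and the maximal sagittal-plane area ``A_Sag`` in the same range.

Conventions (documented design choices):

* "Transversal" planes are axial voxel slices, i.e. perpendicular to the
  inferior-superior axis, matching conventional CT axial reformats.
* The bounding Pns and Hy planes are the axial planes through the z
  coordinates of the Pns and Hy landmarks.
* The midsagittal plane is the sagittal voxel slab containing the median x
  of the S, N and Me landmarks.
* A sagittal diameter is the longest contiguous airway run along the
  measurement line (a diameter spanning two disjoint lumina would be
  anatomically meaningless), sampled at quarter-voxel steps.
* Level planes use nearest-slice selection without sub-voxel interpolation;
  a tie between two equidistant slices resolves to the inferior slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InvalidRangeError,
    OutOfBoundsError,
)
from .landmarks import LandmarkSet


@dataclass
class AirwayMask:
    """Binary airway voxel grid.

    ``data`` has shape (nx, ny, nz) with axes x: left->right,
    y: posterior->anterior, z: inferior->superior. ``spacing`` is the per-axis
    voxel size in mm and ``origin`` the world coordinate of the centre of
    voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not self.data.any():
            raise ValueError("airway mask contains no airway voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def index_at(self, axis: int, coord: float) -> int:
        """Nearest voxel index along ``axis``; ties resolve to the lower index."""
        o, s = self.origin[axis], self.spacing[axis]
        n = self.data.shape[axis]
        f = (coord - o) / s
        if f < -0.5 or f > n - 0.5:
            raise OutOfBoundsError(
                f"coordinate {coord:.3f} mm outside grid on axis {axis} "
                f"(extent {o - 0.5 * s:.3f}..{o + (n - 0.5) * s:.3f})"
            )
        k = int(np.ceil(f - 0.5))
        return min(max(k, 0), n - 1)

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class MidsagittalLine:
    """A measurement line in midsagittal-plane coordinates (y, z)."""

    anchor: np.ndarray      # (y, z) in mm
    direction: np.ndarray   # unit vector (dy, dz)
    x_mm: float             # sagittal slab in which the line is measured
    name: str = ""

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise DegenerateGeometryError(f"line {self.name!r} has zero direction")
        self.direction = d / norm


def measurement_lines(landmarks: LandmarkSet) -> dict[str, MidsagittalLine]:
    """Construct the IPAS, MPAS and SPAS measurement lines.

    IPAS runs through B and Go; MPAS through the uvula tip (Ut) parallel to
    B-Go; SPAS through the midpoint of Ut and Pns parallel to B-Go. All lines
    live in the midsagittal plane (coordinates are (y, z) after dropping x).
    """
    landmarks.require("B", "Go", "Ut", "Pns", "S", "N", "Me")
    x_mid = landmarks.midsagittal_x
    b = landmarks["B"][1:]
    go = landmarks["Go"][1:]
    ut = landmarks["Ut"][1:]
    pns = landmarks["Pns"][1:]
    d = go - b
    if np.linalg.norm(d) == 0:
        raise DegenerateGeometryError("B and Go coincide in the midsagittal plane")
    return {
        "IPAS": MidsagittalLine((b + go) / 2.0, d, x_mid, "IPAS"),
        "MPAS": MidsagittalLine(ut, d, x_mid, "MPAS"),
        "SPAS": MidsagittalLine((ut + pns) / 2.0, d, x_mid, "SPAS"),
    }


def _line_grid_range(mask: AirwayMask, line: MidsagittalLine) -> tuple[float, float]:
    """Parameter interval of the line inside the grid's (y, z) extent."""
    t_lo, t_hi = -np.inf, np.inf
    for axis, (p0, d) in zip((1, 2), zip(line.anchor, line.direction)):
        o, s = mask.origin[axis], mask.spacing[axis]
        n = mask.data.shape[axis]
        lo, hi = o - 0.5 * s, o + (n - 0.5) * s
        if abs(d) < 1e-12:
            if not (lo <= p0 <= hi):
                return (np.inf, -np.inf)
            continue
        ta, tb = (lo - p0) / d, (hi - p0) / d
        t_lo = max(t_lo, min(ta, tb))
        t_hi = min(t_hi, max(ta, tb))
    return (t_lo, t_hi)


def sagittal_diameter(mask: AirwayMask, line: MidsagittalLine) -> float:
    """Sagittal airway diameter (mm) along a measurement line.

    Returns the length of the longest contiguous airway run along the line,
    sampled at quarter-voxel steps within the midsagittal slab; 0.0 when the
    line misses the airway entirely.
    """
    ix = mask.index_at(0, line.x_mm)
    t_lo, t_hi = _line_grid_range(mask, line)
    if not t_lo < t_hi:
        raise OutOfBoundsError("measurement line lies outside the voxel grid")
    step = min(mask.spacing[1], mask.spacing[2]) / 4.0
    ts = np.arange(t_lo, t_hi + step / 2, step)
    ys = line.anchor[0] + ts * line.direction[0]
    zs = line.anchor[1] + ts * line.direction[1]

    oy, sy = mask.origin[1], mask.spacing[1]
    oz, sz = mask.origin[2], mask.spacing[2]
    ny, nz = mask.data.shape[1], mask.data.shape[2]
    iy = np.ceil((ys - oy) / sy - 0.5).astype(int)
    iz = np.ceil((zs - oz) / sz - 0.5).astype(int)
    ok = (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
    inside = np.zeros(ts.shape, dtype=bool)
    inside[ok] = mask.data[ix, iy[ok], iz[ok]]

    if not inside.any():
        return 0.0
    # longest run of consecutive True samples
    padded = np.concatenate(([False], inside, [False])).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    run_lengths = edges[1::2] - edges[0::2]
    return float(run_lengths.max() * step)


def axial_area(mask: AirwayMask, z: float) -> float:
    """Airway cross-sectional area (mm^2) in the axial slice nearest ``z``."""
    k = mask.index_at(2, z)
    count = int(mask.data[:, :, k].sum())
    return count * mask.spacing[0] * mask.spacing[1]


def _slices_in_range(mask: AirwayMask, z_top: float, z_bottom: float) -> np.ndarray:
    if z_top < z_bottom:
        raise InvalidRangeError(
            f"empty craniocaudal range: z_top={z_top:.2f} < z_bottom={z_bottom:.2f}"
        )
    mask.index_at(2, z_top)
    mask.index_at(2, z_bottom)
    zs = mask.axis_coords(2)
    ks = np.flatnonzero((zs >= z_bottom) & (zs <= z_top))
    if ks.size == 0:
        # range narrower than one voxel: fall back to the nearest single slice
        ks = np.asarray([mask.index_at(2, 0.5 * (z_top + z_bottom))])
    return ks


def min_axial_area(mask: AirwayMask, z_top: float, z_bottom: float) -> tuple[float, float]:
    """Minimal axial airway area between two planes.

    Returns ``(A_min in mm^2, z of the most inferior minimiser in mm)``.
    Slices with zero airway inside the range yield ``A_min = 0``.
    """
    ks = _slices_in_range(mask, z_top, z_bottom)
    areas = mask.data[:, :, ks].sum(axis=(0, 1)) * mask.spacing[0] * mask.spacing[1]
    i = int(np.argmin(areas))  # argmin takes the first (most inferior) minimiser
    zs = mask.axis_coords(2)
    return float(areas[i]), float(zs[ks[i]])


def airway_volume(mask: AirwayMask, z_top: float, z_bottom: float) -> float:
    """Airway volume (cm^3) summed over axial slices with centre in range."""
    ks = _slices_in_range(mask, z_top, z_bottom)
    count = int(mask.data[:, :, ks].sum())
    return count * mask.voxel_volume / 1000.0


def max_sagittal_area(mask: AirwayMask, z_top: float, z_bottom: float) -> float:
    """Maximal airway area (mm^2) over sagittal slices, restricted to the z range."""
    ks = _slices_in_range(mask, z_top, z_bottom)
    counts = mask.data[:, :, ks].sum(axis=(1, 2))
    return float(counts.max() * mask.spacing[1] * mask.spacing[2])


@dataclass
class AirwayParams:
    """Bundle of all three- and two-dimensional airway measurements."""

    IPAS: float        # mm
    MPAS: float        # mm
    SPAS: float        # mm
    A_IAS: float       # mm^2
    A_MAS: float       # mm^2
    A_SPAS: float      # mm^2
    A_min: float       # mm^2
    z_of_A_min: float  # mm
    V_PAS: float       # cm^3
    A_Sag: float       # mm^2

    def to_row(self) -> dict[str, float]:
        return {
            "IPAS": self.IPAS, "MPAS": self.MPAS, "SPAS": self.SPAS,
            "A_IAS": self.A_IAS, "A_MAS": self.A_MAS, "A_SPAS": self.A_SPAS,
            "A_min": self.A_min, "z_of_A_min": self.z_of_A_min,
            "V_PAS": self.V_PAS, "A_Sag": self.A_Sag,
        }


def compute_airway_params(mask: AirwayMask, landmarks: LandmarkSet) -> AirwayParams:
    """Compute every airway parameter from a mask and its landmark set.

    The mask and landmarks must share a frame, and the Pns landmark must lie
    strictly superior to the hyoid. Areas at the IPAS/MPAS/SPAS levels are
    axial areas at each measurement line's anchor height (for IPAS the
    midpoint of B and Go).
    """
    landmarks.validate_mandatory()
    lines = measurement_lines(landmarks)
    z_top = float(landmarks["Pns"][2])
    z_bottom = float(landmarks["Hy"][2])

    a_min, z_star = min_axial_area(mask, z_top, z_bottom)
    return AirwayParams(
        IPAS=sagittal_diameter(mask, lines["IPAS"]),
        MPAS=sagittal_diameter(mask, lines["MPAS"]),
        SPAS=sagittal_diameter(mask, lines["SPAS"]),
        A_IAS=axial_area(mask, float(lines["IPAS"].anchor[1])),
        A_MAS=axial_area(mask, float(lines["MPAS"].anchor[1])),
        A_SPAS=axial_area(mask, float(lines["SPAS"].anchor[1])),
        A_min=a_min,
        z_of_A_min=z_star,
        V_PAS=airway_volume(mask, z_top, z_bottom),
        A_Sag=max_sagittal_area(mask, z_top, z_bottom),
    )
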