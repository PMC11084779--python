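"""Parametric 3D airway phantoms with closed-form areas and volumes.

A phantom is an elliptical tube swept along a centerline between the hyoid
and posterior-nasal-spine planes, voxelised onto a regular grid (a voxel is
airway iff its centre lies inside the tube), plus a rigid landmark template
scaled to the tube so every morphometry operator can run on it. The analytic
cross-sectional areas A(z) = pi * a(z) * b(z), the analytic minimum, volume
and sagittal diameters are returned alongside as oracles.

The landmark template keeps all midsagittal landmarks at the tube's x centre
and places B and Go at the same height, so the three measurement lines are
horizontal and their analytic diameters are simply twice the sagittal
semi-axis at the line's level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidSpecError, OutOfBoundsError
from ..landmarks import LandmarkSet
from ..morphometry import AirwayMask


@dataclass
class PhantomSpec:
    """Swept elliptical-tube airway phantom.

    ``centerline`` is an ordered array of 3D control points (mm), inferior to
    superior; ``radii_profile`` an (m, 2) array of (sagittal, lateral) ellipse
    semi-axes (mm) at levels evenly spaced along the tube's z extent. Both are
    linearly interpolated between levels. ``spacing`` is the voxel size per
    axis (mm). If ``grid_origin``/``grid_shape`` are given the mask is
    rendered on that fixed grid and the tube must fit inside it; otherwise a
    grid is fitted around the tube with a two-voxel margin.
    """

    centerline: np.ndarray
    radii_profile: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    seed: int = 0
    grid_origin: tuple[float, float, float] | None = None
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        self.radii_profile = np.atleast_2d(np.asarray(self.radii_profile, dtype=float))
        self.spacing = tuple(float(s) for s in self.spacing)

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise InvalidSpecError(f"spacing must be positive, got {self.spacing}")
        if self.radii_profile.size == 0:
            raise InvalidSpecError("radii profile is empty")
        if self.radii_profile.shape[1] != 2:
            raise InvalidSpecError("radii profile must be (m, 2) semi-axis pairs")
        if np.any(self.radii_profile <= 0):
            raise InvalidSpecError("all ellipse semi-axes must be > 0")
        if self.centerline.shape[0] < 2 or self.centerline.shape[1] != 3:
            raise InvalidSpecError("centerline needs >= 2 control points in 3D")
        z = self.centerline[:, 2]
        if not np.all(np.diff(z) > 0):
            raise InvalidSpecError("centerline control points must ascend in z")

    # interpolants along z ---------------------------------------------------

    @property
    def z_bottom(self) -> float:
        return float(self.centerline[0, 2])

    @property
    def z_top(self) -> float:
        return float(self.centerline[-1, 2])

    def center_at(self, z):
        zc = self.centerline[:, 2]
        return (np.interp(z, zc, self.centerline[:, 0]),
                np.interp(z, zc, self.centerline[:, 1]))

    def radii_at(self, z):
        levels = np.linspace(self.z_bottom, self.z_top, self.radii_profile.shape[0])
        if self.radii_profile.shape[0] == 1:
            a = np.full_like(np.asarray(z, dtype=float), self.radii_profile[0, 0])
            b = np.full_like(np.asarray(z, dtype=float), self.radii_profile[0, 1])
            return a, b
        return (np.interp(z, levels, self.radii_profile[:, 0]),
                np.interp(z, levels, self.radii_profile[:, 1]))


@dataclass
class PhantomTruth:
    """Closed-form reference values for a generated phantom."""

    spec: PhantomSpec
    z_hyoid: float
    z_pns: float
    z_ipas: float
    z_mpas: float
    z_spas: float

    def area_at(self, z) -> np.ndarray | float:
        a, b = self.spec.radii_at(z)
        return np.pi * a * b

    def min_area(self, z_top=None, z_bottom=None) -> tuple[float, float]:
        z_top = self.z_pns if z_top is None else z_top
        z_bottom = self.z_hyoid if z_bottom is None else z_bottom
        zs = np.linspace(z_bottom, z_top, 20001)
        areas = self.area_at(zs)
        i = int(np.argmin(areas))
        return float(areas[i]), float(zs[i])

    def volume(self, z_top=None, z_bottom=None) -> float:
        """Analytic tube volume between two planes, in cm^3."""
        z_top = self.z_pns if z_top is None else z_top
        z_bottom = self.z_hyoid if z_bottom is None else z_bottom
        zs = np.linspace(z_bottom, z_top, 20001)
        return float(np.trapezoid(self.area_at(zs), zs)) / 1000.0

    def sagittal_diameter_at(self, z) -> float:
        a, _ = self.spec.radii_at(z)
        return float(2.0 * a)

    def midsagittal_area(self, z_top=None, z_bottom=None) -> float:
        """Airway area in the midsagittal plane between two levels (mm^2)."""
        z_top = self.z_pns if z_top is None else z_top
        z_bottom = self.z_hyoid if z_bottom is None else z_bottom
        zs = np.linspace(z_bottom, z_top, 20001)
        a, _ = self.spec.radii_at(zs)
        return float(np.trapezoid(2.0 * a, zs))

    @property
    def diameters(self) -> dict[str, float]:
        return {"IPAS": self.sagittal_diameter_at(self.z_ipas),
                "MPAS": self.sagittal_diameter_at(self.z_mpas),
                "SPAS": self.sagittal_diameter_at(self.z_spas)}


def _template_landmarks(spec: PhantomSpec) -> tuple[LandmarkSet, dict[str, float]]:
    """Rigid landmark template scaled to the tube.

    Only the plane-defining coordinates matter for morphometry: Hy and Pns sit
    at the tube's bottom/top planes, B and Go share a height (horizontal IPAS
    line crossing the tube), Ut sits at 55% of tube height and the SPAS anchor
    (midpoint of Ut and Pns) lands at ~77.5%.
    """
    z0, z1 = spec.z_bottom, spec.z_top
    h = z1 - z0
    z_ipas = z0 + 0.20 * h
    z_ut = z0 + 0.55 * h
    cx0, cy0 = spec.center_at(z0)
    cx1, cy1 = spec.center_at(z1)
    cxu, cyu = spec.center_at(z_ut)
    cxb, cyb = spec.center_at(z_ipas)
    a_top, _ = spec.radii_at(z1)
    a_ut, _ = spec.radii_at(z_ut)

    pns = np.array([cx1, cy1 + float(a_top) + 8.0, z1])
    ut = np.array([cxu, cyu + float(a_ut) + 2.0, z_ut])
    lms = LandmarkSet({
        "Hy": np.array([cx0, cy0 - 20.0, z0]),
        "Pns": pns,
        "Ut": ut,
        "B": np.array([cxb, cyb + 50.0, z_ipas]),
        "Go": np.array([cxb, cyb - 50.0, z_ipas]),
        "S": np.array([cx1, cy1 - 10.0, z1 + 35.0]),
        "N": np.array([cx1, cy1 + 80.0, z1 + 30.0]),
        "A": np.array([cx1, cy1 + 70.0, z0 + 10.0]),
        "Gn": np.array([cx0, cy0 + 75.0, z0 - 15.0]),
        "Me": np.array([cx1, cy0 + 70.0, z0 - 18.0]),
        "Ar": np.array([cx1, cy1 - 45.0, z1 - 5.0]),
        "Ans": np.array([cx1, cy1 + 75.0, z1 - 2.0]),
    })
    levels = {"z_ipas": z_ipas, "z_mpas": z_ut,
              "z_spas": float((ut[2] + pns[2]) / 2.0)}
    return lms, levels


def generate_airway_phantom(
    spec: PhantomSpec,
) -> tuple[AirwayMask, LandmarkSet, PhantomTruth]:
    """Voxelise a phantom and place its landmark template.

    Returns ``(mask, landmarks, truth)`` where ``truth`` carries the analytic
    areas, volume and diameters used as oracles in tests.
    """
    spec.validate()
    sx, sy, sz = spec.spacing

    zs_dense = np.linspace(spec.z_bottom, spec.z_top, 2001)
    cx, cy = spec.center_at(zs_dense)
    a, b = spec.radii_at(zs_dense)
    x_lo, x_hi = float((cx - b).min()), float((cx + b).max())
    y_lo, y_hi = float((cy - a).min()), float((cy + a).max())

    if spec.grid_origin is None or spec.grid_shape is None:
        # Voxel *boundaries* (not centres) align with the tube's extreme
        # planes: the first slice centre sits half a voxel inside. This keeps
        # slice-counting volumes and boundary voxels free of knife-edge ties
        # (a voxel centre exactly on the analytic surface).
        origin = (x_lo - 2 * sx + sx / 2,
                  y_lo - 2 * sy + sy / 2,
                  spec.z_bottom - 2 * sz + sz / 2)
        shape = (int(np.ceil((x_hi - x_lo) / sx)) + 4,
                 int(np.ceil((y_hi - y_lo) / sy)) + 4,
                 int(np.ceil((spec.z_top - spec.z_bottom) / sz)) + 4)
    else:
        origin = tuple(float(o) for o in spec.grid_origin)
        shape = tuple(int(n) for n in spec.grid_shape)
        ext = [origin[i] + (shape[i] - 1) * spec.spacing[i] for i in range(3)]
        if (x_lo < origin[0] or x_hi > ext[0] or y_lo < origin[1]
                or y_hi > ext[1] or spec.z_bottom < origin[2]
                or spec.z_top > ext[2]):
            raise OutOfBoundsError("tube exits the supplied voxel grid")

    nx, ny, nz = shape
    xs = origin[0] + sx * np.arange(nx)
    ys = origin[1] + sy * np.arange(ny)
    zsl = origin[2] + sz * np.arange(nz)

    data = np.zeros(shape, dtype=bool)
    in_tube = (zsl >= spec.z_bottom) & (zsl <= spec.z_top)
    for k in np.flatnonzero(in_tube):
        z = zsl[k]
        cxk, cyk = spec.center_at(z)
        ak, bk = spec.radii_at(z)
        u = (xs[:, None] - cxk) / float(bk)   # lateral semi-axis b
        v = (ys[None, :] - cyk) / float(ak)   # sagittal semi-axis a
        data[:, :, k] = u**2 + v**2 <= 1.0

    mask = AirwayMask(data, spec.spacing, origin)
    landmarks, levels = _template_landmarks(spec)
    truth = PhantomTruth(spec, z_hyoid=spec.z_bottom, z_pns=spec.z_top, **levels)
    return mask, landmarks, truth


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def cylinder_spec(radius: float = 5.0, height: float = 40.0,
                  spacing: float = 0.5) -> PhantomSpec:
    """Straight vertical circular tube."""
    return PhantomSpec(
        centerline=[[0.0, 0.0, 0.0], [0.0, 0.0, height]],
        radii_profile=[[radius, radius]],
        spacing=(spacing, spacing, spacing),
    )


def elliptic_spec(a_sag: float = 6.0, a_lat: float = 3.0, height: float = 40.0,
                  spacing: float = 0.5) -> PhantomSpec:
    """Straight tube with a constant elliptical cross-section."""
    return PhantomSpec(
        centerline=[[0.0, 0.0, 0.0], [0.0, 0.0, height]],
        radii_profile=[[a_sag, a_lat]],
        spacing=(spacing, spacing, spacing),
    )


def pinched_spec(r_end: float = 8.0, r_min: float = 3.0, height: float = 80.0,
                 pinch_frac: float = 0.5, spacing: float = 0.5) -> PhantomSpec:
    """Circular tube pinched to ``r_min`` at ``pinch_frac`` of its height."""
    n_levels = 41
    fracs = np.linspace(0.0, 1.0, n_levels)
    # smooth V-profile with its minimum exactly at the pinch level
    radii = r_end + (r_min - r_end) * np.maximum(
        0.0, 1.0 - np.abs(fracs - pinch_frac) / min(pinch_frac, 1 - pinch_frac))
    profile = np.column_stack([radii, radii])
    return PhantomSpec(
        centerline=[[0.0, 0.0, 0.0], [0.0, 0.0, height]],
        radii_profile=profile,
        spacing=(spacing, spacing, spacing),
    )


PRESETS = {
    "cylinder": cylinder_spec,
    "elliptic": elliptic_spec,
    "pinched": pinched_spec,
}
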