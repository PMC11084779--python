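"""Named anatomical landmark sets in a common millimetre frame.

Axis convention throughout the package: x left->right, y posterior->anterior,
z inferior->superior (all in mm). A :class:`LandmarkSet` stores named 3D
points; bilateral structures carry ``_L``/``_R`` suffixes (e.g. ``Go_L``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MissingLandmarkError

#: Landmarks that must be present for the airway/cephalometric core.
MANDATORY = ("S", "N", "A", "B", "Gn", "Me", "Hy", "Go", "Ut", "Ar", "Ans", "Pns")

#: Optional landmarks: bilateral dental/mandibular points, incisor edges and
#: soft-palate surface points. Bilateral pairs are (left, right).
OPTIONAL_BILATERAL = {
    "molar": ("M1_L", "M1_R"),          # first lower molar
    "premolar": ("P1_L", "P1_R"),       # first lower premolar
    "mandibular_angle": ("MA_L", "MA_R"),
    "condyle": ("Cd_L", "Cd_R"),        # condylar lateral poles
}
OPTIONAL_SINGLE = ("UIE", "LIE", "SPa", "SPp")  # incisor edges, soft palate


@dataclass
class LandmarkSet:
    """Named 3D points (mm) in a shared scanner frame.

    Parameters
    ----------
    points
        Mapping of landmark name to a length-3 coordinate (x, y, z) in mm.
    """

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        for name, p in self.points.items():
            if p.shape != (3,):
                raise ValueError(f"landmark {name!r} must be a 3-vector, got {p.shape}")
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def get(self, name: str):
        return self.points.get(name)

    def require(self, *names: str) -> None:
        """Raise :class:`MissingLandmarkError` naming the first absent point."""
        for name in names:
            if name not in self.points:
                raise MissingLandmarkError(name)

    def validate_mandatory(self) -> None:
        self.require(*MANDATORY)
        if self["Pns"][2] <= self["Hy"][2]:
            raise ValueError(
                "Pns must lie strictly superior to Hy "
                f"(z_Pns={self['Pns'][2]:.2f}, z_Hy={self['Hy'][2]:.2f})"
            )

    @property
    def midsagittal_x(self) -> float:
        """x of the midsagittal plane: median x of S, N and Me."""
        return float(np.median([self["S"][0], self["N"][0], self["Me"][0]]))

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({k: np.asarray(v, dtype=float) for k, v in raw.items()})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({k: [float(c) for c in v] for k, v in self.points.items()},
                      fh, indent=1, sort_keys=True)

    def translated(self, offset) -> "LandmarkSet":
        off = np.asarray(offset, dtype=float)
        return LandmarkSet({k: v + off for k, v in self.points.items()})

    def scaled(self, factor: float) -> "LandmarkSet":
        return LandmarkSet({k: v * float(factor) for k, v in self.points.items()})
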