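"""Two-dimensional cephalometric analysis from 3D landmarks.

Sagittal measurements are taken after projecting landmarks onto the
midsagittal plane (dropping the left-right coordinate; bilateral pairs are
replaced by their midpoint). Transversal distances (DI4, DI6, DMA, DCH) are
computed in 3D between the bilateral originals.

Sign conventions:

* ``ANB = SNA - SNB`` (signed, so a Class III skeletal pattern yields a
  negative ANB).
* Overjet OJ is positive when the upper incisor edge lies anterior to the
  lower; overbite OB is positive for vertical incisor overlap and negative
  for an open bite.
* The plane angles MP-SN and SP-MP use the conventional anterior-opening
  form: each line is oriented to point anteriorly and the unsigned angle
  between the oriented directions is reported, in [0, 180). SP-SN is the
  acute angle between the undirected lines.

Missing optional landmarks yield ``None`` fields (absent, never zero) so
downstream statistics can drop them pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, MissingLandmarkError
from .landmarks import OPTIONAL_BILATERAL, LandmarkSet

#: Order of the cephalometric columns in cohort CSVs.
CEPH_COLUMNS = (
    "S-N", "NSAr", "SNA", "SNB", "ANB", "Ans-Pns", "GoGn",
    "SP-SN", "MP-SN", "SP-MP", "SArGo", "ArGoMe", "Sum", "NSGn",
    "S-Go", "N-Me", "N-Ans", "Ans-Me", "S-Go/N-Me", "Ans-Me/N-Ans",
    "MP-Hy", "OJ", "OB", "DI6", "DI4", "DMA", "DCH", "SPL", "SPT",
)


# --------------------------------------------------------------------------
# geometric primitives
# --------------------------------------------------------------------------

def angle_at(vertex, p, q) -> float:
    """Interior angle (degrees, in [0, 180]) at ``vertex`` subtended by p and q."""
    vertex, p, q = (np.asarray(a, dtype=float) for a in (vertex, p, q))
    u, v = p - vertex, q - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("zero-length arm at angle vertex")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(c))


def line_angle(line_a, line_b) -> float:
    """Acute-or-right angle (degrees, [0, 90]) between two undirected lines.

    Each line is a pair of points.
    """
    da = np.asarray(line_a[1], float) - np.asarray(line_a[0], float)
    db = np.asarray(line_b[1], float) - np.asarray(line_b[0], float)
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise DegenerateGeometryError("degenerate line in line_angle")
    c = np.clip(abs(np.dot(da, db)) / (na * nb), 0.0, 1.0)
    return math.degrees(math.acos(c))


def _oriented_anterior(d: np.ndarray) -> np.ndarray:
    """Orient a midsagittal direction (y, z) so it points anteriorly."""
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        return -d
    return d


def opening_angle(line_a, line_b) -> float:
    """Anterior-opening angle (degrees, [0, 180)) between two midsagittal lines.

    The cephalometric convention for MP-SN and SP-MP: both lines are oriented
    to point anteriorly before taking the unsigned angle between them.
    """
    da = np.asarray(line_a[1], float) - np.asarray(line_a[0], float)
    db = np.asarray(line_b[1], float) - np.asarray(line_b[0], float)
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise DegenerateGeometryError("degenerate line in opening_angle")
    da = _oriented_anterior(da / na)
    db = _oriented_anterior(db / nb)
    c = np.clip(np.dot(da, db), -1.0, 1.0)
    return math.degrees(math.acos(c))


def point_line_distance(p, line) -> float:
    """Perpendicular distance (mm, >= 0) from a point to an infinite line."""
    a = np.asarray(line[0], dtype=float)
    b = np.asarray(line[1], dtype=float)
    p = np.asarray(p, dtype=float)
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        raise DegenerateGeometryError("degenerate line in point_line_distance")
    r = p - a
    if p.shape == (2,):
        return float(abs(d[0] * r[1] - d[1] * r[0]) / n)
    return float(np.linalg.norm(np.cross(d, r)) / n)


def _dist(p, q) -> float:
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


# --------------------------------------------------------------------------
# midsagittal projection
# --------------------------------------------------------------------------

@dataclass
class MidsagittalProjection:
    """Landmarks projected to the midsagittal plane.

    ``points`` maps names to (y, z); bilateral pairs appear once under their
    pair key (midpoint). ``bilateral`` retains the 3D originals for
    transversal distances.
    """

    points: dict[str, np.ndarray]
    bilateral: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None


def project_midsagittal(landmarks: LandmarkSet) -> MidsagittalProjection:
    """Drop the left-right coordinate; average bilateral pairs for sagittal use."""
    landmarks.validate_mandatory()
    pts: dict[str, np.ndarray] = {}
    bilateral: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    paired = {n for pair in OPTIONAL_BILATERAL.values() for n in pair}
    for name, p in landmarks.points.items():
        if name not in paired:
            pts[name] = p[1:].copy()
    for key, (left, right) in OPTIONAL_BILATERAL.items():
        if left in landmarks and right in landmarks:
            pl, pr = landmarks[left], landmarks[right]
            pts[key] = (pl[1:] + pr[1:]) / 2.0
            bilateral[key] = (pl, pr)
    return MidsagittalProjection(pts, bilateral)


# --------------------------------------------------------------------------
# the full record
# --------------------------------------------------------------------------

@dataclass
class CephRecord:
    """One patient's cephalometric parameter set (angles deg, distances mm).

    Optional parameters whose landmarks were absent are ``None``.
    """

    values: dict[str, float | None]

    def __getitem__(self, key: str):
        return self.values[key]

    def to_row(self) -> dict[str, float | None]:
        return {k: self.values.get(k) for k in CEPH_COLUMNS}

    def validate(self, tol: float = 0.1) -> None:
        """Check the arithmetic identities that define derived parameters."""
        v = self.values
        assert abs(v["Sum"] - (v["NSAr"] + v["SArGo"] + v["ArGoMe"])) <= tol
        assert abs(v["ANB"] - (v["SNA"] - v["SNB"])) <= tol
        assert abs(v["S-Go/N-Me"] - v["S-Go"] / v["N-Me"]) <= 1e-9
        assert abs(v["Ans-Me/N-Ans"] - v["Ans-Me"] / v["N-Ans"]) <= 1e-9


def compute_ceph_record(landmarks: LandmarkSet) -> CephRecord:
    """Compute every cephalometric parameter available from a landmark set."""
    proj = project_midsagittal(landmarks)
    S, N, A, B = proj["S"], proj["N"], proj["A"], proj["B"]
    Gn, Me, Hy, Go = proj["Gn"], proj["Me"], proj["Hy"], proj["Go"]
    Ut, Ar, Ans, Pns = proj["Ut"], proj["Ar"], proj["Ans"], proj["Pns"]

    sna = angle_at(N, S, A)
    snb = angle_at(N, S, B)
    nsar = angle_at(S, N, Ar)
    sargo = angle_at(Ar, S, Go)   # articular angle S-Ar-Go
    argome = angle_at(Go, Ar, Me)
    s_go, n_me = _dist(S, Go), _dist(N, Me)
    n_ans, ans_me = _dist(N, Ans), _dist(Ans, Me)

    v: dict[str, float | None] = {
        "S-N": _dist(S, N),
        "NSAr": nsar,
        "SNA": sna,
        "SNB": snb,
        "ANB": sna - snb,
        "Ans-Pns": _dist(Ans, Pns),
        "GoGn": _dist(Go, Gn),
        "SP-SN": line_angle((Ans, Pns), (S, N)),
        "MP-SN": opening_angle((Go, Me), (S, N)),
        "SP-MP": opening_angle((Ans, Pns), (Go, Me)),
        "SArGo": sargo,
        "ArGoMe": argome,
        "Sum": nsar + sargo + argome,
        "NSGn": angle_at(S, N, Gn),
        "S-Go": s_go,
        "N-Me": n_me,
        "N-Ans": n_ans,
        "Ans-Me": ans_me,
        "S-Go/N-Me": s_go / n_me,
        "Ans-Me/N-Ans": ans_me / n_ans,
        "MP-Hy": point_line_distance(Hy, (Go, Me)),
        "SPL": _dist(Pns, Ut),
    }

    # dental relations from the incisor edge points (occlusal offsets in the
    # midsagittal frame: y anterior, z superior)
    if "UIE" in landmarks and "LIE" in landmarks:
        uie, lie = proj["UIE"], proj["LIE"]
        v["OJ"] = float(uie[0] - lie[0])
        v["OB"] = float(lie[1] - uie[1])
    else:
        v["OJ"] = v["OB"] = None

    # transversal 3D distances between bilateral originals
    for key, col in (("molar", "DI6"), ("premolar", "DI4"),
                     ("mandibular_angle", "DMA"), ("condyle", "DCH")):
        pair = proj.bilateral.get(key)
        v[col] = _dist(*pair) if pair is not None else None

    # soft palate thickness between its anterior/posterior surface points
    if "SPa" in landmarks and "SPp" in landmarks:
        v["SPT"] = _dist(proj["SPa"], proj["SPp"])
    else:
        v["SPT"] = None

    return CephRecord(v)
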