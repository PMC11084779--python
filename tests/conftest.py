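import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cephscreen.landmarks import LandmarkSet
from cephscreen.morphometry import AirwayMask
from cephscreen.simulate import cylinder_spec, generate_airway_phantom

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def _rot(d, degrees):
    """Rotate a 2D (y, z) direction counterclockwise."""
    th = math.radians(degrees)
    c, s = math.cos(th), math.sin(th)
    return np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def synthetic_face(sna=80.0, snb=78.0, mp_sn=36.0, scale=1.0,
                   with_optional=True) -> LandmarkSet:
    """Anatomically plausible landmark frame with prescribed SNA/SNB/MP-SN.

    Built in the midsagittal plane (x = 0, y anterior, z superior); A and B
    are placed by rotating the N->S direction about N by the requested
    angles, and the mandibular plane by rotating the S->N direction.
    """
    S2 = np.array([0.0, 0.0])
    N2 = np.array([70.0, 5.0])
    u = (S2 - N2) / np.linalg.norm(S2 - N2)   # N -> S
    d1 = -u                                   # S -> N, anterior-pointing
    A2 = N2 + 55.0 * _rot(u, sna)
    B2 = N2 + 95.0 * _rot(u, snb)
    Go2 = np.array([10.0, -75.0])
    Me2 = Go2 + 85.0 * _rot(d1, -mp_sn)
    pts2 = {
        "S": S2, "N": N2, "A": A2, "B": B2,
        "Go": Go2, "Me": Me2,
        "Gn": np.array([75.0, -110.0]),
        "Ar": np.array([-15.0, -35.0]),
        "Ans": np.array([72.0, -42.0]),
        "Pns": np.array([20.0, -40.0]),
        "Hy": np.array([30.0, -105.0]),
        "Ut": np.array([30.0, -60.0]),
    }
    pts = {k: np.array([0.0, v[0], v[1]]) * scale for k, v in pts2.items()}
    if with_optional:
        extra = {
            "UIE": (0.0, 68.0, -70.0), "LIE": (0.0, 65.0, -72.0),
            "M1_L": (-22.0, 40.0, -85.0), "M1_R": (22.0, 40.0, -85.0),
            "P1_L": (-18.0, 50.0, -82.0), "P1_R": (18.0, 50.0, -82.0),
            "MA_L": (-50.0, 5.0, -78.0), "MA_R": (50.0, 5.0, -78.0),
            "Cd_L": (-57.0, -15.0, -30.0), "Cd_R": (57.0, -15.0, -30.0),
            "SPa": (0.0, 28.0, -50.0), "SPp": (0.0, 22.0, -52.0),
        }
        pts.update({k: np.asarray(v) * scale for k, v in extra.items()})
    return LandmarkSet(pts)


def box_mask(depth_mm=12.0, width_mm=10.0, height_mm=10.0, spacing=0.5):
    """Axis-aligned box airway; box spans [0, extent) per axis exactly."""
    nx = int(round(width_mm / spacing))
    ny = int(round(depth_mm / spacing))
    nz = int(round(height_mm / spacing))
    data = np.ones((nx, ny, nz), dtype=bool)
    origin = (spacing / 2, spacing / 2, spacing / 2)
    return AirwayMask(data, (spacing,) * 3, origin)


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Radius-5 mm, height-40 mm circular tube at 0.5 mm spacing."""
    return generate_airway_phantom(cylinder_spec(radius=5.0, height=40.0,
                                                 spacing=0.5))


@pytest.fixture(scope="session")
def default_cohort():
    import cephscreen as cs

    return cs.generate_tabular_cohort(cs.CohortSpec(n_patients=100, seed=1))
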