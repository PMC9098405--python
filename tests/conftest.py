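"""Shared fixtures: analytic toys and phantom builds reused across tests."""
import numpy as np
import pytest

from zmo import LandmarkSet, PhantomSpec, build_phantom, compute_head_frame


def toy_landmarks(extra=None):
    """Perfectly symmetric head landmarks whose frame is the identity."""
    lm = {
        "porion_L": (-50.0, -40.0, 0.0),
        "porion_R": (50.0, -40.0, 0.0),
        "orbitale_L": (-35.0, 30.0, 0.0),
        "orbitale_R": (35.0, 30.0, 0.0),
        "nasion": (0.0, 45.0, 10.0),
        "incisor_tip": (0.0, 45.0, -30.0),
    }
    if extra:
        lm.update(extra)
    return LandmarkSet(lm)


@pytest.fixture(scope="session")
def identity_frame():
    return compute_head_frame(toy_landmarks())


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Identity displacement, zero increment, 1 mm grid."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def displaced_phantom():
    """3 mm pure lateral translation of the left zygoma fragment."""
    return build_phantom(PhantomSpec(zygoma_translation_mm=(-3.0, 0.0, 0.0)))


def arc_contour(center, radius, theta0_deg, theta1_deg, n=721):
    """Open circular-arc polyline (closing chord is implied downstream)."""
    th = np.radians(np.linspace(theta0_deg, theta1_deg, n))
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def wedge_mask(alpha_deg, spacing=0.5, size_scale=1.0, side="right", flat=False):
    """Synthetic cavity cross-section prism with a known floor/medial-wall
    dihedral angle (or a smooth half-ellipsoid when ``flat``).

    Returns (mask, affine) on a grid whose world coordinates line up with the
    toy identity frame; the cavity sits on the requested side.
    """
    s = size_scale
    nx = int(70 * s / spacing)
    ny = int(30 / spacing)
    nz = int(45 * s / spacing)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = spacing
    affine[:3, 3] = (5.0, -5.0, -10.0 * s)
    xs = affine[0, 3] + spacing * np.arange(nx)
    ys = affine[1, 3] + spacing * np.arange(ny)
    zs = affine[2, 3] + spacing * np.arange(nz)
    X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
    if flat:
        # large-radius cylinder: the floor continues into the medial wall
        # without any angular break
        m = (
            ((X - 40 * s) ** 2 + (Z - 14 * s) ** 2 <= (22 * s) ** 2)
            & (Y >= 0.0)
            & (Y <= 20.0)
        )
    else:
        al = np.radians(alpha_deg)
        m = (
            (Z >= 0.0)
            & (Z <= 22.0 * s)
            & (X >= 8.0 * s)
            & (X <= 55.0 * s)
            & (Y >= 0.0)
            & (Y <= 20.0)
            & (((X - 15.0 * s) * np.sin(al) - Z * np.cos(al)) >= 0.0)
        )
    m = np.broadcast_to(m, (nx, ny, nz)).copy()
    if side == "left":
        m = m[::-1]
        affine = affine.copy()
        affine[0, 3] = -(xs[-1])
    return m, affine
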