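"""Digital compressed-breast phantom and analytic cone-beam ray tracer.

The phantom is a half-cylindrical compressed breast: a stack of z-slabs
(downstream Lexan paddle, skin, interior, skin, upstream Lexan paddle)
bounded laterally by the breast half-disc (flat face on the chest-wall
edge).  A denser half-cylindrical glandular slab of configurable radius and
height sits inside the interior; everything else in the interior is adipose.
Optional hydroxyapatite microcalcification cylinders sit inside the
glandular volume.

Coordinates: detector plane z = 0; x runs along the chest-wall edge
(centered), y from the chest wall toward the nipple; the point source is on
the z axis at the source-detector distance, over the chest-wall edge
midpoint.  Pixel centers are at ``(i + 0.5) * pitch``.  Because every
boundary is either a z-plane or a vertical cylinder, all per-pixel
intersection lengths are available in closed form, including cone-beam
obliquity (slab components scale with the secant of the ray angle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "BreastPhantom",
    "MicroCalc",
    "ProjectionGeometry",
    "PathDecomposition",
    "InvalidPhantomError",
    "build_phantom",
    "trace_paths",
]


class InvalidPhantomError(ValueError):
    """Phantom parameters violate the geometric constraints."""


@dataclass(frozen=True)
class MicroCalc:
    """Cylindrical hydroxyapatite deposit (axis along z)."""

    x: float               # cm, in-plane center
    y: float
    z_center: float        # cm above the detector plane
    diameter: float = 0.1  # cm
    height: float = 0.05   # cm

    def __post_init__(self) -> None:
        if self.diameter < 0 or self.height < 0:
            raise InvalidPhantomError("microcalcification dimensions must be >= 0")


@dataclass(frozen=True)
class BreastPhantom:
    thickness: float                  # cm, compression (z) direction
    outer_radius: float = 7.5
    glandular_radius: float = 5.0
    glandular_height: float = 0.0
    glandular_offset: float = 0.0     # cm, + toward the source
    skin_thickness: float = 0.145
    n_skin_layers: int = 2
    paddle_thickness_each: float = 0.25
    n_paddles: int = 2
    paddle_radius: float = 8.0   # lateral extent of the compression paddles
    microcalcs: Tuple[MicroCalc, ...] = ()

    def __post_init__(self) -> None:
        interior = self.thickness - self.n_skin_layers * self.skin_thickness
        if interior <= 0:
            raise InvalidPhantomError("breast thinner than its skin layers")
        if self.glandular_height > interior + 1e-12:
            raise InvalidPhantomError("glandular slab taller than the interior")
        if self.glandular_radius >= self.outer_radius:
            raise InvalidPhantomError("glandular radius must be < outer radius")
        if self.paddle_radius < self.outer_radius:
            raise InvalidPhantomError("paddles must cover the breast")
        if abs(self.glandular_offset) + self.glandular_height / 2 > interior / 2 + 1e-12:
            raise InvalidPhantomError("glandular slab shifted outside the interior")
        object.__setattr__(self, "microcalcs", tuple(self.microcalcs))

    @property
    def interior_thickness(self) -> float:
        return self.thickness - self.n_skin_layers * self.skin_thickness

    @property
    def lexan_total(self) -> float:
        return self.n_paddles * self.paddle_thickness_each


@dataclass(frozen=True)
class ProjectionGeometry:
    source_detector_distance: float = 70.0  # cm
    air_gap: float = 1.5                    # detector to distal object surface
    detector_size: Tuple[float, float] = (20.0, 15.0)  # cm (x, y)
    pixel_pitch: float = 0.1                # cm

    @property
    def shape(self) -> Tuple[int, int]:
        """Raster shape (rows = y, cols = x)."""
        return (int(round(self.detector_size[1] / self.pixel_pitch)),
                int(round(self.detector_size[0] / self.pixel_pitch)))

    def pixel_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        x = (np.arange(nx) + 0.5) * self.pixel_pitch - self.detector_size[0] / 2
        y = (np.arange(ny) + 0.5) * self.pixel_pitch
        return np.meshgrid(x, y)


@dataclass
class PathDecomposition:
    """Per-pixel intercept lengths (cm) and ground-truth glandular fraction."""

    t_lexan: np.ndarray
    t_skin: np.ndarray
    t_adipose: np.ndarray
    t_glandular: np.ndarray
    t_calc: np.ndarray
    mask: np.ndarray             # rays through the full tissue stack (no air)
    glandular_full: np.ndarray   # rays crossing the glandular slab end to end
    cos_theta: np.ndarray
    geometry: ProjectionGeometry = None
    phantom: BreastPhantom = None

    @property
    def t_breast(self) -> np.ndarray:
        return self.t_skin + self.t_adipose + self.t_glandular + self.t_calc

    @property
    def t_total(self) -> np.ndarray:
        return self.t_breast + self.t_lexan

    @property
    def j(self) -> np.ndarray:
        """Lexan path fraction t_lexan/t_total (NaN outside the mask)."""
        return self._frac(self.t_lexan)

    @property
    def k(self) -> np.ndarray:
        """Skin path fraction t_skin/t_total (NaN outside the mask)."""
        return self._frac(self.t_skin)

    def _frac(self, num: np.ndarray) -> np.ndarray:
        out = np.full_like(num, np.nan)
        np.divide(num, self.t_total, out=out, where=self.t_total > 0)
        return out

    @property
    def m_true(self) -> np.ndarray:
        """Ground-truth glandular fraction t_g/t_breast (NaN where undefined)."""
        out = np.full_like(self.t_glandular, np.nan)
        tb = self.t_breast
        np.divide(self.t_glandular, tb, out=out, where=(tb > 0) & self.mask)
        return out

    def glandular_interior(self, erode_px: int = 2) -> np.ndarray:
        """Full-chord glandular-shadow pixels, eroded to drop edge pixels."""
        m = self.glandular_full & self.mask
        if erode_px > 0:
            m = ndimage.binary_erosion(m, iterations=erode_px)
        return m


def build_phantom(
    thickness: float,
    gf_target: float,
    glandular_radius: float = 5.0,
    glandular_offset: float = 0.0,
    **kwargs,
) -> BreastPhantom:
    """Phantom with a glandular slab sized for the requested fraction.

    ``glandular_height = gf_target * (thickness - skin)`` so that a
    perpendicular ray through the glandular cylinder carries the target
    fraction of the skin-free interior; the skin layers are counted in
    ``t_breast`` but not in the glandular length.
    """
    if not 0.0 <= gf_target <= 1.0:
        raise InvalidPhantomError("gf_target must lie in [0, 1]")
    skin = kwargs.get("skin_thickness", 0.145)
    n_skin = kwargs.get("n_skin_layers", 2)
    interior = thickness - n_skin * skin
    if interior <= 0:
        raise InvalidPhantomError("gf_target incompatible with skin/thickness")
    return BreastPhantom(
        thickness=thickness,
        glandular_radius=glandular_radius,
        glandular_height=gf_target * interior,
        glandular_offset=glandular_offset,
        **kwargs,
    )


def _sublength(z_lo, z_hi, z_enter):
    """Length of [z_lo, z_hi] above the per-pixel entry height ``z_enter``."""
    return np.clip(z_hi - np.maximum(z_lo, z_enter), 0.0, None)


def trace_paths(phantom: BreastPhantom, geom: ProjectionGeometry) -> PathDecomposition:
    """Exact per-pixel path decomposition for the cone-beam geometry."""
    sdd = geom.source_detector_distance
    stack_top = geom.air_gap + phantom.lexan_total + phantom.thickness
    if stack_top >= sdd:
        raise InvalidPhantomError("phantom stack reaches the source")

    xd, yd = geom.pixel_centers()
    r_d = np.hypot(xd, yd)
    ray_len = np.sqrt(r_d**2 + sdd**2)
    lf = ray_len / sdd                # path length per unit z
    cos_theta = sdd / ray_len

    # z-slab boundaries, from the detector upward
    z = geom.air_gap
    pad_lo = (z, z + phantom.paddle_thickness_each)
    z = pad_lo[1]
    skin_lo = (z, z + phantom.skin_thickness)
    z = skin_lo[1]
    interior = (z, z + phantom.interior_thickness)
    z = interior[1]
    skin_hi = (z, z + phantom.skin_thickness)
    z = skin_hi[1]
    pad_hi = (z, z + phantom.paddle_thickness_each)

    g_mid = 0.5 * (interior[0] + interior[1]) + phantom.glandular_offset
    g_slab = (g_mid - phantom.glandular_height / 2, g_mid + phantom.glandular_height / 2)

    # per-pixel z above which the ray is inside a vertical cylinder of radius R
    def z_enter(R):
        with np.errstate(divide="ignore"):
            out = sdd * (1.0 - R / np.maximum(r_d, 1e-300))
        return np.where(r_d <= R, 0.0, out)

    ze_outer = z_enter(phantom.outer_radius)
    ze_gland = z_enter(phantom.glandular_radius)
    ze_pad = z_enter(phantom.paddle_radius)

    t_lexan = (_sublength(*pad_lo, ze_pad) + _sublength(*pad_hi, ze_pad)) * lf
    t_skin = (_sublength(*skin_lo, ze_outer) + _sublength(*skin_hi, ze_outer)) * lf
    t_int = _sublength(*interior, ze_outer) * lf
    t_gl = _sublength(*g_slab, np.maximum(ze_gland, ze_outer)) * lf

    # microcalcification chords (cylinder axis parallel to z)
    t_calc = np.zeros_like(t_gl)
    for mc in phantom.microcalcs:
        c_lo, c_hi = mc.z_center - mc.height / 2, mc.z_center + mc.height / 2
        if not (g_slab[0] - 1e-9 <= c_lo and c_hi <= g_slab[1] + 1e-9
                and np.hypot(mc.x, mc.y) + mc.diameter / 2 <= phantom.glandular_radius):
            raise InvalidPhantomError("microcalcification outside the glandular volume")
        # |u*(xd,yd) - c|^2 = rc^2 with u = (sdd - z)/sdd
        a = xd**2 + yd**2
        b = -2.0 * (xd * mc.x + yd * mc.y)
        c0 = mc.x**2 + mc.y**2 - (mc.diameter / 2) ** 2
        disc = b**2 - 4.0 * a * c0
        hit = disc > 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            u1 = (-b - sq) / (2.0 * a)
            u2 = (-b + sq) / (2.0 * a)
        z1 = sdd * (1.0 - np.maximum(u1, u2))   # lower z bound
        z2 = sdd * (1.0 - np.minimum(u1, u2))
        chord = np.clip(np.minimum(c_hi, z2) - np.maximum(c_lo, z1), 0.0, None)
        t_calc += np.where(hit, chord * lf, 0.0)

    t_gl = np.clip(t_gl - t_calc, 0.0, None)
    t_adipose = np.clip(t_int - t_gl - t_calc, 0.0, None)

    # full tissue stack with no air: the ray is already inside the breast
    # cylinder at the bottom skin surface (margin rays keep their partial
    # lengths but are masked out; rays beside the shadow have t_breast = 0)
    mask = ze_outer <= skin_lo[0] + 1e-12
    glandular_full = mask & (ze_gland <= g_slab[0] + 1e-12) & (phantom.glandular_height > 0)

    return PathDecomposition(
        t_lexan=t_lexan, t_skin=t_skin, t_adipose=t_adipose,
        t_glandular=t_gl, t_calc=t_calc, mask=mask,
        glandular_full=glandular_full, cos_theta=cos_theta,
        geometry=geom, phantom=phantom,
    )
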