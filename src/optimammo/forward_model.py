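"""Time-domain diffusion model of photon transport through a breast-like slab.

The breast compressed between the scan plates is modelled as a homogeneous
diffusive slab.  The time-resolved transmittance is the diffusion-theory
Green's function with extrapolated boundary conditions, evaluated as a
series of image sources.  A lesion is modelled as a spherical absorbing
perturbation; its effect on the signal enters through the time-resolved
mean partial pathlength l(t) that detected photons spend inside the sphere,
via the perturbative (modified Lambert-Beer) relation

    T(t) = T0(t) * exp(-delta_mua * l(t)).

l(t) is computed here to first Born order: the time convolution of the
source-to-voxel fluence Green's function with the voxel-to-detector
transmittance Green's function, integrated over the sphere volume and
normalized by the unperturbed transmittance.  A Monte-Carlo photon
transport oracle (``montecarlo`` module) validates both the curve shape
and l(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .defaults import (
    DEFAULT_REFRACTIVE_INDEX,
    DEFAULT_SLAB_THICKNESS_CM,
    internal_reflection_coefficient,
    light_speed,
)

__all__ = [
    "OpticalProperties",
    "SlabGeometry",
    "SphericalPerturbation",
    "PathlengthKernel",
    "slab_transmittance",
    "cw_transmittance",
    "partial_pathlength",
    "partial_pathlength_family",
    "perturbed_transmittance",
]

# exp() underflows below ~-745; clip exponents there instead of warning
_EXP_FLOOR = -700.0


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of the medium at one wavelength.

    mua, musp in cm^-1; wavelength in nm.
    """

    mua: float
    musp: float
    wavelength: float = float("nan")

    def __post_init__(self):
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if self.musp <= 0:
            raise ValueError(f"musp must be > 0, got {self.musp}")

    @property
    def diffusion_coefficient(self) -> float:
        """D = 1/(3 musp), cm (absorption-independent convention)."""
        return 1.0 / (3.0 * self.musp)


@dataclass(frozen=True)
class SlabGeometry:
    """Transmittance geometry: source and detector on opposite slab faces.

    The collection bundle faces the illumination fiber, so source and
    detector share the same lateral (x, y) position (mm) by default.
    """

    thickness: float = DEFAULT_SLAB_THICKNESS_CM
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX
    source_pos: tuple[float, float] = (0.0, 0.0)
    detector_pos: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("slab thickness must be > 0")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def speed(self) -> float:
        """Light speed in the medium, cm/ps."""
        return light_speed(self.refractive_index)

    @property
    def lateral_offset_cm(self) -> float:
        """Source-detector lateral distance (cm)."""
        dx = (self.detector_pos[0] - self.source_pos[0]) / 10.0
        dy = (self.detector_pos[1] - self.source_pos[1]) / 10.0
        return float(np.hypot(dx, dy))


@dataclass(frozen=True)
class SphericalPerturbation:
    """Spherical absorbing inclusion inside the slab.

    center is (x, y, z) in cm with z measured from the source face; by
    convention the lesion sits halfway between source and detector
    (z = thickness / 2).  delta_mua (cm^-1) is the absorption contrast of
    the sphere relative to the background at one wavelength.
    """

    center: tuple[float, float, float]
    radius: float
    delta_mua: float = 0.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("perturbation radius must be > 0")

    def check_inside(self, geom: SlabGeometry) -> None:
        z = self.center[2]
        if z - self.radius <= 0 or z + self.radius >= geom.thickness:
            raise ValueError(
                "spherical perturbation intersects a slab face "
                f"(z={z}, radius={self.radius}, thickness={geom.thickness})"
            )


@dataclass
class PathlengthKernel:
    """Time-resolved mean partial pathlength l(t) inside a perturbation.

    time_grid in ps, l_of_t in cm.  l(t) is bounded by the total optical
    pathlength v*t of photons detected at time t.
    """

    time_grid: np.ndarray
    l_of_t: np.ndarray
    speed: float = field(default=light_speed(DEFAULT_REFRACTIVE_INDEX))

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.l_of_t = np.asarray(self.l_of_t, dtype=float)
        if self.time_grid.shape != self.l_of_t.shape:
            raise ValueError("time_grid and l_of_t must have the same shape")


def _check_time_grid(time_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time_grid must be a non-empty 1-D array")
    if np.any(t <= 0):
        raise ValueError("time_grid must contain strictly positive times")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    return t


def _image_source_depths(geom: SlabGeometry, z0: float, D: float, n_images: int):
    """Positive/negative image-source depths for the extrapolated-boundary slab.

    Zero-fluence planes sit at -ze and thickness + ze with ze = 2 A D.
    Returns arrays (z_plus, z_minus) for m = -n_images .. n_images.
    """
    s = geom.thickness
    ze = 2.0 * internal_reflection_coefficient(geom.refractive_index) * D
    m = np.arange(-n_images, n_images + 1, dtype=float)
    period = 2.0 * (s + 2.0 * ze)
    z_plus = m * period + z0
    z_minus = m * period - 2.0 * ze - z0
    return z_plus, z_minus


def _transmittance_terms(
    t: np.ndarray,
    props: OpticalProperties,
    geom: SlabGeometry,
    source_depth,
    rho,
    n_images: int,
) -> np.ndarray:
    """Time-resolved transmitted flux density at the back face (z = thickness)
    for impulsive isotropic unit sources at depth ``source_depth`` and
    lateral distance ``rho`` (cm); units cm^-2 ps^-1.

    Scalars give a (nt,) curve; arrays of shape (nsrc,) give (nsrc, nt).
    """
    D = props.diffusion_coefficient
    v = geom.speed
    s = geom.thickness
    zsrc = np.atleast_1d(np.asarray(source_depth, dtype=float))
    rho_arr = np.broadcast_to(
        np.atleast_1d(np.asarray(rho, dtype=float)), zsrc.shape
    )
    four_Dvt = 4.0 * D * v * t  # (nt,)
    inv = 1.0 / four_Dvt
    pref = np.exp(
        np.clip(
            -props.mua * v * t[None, :] - rho_arr[:, None] ** 2 * inv[None, :],
            _EXP_FLOOR,
            0.0,
        )
    ) / (2.0 * (4.0 * np.pi * D * v) ** 1.5 * t[None, :] ** 2.5)
    ze = 2.0 * internal_reflection_coefficient(geom.refractive_index) * D
    period = 2.0 * (s + 2.0 * ze)
    m = np.arange(-n_images, n_images + 1, dtype=float)
    series = np.zeros((zsrc.size, t.size))
    for mm in m:
        z1 = s - (mm * period + zsrc)  # (nsrc,)
        z2 = s - (mm * period - 2.0 * ze - zsrc)
        series += z1[:, None] * np.exp(
            np.clip(-(z1[:, None] ** 2) * inv[None, :], _EXP_FLOOR, 0.0)
        )
        series -= z2[:, None] * np.exp(
            np.clip(-(z2[:, None] ** 2) * inv[None, :], _EXP_FLOOR, 0.0)
        )
    out = np.clip(pref * series, 0.0, None)
    if np.isscalar(source_depth) or np.ndim(source_depth) == 0:
        return out[0]
    return out


def slab_transmittance(
    props: OpticalProperties,
    geom: SlabGeometry,
    time_grid: np.ndarray,
    n_images: int = 10,
) -> np.ndarray:
    """Noise-free time-resolved transmittance through the homogeneous slab.

    Diffusion approximation with extrapolated boundary conditions; the
    photon injection point is the standard isotropic-source depth
    z0 = 1/musp.  Returns the transmitted flux density on ``time_grid``
    (arbitrary units: cm^-2 ps^-1 per unit injected photon).

    The image-source series is truncated at ``n_images`` dipole pairs on
    each side; contributions decay super-exponentially so the default is
    far below any practical precision requirement.
    """
    t = _check_time_grid(time_grid)
    z0 = 1.0 / props.musp
    if z0 >= geom.thickness:
        raise ValueError("slab thinner than one transport mean free path")
    return _transmittance_terms(
        t, props, geom, z0, geom.lateral_offset_cm, n_images
    )


def cw_transmittance(
    props: OpticalProperties,
    geom: SlabGeometry,
    n_images: int = 10,
) -> float:
    """Continuous-wave (time-integrated) slab transmittance, closed form.

    Each time-domain image term integrates analytically to the steady-state
    point-source flux sign(z) (1 + mueff |z|) exp(-mueff |z|) / (4 pi z^2);
    this is the closed-form sum used to check the time integral of
    :func:`slab_transmittance`.
    """
    D = props.diffusion_coefficient
    z0 = 1.0 / props.musp
    mueff = np.sqrt(props.mua / D)
    rho = geom.lateral_offset_cm
    z_plus, z_minus = _image_source_depths(geom, z0, D, n_images)
    total = 0.0
    for zp, zm in zip(geom.thickness - z_plus, geom.thickness - z_minus):
        for z, sign in ((zp, 1.0), (zm, -1.0)):
            r = np.hypot(rho, z)
            total += (
                sign
                * np.sign(z)
                * (1.0 + mueff * r)
                * np.exp(-mueff * r)
                * abs(z)
                / (4.0 * np.pi * r**3)
            )
    return float(total)


def _fluence_at_voxels(
    t: np.ndarray,
    props: OpticalProperties,
    geom: SlabGeometry,
    rho: np.ndarray,
    z: np.ndarray,
    n_images: int,
) -> np.ndarray:
    """Fluence Green's function (impulsive unit isotropic source at depth
    z0 = 1/musp) at voxels with lateral distance ``rho`` and depth ``z``;
    shape (nvox, nt)."""
    D = props.diffusion_coefficient
    v = geom.speed
    z0 = 1.0 / props.musp
    z_plus, z_minus = _image_source_depths(geom, z0, D, n_images)
    four_Dvt = 4.0 * D * v * t
    inv = 1.0 / four_Dvt  # (nt,)
    pref = v * (4.0 * np.pi * D * v * t) ** -1.5 * np.exp(
        np.clip(-props.mua * v * t, _EXP_FLOOR, 0.0)
    )  # (nt,)
    out = np.zeros((rho.size, t.size))
    lateral = np.exp(np.clip(-(rho[:, None] ** 2) * inv[None, :], _EXP_FLOOR, 0.0))
    for zp, zm in zip(z_plus, z_minus):
        out += np.exp(np.clip(-((z[:, None] - zp) ** 2) * inv, _EXP_FLOOR, 0.0))
        out -= np.exp(np.clip(-((z[:, None] - zm) ** 2) * inv, _EXP_FLOOR, 0.0))
    return np.clip(out, 0.0, None) * lateral * pref


def _sphere_quadrature(pert: SphericalPerturbation, order: int):
    """Gauss-Legendre product rule over the sphere in spherical coordinates.

    Radial and polar nodes are Gauss-Legendre; azimuth is an equal-weight
    trapezoidal rule (exact for trigonometric integrands).  Returns points
    (nq, 3) in cm (absolute coordinates) and weights (nq,) summing to the
    sphere volume.
    """
    r_nodes, r_w = np.polynomial.legendre.leggauss(order)
    r = 0.5 * (r_nodes + 1.0) * pert.radius
    r_w = 0.5 * pert.radius * r_w * r**2
    c_nodes, c_w = np.polynomial.legendre.leggauss(order)
    phi = 2.0 * np.pi * (np.arange(order) + 0.5) / order
    phi_w = 2.0 * np.pi / order
    sin_theta = np.sqrt(1.0 - c_nodes**2)
    R, CT, PH = np.meshgrid(r, c_nodes, phi, indexing="ij")
    RW, CW, _ = np.meshgrid(r_w, c_w, phi, indexing="ij")
    ST = np.sqrt(1.0 - CT**2)
    x = pert.center[0] + (R * ST * np.cos(PH)).ravel()
    y = pert.center[1] + (R * ST * np.sin(PH)).ravel()
    z = pert.center[2] + (R * CT).ravel()
    w = (RW * CW).ravel() * phi_w
    return np.column_stack([x, y, z]), w


def partial_pathlength(
    props: OpticalProperties,
    geom: SlabGeometry,
    pert: SphericalPerturbation,
    time_grid: np.ndarray,
    n_images: int = 10,
    quadrature_order: int = 16,
) -> PathlengthKernel:
    """First-Born time-resolved mean partial pathlength l(t) in the sphere.

    l(t) is the volume integral over the sphere of the time convolution of
    the source-to-voxel fluence Green's function with the voxel-to-detector
    transmittance Green's function, divided by the unperturbed
    transmittance.  For a perturbation filling the whole slab this
    construction recovers l(t) = v t exactly (the homogeneous Beer-Lambert
    limit), which fixes the normalization.

    The sphere integral uses a Gauss-Legendre product rule of the given
    order per dimension (default 16, i.e. 16^3 nodes).
    """
    t = _check_time_grid(time_grid)
    pert.check_inside(geom)
    dt_steps = np.diff(t)
    dt = float(dt_steps[0])
    if not np.allclose(dt_steps, dt, rtol=1e-8):
        raise ValueError("partial_pathlength requires a uniform time grid")

    pts, w = _sphere_quadrature(pert, quadrature_order)
    sx, sy = geom.source_pos[0] / 10.0, geom.source_pos[1] / 10.0
    dx, dy = geom.detector_pos[0] / 10.0, geom.detector_pos[1] / 10.0
    rho_src = np.hypot(pts[:, 0] - sx, pts[:, 1] - sy)
    rho_det = np.hypot(pts[:, 0] - dx, pts[:, 1] - dy)
    z_vox = pts[:, 2]

    # prepend a t=0 sample (both Green's functions vanish there) so that the
    # discrete convolution represents the integral from 0 to t
    t_ext = np.concatenate([[0.0], t])
    g_src = np.zeros((pts.shape[0], t_ext.size))
    g_det = np.zeros_like(g_src)
    g_src[:, 1:] = _fluence_at_voxels(t, props, geom, rho_src, z_vox, n_images)
    g_det[:, 1:] = _transmittance_terms(t, props, geom, z_vox, rho_det, n_images)

    conv = fftconvolve(g_src, g_det, mode="full", axes=1)[:, : t_ext.size] * dt
    numerator = conv[:, 1:].T @ w  # (nt,)

    t0 = slab_transmittance(props, geom, t, n_images=n_images)
    l_of_t = np.zeros_like(t)
    ok = t0 > max(t0.max(), 1e-300) * 1e-12
    l_of_t[ok] = numerator[ok] / t0[ok]
    l_of_t = np.clip(l_of_t, 0.0, None)
    return PathlengthKernel(time_grid=t, l_of_t=l_of_t, speed=geom.speed)


def partial_pathlength_family(
    props: OpticalProperties,
    geom: SlabGeometry,
    pert: SphericalPerturbation,
    time_grid: np.ndarray,
    lateral_offsets_cm: np.ndarray,
    n_images: int = 10,
    quadrature_order: int = 10,
) -> list[PathlengthKernel]:
    """Pathlength kernels for a family of lateral sphere offsets.

    Used when a scan sweeps the source-detector axis past a fixed lesion:
    ``lateral_offsets_cm[k]`` is the distance between the scan axis and the
    sphere center.  Returns one kernel per offset; equivalent to calling
    :func:`partial_pathlength` with the sphere center displaced laterally,
    but sharing the quadrature setup.
    """
    out = []
    cx, cy, cz = pert.center
    for d in np.asarray(lateral_offsets_cm, dtype=float):
        pert_d = SphericalPerturbation(
            center=(cx + d, cy, cz), radius=pert.radius, delta_mua=pert.delta_mua
        )
        out.append(
            partial_pathlength(
                props,
                geom,
                pert_d,
                time_grid,
                n_images=n_images,
                quadrature_order=quadrature_order,
            )
        )
    return out


def perturbed_transmittance(
    props: OpticalProperties,
    geom: SlabGeometry,
    pert: SphericalPerturbation,
    time_grid: np.ndarray,
    n_images: int = 10,
    quadrature_order: int = 16,
    kernel: PathlengthKernel | None = None,
) -> np.ndarray:
    """Transmittance with the absorbing sphere: T(t) = T0(t) exp(-dmua l(t)).

    ``kernel`` may be passed to reuse a precomputed pathlength kernel for
    the same (props, geom, sphere position/radius).
    """
    t = _check_time_grid(time_grid)
    t0 = slab_transmittance(props, geom, t, n_images=n_images)
    if pert.delta_mua == 0.0:
        return t0
    if kernel is None:
        kernel = partial_pathlength(
            props, geom, pert, t, n_images=n_images, quadrature_order=quadrature_order
        )
    return t0 * np.exp(np.clip(-pert.delta_mua * kernel.l_of_t, _EXP_FLOOR, 700.0))
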