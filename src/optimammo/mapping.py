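"""From scanned transmittance grids to absorption and composition maps.

A scan is a 1 mm-pitch grid of time-resolved curves at the seven
wavelengths.  Each position is treated in turn as a potential lesion
location: the windowed counts at that position are compared with a
reference (average healthy tissue) curve through the perturbative relation
to give a delta_mua map per wavelength, and the seven delta_mua values per
pixel are unmixed into constituent-difference maps (Hb, HbO2, tHb, water,
lipid, collagen).  Lesion quantification averages the maps over a small
square region centered on the lesion whose side follows the lesion size
(9 mm for diameters above 15 mm, else 5 mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .defaults import ANALYSIS_WINDOW, N_TIME_WINDOWS, SCAN_PITCH_MM
from .curve_processing import TimeWindows, equal_count_windows, window_pathlength
from .forward_model import (
    OpticalProperties,
    PathlengthKernel,
    SlabGeometry,
    SphericalPerturbation,
    partial_pathlength,
)
from .spectral_unmixing import CONSTITUENTS, ExtinctionSpectra

__all__ = [
    "ScanImage",
    "LesionROI",
    "MapSet",
    "breast_mask",
    "reference_curve",
    "roi_for_diameter",
    "equivalent_sphere",
    "compute_maps",
    "quantify_lesion",
    "roi_mean",
    "roi_composition",
]


@dataclass
class ScanImage:
    """Grid of per-position time-resolved curves, co-registered across
    wavelengths.

    ``curves`` maps wavelength (nm) to an array of shape (ny, nx, nt);
    ``time_grid`` is shared (ps, uniform).  Pixel (0, 0) is the top-left
    corner, x rightward, y downward; physical mm = index * pitch.
    """

    curves: dict
    time_grid: np.ndarray
    pitch_mm: float = SCAN_PITCH_MM
    view: str = "CC"

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        shapes = {wl: c.shape for wl, c in self.curves.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"wavelength grids are not co-registered: {shapes}")
        if first[-1] != self.time_grid.size:
            raise ValueError("curve length does not match time grid")

    @property
    def wavelengths(self) -> tuple:
        return tuple(sorted(self.curves))

    @property
    def shape(self) -> tuple:
        return next(iter(self.curves.values())).shape[:2]

    def total_counts(self) -> np.ndarray:
        """Total counts per position, summed over time and wavelengths."""
        out = np.zeros(self.shape)
        for c in self.curves.values():
            out += c.sum(axis=-1)
        return out


@dataclass(frozen=True)
class LesionROI:
    """Square lesion region: center in mm, side in {5, 9} mm."""

    center_mm: tuple
    side_mm: int

    def __post_init__(self):
        if self.side_mm not in (5, 9):
            raise ValueError("ROI side must be 5 or 9 mm")

    def pixel_slices(self, pitch_mm: float = SCAN_PITCH_MM) -> tuple:
        cx = int(round(self.center_mm[0] / pitch_mm))
        cy = int(round(self.center_mm[1] / pitch_mm))
        half = int(self.side_mm // 2)
        return (slice(cy - half, cy + half + 1), slice(cx - half, cx + half + 1))


def roi_for_diameter(max_diameter_mm: float) -> int:
    """Lesion-area side (mm) from the maximum lesion diameter.

    9 x 9 mm^2 for diameters strictly above 15 mm, else 5 x 5 mm^2; only
    lesions of at least 10 mm are characterized.
    """
    if max_diameter_mm < 10:
        raise ValueError("only lesions with maximum diameter >= 10 mm are considered")
    return 9 if max_diameter_mm > 15 else 5


def equivalent_sphere(max_diameter_mm: float) -> float:
    """Equivalent-sphere radius (cm) from the maximum lesion diameter (mm)."""
    if max_diameter_mm <= 0:
        raise ValueError("lesion diameter must be positive")
    return max_diameter_mm / 2.0 / 10.0


def breast_mask(scan: ScanImage, count_threshold: float) -> np.ndarray:
    """In-breast mask: positions with total counts >= threshold, keeping
    only the largest connected component (the scan feedback restricts the
    acquisition to the breast, stray above-threshold islands are noise)."""
    if count_threshold <= 0:
        raise ValueError("count_threshold must be > 0")
    raw = scan.total_counts() >= count_threshold
    labels, n = ndimage.label(raw)
    if n == 0:
        return raw
    sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def reference_curve(
    scan: ScanImage,
    mask: np.ndarray,
    erosion_mm: float = 10.0,
    outlier_mad: float = 3.0,
    exclude: np.ndarray | None = None,
    n_windows: int = N_TIME_WINDOWS,
    window: int = ANALYSIS_WINDOW,
) -> dict:
    """Average healthy-tissue curve T0 per wavelength.

    The mask is eroded by ``erosion_mm`` to exclude boundary pixels, then
    pixels whose analysis-window counts deviate from the regional median by
    more than ``outlier_mad`` MADs at any wavelength (marked
    inhomogeneities: vessels) are trimmed.  ``exclude`` optionally removes
    an explicitly marked region first — typically a generous neighborhood
    of the known lesion, which would otherwise bias the healthy average.
    Returns {wavelength: mean curve per pixel}.  A warning is raised when
    the surviving region covers less than half of the mask.
    """
    n_iter = int(round(erosion_mm / scan.pitch_mm))
    region = ndimage.binary_erosion(mask, iterations=n_iter) if n_iter else mask.copy()
    if exclude is not None:
        region &= ~np.asarray(exclude, dtype=bool)
    if not region.any():
        raise ValueError("reference region empty after erosion")
    keep = region.copy()
    for wl in scan.wavelengths:
        curves = scan.curves[wl][region]
        mean_curve = curves.mean(axis=0)
        windows = equal_count_windows(mean_curve, n_windows)
        sl = windows.window_slice(window)
        w8 = scan.curves[wl][..., sl].sum(axis=-1)
        vals = w8[region]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        if mad > 0:
            keep &= np.abs(w8 - med) <= outlier_mad * 1.4826 * mad
    if not keep.any():
        raise ValueError("reference region empty after outlier trimming")
    if keep.sum() < 0.5 * mask.sum():
        warnings.warn(
            "reference region covers less than 50% of the breast mask",
            stacklevel=2,
        )
    return {wl: scan.curves[wl][keep].mean(axis=0) for wl in scan.wavelengths}


@dataclass
class MapSet:
    """Per-wavelength delta_mua maps and constituent delta_C maps."""

    dmua: dict  # wavelength -> (ny, nx)
    dc: dict  # constituent name (incl. "tHb") -> (ny, nx)
    mask: np.ndarray
    pitch_mm: float = SCAN_PITCH_MM
    window_pathlengths: dict = field(default_factory=dict)  # wavelength -> l_w (cm)

    def ranges(self) -> dict:
        """Per-map (min, max) over the mask, for sidecar/colorbar use."""
        out = {}
        for wl, m in self.dmua.items():
            vals = m[self.mask & np.isfinite(m)]
            out[f"dmua_{wl:g}nm"] = (vals.min(), vals.max()) if vals.size else (np.nan, np.nan)
        for name, m in self.dc.items():
            vals = m[self.mask & np.isfinite(m)]
            out[f"dC_{name}"] = (vals.min(), vals.max()) if vals.size else (np.nan, np.nan)
        return out


def compute_maps(
    scan: ScanImage,
    mask: np.ndarray,
    t0_by_wavelength: dict,
    props_by_wavelength: dict,
    geom: SlabGeometry,
    spectra: ExtinctionSpectra,
    pert_radius_cm: float = 0.5,
    irf=None,
    n_windows: int = N_TIME_WINDOWS,
    window: int = ANALYSIS_WINDOW,
    quadrature_order: int = 10,
) -> MapSet:
    """Perturbative delta_mua maps and unmixed delta_C maps for one scan.

    Every in-mask position is treated as a potential lesion at mid-slab on
    the local line of sight, with a default equivalent sphere of radius
    ``pert_radius_cm`` (maps are qualitative; ROI quantification should
    pass the lesion's own equivalent-sphere radius).  For each wavelength
    the equal-count windows are defined on the reference curve and the same
    temporal boundaries are applied to every pixel, as the gating integrates
    counts over fixed time intervals.

    When the measurement includes an instrument response (``irf``,
    an :class:`~optimammo.curve_processing.InstrumentResponse`), the
    pathlength kernel is smeared consistently before windowing:
    l_eff(tau) = (IRF * T0_model l)(tau) / (IRF * T0_model)(tau), i.e. the
    mean partial pathlength of the photons actually counted at measured
    time tau.  Omitting it with IRF-broadened data biases delta_mua low.
    """
    wavelengths = scan.wavelengths
    missing = [wl for wl in wavelengths if wl not in t0_by_wavelength or wl not in props_by_wavelength]
    if missing:
        raise ValueError(f"missing reference or properties for wavelengths {missing}")
    ny, nx = scan.shape
    dmua_maps = {}
    window_ls = {}
    for wl in wavelengths:
        t0 = np.asarray(t0_by_wavelength[wl], dtype=float)
        props = props_by_wavelength[wl]
        windows = equal_count_windows(t0, n_windows)
        sl = windows.window_slice(window)
        pert = SphericalPerturbation(
            center=(0.0, 0.0, geom.thickness / 2.0), radius=pert_radius_cm
        )
        kernel = partial_pathlength(
            props, geom, pert, scan.time_grid, quadrature_order=quadrature_order
        )
        if irf is not None:
            from .curve_processing import TimeResolvedCurve, convolve_irf
            from .forward_model import slab_transmittance

            t0_model = slab_transmittance(props, geom, scan.time_grid)
            denom = convolve_irf(
                TimeResolvedCurve(scan.time_grid, t0_model), irf
            ).counts
            numer = convolve_irf(
                TimeResolvedCurve(scan.time_grid, t0_model * kernel.l_of_t), irf
            ).counts
            l_eff = np.where(denom > 0, numer / np.maximum(denom, 1e-300), 0.0)
            kernel = PathlengthKernel(
                time_grid=scan.time_grid, l_of_t=l_eff, speed=geom.speed
            )
        l_w = window_pathlength(kernel, t0, windows, window)
        window_ls[wl] = l_w
        t0_w = t0[sl].sum()
        t_w = scan.curves[wl][..., sl].sum(axis=-1)
        m = np.full((ny, nx), np.nan)
        valid = mask & (t_w > 0)
        m[valid] = np.log(t0_w / t_w[valid]) / l_w
        dmua_maps[wl] = m
    # per-pixel unmixing via the pseudo-inverse (identical to lstsq per pixel)
    stack = np.stack([dmua_maps[wl] for wl in wavelengths], axis=-1)  # (ny, nx, 7)
    pinv = np.linalg.pinv(spectra.matrix)
    flat = stack.reshape(-1, len(wavelengths))
    ok = np.all(np.isfinite(flat), axis=1)
    dc_flat = np.full((flat.shape[0], len(CONSTITUENTS)), np.nan)
    dc_flat[ok] = flat[ok] @ pinv.T
    dc_maps = {
        name: dc_flat[:, i].reshape(ny, nx) for i, name in enumerate(CONSTITUENTS)
    }
    dc_maps["tHb"] = dc_maps["Hb"] + dc_maps["HbO2"]
    return MapSet(
        dmua=dmua_maps,
        dc=dc_maps,
        mask=mask,
        pitch_mm=scan.pitch_mm,
        window_pathlengths=window_ls,
    )


def quantify_lesion(
    scan: ScanImage,
    t0_by_wavelength: dict,
    props_by_wavelength: dict,
    geom: SlabGeometry,
    spectra: ExtinctionSpectra,
    roi: LesionROI,
    lesion_radius_cm: float,
    irf=None,
    n_windows: int = N_TIME_WINDOWS,
    window: int = ANALYSIS_WINDOW,
    quadrature_order: int = 8,
):
    """ROI quantification with the a-priori lesion position and volume.

    Unlike :func:`compute_maps`, which treats every pixel as a potential
    on-axis lesion, this uses the known equivalent sphere at the ROI
    center: each ROI pixel inverts its windowed counts with the pathlength
    kernel for the sphere seen at that pixel's lateral offset.  Returns
    (delta_mua vector over wavelengths, CompositionDelta, residual).
    """
    from .curve_processing import TimeResolvedCurve, convolve_irf
    from .forward_model import partial_pathlength_family

    wavelengths = scan.wavelengths
    ys, xs = roi.pixel_slices(scan.pitch_mm)
    cx, cy = roi.center_mm
    yy, xx = np.mgrid[ys, xs]
    dist_cm = np.hypot(xx * scan.pitch_mm - cx, yy * scan.pitch_mm - cy).ravel() / 10.0
    unique_d, inv_idx = np.unique(np.round(dist_cm, 3), return_inverse=True)
    dmua = np.empty(len(wavelengths))
    for i, wl in enumerate(wavelengths):
        t0 = np.asarray(t0_by_wavelength[wl], dtype=float)
        props = props_by_wavelength[wl]
        windows = equal_count_windows(t0, n_windows)
        sl = windows.window_slice(window)
        pert = SphericalPerturbation(
            center=(0.0, 0.0, geom.thickness / 2.0), radius=lesion_radius_cm
        )
        kernels = partial_pathlength_family(
            props, geom, pert, scan.time_grid, unique_d,
            quadrature_order=quadrature_order,
        )
        if irf is not None:
            from .forward_model import slab_transmittance as _slab

            t0_model = _slab(props, geom, scan.time_grid)
            denom = convolve_irf(
                TimeResolvedCurve(scan.time_grid, t0_model), irf
            ).counts
            smeared = []
            for k in kernels:
                numer = convolve_irf(
                    TimeResolvedCurve(scan.time_grid, t0_model * k.l_of_t), irf
                ).counts
                smeared.append(
                    PathlengthKernel(
                        scan.time_grid,
                        np.where(denom > 0, numer / np.maximum(denom, 1e-300), 0.0),
                        geom.speed,
                    )
                )
            kernels = smeared
        l_w = np.array([window_pathlength(k, t0, windows, window) for k in kernels])
        t0_w = t0[sl].sum()
        patch = scan.curves[wl][ys, xs, sl].reshape(-1, sl.stop - sl.start).sum(axis=1)
        ests = np.log(t0_w / patch) / l_w[inv_idx]
        dmua[i] = ests.mean()
    from .spectral_unmixing import unmix

    dc, residual = unmix(dmua, spectra)
    return dmua, dc, residual


def roi_mean(image: np.ndarray, roi: LesionROI, pitch_mm: float = SCAN_PITCH_MM) -> float:
    """Mean of a map over the lesion ROI (NaN pixels excluded)."""
    ys, xs = roi.pixel_slices(pitch_mm)
    patch = image[ys, xs]
    vals = patch[np.isfinite(patch)]
    if vals.size == 0:
        raise ValueError("ROI contains no valid pixels")
    return float(vals.mean())


def roi_composition(maps: MapSet, roi: LesionROI):
    """ROI-averaged constituent differences from a map set."""
    from .spectral_unmixing import CompositionDelta

    return CompositionDelta(
        dHb=roi_mean(maps.dc["Hb"], roi, maps.pitch_mm),
        dHbO2=roi_mean(maps.dc["HbO2"], roi, maps.pitch_mm),
        dWater=roi_mean(maps.dc["water"], roi, maps.pitch_mm),
        dLipid=roi_mean(maps.dc["lipid"], roi, maps.pitch_mm),
        dCollagen=roi_mean(maps.dc["collagen"], roi, maps.pitch_mm),
    )
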