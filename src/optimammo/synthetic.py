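"""Synthetic inputs with the statistical structure of the clinical study.

No patient data are deposited, so every pipeline input is emulated:

* two-group lesion cohorts (45 malignant / 39 benign by default) whose
  mean composition-difference vectors coincide while their
  variance-covariance matrices differ — the qualitative signature of the
  clinical finding — with a strong negative collagen-lipid correlation in
  the healthy background composition and realistic anamnesis covariates;
* phantom scans: a homogeneous slab with an embedded spherical lesion of
  known composition contrast, rendered through the diffusion forward
  model, IRF-convolved and Poisson-sampled, with a ground-truth sidecar.

Printed clinical coefficients used as generator parameters (the -0.78
healthy collagen-lipid correlation, the -0.271 malignant delta-collagen /
delta-lipid correlation, the 45/39 group sizes, the rarity of Tamoxifen
use) are anchors for realism, not reproduced findings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .defaults import DEFAULT_SLAB_THICKNESS_CM, WAVELENGTHS_NM
from .curve_processing import TimeResolvedCurve, convolve_irf, gaussian_irf
from .forward_model import (
    OpticalProperties,
    SlabGeometry,
    SphericalPerturbation,
    partial_pathlength_family,
    slab_transmittance,
)
from .mapping import ScanImage
from .spectral_unmixing import CompositionDelta, ExtinctionSpectra, load_extinction_table

__all__ = [
    "CohortSpec",
    "PhantomSpec",
    "generate_cohort",
    "generate_phantom_scan",
    "preset_catalog",
    "gaussian_bayes_error",
    "FEATURE_COLUMNS",
    "COVARIATE_COLUMNS",
]

FEATURE_COLUMNS = ("dHb", "dHbO2", "dWater", "dLipid", "dCollagen")
COVARIATE_COLUMNS = ("age", "BMI", "familiarity", "parity", "OC", "TAM")


def _corr_to_cov(sd: np.ndarray, corr: np.ndarray) -> np.ndarray:
    return corr * np.outer(sd, sd)


def _default_benign_cov() -> np.ndarray:
    # feature SDs of the same order of magnitude (Hb, HbO2 uM; rest mg/cm3)
    sd = np.array([4.0, 6.0, 15.0, 12.0, 10.0])
    corr = np.eye(5)
    corr[3, 4] = corr[4, 3] = -0.079  # benign delta-collagen/delta-lipid
    return _corr_to_cov(sd, corr)


def _default_malignant_cov() -> np.ndarray:
    # inflated HbO2 and collagen variability, altered collagen-lipid coupling
    sd = np.array([4.0, 6.0 * np.sqrt(3.0), 15.0, 12.0, 10.0 * np.sqrt(3.0)])
    corr = np.eye(5)
    corr[3, 4] = corr[4, 3] = -0.271  # malignant delta-collagen/delta-lipid
    return _corr_to_cov(sd, corr)


#: Common mean contrast: lesions show higher collagen, HbO2 and water,
#: lower lipid than average tissue; identical for both groups so that the
#: group difference lives in the covariances, not the means.
_DEFAULT_MEAN = np.array([2.0, 8.0, 25.0, -18.0, 15.0])


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-group Gaussian lesion cohort."""

    n_malignant: int = 45
    n_benign: int = 39
    mu_malignant: np.ndarray = field(default_factory=lambda: _DEFAULT_MEAN.copy())
    mu_benign: np.ndarray = field(default_factory=lambda: _DEFAULT_MEAN.copy())
    sigma_malignant: np.ndarray = field(default_factory=_default_malignant_cov)
    sigma_benign: np.ndarray = field(default_factory=_default_benign_cov)
    background_collagen_lipid_corr: float = -0.78
    tam_probability: float = 3.0 / 84.0
    heavy_tails: bool = False  # multivariate-t alternative (df=5)
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_malignant", "sigma_benign"):
            s = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, s)
            if not np.allclose(s, s.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(s) <= 0):
                raise ValueError(f"{name} must be positive definite")
        for name in ("mu_malignant", "mu_benign"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


def _draw_group(rng, mu, sigma, n, heavy_tails):
    if not heavy_tails:
        return rng.multivariate_normal(mu, sigma, size=n, method="cholesky")
    df = 5.0
    g = rng.chisquare(df, size=n) / df
    z = rng.multivariate_normal(np.zeros(len(mu)), sigma, size=n, method="cholesky")
    return mu + z / np.sqrt(g)[:, None] * np.sqrt((df - 2) / df)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        good = draw[(draw >= lo) & (draw <= hi)]
        take = min(good.size, size - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a lesion cohort as a data frame.

    Columns: lesion_id, label (+1 malignant / -1 benign), the five
    composition-difference features, the healthy-background absolute
    collagen and lipid concentrations (correlated at the configured
    level), and the six anamnesis covariates.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_mal, n_ben = spec.n_malignant, spec.n_benign
    n = n_mal + n_ben
    feats_mal = _draw_group(rng, spec.mu_malignant, spec.sigma_malignant, n_mal, spec.heavy_tails)
    feats_ben = _draw_group(rng, spec.mu_benign, spec.sigma_benign, n_ben, spec.heavy_tails)
    feats = np.vstack([feats_mal, feats_ben])
    labels = np.concatenate([np.ones(n_mal, dtype=int), -np.ones(n_ben, dtype=int)])

    # healthy background composition: adipose vs fibroglandular trade-off
    r = spec.background_collagen_lipid_corr
    cov_bg = _corr_to_cov(np.array([30.0, 150.0]), np.array([[1.0, r], [r, 1.0]]))
    bg = rng.multivariate_normal([100.0, 600.0], cov_bg, size=n, method="cholesky")
    bg = np.clip(bg, 1.0, None)

    frame = pd.DataFrame(feats, columns=list(FEATURE_COLUMNS))
    frame.insert(0, "lesion_id", [f"L{i:03d}" for i in range(n)])
    frame.insert(1, "label", labels)
    frame["bg_collagen"] = bg[:, 0]
    frame["bg_lipid"] = bg[:, 1]
    frame["age"] = np.round(_truncated_normal(rng, 55.0, 10.0, 40.0, 75.0, n), 0)
    frame["BMI"] = np.round(_truncated_normal(rng, 25.0, 4.0, 18.0, 35.0, n), 1)
    frame["familiarity"] = rng.binomial(1, 0.15, size=n)
    frame["parity"] = rng.choice(5, size=n, p=[0.15, 0.20, 0.35, 0.20, 0.10])
    frame["OC"] = rng.binomial(1, 0.40, size=n)
    frame["TAM"] = rng.binomial(1, spec.tam_probability, size=n)
    return frame


def gaussian_bayes_error(spec: CohortSpec) -> float:
    """Analytic Bayes error for an equal-covariance, equal-prior spec.

    For two Gaussians with shared covariance S the optimal rule errs with
    probability Phi(-Delta/2) where Delta^2 = dmu' S^-1 dmu (the
    Mahalanobis distance between the class means).
    """
    if not np.allclose(spec.sigma_malignant, spec.sigma_benign):
        raise ValueError("analytic Bayes error requires equal covariances")
    dmu = spec.mu_malignant - spec.mu_benign
    delta = float(np.sqrt(dmu @ np.linalg.solve(spec.sigma_malignant, dmu)))
    return float(norm.cdf(-delta / 2.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic scanned breast phantom."""

    grid_shape: tuple = (35, 35)  # (ny, nx) pixels at 1 mm pitch
    thickness_cm: float = DEFAULT_SLAB_THICKNESS_CM
    musp0: float = 10.0  # background reduced scattering, cm^-1 (all wavelengths)
    mua0: dict | None = None  # wavelength -> background mua; default preset
    lesion_center_mm: tuple = (11.0, 11.0)
    lesion_diameter_mm: float = 10.0
    #: lesion composition contrast; defaults sit inside the delta-C map
    #: ranges the clinical study reports for an example lesion breast
    lesion_dc: CompositionDelta = field(
        default_factory=lambda: CompositionDelta(8.0, 12.0, 120.0, -80.0, 60.0)
    )
    counts_per_pixel: float = 1e6
    irf_fwhm_ps: float = 460.0
    t_max_ps: float = 8000.0
    dt_ps: float = 10.0
    seed: int = 0

    def background_mua(self) -> dict:
        if self.mua0 is not None:
            return dict(self.mua0)
        # breast-like background spectrum (cm^-1)
        return {
            635: 0.085, 685: 0.055, 785: 0.045, 905: 0.065,
            930: 0.10, 975: 0.16, 1060: 0.09,
        }


def generate_phantom_scan(
    spec: PhantomSpec,
    spectra: ExtinctionSpectra | None = None,
    quadrature_order: int = 8,
) -> tuple[ScanImage, dict]:
    """Render a scanned phantom with an embedded spherical lesion.

    Per pixel and wavelength the slab transmittance is attenuated by
    exp(-delta_mua * l_d(t)) with the Born pathlength kernel for the
    pixel's lateral distance d to the lesion axis, convolved with a
    Gaussian IRF and Poisson-sampled at the configured expected counts.
    The lesion composition contrast is converted to per-wavelength
    delta_mua through the same extinction table used downstream, keeping
    the loop closed.

    Returns the scan and a ground-truth sidecar dict (delta_mua per
    wavelength, composition contrast, center, radius).
    """
    if spectra is None:
        spectra = load_extinction_table()
    ny, nx = spec.grid_shape
    t = np.arange(spec.dt_ps / 2.0, spec.t_max_ps, spec.dt_ps)
    geom = SlabGeometry(thickness=spec.thickness_cm)
    radius_cm = spec.lesion_diameter_mm / 20.0
    depth = spec.thickness_cm / 2.0
    dmua_vec = spectra.absorption(spec.lesion_dc.as_array())
    irf = gaussian_irf(spec.irf_fwhm_ps, spec.dt_ps)
    rng = np.random.default_rng(spec.seed)

    xs = np.arange(nx) * 1.0
    ys = np.arange(ny) * 1.0
    cx_mm, cy_mm = spec.lesion_center_mm
    dist_mm = np.hypot(
        xs[None, :] - cx_mm, ys[:, None] - cy_mm
    )  # pixel distance to lesion axis
    # kernels only matter while the sphere still shadows the axis appreciably
    cutoff_mm = radius_cm * 10.0 + 8.0
    dist_idx = np.clip(np.rint(dist_mm), 0, None).astype(int)
    unique_d = np.unique(dist_idx[dist_idx <= cutoff_mm])

    mua0 = spec.background_mua()
    wavelengths = sorted(mua0)
    curves = {}
    truth_dmua = {}
    for i, wl in enumerate(wavelengths):
        props = OpticalProperties(mua=mua0[wl], musp=spec.musp0, wavelength=wl)
        pert = SphericalPerturbation(
            center=(0.0, 0.0, depth), radius=radius_cm, delta_mua=float(dmua_vec[i])
        )
        t0 = slab_transmittance(props, geom, t)
        if pert.delta_mua == 0.0:
            # null lesion at this wavelength: no kernels needed
            base_raw = convolve_irf(TimeResolvedCurve(t, t0), irf).counts
            lam = np.empty((ny, nx, t.size))
            lam[:] = base_raw * (spec.counts_per_pixel / base_raw.sum())
            curves[wl] = rng.poisson(lam).astype(float)
            truth_dmua[wl] = 0.0
            continue
        kernels = partial_pathlength_family(
            props, geom, pert, t, unique_d / 10.0, quadrature_order=quadrature_order
        )
        base_raw = convolve_irf(TimeResolvedCurve(t, t0), irf).counts
        # one acquisition scale per wavelength: perturbed pixels keep their
        # physically lower count totals relative to the background
        scale = spec.counts_per_pixel / base_raw.sum()
        lam = np.empty((ny, nx, t.size))
        lam[:] = base_raw * scale
        for d, k in zip(unique_d, kernels):
            pert_curve = t0 * np.exp(-pert.delta_mua * k.l_of_t)
            pc = convolve_irf(TimeResolvedCurve(t, pert_curve), irf).counts
            lam[dist_idx == d] = pc * scale
        curves[wl] = rng.poisson(lam).astype(float)
        truth_dmua[wl] = float(dmua_vec[i])

    scan = ScanImage(curves=curves, time_grid=t)
    truth = {
        "delta_mua": truth_dmua,
        "delta_c": {
            "Hb": spec.lesion_dc.dHb,
            "HbO2": spec.lesion_dc.dHbO2,
            "water": spec.lesion_dc.dWater,
            "lipid": spec.lesion_dc.dLipid,
            "collagen": spec.lesion_dc.dCollagen,
        },
        "center_mm": [float(cx_mm), float(cy_mm)],
        "radius_cm": radius_cm,
        "diameter_mm": spec.lesion_diameter_mm,
        "depth_cm": depth,
        "background_mua": {float(k): float(v) for k, v in mua0.items()},
        "musp": spec.musp0,
    }
    return scan, truth


def preset_catalog() -> dict:
    """Named study presets.

    * ``null-cohort`` — identical groups (benign parameters for both);
      calibration runs of the permutation tests should reject at ~alpha.
    * ``paper-like-cohort`` — equal means, differing covariances, 45/39:
      the covariance test should reject, the mean test should not.
    * ``bayes15-cohort`` — equal covariances with a mean shift tuned to an
      analytic Bayes error of 15%, for classifier benchmarking.
    * ``fibroadenoma-phantom`` — 10 mm lesion (5 x 5 mm^2 lesion area).
    * ``carcinoma-phantom`` — 18 mm lesion (9 x 9 mm^2 lesion area).
    """
    null_spec = CohortSpec(
        sigma_malignant=_default_benign_cov(),
        sigma_benign=_default_benign_cov(),
    )
    # mean shift along collagen: Delta = dmu/sd = 2 * 1.03643 -> Phi(-1.03643) = 15%
    shift = 2.0 * 1.0364333894937898 * 10.0
    mu_b = _DEFAULT_MEAN.copy()
    mu_m = _DEFAULT_MEAN.copy()
    mu_m[4] += shift
    bayes15 = CohortSpec(
        n_malignant=1000,
        n_benign=1000,
        mu_malignant=mu_m,
        mu_benign=mu_b,
        sigma_malignant=_default_benign_cov(),
        sigma_benign=_default_benign_cov(),
    )
    return {
        "null-cohort": null_spec,
        "paper-like-cohort": CohortSpec(),
        "bayes15-cohort": bayes15,
        "fibroadenoma-phantom": PhantomSpec(lesion_diameter_mm=10.0),
        "carcinoma-phantom": PhantomSpec(
            lesion_diameter_mm=18.0,
            lesion_dc=CompositionDelta(10.0, 18.0, 160.0, -90.0, 90.0),
        ),
    }
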