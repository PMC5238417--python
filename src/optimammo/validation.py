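"""Seeded validation studies tying the pipeline stages together.

Each function runs one self-contained computation — forward model vs
Monte-Carlo, inverse round trips, statistical calibration, classifier
benchmarks — at study-scale problem sizes, and returns plain numbers.
They back both the validation tests and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import (
    CohortSpec,
    CompositionDelta,
    LesionROI,
    OpticalProperties,
    PhantomSpec,
    SlabGeometry,
    SphericalPerturbation,
    add_poisson_noise,
    breast_mask,
    compute_maps,
    convolve_irf,
    covariance_permutation_test,
    equal_count_windows,
    estimate_delta_mua,
    evaluate_repeated,
    fit_homogeneous,
    gaussian_bayes_error,
    gaussian_irf,
    generate_cohort,
    generate_phantom_scan,
    load_extinction_table,
    monte_carlo_oracle,
    partial_pathlength,
    partial_pathlength_family,
    permutation_mean_test,
    preset_catalog,
    reference_curve,
    roi_composition,
    roi_for_diameter,
    slab_transmittance,
    unmix,
)
from .curve_processing import TimeResolvedCurve, window_pathlength
from .forward_model import PathlengthKernel
from .synthetic import FEATURE_COLUMNS

__all__ = [
    "beer_lambert_error",
    "cw_integral_error",
    "mc_curve_shape_agreement",
    "mc_pathlength_agreement",
    "fit_recovery_study",
    "gated_inversion_roundtrip",
    "unmix_roundtrip_error",
    "phantom_roi_study",
    "window_balance_study",
    "null_calibration_study",
    "paper_like_power_study",
    "bayes15_benchmark",
]


def beer_lambert_error(delta: float = 0.02) -> float:
    """Max relative deviation from the exact time-domain Beer-Lambert
    scaling under a homogeneous absorption shift."""
    props = OpticalProperties(mua=0.05, musp=10.0)
    geom = SlabGeometry()
    t = np.arange(5.0, 12000.0, 10.0)
    t0 = slab_transmittance(props, geom, t)
    t1 = slab_transmittance(OpticalProperties(props.mua + delta, props.musp), geom, t)
    return float(np.max(np.abs(t1 - t0 * np.exp(-delta * geom.speed * t))) / t0.max())


def cw_integral_error() -> float:
    """Relative difference between the time integral of the transmittance
    and the closed-form steady-state value."""
    from .forward_model import cw_transmittance

    props = OpticalProperties(mua=0.05, musp=10.0)
    geom = SlabGeometry()
    t = np.arange(0.5, 60000.0, 1.0)
    integral = np.trapezoid(slab_transmittance(props, geom, t), t)
    cw = cw_transmittance(props, geom)
    return float(abs(integral - cw) / cw)


def _fwhm_and_peak(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Interpolated full width at half maximum and parabolic peak time."""
    sm = np.convolve(c, np.ones(5) / 5.0, mode="same")
    i = int(np.argmax(sm))
    half = sm[i] / 2.0
    left = np.where(sm[:i] <= half)[0]
    li = left[-1] if left.size else 0
    tl = np.interp(half, [sm[li], sm[li + 1]], [t[li], t[li + 1]])
    right = np.where(sm[i:] <= half)[0]
    ri = i + (right[0] if right.size else len(sm) - 1 - i)
    tr = np.interp(half, [sm[ri], sm[ri - 1]], [t[ri], t[ri - 1]])
    sel = slice(max(i - 6, 0), i + 7)
    coef = np.polyfit(t[sel], sm[sel], 2)
    return tr - tl, -coef[1] / (2 * coef[0])


def mc_curve_shape_agreement(seed: int, n_photons: int = 1_000_000) -> dict:
    """Diffusion vs Monte-Carlo transmittance shape in the diffusive regime
    (mua 0.05, musp 10 cm^-1, 4 cm slab): relative peak-time and FWHM
    differences of the spatially integrated curves."""
    props = OpticalProperties(mua=0.05, musp=10.0)
    geom = SlabGeometry()
    t = np.arange(25.0, 8000.0, 50.0)
    mc = monte_carlo_oracle(
        props, geom, None, t, n_photons, seed=seed, detector_radius=1e9
    )
    model = slab_transmittance(props, geom, t)
    D = props.diffusion_coefficient
    total = model * 4.0 * np.pi * D * geom.speed * t  # lateral integral
    fw_mc, pk_mc = _fwhm_and_peak(t, mc.counts)
    fw_d, pk_d = _fwhm_and_peak(t, total)
    return {
        "peak_rel_dev": abs(pk_mc - pk_d) / pk_d,
        "fwhm_rel_dev": abs(fw_mc - fw_d) / fw_d,
        "n_detected": mc.n_detected,
    }


def mc_pathlength_agreement(seed: int, n_photons: int = 1_000_000) -> dict:
    """Born partial-pathlength kernel vs the Monte-Carlo mean pathlength
    inside a mid-slab sphere (mua 0.07, musp 10 cm^-1, radius 0.5 cm).

    Photons within 1.2 cm of the axis are compared against a
    detection-weighted average of kernels across lateral offsets; the
    headline number is the count-weighted mean relative deviation over
    well-populated bins past the transmittance peak.
    """
    props = OpticalProperties(mua=0.07, musp=10.0)
    geom = SlabGeometry()
    radius_det = 1.2
    pert = SphericalPerturbation(center=(0.0, 0.0, 2.0), radius=0.5, delta_mua=0.1)
    coarse = np.arange(125.0, 8000.0, 250.0)
    fine = np.arange(5.0, 8000.0, 10.0)
    offsets = np.arange(0.1, radius_det, 0.2)
    # photons exit across the detection disc: the matching kernel keeps the
    # sphere on the source axis and displaces the detection point
    kernels = [
        partial_pathlength(
            props,
            SlabGeometry(detector_pos=(off * 10.0, 0.0)),
            pert,
            fine,
            quadrature_order=10,
        )
        for off in offsets
    ]
    t0_fine = slab_transmittance(props, geom, fine)
    D = props.diffusion_coefficient
    v = geom.speed
    edges = np.arange(0.0, 8000.0 + 1.0, 250.0)
    idx = np.digitize(fine, edges) - 1
    binned = []
    for off, k in zip(offsets, kernels):
        w_t = t0_fine * np.exp(-(off**2) / (4.0 * D * v * fine))
        binned.append(np.array([
            np.average(k.l_of_t[idx == i], weights=w_t[idx == i])
            for i in range(len(coarse))
        ]))
    binned = np.array(binned)
    w_off = offsets[:, None] * np.exp(-(offsets[:, None] ** 2) / (4.0 * D * v * coarse[None, :]))
    k_avg = (binned * w_off).sum(axis=0) / w_off.sum(axis=0)

    mc = monte_carlo_oracle(
        props, geom, pert, coarse, n_photons, seed=seed, detector_radius=radius_det
    )
    n_per_bin = mc.counts / np.exp(-props.mua * v * coarse)
    peak_bin = int(np.argmax(slab_transmittance(props, geom, coarse)))
    sel = (np.arange(len(coarse)) >= peak_bin) & (n_per_bin >= 250)
    rel = np.abs(mc.mean_sphere_path[sel] - k_avg[sel]) / k_avg[sel]
    return {
        "weighted_mean_rel_dev": float(np.average(rel, weights=n_per_bin[sel])),
        "max_rel_dev": float(rel.max()),
        "n_bins": int(sel.sum()),
    }


def fit_recovery_study(seed: int, n_seeds: int = 20, counts: float = 1e6) -> dict:
    """Homogeneous-fit recovery of (mua, musp) from Poisson curves."""
    geom = SlabGeometry()
    truth = OpticalProperties(mua=0.08, musp=12.0)
    t = np.arange(5.0, 12000.0, 10.0)
    irf = gaussian_irf(600.0, 10.0)
    model = convolve_irf(
        TimeResolvedCurve(t, slab_transmittance(truth, geom, t)), irf
    )
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_seeds) & 0x7FFFFFFF
    mua_err, musp_err = [], []
    for s in rng_seeds:
        noisy = add_poisson_noise(model, counts, seed=int(s))
        fit = fit_homogeneous(noisy, irf, geom)
        if not fit.converged:
            raise RuntimeError("homogeneous fit failed to converge")
        mua_err.append(abs(fit.props.mua / truth.mua - 1.0))
        musp_err.append(abs(fit.props.musp / truth.musp - 1.0))
    return {
        "max_mua_rel_err": float(np.max(mua_err)),
        "max_musp_rel_err": float(np.max(musp_err)),
        "mean_mua_rel_err": float(np.mean(mua_err)),
        "mean_musp_rel_err": float(np.mean(musp_err)),
    }


def gated_inversion_roundtrip() -> dict:
    """Noise-free window-8 inversion of a planted absorption contrast.

    Two variants: a window-constant kernel (machine-precision recovery)
    and the physical time-varying kernel (limited only by exponential
    averaging across the window).
    """
    props = OpticalProperties(mua=0.05, musp=10.0)
    geom = SlabGeometry()
    t = np.arange(5.0, 12000.0, 10.0)
    t0 = slab_transmittance(props, geom, t)
    win = equal_count_windows(t0, 10)
    sl = win.window_slice(8)
    dmua = 0.0432

    const = PathlengthKernel(t, np.full_like(t, 1.7))
    tp = t0 * np.exp(-dmua * const.l_of_t)
    lw = window_pathlength(const, t0, win, 8)
    err_const = abs(estimate_delta_mua(tp[sl].sum(), t0[sl].sum(), lw) / dmua - 1.0)

    pert = SphericalPerturbation(center=(0, 0, 2.0), radius=0.5, delta_mua=dmua)
    kern = partial_pathlength(props, geom, pert, t, quadrature_order=8)
    tp2 = t0 * np.exp(-dmua * kern.l_of_t)
    lw2 = window_pathlength(kern, t0, win, 8)
    err_phys = abs(estimate_delta_mua(tp2[sl].sum(), t0[sl].sum(), lw2) / dmua - 1.0)
    return {"constant_kernel_rel_err": err_const, "physical_kernel_rel_err": err_phys}


def unmix_roundtrip_error(seed: int, n_vectors: int = 50) -> float:
    """Worst-case relative recovery error of consistent Beer-law systems."""
    spectra = load_extinction_table()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        truth = rng.normal(scale=[5.0, 10.0, 50.0, 40.0, 30.0])
        dc, _ = unmix(spectra.absorption(truth), spectra)
        denom = np.maximum(np.abs(truth), 1e-6)
        worst = max(worst, float(np.max(np.abs(dc.as_array() - truth) / denom)))
    return worst


def phantom_roi_study(seed: int, counts_per_pixel: float = 1e6) -> dict:
    """End-to-end phantom round trip: render a scanned phantom with an
    embedded 10 mm lesion, run masking, reference extraction, gated
    inversion and unmixing, and compare the ROI-mean composition contrast
    with the planted ground truth."""
    spec = PhantomSpec(counts_per_pixel=counts_per_pixel, seed=seed)
    spectra = load_extinction_table()
    scan, truth = generate_phantom_scan(spec)
    mask = breast_mask(scan, count_threshold=1.0)
    ny, nx = scan.shape
    ys, xs = np.ogrid[:ny, :nx]
    near_lesion = np.hypot(
        xs - truth["center_mm"][0], ys - truth["center_mm"][1]
    ) <= truth["radius_cm"] * 10.0 + 8.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t0 = reference_curve(scan, mask, erosion_mm=2.0, exclude=near_lesion)
    props = {
        wl: OpticalProperties(mua=truth["background_mua"][wl], musp=truth["musp"])
        for wl in scan.wavelengths
    }
    irf = gaussian_irf(spec.irf_fwhm_ps, spec.dt_ps)
    maps = compute_maps(
        scan, mask, t0, props, SlabGeometry(thickness=spec.thickness_cm), spectra,
        pert_radius_cm=truth["radius_cm"], irf=irf,
    )
    roi = LesionROI(
        center_mm=tuple(truth["center_mm"]),
        side_mm=roi_for_diameter(truth["diameter_mm"]),
    )
    from .mapping import quantify_lesion

    _, est, _ = quantify_lesion(
        scan, t0, props, SlabGeometry(thickness=spec.thickness_cm), spectra,
        roi, lesion_radius_cm=truth["radius_cm"], irf=irf,
    )
    ref = truth["delta_c"]
    rel = {
        name: abs(val / ref[key] - 1.0)
        for name, key, val in (
            ("Hb", "Hb", est.dHb),
            ("HbO2", "HbO2", est.dHbO2),
            ("water", "water", est.dWater),
            ("lipid", "lipid", est.dLipid),
            ("collagen", "collagen", est.dCollagen),
        )
    }
    # localization: centroid of the above-half-max region of the lightly
    # smoothed collagen map (robust to the flat top and pixel noise)
    from scipy import ndimage

    sm = ndimage.uniform_filter(np.nan_to_num(maps.dc["collagen"]), 3)
    top = sm >= 0.5 * sm.max()
    cy, cx = ndimage.center_of_mass(sm * top)
    loc_err = float(np.hypot(cx - truth["center_mm"][0], cy - truth["center_mm"][1]))
    return {
        "roi_rel_err": rel,
        "max_roi_rel_err": float(max(rel.values())),
        "localization_err_mm": loc_err,
    }


def window_balance_study(seed: int, n_curves: int = 300) -> float:
    """Max deviation of split-mode window totals from total/K over random
    count histograms (including adversarial spiky ones)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_curves):
        n = rng.integers(5, 400)
        counts = rng.poisson(rng.uniform(0, 50), size=n).astype(float)
        spikes = rng.integers(0, n, size=rng.integers(0, 4))
        counts[spikes] += rng.integers(100, 10_000, size=spikes.size)
        k = int(rng.integers(2, 11))
        if counts.sum() < k:
            continue
        win = equal_count_windows(counts, k, split_bins=True)
        worst = max(worst, float(np.max(np.abs(win.totals - counts.sum() / k))))
    return worst


def _simulate_rejections(seed: int, n_sims: int, make_groups, n_perm: int = 199,
                         alpha: float = 0.05) -> dict:
    rng = np.random.default_rng(seed)
    rej_mean = rej_cov = 0
    for i in range(n_sims):
        X, labels = make_groups(rng)
        s = int(rng.integers(2**31 - 1))
        p_m = permutation_mean_test(X, labels, n_perm=n_perm, seed=s).p_value
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_c = covariance_permutation_test(X, labels, n_perm=n_perm, seed=s + 1).p_value
        rej_mean += p_m <= alpha
        rej_cov += p_c <= alpha
    return {"mean_test_rate": rej_mean / n_sims, "cov_test_rate": rej_cov / n_sims,
            "n_sims": n_sims}


def null_calibration_study(seed: int, n_sims: int = 1000) -> dict:
    """Type-I error of both permutation tests on identically distributed
    groups (n = 20 + 20, d = 5) at alpha = 0.05."""
    def make(rng):
        X = rng.standard_normal((40, 5))
        return X, np.repeat([0, 1], 20)

    return _simulate_rejections(seed, n_sims, make)


def paper_like_power_study(seed: int, n_sims: int = 250) -> dict:
    """Rejection rates on draws of the default cohort preset (45/39,
    equal means, differing covariances): the covariance test should have
    high power while the mean test stays near alpha."""
    base = preset_catalog()["paper-like-cohort"]
    L_mal = np.linalg.cholesky(base.sigma_malignant)
    L_ben = np.linalg.cholesky(base.sigma_benign)

    def make(rng):
        mal = base.mu_malignant + rng.standard_normal((base.n_malignant, 5)) @ L_mal.T
        ben = base.mu_benign + rng.standard_normal((base.n_benign, 5)) @ L_ben.T
        X = np.vstack([mal, ben])
        labels = np.repeat([1, -1], [base.n_malignant, base.n_benign])
        return X, labels

    return _simulate_rejections(seed, n_sims, make)


def bayes15_benchmark(seed: int, runs: int = 20) -> dict:
    """Discrete AdaBoost on the analytic 15%-Bayes-error cohort: mean +/- SD
    held-out misclassification over repeated runs of 50 boosting rounds."""
    spec = preset_catalog()["bayes15-cohort"]
    spec = CohortSpec(
        n_malignant=spec.n_malignant, n_benign=spec.n_benign,
        mu_malignant=spec.mu_malignant, mu_benign=spec.mu_benign,
        sigma_malignant=spec.sigma_malignant, sigma_benign=spec.sigma_benign,
        seed=seed,
    )
    cohort = generate_cohort(spec)
    X = cohort[list(FEATURE_COLUMNS)].to_numpy()
    y = cohort["label"].to_numpy()
    summary = evaluate_repeated(X, y, runs=runs, n_rounds=50, seed=seed)
    mean, sd = summary.misclassification_mean_sd
    return {
        "bayes_error_pct": 100.0 * gaussian_bayes_error(spec),
        "misclassification_mean_pct": mean,
        "misclassification_sd_pct": sd,
        "auc": summary.auc,
        "sensitivity_mean_pct": summary.sensitivity_mean_sd[0],
        "specificity_mean_pct": summary.specificity_mean_sd[0],
    }
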