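"""Composite validation experiments tying the pipeline stages together.

Each function runs one of the package's headline studies end to end on
synthetic data with known ground truth and returns plain dictionaries of
numbers: placement contact fractions against the closed-form acceptance
probability, attraction-model recovery by total-variation distance, the
Kd calibration and clustered-vs-distributed comparison, particle-pose
recovery, fiducial registration noise response, surface-topology checks,
and the synthesize-render-detect round trip.  The problem sizes default
to values that keep each study in the minutes range on one core.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .averaging import ParticleStack, align_stack, average_stack, pose_recovery_errors
from .clusters import binarize, detect_clusters
from .geometry import Ellipse, ellipses_overlap
from .placement import (
    PlacementConfig,
    compare_distributions,
    expected_contact_probability,
    place_query,
    run_placement_experiment,
)
from .registration import AffineTransform2D, estimate_affine, registration_error
from .synthetic import (
    gen_ellipse_field,
    gen_fiducial_pairs,
    gen_height_map,
    gen_particle_stack,
    render_localization_image,
)
from .topology import amplification_factor, detect_peaks, peak_spacing_stats, periodicity_spectrum
from .walk import WalkConfig, calibrate_probabilities, compare_arrangements, _with_probs

__all__ = [
    "placement_contact_study",
    "placement_model_recovery",
    "kd_arrangement_study",
    "averaging_recovery_study",
    "registration_noise_study",
    "topology_study",
    "roundtrip_detection_study",
]

# single circular reference in the middle of a 2 x 2 um box; a circular
# query of radius 100 nm overlaps it iff its center falls within 300 nm
_BOX = (2000.0, 2000.0)
_REF = Ellipse(1000.0, 1000.0, 200.0, 200.0)
_QUERY_R = 100.0


def placement_contact_study(
    f_values=(1.0, 2.0, 4.0, 8.0), n_reps: int = 1000, seed: int = 0
) -> dict:
    """Simulated contact fraction vs. the analytic acceptance probability.

    Single-circular-reference geometry where the uniform overlap
    probability p is closed-form; returns per-f simulated fractions,
    expectations p*f/(p*f+1-p) and binomial standard errors.
    """
    p = np.pi * (_REF.a + _QUERY_R) ** 2 / (_BOX[0] * _BOX[1])
    rng = np.random.default_rng(seed)
    out = {"p_overlap": p, "n_reps": n_reps, "f": {}}
    for f in f_values:
        hits = 0
        for _ in range(n_reps):
            q = place_query(*_BOX, [_REF], np.array([[_QUERY_R, _QUERY_R]]), f, rng)[0]
            hits += ellipses_overlap(q, _REF)
        expected = expected_contact_probability(p, f)
        out["f"][f] = {
            "simulated": hits / n_reps,
            "expected": expected,
            "se": float(np.sqrt(expected * (1 - expected) / n_reps)),
        }
    return out


def _experiment_config(f: float, reps: int, seed: int) -> PlacementConfig:
    return PlacementConfig(
        boxes=[(3000.0, 3, 6)],
        size_source={"reference": [(150.0, 90.0)], "query": [(100.0, 60.0)]},
        attraction_f=f,
        n_reps=reps,
        seed=seed,
    )


def placement_model_recovery(
    n_replicates: int = 100, obs_reps: int = 10, model_reps: int = 200, seed: int = 0
) -> dict:
    """Attraction-model identification by total-variation distance.

    Mean distance histograms are simulated for the random (f=1) and
    attraction (f=4) models; observed data generated under f=4 are
    assigned to whichever model histogram is closer in total variation.
    Returns the fraction of replicates assigned correctly.
    """
    h1 = run_placement_experiment(_experiment_config(1.0, model_reps, seed + 1)).mean_histogram
    h4 = run_placement_experiment(_experiment_config(4.0, model_reps, seed + 2)).mean_histogram
    correct = 0
    for r in range(n_replicates):
        obs = run_placement_experiment(
            _experiment_config(4.0, obs_reps, seed + 1000 + r)
        ).mean_histogram
        tv4 = compare_distributions(h4, obs)["total_variation"]
        tv1 = compare_distributions(h1, obs)["total_variation"]
        correct += tv4 < tv1
    return {
        "n_replicates": n_replicates,
        "recovery_fraction": correct / n_replicates,
        "model_tv_f1_vs_f4": compare_distributions(h1, h4)["total_variation"],
    }


KD_TARGET_NM = 110.0  # mean of the 88 nM (apoCaM) and 132 nM (Ca2+/CaM) anchors
DEFAULT_CALIBRATION_GRID = (
    (0.5, 0.002),
    (0.5, 0.005),
    (0.5, 0.008),
    (0.5, 0.012),
    (1.0, 0.005),
    (1.0, 0.012),
)


def kd_arrangement_study(
    seed: int = 0,
    calibration_reps: int = 20,
    comparison_reps: int = 200,
    grid=DEFAULT_CALIBRATION_GRID,
) -> dict:
    """Calibrate (p_bind, p_unbind) toward the experimental Kd anchors and
    compare channel arrangements.

    Calibration runs on the clustered arrangement (the physiological
    geometry); the best grid point is then used for a paired
    clustered-vs-distributed comparison with a one-sided Wilcoxon
    signed-rank test.
    """
    base = WalkConfig(arrangement="clustered")
    table = calibrate_probabilities(
        KD_TARGET_NM, grid, base, n_reps=calibration_reps, seed=seed
    )
    best = table.iloc[0]
    cfg = _with_probs(base, float(best["p_bind"]), float(best["p_unbind"]))
    comparison = compare_arrangements(cfg, n_reps=comparison_reps, seed=seed + 17)
    return {
        "calibration_table": table,
        "p_bind": float(best["p_bind"]),
        "p_unbind": float(best["p_unbind"]),
        "calibrated_kd_nM": float(best["kd_nM"]),
        "target_kd_nM": KD_TARGET_NM,
        "clustered_kd_nM": comparison["clustered_kd_nM"],
        "distributed_kd_nM": comparison["distributed_kd_nM"],
        "p_value_one_sided": comparison["p_value_one_sided"],
        "comparison_reps": comparison_reps,
    }


def registered_correlation(image: np.ndarray, template: np.ndarray) -> float:
    """Pearson correlation maximized over a rigid registration.

    The consensus frame of a reference-free average is arbitrary, so the
    average is registered to the template (rotation grid search plus FFT
    translation) before correlating.
    """
    tpl = template - template.mean()
    best = -1.0
    for ang in np.arange(-45.0, 45.5, 1.0):
        a = ndimage.rotate(image, ang, reshape=False, order=1)
        a = a - a.mean()
        C = np.fft.irfft2(np.conj(np.fft.rfft2(a)) * np.fft.rfft2(tpl), s=a.shape)
        best = max(best, float(C.max() / np.sqrt((a * a).sum() * (tpl * tpl).sum())))
    return best


def averaging_recovery_study(
    n_stacks: int = 10,
    n_particles: int = 50,
    max_shift_px: float = 10.0,
    max_rot_deg: float = 30.0,
    noise_level: float = 0.1,
    seed: int = 0,
) -> dict:
    """Pose recovery and template correlation on synthetic particle stacks."""
    ok, corrs, monotone = [], [], True
    for k in range(n_stacks):
        truth = gen_particle_stack(
            n=n_particles,
            max_shift_px=max_shift_px,
            max_rot_deg=max_rot_deg,
            noise_level=noise_level,
            seed=seed + k,
        )
        stack = ParticleStack(truth.particles).binarized()
        margin = 3 * 2.0  # rotation search band beyond the generating range
        poses = align_stack(
            stack, channel=0, rot_range_deg=(-max_rot_deg - margin, max_rot_deg + margin)
        )
        hist = np.array(poses.score_history)
        monotone &= bool((np.diff(hist) >= -1e-9 * np.abs(hist[:-1])).all())
        rot_err, shift_err = pose_recovery_errors(poses, truth.poses)
        ok.extend(((rot_err <= 2.0) & (shift_err <= 1.0)).tolist())
        avg = average_stack(stack, poses)
        corrs.append(registered_correlation(avg[0], truth.template[0]))
    return {
        "pose_recovery_fraction": float(np.mean(ok)),
        "mean_template_correlation": float(np.mean(corrs)),
        "min_template_correlation": float(np.min(corrs)),
        "score_monotone": monotone,
        "n_stacks": n_stacks,
    }


def registration_noise_study(
    n_trials: int = 100, n_pairs: int = 20, noise_nm: float = 5.0, seed: int = 0
) -> dict:
    """Affine recovery under fiducial noise: residual RMSE per trial."""
    true = AffineTransform2D(np.array([[1.1, 0.15], [-0.08, 0.95]]), np.array([300.0, -120.0]))
    rmses = []
    for t in range(n_trials):
        src, dst = gen_fiducial_pairs(true, n=n_pairs, noise_nm=noise_nm, seed=seed + t)
        T = estimate_affine(src, dst)
        rmse, _ = registration_error(src, dst, T)
        rmses.append(rmse)
    return {
        "noise_nm": noise_nm,
        "rmse_nm": np.array(rmses),
        "max_rmse_nm": float(np.max(rmses)),
        "mean_rmse_nm": float(np.mean(rmses)),
    }


def topology_study() -> dict:
    """Amplification, periodicity and peak-spacing checks on analytic surfaces."""
    flat = amplification_factor(gen_height_map("flat", extent=2000, spacing=20))
    lam = 500.0
    amp_sin = amplification_factor(
        gen_height_map("sinusoid", lam / (2 * np.pi), lam, extent=4000, spacing=5)
    )
    hm = gen_height_map("bump_lattice", 150.0, 500.0, 4000.0, 20.0)
    peaks = detect_peaks(hm, 250.0, 50.0)
    nn, _, _ = peak_spacing_stats(peaks, "projected_2d")
    spec = periodicity_spectrum(peaks, render_sigma_nm=50.0, pixel_nm=20.0)
    # modal nearest-neighbour spacing on the 20 nm grid
    vals, counts = np.unique(np.round(nn / 20.0) * 20.0, return_counts=True)
    return {
        "flat_amplification": float(flat),
        "sinusoid_amplification": float(amp_sin),
        "n_peaks": len(peaks),
        "modal_peak_spacing_nm": float(vals[np.argmax(counts)]),
        "dominant_period_nm": float(spec["dominant_period_nm"]),
        "frequency_bin_nm_inv": float(spec["frequency_bin_nm_inv"]),
    }


def roundtrip_detection_study(n_seeds: int = 20, seed: int = 0) -> dict:
    """Synthesize -> render -> binarize -> detect, against ground truth."""
    exact = 0
    max_err = 0.0
    for k in range(n_seeds):
        field = gen_ellipse_field(
            8000, 0, 8, seed=seed + k, min_clearance_nm=150.0, edge_margin_nm=250.0
        )
        img = render_localization_image(field, 20.0, density=0.02, precision_nm=10.0, seed=seed + k)
        mask = binarize(img, "query", 1, "otsu")
        found = detect_clusters(mask, pixel_nm=20.0, min_size=4, channel="query")
        if len(found) == len(field.query_ellipses):
            exact += 1
            det = np.array([c.centroid_nm for c in found])
            for e in field.query_ellipses:
                max_err = max(
                    max_err, float(np.min(np.linalg.norm(det - [e.cx, e.cy], axis=1)))
                )
    return {
        "n_seeds": n_seeds,
        "count_exact_fraction": exact / n_seeds,
        "max_centroid_error_nm": max_err,
    }
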