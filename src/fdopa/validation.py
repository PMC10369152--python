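"""Seeded end-to-end validation experiments.

Self-contained experiments used by the test suite and the acceptance
script: rigid-motion parameter recovery against injected ground truth,
ICC estimator calibration against its variance-components definition,
and a two-session test-retest study of the full pipeline at increasing
noise.  All experiments run at desk scale (small grids, shortened
schedules) so they complete in minutes on one CPU; problem sizes are
part of each experiment's definition.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .kinetics import patlak_region
from .motion import RigidTransform, realign_frames
from .pet_io import FrameSchedule, extract_tac
from .phantom import (DEFAULT_REGION_PARAMS, KineticParameters, PhantomSpec,
                      build_phantom, inject_motion, write_phantom)
from .reliability import PairedOutcomes, icc_two_way
from .report import PipelineConfig, run_pipeline


def desk_schedule() -> FrameSchedule:
    """Shortened 15-frame 95-min schedule for repeated experiments.

    4 x 2.5 min, 5 x 5 min, 6 x 10 min: same scan span as the default
    32-frame schedule but without the sub-minute early frames, so every
    frame carries enough signal to realign.
    """
    return FrameSchedule.from_durations([2.5] * 4 + [5.0] * 5 + [10.0] * 6)


# ---------------------------------------------------------------------------
# Motion parameter recovery
# ---------------------------------------------------------------------------


def motion_recovery_experiment(n_phantoms: int = 20, seed: int = 2024,
                               max_translation_mm: float = 2.8,
                               max_rotation_deg: float = 1.7,
                               noise_sigma0: float = 0.5,
                               shape=(24, 24, 18)) -> dict:
    """Inject known rigid motion and measure realignment recovery error.

    Each phantom uses the desk schedule; frames with mid-time > 5 min
    (except the reference) receive an independent rigid perturbation
    with per-axis translation U(-max_t, max_t) mm and per-axis rotation
    U(-max_r, max_r) degrees (so vector magnitudes stay within about
    5 mm / 3 degrees).  Returns per-frame absolute errors and their
    medians.
    """
    rng = np.random.default_rng(seed)
    schedule = desk_schedule()
    max_rot = np.radians(max_rotation_deg)
    t_errors: list[float] = []
    r_errors: list[float] = []
    for i in range(n_phantoms):
        spec = PhantomSpec(seed=int(rng.integers(2**31)), shape=shape,
                           schedule=schedule, noise_sigma0=noise_sigma0)
        img, labels, _ = build_phantom(spec)
        ref_idx = int(np.argmin(np.abs(schedule.mid - 15.0)))
        transforms = []
        for f in range(len(schedule)):
            if f == ref_idx or schedule.mid[f] <= 5.0:
                transforms.append(RigidTransform())
            else:
                transforms.append(RigidTransform(
                    translation=tuple(rng.uniform(-max_translation_mm,
                                                  max_translation_mm, 3)),
                    rotation=tuple(rng.uniform(-max_rot, max_rot, 3))))
        moved = inject_motion(img, transforms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, est = realign_frames(moved)
        for f, (true, got) in enumerate(zip(transforms, est)):
            if f == ref_idx or true.is_identity():
                continue
            err = got.params - true.params
            t_errors.extend(np.abs(err[:3]).tolist())
            r_errors.extend(np.degrees(np.abs(err[3:])).tolist())
    return {
        "n_phantoms": n_phantoms,
        "n_perturbed_frames": len(t_errors) // 3,
        "median_abs_translation_error_mm": float(np.median(t_errors)),
        "median_abs_rotation_error_deg": float(np.median(r_errors)),
        "max_abs_translation_error_mm": float(np.max(t_errors)),
        "translation_errors_mm": t_errors,
        "rotation_errors_deg": r_errors,
    }


# ---------------------------------------------------------------------------
# ICC calibration against variance components
# ---------------------------------------------------------------------------


def icc_calibration_experiment(n_subjects: int = 50, n_replicates: int = 500,
                               sigma_b: float = 1.0, sigma_w: float = 0.5,
                               seed: int = 7) -> dict:
    """Mean ICC(3,1) over replicated two-session tables vs its target.

    Sessions are generated as subject effect N(0, sigma_b^2) plus
    independent noise N(0, sigma_w^2); the estimator should average to
    sigma_b^2 / (sigma_b^2 + sigma_w^2).
    """
    rng = np.random.default_rng(seed)
    target = sigma_b**2 / (sigma_b**2 + sigma_w**2)
    vals = []
    for _ in range(n_replicates):
        subj = rng.normal(0.0, sigma_b, n_subjects)
        s1 = subj + rng.normal(0.0, sigma_w, n_subjects)
        s2 = subj + rng.normal(0.0, sigma_w, n_subjects)
        data = PairedOutcomes(subjects=range(n_subjects),
                              session1=s1, session2=s2)
        vals.append(icc_two_way(data))
    return {
        "n_subjects": n_subjects,
        "n_replicates": n_replicates,
        "target_icc": float(target),
        "mean_icc": float(np.mean(vals)),
        "abs_deviation": float(abs(np.mean(vals) - target)),
    }


# ---------------------------------------------------------------------------
# End-to-end test-retest reliability vs noise
# ---------------------------------------------------------------------------


def _subject_params(rng) -> dict:
    """Per-subject kinetics: striatal Ki drawn from the population
    distribution (0.0137 +/- 0.0015 1/min, truncated to plausible range)."""
    ki = float(np.clip(rng.normal(0.0137, 0.0015), 0.006, 0.025))
    params = dict(DEFAULT_REGION_PARAMS)
    params["striatum"] = KineticParameters.for_net_uptake(ki)
    return params


def reliability_noise_experiment(work_dir: str | Path,
                                 noise_levels=(0.2, 1.5, 4.0),
                                 n_subjects: int = 8, seed: int = 99,
                                 shape=(20, 20, 14)) -> dict:
    """Two-session phantom study through the full pipeline per noise level.

    Every subject gets fixed kinetics and anatomy (texture); the two
    sessions differ only by independent noise.  Scans are written to
    disk and quantified with :func:`run_pipeline` (realignment, QC,
    regional Patlak, SUVr; the voxelwise map is skipped — the outcome is
    the regional striatal Ki).  Returns the ICC per noise level.
    """
    work = Path(work_dir)
    rng = np.random.default_rng(seed)
    schedule = desk_schedule()
    subjects = []
    for s in range(n_subjects):
        subjects.append({
            "params": _subject_params(rng),
            "texture_seed": int(rng.integers(2**31)),
        })
    results: dict = {"noise_levels": list(map(float, noise_levels)),
                     "n_subjects": n_subjects, "icc": [], "var_pct": []}
    from .reliability import percent_var
    for level in noise_levels:
        ki_sessions = np.zeros((n_subjects, 2))
        for s, subj in enumerate(subjects):
            for sess in range(2):
                spec = PhantomSpec(
                    seed=int(rng.integers(2**31)), shape=shape,
                    schedule=schedule, noise_sigma0=float(level),
                    texture_seed=subj["texture_seed"],
                    region_params=subj["params"])
                out = work / f"lvl{level}_s{s}_sess{sess}"
                paths = write_phantom(spec, out)
                cfg = PipelineConfig(
                    scan_id=f"s{s}_sess{sess}",
                    dynamic_path=paths["image"],
                    timing_path=paths["timing"],
                    labels_path=paths["labels"],
                    label_names={"striatum": 1, "cerebellum": 2,
                                 "background": 3},
                    voxelwise=False, seed=spec.seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    report = run_pipeline(cfg, out)
                if report.status != "ok":
                    raise RuntimeError(
                        f"pipeline failed at noise {level}: "
                        f"{report.stage_errors}")
                ki_sessions[s, sess] = report.kinetics[0].ki_per_min
        data = PairedOutcomes(subjects=range(n_subjects),
                              session1=ki_sessions[:, 0],
                              session2=ki_sessions[:, 1],
                              outcome="striatum Ki")
        results["icc"].append(float(icc_two_way(data)))
        results["var_pct"].append(float(percent_var(data)))
    return results


# ---------------------------------------------------------------------------
# Dense-grid kinetic oracle (independent of simulate_tissue_tac)
# ---------------------------------------------------------------------------


def dense_ode_patlak_oracle(striatal: KineticParameters | None = None,
                            reference: KineticParameters | None = None,
                            plasma_peak_time: float = 1.0,
                            plasma_scale: float = 100.0,
                            t_star: float = 20.0,
                            t_end: float = 95.0) -> dict:
    """Reference Patlak slope from an adaptive ODE solve on a dense grid.

    Independent of the package's stepwise compartment solver and of its
    frame-sampled Patlak transform: tissue curves come from
    scipy.integrate.solve_ivp at tight tolerance and the Patlak fit uses
    a dense (0.01 min) time grid.
    """
    from scipy.integrate import cumulative_trapezoid, solve_ivp

    from .phantom import FengInput

    striatal = striatal or DEFAULT_REGION_PARAMS["striatum"]
    reference = reference or DEFAULT_REGION_PARAMS["cerebellum"]
    plasma = FengInput(peak_time=plasma_peak_time, scale=plasma_scale)
    tt = np.linspace(0.0, t_end, int(t_end * 100) + 1)

    def solve(p: KineticParameters) -> np.ndarray:
        sol = solve_ivp(
            lambda t, y: [p.K1 * plasma(t) - (p.k2 + p.k3) * y[0],
                          p.k3 * y[0]],
            (0.0, t_end), [0.0, 0.0], t_eval=tt, method="LSODA",
            rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"ODE oracle failed: {sol.message}")
        return sol.y.sum(axis=0)

    ct, cr = solve(striatal), solve(reference)
    cr_int = np.concatenate([[0.0], cumulative_trapezoid(cr, tt)])
    late = tt >= t_star
    x = cr_int[late] / cr[late]
    y = ct[late] / cr[late]
    slope, intercept = np.polyfit(x, y, 1)
    return {"ki": float(slope), "intercept": float(intercept),
            "striatal_ki_plasma": striatal.ki_true,
            "reference_dv": reference.K1 / reference.k2}


def phantom_region_ki(noise_sigma0: float = 0.0, seed: int = 1,
                      t_star: float = 20.0) -> dict:
    """Region-wise striatal Ki^cer of a default-geometry phantom."""
    img, labels, truth = build_phantom(
        PhantomSpec(seed=seed, noise_sigma0=noise_sigma0))
    ref = extract_tac(img, labels, "cerebellum")
    tar = extract_tac(img, labels, "striatum")
    fit = patlak_region(tar, ref, t_star=t_star)
    return {"ki": fit.ki, "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "ki_plasma_true": truth["regions"]["striatum"]["ki_plasma_true"]}
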