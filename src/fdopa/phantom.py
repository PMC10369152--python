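"""Synthetic dynamic FDOPA phantoms with known kinetic ground truth.

Real FDOPA archives are institutional and access-restricted, so every
pipeline stage here is validated against simulated data whose truth is
known by construction: a parametric Feng-type bolus plasma input drives
a two-tissue irreversible compartment model in the striatum (trapping
rate k3 > 0, net uptake Ki = K1*k3/(k2+k3)), a one-tissue model in the
cerebellar reference (k3 = 0) and a low-uptake background.  Regional
time courses are painted into ellipsoidal blobs on a small 3D grid,
optionally perturbed by per-frame rigid motion and Gaussian noise whose
variance scales with activity and inversely with frame duration (a
reconstruction-noise proxy: shorter frames are noisier).

Defaults reproduce the study conditions: the 32-frame, 95-min bolus
schedule (8x15 s, 3x60 s, 5x120 s, 16x300 s) and a striatal reference
Patlak slope targeted at 0.0137 1/min.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .kinetics import integrate_tac_from_zero
from .motion import RigidTransform, resample_volume
from .pet_io import (DynamicImage, FrameSchedule, LabelVolume,
                     TimeActivityCurve, write_dynamic, write_labels)

#: Frame durations (s) of the default 95-min bolus acquisition.
DEFAULT_FRAME_DURATIONS_S = [15.0] * 8 + [60.0] * 3 + [120.0] * 5 + [300.0] * 16

#: Striatal reference-Patlak net uptake target (1/min).
DEFAULT_STRIATAL_KI_CER = 0.0137
#: Low-uptake background target (1/min), occipital-like.
DEFAULT_BACKGROUND_KI_CER = 0.0005


def default_schedule() -> FrameSchedule:
    """The 32-frame schedule: 8x15 s, 3x60 s, 5x120 s, 16x300 s (95 min)."""
    return FrameSchedule.from_durations(
        np.asarray(DEFAULT_FRAME_DURATIONS_S) / 60.0)


# ---------------------------------------------------------------------------
# Kinetic parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the (reduced) tissue model.

    K1 : plasma -> tissue clearance (mL/g/min)
    k2 : tissue -> plasma rate (1/min)
    k3 : trapping (decarboxylation) rate (1/min); 0 for the reference.
    """

    K1: float
    k2: float
    k3: float = 0.0

    def __post_init__(self):
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("rate constants must be non-negative")

    @property
    def ki_true(self) -> float:
        """Net plasma-to-trap influx K1*k3/(k2+k3) (1/min)."""
        if self.k3 == 0:
            return 0.0
        return self.K1 * self.k3 / (self.k2 + self.k3)

    @classmethod
    def for_net_uptake(cls, ki: float, K1: float = 0.13,
                       k2: float = 0.10) -> "KineticParameters":
        """Solve k3 so that K1*k3/(k2+k3) equals ``ki`` (requires ki < K1)."""
        if ki == 0:
            return cls(K1=K1, k2=k2, k3=0.0)
        if not 0 < ki < K1:
            raise ValueError(f"need 0 < ki < K1, got ki={ki}, K1={K1}")
        k3 = ki * k2 / (K1 - ki)
        return cls(K1=K1, k2=k2, k3=k3)


#: Default regional kinetics.  The cerebellar distribution volume K1/k2 is 1,
#: so the striatal reference-Patlak slope approximates its plasma Ki; rates
#: are fast enough that the reversible pools equilibrate well before the
#: 20-min Patlak start, and the striatal delivery excess puts the late-time
#: striatum/cerebellum ratio near the observed population mean (~2.3).
DEFAULT_REGION_PARAMS: Mapping[str, KineticParameters] = {
    "striatum": KineticParameters.for_net_uptake(DEFAULT_STRIATAL_KI_CER),
    "cerebellum": KineticParameters(K1=0.10, k2=0.10, k3=0.0),
    "background": KineticParameters.for_net_uptake(DEFAULT_BACKGROUND_KI_CER,
                                                   K1=0.10, k2=0.10),
}

REGION_LABELS: Mapping[str, int] = {"striatum": 1, "cerebellum": 2,
                                    "background": 3}


# ---------------------------------------------------------------------------
# Plasma input
# ---------------------------------------------------------------------------

# Canonical Feng bolus shape parameters (arbitrary activity units; the
# curve is rescaled to the requested peak height and dilated to the
# requested peak time).
_FENG_A = (851.1225, 21.8798, 20.8113)
_FENG_L = (-4.133859, -0.1190996, -0.01043449)


def _feng_shape(t: np.ndarray) -> np.ndarray:
    """Unnormalized Feng model: (A1*t - A2 - A3)e^{l1 t} + A2 e^{l2 t} + A3 e^{l3 t}."""
    t = np.asarray(t, dtype=float)
    a1, a2, a3 = _FENG_A
    l1, l2, l3 = _FENG_L
    out = ((a1 * t - a2 - a3) * np.exp(l1 * t)
           + a2 * np.exp(l2 * t) + a3 * np.exp(l3 * t))
    return np.where(t > 0, out, 0.0)


def _feng_peak_time() -> float:
    """Argmax of the canonical shape (dense grid + golden refinement)."""
    tt = np.linspace(0.0, 5.0, 5001)
    t0 = tt[int(np.argmax(_feng_shape(tt)))]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda t: -_feng_shape(np.array(t)),
                          bounds=(max(t0 - 0.01, 1e-6), t0 + 0.01),
                          method="bounded")
    return float(res.x)


_CANONICAL_PEAK = _feng_peak_time()


class FengInput:
    """Callable Feng-type plasma bolus: fast rise, tri-exponential decay.

    Time-dilated so the maximum sits at ``peak_time`` (min) and rescaled
    so the peak value equals ``scale`` (kBq/mL).  Zero at and before t=0.
    """

    def __init__(self, peak_time: float = 1.0, scale: float = 100.0):
        if scale < 0:
            raise ValueError("scale must be non-negative")
        if peak_time <= 0:
            raise ValueError("peak_time must be positive")
        self.peak_time = float(peak_time)
        self.scale = float(scale)
        self._dilation = _CANONICAL_PEAK / self.peak_time
        peak_val = _feng_shape(np.array(_CANONICAL_PEAK))
        self._gain = 0.0 if scale == 0 else self.scale / float(peak_val)

    def __call__(self, t) -> np.ndarray:
        return self._gain * _feng_shape(np.asarray(t, dtype=float)
                                        * self._dilation)


def input_function(schedule: FrameSchedule, peak_time: float = 1.0,
                   scale: float = 100.0) -> TimeActivityCurve:
    """Plasma input sampled at the schedule's frame mid-times.

    ``scale`` must be positive here (use :class:`FengInput` directly for
    the degenerate zero-scale curve in tests).
    """
    if scale <= 0:
        if scale == 0:
            model = FengInput(peak_time=peak_time, scale=0.0)
            return TimeActivityCurve(mid=schedule.mid,
                                     value=model(schedule.mid),
                                     region="plasma")
        raise ValueError("scale must be positive")
    if peak_time > schedule.end[-1]:
        raise ValueError("peak_time lies outside the scan")
    model = FengInput(peak_time=peak_time, scale=scale)
    return TimeActivityCurve(mid=schedule.mid, value=model(schedule.mid),
                             region="plasma")


# ---------------------------------------------------------------------------
# Tissue model
# ---------------------------------------------------------------------------


def _plasma_on_grid(plasma, grid: np.ndarray) -> np.ndarray:
    if callable(plasma):
        return np.asarray(plasma(grid), dtype=float)
    if isinstance(plasma, TimeActivityCurve):
        return np.interp(grid, np.concatenate([[0.0], plasma.mid]),
                         np.concatenate([[0.0], plasma.value]))
    raise TypeError("plasma must be a TimeActivityCurve or a callable Cp(t)")


def simulate_tissue_tac(params: KineticParameters, plasma,
                        schedule: FrameSchedule, dt: float = 0.01,
                        ) -> TimeActivityCurve:
    """Tissue TAC C1+C2 of the irreversible two-tissue model.

        dC1/dt = K1*Cp - (k2 + k3)*C1
        dC2/dt = k3*C1

    Solved on a dense grid with an exact exponential update per step
    (plasma treated as piecewise linear), then sampled at frame
    mid-times.  ``plasma`` is a callable Cp(t) or a TAC (linearly
    interpolated, anchored at (0, 0)).
    """
    t_end = float(schedule.end[-1])
    n = max(int(np.ceil(t_end / dt)), 2)
    grid = np.linspace(0.0, t_end, n + 1)
    h = grid[1] - grid[0]
    cp = _plasma_on_grid(plasma, grid)
    if np.any(~np.isfinite(cp)):
        raise RuntimeError("plasma input evaluated to non-finite values")

    a = params.k2 + params.k3
    c1 = np.zeros_like(grid)
    if params.K1 > 0:
        if a > 0:
            ea = np.exp(-a * h)
            w0 = (1.0 - ea) / a                       # int e^{-a(h-s)} ds
            w1 = (h - w0) / a                         # int e^{-a(h-s)} s ds
            for i in range(n):
                c0 = cp[i]
                m = (cp[i + 1] - cp[i]) / h
                c1[i + 1] = c1[i] * ea + params.K1 * (c0 * w0 + m * w1)
        else:
            # no efflux: C1 is K1 * cumulative integral of Cp
            from scipy.integrate import cumulative_trapezoid
            c1 = params.K1 * np.concatenate(
                [[0.0], cumulative_trapezoid(cp, grid)])
    if np.any(~np.isfinite(c1)):
        raise RuntimeError("compartment solution diverged")
    from scipy.integrate import cumulative_trapezoid
    c2 = params.k3 * np.concatenate([[0.0], cumulative_trapezoid(c1, grid)])
    total = c1 + c2
    values = np.interp(schedule.mid, grid, total)
    return TimeActivityCurve(mid=schedule.mid, value=values)


def patlak_consistent_tac(ref: TimeActivityCurve, ki: float,
                          intercept: float) -> TimeActivityCurve:
    """Target TAC whose Patlak plot against ``ref`` is exactly linear.

        C_T(t) = intercept * C_ref(t) + ki * int_0^t C_ref

    Uses the same origin-anchored trapezoid convention as the Patlak
    transform, so a downstream fit recovers (ki, intercept) exactly.
    """
    if np.any(ref.value[ref.mid > 0] < 0):
        raise ValueError("reference TAC must be non-negative after t=0")
    ref_int = integrate_tac_from_zero(ref.mid, ref.value)
    values = intercept * ref.value + ki * ref_int
    return TimeActivityCurve(mid=ref.mid, value=values,
                             region=f"patlak_consistent(ki={ki:g})")


# ---------------------------------------------------------------------------
# Phantom assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to build a deterministic 4D phantom."""

    seed: int
    shape: tuple[int, int, int] = (32, 32, 24)
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0)
    schedule: FrameSchedule = field(default_factory=default_schedule)
    region_params: Mapping[str, KineticParameters] = field(
        default_factory=lambda: dict(DEFAULT_REGION_PARAMS))
    plasma_peak_time: float = 1.0
    plasma_scale: float = 100.0
    noise_sigma0: float = 0.0
    texture_sigma: float = 0.1
    texture_seed: int | None = None
    motion: Sequence[RigidTransform] | None = None

    def __post_init__(self):
        if self.noise_sigma0 < 0:
            raise ValueError("noise_sigma0 must be >= 0")
        if self.texture_sigma < 0:
            raise ValueError("texture_sigma must be >= 0")
        if self.motion is not None and len(self.motion) != len(self.schedule):
            raise ValueError("need one motion transform per frame")


def _ellipsoid(shape, center, semi) -> np.ndarray:
    idx = np.indices(shape).astype(float)
    d = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return d <= 1.0


def make_region_labels(shape=(32, 32, 24)) -> LabelVolume:
    """Default geometry: bilateral striatal blobs, a cerebellar blob and
    brain background inside a head ellipsoid; label 0 is outside."""
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    brain = _ellipsoid(shape, (cx, cy, cz), (0.42 * nx, 0.45 * ny, 0.42 * nz))
    striatum = (_ellipsoid(shape, (cx - 0.18 * nx, cy + 0.08 * ny, cz + 0.08 * nz),
                           (0.09 * nx, 0.14 * ny, 0.10 * nz))
                | _ellipsoid(shape, (cx + 0.18 * nx, cy + 0.08 * ny, cz + 0.08 * nz),
                             (0.09 * nx, 0.14 * ny, 0.10 * nz)))
    cerebellum = _ellipsoid(shape, (cx, cy - 0.30 * ny, cz - 0.25 * nz),
                            (0.22 * nx, 0.12 * ny, 0.12 * nz))
    striatum &= brain
    cerebellum &= brain & ~striatum
    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = REGION_LABELS["background"]
    labels[cerebellum] = REGION_LABELS["cerebellum"]
    labels[striatum] = REGION_LABELS["striatum"]
    return LabelVolume(labels=labels, names=dict(REGION_LABELS))


def inject_motion(img: DynamicImage,
                  transforms: Sequence[RigidTransform],
                  order: int = 3) -> DynamicImage:
    """Resample each frame under its rigid transform.

    The inverse operation of realignment: simulates the head moving by
    each frame's transform during acquisition.  Cubic B-spline
    interpolation by default — linear resampling visibly blurs the
    moved frames, which would bias recovery experiments against the
    realignment stage for reasons unrelated to the estimator.
    """
    if len(transforms) != img.n_frames:
        raise ValueError(
            f"{len(transforms)} transforms for {img.n_frames} frames")
    data = np.empty_like(img.data)
    for t, tr in enumerate(transforms):
        if tr.is_identity():
            data[..., t] = img.frame(t)
        else:
            data[..., t] = resample_volume(img.frame(t), tr, img.voxel_size,
                                           order=order)
    from dataclasses import replace
    return replace(img, data=data)


def build_phantom(spec: PhantomSpec
                  ) -> tuple[DynamicImage, LabelVolume, dict]:
    """Assemble a 4D phantom, its labels and a ground-truth record.

    Voxels of each region carry that region's noiseless model TAC; frame
    f then receives i.i.d. Gaussian noise with standard deviation
    ``noise_sigma0 * sqrt(mean_brain_activity_f / duration_f)``, and
    per-frame rigid motion (if any) is applied last by resampling.
    Deterministic for a fixed spec (the seed is mandatory).
    """
    labels = make_region_labels(spec.shape)
    plasma = FengInput(peak_time=spec.plasma_peak_time,
                       scale=spec.plasma_scale)
    tacs: dict[str, TimeActivityCurve] = {}
    for name in spec.region_params:
        if name not in labels.names:
            raise ValueError(f"no geometry for region {name!r}")
        tacs[name] = simulate_tissue_tac(spec.region_params[name], plasma,
                                         spec.schedule)

    n_frames = len(spec.schedule)
    data = np.zeros(spec.shape + (n_frames,), dtype=float)
    for name, tac in tacs.items():
        mask = labels.mask(name)
        data[mask, :] = tac.value[np.newaxis, :]

    if spec.texture_sigma > 0:
        # smooth multiplicative tissue-heterogeneity field, frozen in time
        # and zero-mean within each region so regional mean TACs remain
        # exactly the generator TACs
        tseed = spec.seed if spec.texture_seed is None else spec.texture_seed
        trng = np.random.default_rng(tseed)
        from scipy.ndimage import gaussian_filter
        field = gaussian_filter(trng.standard_normal(spec.shape), sigma=1.5)
        brain = labels.labels > 0
        field *= spec.texture_sigma / max(field[brain].std(), 1e-12)
        field = np.clip(field, -0.45, 0.45)
        for name in spec.region_params:
            mask = labels.mask(name)
            f = field[mask] - field[mask].mean()
            data[mask, :] *= (1.0 + f)[:, np.newaxis]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma0 > 0:
        brain = labels.labels > 0
        mean_act = data[brain].mean(axis=0)            # per frame
        sd = spec.noise_sigma0 * np.sqrt(
            np.clip(mean_act, 0.0, None) / spec.schedule.duration)
        noise = rng.standard_normal(data.shape) * sd
        data[brain] += noise[brain]

    img = DynamicImage(data=data, voxel_size=spec.voxel_size,
                       schedule=spec.schedule, decay_corrected=True)
    if spec.motion is not None:
        img = inject_motion(img, list(spec.motion))

    truth = {
        "seed": int(spec.seed),
        "noise_sigma0": float(spec.noise_sigma0),
        "texture_sigma": float(spec.texture_sigma),
        "texture_seed": (int(spec.texture_seed)
                         if spec.texture_seed is not None else int(spec.seed)),
        "plasma": {"peak_time": spec.plasma_peak_time,
                   "scale": spec.plasma_scale},
        "regions": {
            name: {
                "label": labels.names[name],
                "params": {"K1": p.K1, "k2": p.k2, "k3": p.k3},
                "ki_plasma_true": p.ki_true,
                "tac": tacs[name].value.tolist(),
            }
            for name, p in spec.region_params.items()
        },
        "motion": ([tr.params.tolist() for tr in spec.motion]
                   if spec.motion is not None else None),
    }
    return img, labels, truth


def write_phantom(spec: PhantomSpec, out_dir: str | Path,
                  stem: str = "phantom") -> dict:
    """Write phantom NIfTI + sidecar + labels + ground_truth.json.

    Returns the paths written (as strings)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img, labels, truth = build_phantom(spec)
    paths = {
        "image": str(out / f"{stem}.nii.gz"),
        "timing": str(out / f"{stem}.json"),
        "labels": str(out / f"{stem}_labels.nii.gz"),
        "ground_truth": str(out / f"{stem}_ground_truth.json"),
    }
    write_dynamic(img, paths["image"], paths["timing"],
                  extra_sidecar={"TracerName": "FDOPA"})
    write_labels(labels, paths["labels"], affine=img.affine)
    truth["label_names"] = dict(labels.names)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths
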