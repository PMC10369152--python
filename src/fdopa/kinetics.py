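"""Gjedde-Patlak reference-region graphical analysis and SUVr.

For an irreversibly trapped tracer, plotting

    y(t) = C_T(t) / C_ref(t)   against   x(t) = int_0^t C_ref(tau) dtau / C_ref(t)

becomes linear once the reversible compartments equilibrate (t >= t*).
The slope is the net influx rate constant Ki^cer (1/min) relative to the
cerebellar reference — the standard proxy of presynaptic dopamine
synthesis capacity for FDOPA.  The fit is ordinary least squares on the
points with frame mid-time >= t* (20 min by default), applied both
region-wise (on regional TACs) and voxel-wise (producing a Ki parametric
map, with optional per-frame total-variation denoising beforehand).

SUVr is the complementary semi-quantitative index: the ratio of target
to reference mean activity over a late window (60-75 min by default),
duration-overlap weighted across frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .denoise import TVConfig, denoise_frames
from .pet_io import DynamicImage, LabelVolume, TimeActivityCurve, extract_tac

DEFAULT_T_STAR_MIN = 20.0
DEFAULT_SUVR_WINDOW = (60.0, 75.0)
#: Reference-positivity floor as a fraction of the reference TAC maximum.
REF_EPS_FRACTION = 1e-6


@dataclass(frozen=True)
class PatlakPoints:
    """Patlak-transformed point series (x, y) at the surviving mid-times."""

    x: np.ndarray
    y: np.ndarray
    mid: np.ndarray
    n_dropped: int = 0


@dataclass(frozen=True)
class PatlakResult:
    """Region-wise Patlak fit: Ki^cer slope plus diagnostics."""

    ki: float
    intercept: float
    t_star: float
    n_points: int
    r_squared: float
    region: str = ""


@dataclass(frozen=True)
class ParametricMap:
    """Voxelwise Patlak output; voxels outside the mask (or with
    degenerate time courses) are NaN."""

    ki_map: np.ndarray
    intercept_map: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class SuvrResult:
    suvr: float
    window: tuple[float, float]
    region: str = ""


def integrate_tac_from_zero(mid: np.ndarray, value: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid integral of a TAC with an implicit (0, 0) sample.

    Frames start at injection, when activity is zero, so the curve is
    anchored at the origin before integration.
    """
    mid = np.asarray(mid, dtype=float)
    value = np.asarray(value, dtype=float)
    t = np.concatenate([[0.0], mid])
    v = np.concatenate([[0.0], value])
    return integrate.cumulative_trapezoid(v, t)


def patlak_transform(target: TimeActivityCurve, ref: TimeActivityCurve
                     ) -> PatlakPoints:
    """Map a target/reference TAC pair to Patlak coordinates.

    Points where the reference activity falls at or below
    ``REF_EPS_FRACTION * max(ref)`` are dropped (and counted).
    """
    if target.mid.shape != ref.mid.shape or not np.allclose(target.mid, ref.mid):
        raise ValueError("target and reference TACs must share mid-times")
    ref_int = integrate_tac_from_zero(ref.mid, ref.value)
    eps = REF_EPS_FRACTION * float(np.max(ref.value))
    keep = ref.value > eps
    if not keep.any():
        raise ValueError("all Patlak points dropped: reference never positive")
    x = ref_int[keep] / ref.value[keep]
    y = target.value[keep] / ref.value[keep]
    return PatlakPoints(x=x, y=y, mid=ref.mid[keep],
                        n_dropped=int((~keep).sum()))


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("degenerate Patlak design: all x identical")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def patlak_fit(points: PatlakPoints, t_star: float = DEFAULT_T_STAR_MIN,
               region: str = "") -> PatlakResult:
    """OLS fit of the Patlak plot over points with mid-time >= t*."""
    late = points.mid >= t_star
    if late.sum() < 3:
        raise ValueError(
            f"need >= 3 Patlak points at or after t* = {t_star:g} min, "
            f"have {int(late.sum())}")
    slope, intercept, r2 = _ols_line(points.x[late], points.y[late])
    return PatlakResult(ki=slope, intercept=intercept, t_star=float(t_star),
                        n_points=int(late.sum()), r_squared=r2, region=region)


def patlak_region(target: TimeActivityCurve, ref: TimeActivityCurve,
                  t_star: float = DEFAULT_T_STAR_MIN) -> PatlakResult:
    """Convenience: transform + fit for one regional TAC."""
    return patlak_fit(patlak_transform(target, ref), t_star=t_star,
                      region=target.region)


def patlak_voxelwise(img: DynamicImage, ref: TimeActivityCurve,
                     brain_mask: np.ndarray,
                     t_star: float = DEFAULT_T_STAR_MIN,
                     tv: TVConfig | None = None) -> ParametricMap:
    """Voxelwise Patlak Ki map over ``brain_mask``.

    Each frame is TV-denoised first (when ``tv`` is given with positive
    weight), then every voxel shares the reference-derived x design and
    gets a closed-form OLS slope/intercept.  Voxels with non-finite or
    all-zero time courses are NaN.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != img.shape3d:
        raise ValueError("mask shape does not match image")
    if not brain_mask.any():
        raise ValueError("empty brain mask")

    data = img.data
    if tv is not None and tv.weight > 0:
        data = denoise_frames(data, tv)

    ref_int = integrate_tac_from_zero(ref.mid, ref.value)
    eps = REF_EPS_FRACTION * float(np.max(ref.value))
    keep = (ref.value > eps) & (img.schedule.mid >= t_star)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable late frames for voxelwise fit")
    x = ref_int[keep] / ref.value[keep]          # shared design, (T,)
    refv = ref.value[keep]

    vox = data[brain_mask][:, keep]               # (N, T)
    y = vox / refv[np.newaxis, :]
    valid = np.isfinite(y).all(axis=1) & (np.abs(vox).sum(axis=1) > 0)

    xm = x.mean()
    sxx = np.sum((x - xm) ** 2)
    ym = y.mean(axis=1)
    slope = ((y - ym[:, None]) @ (x - xm)) / sxx
    intercept = ym - slope * xm
    slope[~valid] = np.nan
    intercept[~valid] = np.nan

    ki_map = np.full(img.shape3d, np.nan)
    b_map = np.full(img.shape3d, np.nan)
    ki_map[brain_mask] = slope
    b_map[brain_mask] = intercept
    return ParametricMap(ki_map=ki_map, intercept_map=b_map, mask=brain_mask)


# ---------------------------------------------------------------------------
# SUVr
# ---------------------------------------------------------------------------


def _window_weights(schedule, window: tuple[float, float]) -> np.ndarray:
    """Per-frame overlap (min) between the frame interval and the window."""
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError(f"empty SUVr window ({lo}, {hi})")
    start, end = schedule.start, schedule.end
    overlap = np.minimum(end, hi) - np.maximum(start, lo)
    return np.clip(overlap, 0.0, None)


def windowed_mean_activity(tac: TimeActivityCurve, schedule,
                           window: tuple[float, float]) -> float:
    """Duration-overlap-weighted mean activity of a TAC over a window."""
    w = _window_weights(schedule, window)
    if w.sum() == 0:
        raise ValueError(f"window {window} does not overlap the scan")
    return float(np.sum(w * tac.value) / w.sum())


def suvr(img: DynamicImage, labels: LabelVolume, target_region: str,
         ref_region: str,
         window: tuple[float, float] = DEFAULT_SUVR_WINDOW) -> SuvrResult:
    """Standardized uptake value ratio of target to reference region.

    Both regional TACs are averaged over the window with frame-duration
    overlap weights; the ratio of those means is the SUVr.
    """
    target = extract_tac(img, labels, target_region)
    ref = extract_tac(img, labels, ref_region)
    t_mean = windowed_mean_activity(target, img.schedule, window)
    r_mean = windowed_mean_activity(ref, img.schedule, window)
    if r_mean == 0:
        raise ValueError("reference activity is zero in the SUVr window")
    return SuvrResult(suvr=t_mean / r_mean,
                      window=(float(window[0]), float(window[1])),
                      region=target_region)
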