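"""Pipeline orchestration, configuration and the per-scan summary report.

``run_pipeline`` executes the full quantification chain in order —
decay-correction check, frame realignment, motion QC, static summation,
TAC extraction, region-wise Patlak, SUVr, and (optionally) the
TV-denoised voxelwise Ki map — and emits a validated, reloadable
:class:`ScanReport` with full provenance (software version, a hash of
the analysis-relevant configuration, and the seed).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .denoise import TVConfig
from .kinetics import (DEFAULT_SUVR_WINDOW, DEFAULT_T_STAR_MIN,
                       patlak_region, patlak_voxelwise, suvr)
from .motion import (DEFAULT_FD_RADIUS_MM, DEFAULT_MAX_FD_LIMIT_MM,
                     DEFAULT_SPIKE_THRESHOLD_MM, detect_spikes,
                     framewise_displacement, qc_motion, realign_frames)
from .pet_io import (decay_correct, extract_tac, read_dynamic, read_labels,
                     sum_frames, export_tacs_csv, write_volume)

SCHEMA_VERSION = "1.0"


class PipelineConfig(BaseModel):
    """Analysis configuration for one scan.

    Path fields locate the inputs; the remaining fields are the analysis
    parameters that enter the config hash.
    """

    scan_id: str = "scan"
    dynamic_path: str
    timing_path: str
    labels_path: str
    label_names: dict[str, int]

    ref_region: str = "cerebellum"
    target_regions: list[str] = Field(default_factory=lambda: ["striatum"])
    reference_frame: int | str = "auto"
    decay_correct_if_needed: bool = True
    half_life_min: float = 109.77
    spike_threshold_mm: float = DEFAULT_SPIKE_THRESHOLD_MM
    max_fd_limit_mm: float = DEFAULT_MAX_FD_LIMIT_MM
    fd_radius_mm: float = DEFAULT_FD_RADIUS_MM
    t_star_min: float = DEFAULT_T_STAR_MIN
    suvr_window_min: tuple[float, float] = DEFAULT_SUVR_WINDOW
    tv_weight_rel: float = 0.02       # x robust max of the dynamic data
    tv_max_iter: int = 200
    tv_tol: float = 2.0e-4
    voxelwise: bool = True
    seed: int = 0

    #: fields that do not alter the numerical result
    _NON_ANALYSIS = {"scan_id"}

    def config_hash(self) -> str:
        """SHA-256 over the analysis-relevant configuration."""
        payload = self.model_dump(exclude=self._NON_ANALYSIS)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from JSON or TOML."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib
            with open(path, "rb") as fh:
                return cls.model_validate(tomllib.load(fh))
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


class QCBlock(BaseModel):
    reference_frame: int
    fd: list[float]
    total_motion_mm: float
    max_fd_mm: float
    n_spikes: int
    flagged: bool
    passed: bool
    reasons: list[str] = Field(default_factory=list)


class RegionKinetics(BaseModel):
    region: str
    ki_per_min: float
    intercept: float
    r_squared: float
    n_points: int
    suvr: Optional[float] = None
    voxel_mean_ki_per_min: Optional[float] = None


class Provenance(BaseModel):
    software_version: str
    schema_version: str = SCHEMA_VERSION
    config_hash: str
    seed: int
    started: str
    finished: str


class ScanReport(BaseModel):
    """Per-scan summary: QC, regional kinetics and provenance.

    Serializable to JSON and reloadable losslessly via
    ``ScanReport.model_validate_json``; the published schema is
    ``ScanReport.model_json_schema()`` (version pinned in provenance).
    """

    scan_id: str
    status: str = "ok"
    stage_errors: dict[str, str] = Field(default_factory=dict)
    warnings: list[str] = Field(default_factory=list)
    qc: Optional[QCBlock] = None
    kinetics: list[RegionKinetics] = Field(default_factory=list)
    provenance: Provenance

    def to_json(self, drop_timestamps: bool = False) -> str:
        payload = self.model_dump()
        if drop_timestamps:
            payload["provenance"].pop("started", None)
            payload["provenance"].pop("finished", None)
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ScanReport":
        return cls.model_validate_json(Path(path).read_text())


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat()


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> ScanReport:
    """Execute the full quantification pipeline for one scan.

    Stage order: read -> decay correction (if needed) -> realign + motion
    QC -> static sum -> TAC extraction -> region Patlak + SUVr ->
    voxelwise TV-denoised Ki map.  A stage failure is recorded in the
    report (status "error") rather than raised.
    """
    started = _now()
    warnings_list: list[str] = []
    stage_errors: dict[str, str] = {}
    qc_block = None
    kinetics_rows: list[RegionKinetics] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    try:
        img = read_dynamic(config.dynamic_path, config.timing_path)
        labels = read_labels(config.labels_path, config.label_names)
        if not img.decay_corrected and config.decay_correct_if_needed:
            img = decay_correct(img, config.half_life_min)
            warnings_list.append("input was not decay-corrected; corrected "
                                 f"with half-life {config.half_life_min} min")
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        stage_errors["read"] = str(exc)
        img = labels = None

    transforms = None
    if img is not None:
        try:
            img, transforms = realign_frames(img, config.reference_frame)
            from .motion import choose_reference_frame
            ref_idx = choose_reference_frame(img, config.reference_frame)
            fd = framewise_displacement(transforms, radius=config.fd_radius_mm)
            mqc = detect_spikes(fd, threshold=config.spike_threshold_mm)
            verdict = qc_motion(mqc, max_fd_limit=config.max_fd_limit_mm)
            qc_block = QCBlock(
                reference_frame=ref_idx,
                fd=list(map(float, fd)),
                total_motion_mm=mqc.total_motion,
                max_fd_mm=mqc.max_fd,
                n_spikes=mqc.n_spikes,
                flagged=mqc.flagged,
                passed=verdict["pass"],
                reasons=verdict["reasons"],
            )
        except Exception as exc:  # noqa: BLE001
            stage_errors["motion"] = str(exc)

    if img is not None and labels is not None and "motion" not in stage_errors:
        try:
            static = sum_frames(img)
            if out is not None:
                write_volume(static, out / "static.nii.gz", img.affine)
            ref_tac = extract_tac(img, labels, config.ref_region)
            tacs = [ref_tac]
            for region in config.target_regions:
                tac = extract_tac(img, labels, region)
                tacs.append(tac)
                fit = patlak_region(tac, ref_tac, t_star=config.t_star_min)
                sv = suvr(img, labels, region, config.ref_region,
                          window=config.suvr_window_min)
                kinetics_rows.append(RegionKinetics(
                    region=region, ki_per_min=fit.ki, intercept=fit.intercept,
                    r_squared=fit.r_squared, n_points=fit.n_points,
                    suvr=sv.suvr))
            if out is not None:
                export_tacs_csv(tacs, out / "tacs.csv")
        except Exception as exc:  # noqa: BLE001
            stage_errors["kinetics"] = str(exc)

        if config.voxelwise and "kinetics" not in stage_errors:
            try:
                robust_max = float(np.percentile(img.data, 99.5))
                tv = TVConfig(weight=config.tv_weight_rel * robust_max,
                              max_iter=config.tv_max_iter, tol=config.tv_tol)
                brain = labels.labels > 0
                pmap = patlak_voxelwise(img, ref_tac, brain,
                                        t_star=config.t_star_min, tv=tv)
                for row in kinetics_rows:
                    vox = pmap.ki_map[labels.mask(row.region)]
                    row.voxel_mean_ki_per_min = float(np.nanmean(vox))
                if out is not None:
                    write_volume(pmap.ki_map, out / "ki.nii.gz", img.affine)
                    write_volume(pmap.intercept_map,
                                 out / "intercept.nii.gz", img.affine)
            except Exception as exc:  # noqa: BLE001
                stage_errors["voxelwise"] = str(exc)

    report = ScanReport(
        scan_id=config.scan_id,
        status="error" if stage_errors else "ok",
        stage_errors=stage_errors,
        warnings=warnings_list,
        qc=qc_block,
        kinetics=kinetics_rows,
        provenance=Provenance(
            software_version=__version__,
            config_hash=config.config_hash(),
            seed=config.seed,
            started=started,
            finished=_now(),
        ),
    )
    if out is not None:
        report.save(out / "report.json")
        if kinetics_rows:
            import pandas as pd
            pd.DataFrame([r.model_dump() for r in kinetics_rows]).to_csv(
                out / "regional.csv", index=False)
    return report
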