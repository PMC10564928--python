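"""End-to-end orchestration: simulate -> register -> ROI -> fit -> stats.

`run_pipeline` drives the whole chain on a validated RunConfig and writes
every stage output plus a manifest (config hash, seeds, versions), so a
rerun with the same config reproduces identical results for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .caliber import flicker_ratios, measure_vessels, summarize_diameters
from .cohort_stats import build_report, write_report
from .imgproc import ImageSequence, average_projection, register_sequence
from .phantom import (
    CohortSubject,
    FlickerPair,
    PhantomVideo,
    Scene,
    simulate_cohort,
)
from .pulsation import analyze_sequence
from .roi import FrangiParams, build_rois, frangi_vesselness, segment_vessels

__all__ = ["RunConfig", "run_pipeline", "analyze_pulsation_video",
           "analyze_flicker_pair", "label_centerlines_from_scene"]


@dataclass
class RunConfig:
    """Validated pipeline settings.

    The smoothing window must be odd (buffer = (window-1)/2 points are
    dropped at each end); the QC value is an R² cutoff in (0, 1) for
    fixed mode or a percentile in (0, 100) for percentile mode.
    """

    out_dir: str = "results"
    seed: int = 0
    n_subjects: int = 6
    hr_range: tuple[float, float] = (55.0, 90.0)
    fps: float = 24.0
    n_frames: int = 72
    window: int = 5
    qc_mode: str = "fixed"
    qc_value: float = 0.23
    station_spacing: float = 5.0
    include_flicker: bool = True
    margin: int = 2
    frangi: FrangiParams = field(default_factory=FrangiParams)
    max_shift: int | None = None

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 3")
        if self.qc_mode == "fixed" and not (0.0 < self.qc_value < 1.0):
            raise ValueError("fixed-mode qc value must lie in (0, 1)")
        if self.qc_mode == "percentile" and not (0.0 < self.qc_value < 100.0):
            raise ValueError("percentile-mode qc value must lie in (0, 100)")
        if self.qc_mode not in ("fixed", "percentile"):
            raise ValueError("qc_mode must be fixed | percentile")
        if self.n_frames < 8 or self.fps <= 0:
            raise ValueError("need n_frames >= 8 and fps > 0")

    @property
    def buffer(self) -> int:
        return (self.window - 1) // 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "frangi" in data:
            data["frangi"] = FrangiParams(**data["frangi"])
        if "hr_range" in data:
            data["hr_range"] = tuple(data["hr_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hr_range"] = list(d["hr_range"])
        d["frangi"]["scales"] = list(d["frangi"]["scales"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def analyze_pulsation_video(
    seq: ImageSequence,
    onh_mask: np.ndarray,
    frangi: FrangiParams | None = None,
    margin: int = 2,
    window: int = 5,
    max_shift: int | None = None,
    reference_index: int = 0,
) -> dict:
    """Registration -> projection -> ROIs -> waveform fits for one video.

    Returns registration result, projection, RoiSet and the per-ROI
    analysis dict from :func:`onhpulse.pulsation.analyze_sequence` under
    keys ``RV`` and ``ONHT``.
    """
    frangi = frangi or FrangiParams()
    reg = register_sequence(seq, reference_index=reference_index,
                            max_shift=max_shift)
    proj = average_projection(reg.registered)
    vmap = frangi_vesselness(proj, frangi)
    vessel_mask = segment_vessels(vmap, frangi)
    rois = build_rois(onh_mask, vessel_mask, margin=margin)
    analysis = analyze_sequence(
        reg.registered,
        {"RV": rois.rv_mask, "ONHT": rois.onht_mask},
        window=window,
    )
    return {
        "registration": reg,
        "projection": proj,
        "rois": rois,
        "analysis": analysis,
    }


def label_centerlines_from_scene(
    centerlines: list[np.ndarray], scene: Scene
) -> dict[int, str]:
    """Assign artery/vein labels by nearest phantom vessel centerline.

    Stands in for the observer's manual classification when the truth is
    known; real data uses a labels JSON instead.
    """
    labels: dict[int, str] = {}
    polys = [(v.label, v.polyline(400)) for v in scene.vessels]
    for i, cl in enumerate(centerlines):
        best, best_d = "unlabeled", np.inf
        for lab, poly in polys:
            d = np.mean(
                [np.min(np.linalg.norm(poly - p[None, :], axis=1))
                 for p in cl[:: max(1, len(cl) // 25)]]
            )
            if d < best_d:
                best, best_d = lab, d
        labels[i] = best
    return labels


def analyze_flicker_pair(
    before: ImageSequence,
    during: ImageSequence,
    labels: dict[int, str] | None = None,
    frangi: FrangiParams | None = None,
    spacing: float = 5.0,
    scene: Scene | None = None,
):
    """Measure vessel diameters pre/during flicker and their ratios.

    Both conditions are averaged over frames; vessels are segmented and
    centerlines extracted on the pre-flicker mean image, then both images
    are profiled along the same stations so the ratio isolates the
    caliber change.  ``labels`` maps centerline index to artery/vein; if
    a phantom ``scene`` is given instead, labels come from the truth.
    """
    from .caliber import extract_centerlines

    frangi = frangi or FrangiParams()
    img_b = average_projection(before)
    img_d = average_projection(during)
    vmap = frangi_vesselness(img_b, frangi)
    mask = segment_vessels(vmap, frangi)
    centerlines = extract_centerlines(mask)
    if labels is None:
        if scene is None:
            raise ValueError("provide labels or a phantom scene for labeling")
        labels = label_centerlines_from_scene(centerlines, scene)
    traces_b = measure_vessels(img_b, mask, labels=labels, spacing=spacing,
                               centerlines=centerlines)
    traces_d = measure_vessels(img_d, mask, labels=labels, spacing=spacing,
                               centerlines=centerlines)
    sum_b = summarize_diameters(traces_b)
    sum_d = summarize_diameters(traces_d)
    result = flicker_ratios(
        (sum_b["artery"], sum_b["vein"]), (sum_d["artery"], sum_d["vein"])
    )
    return result, traces_b, traces_d


def _process_subject(subject: CohortSubject, cfg: RunConfig) -> dict:
    video: PhantomVideo = subject.video
    res = analyze_pulsation_video(
        video.seq,
        video.onh_mask,
        frangi=cfg.frangi,
        margin=cfg.margin,
        window=cfg.window,
        max_shift=cfg.max_shift,
    )
    row = dict(subject.metrics)
    for roi_key, col in (("RV", "RV"), ("ONHT", "ONHT")):
        m = res["analysis"][roi_key]["metrics"]
        row[f"PA_{col}"] = m.PA
        row[f"PF_{col}"] = m.PF
        row[f"r2_{col}"] = m.r_squared
    if subject.flicker is not None:
        fp: FlickerPair = subject.flicker
        try:
            dil, _, _ = analyze_flicker_pair(
                fp.before, fp.during, frangi=cfg.frangi,
                spacing=cfg.station_spacing, scene=fp.scene,
            )
            row["D_A_R"] = dil.D_A_R
            row["D_V_R"] = dil.D_V_R
        except ValueError as e:
            warnings.warn(f"{subject.subject_id}: flicker analysis failed: {e}",
                          stacklevel=2)
            row["D_A_R"] = np.nan
            row["D_V_R"] = np.nan
    else:
        row.setdefault("D_A_R", np.nan)
        row.setdefault("D_V_R", np.nan)
    return row


def run_pipeline(cfg: RunConfig) -> Path:
    """Simulate a phantom cohort and run every analysis stage on it.

    Writes per-subject pulsation metrics, the cohort CSV, the statistical
    report, and a manifest.  Raises on stage failure after recording the
    failure point in the manifest; partial outputs are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, status: str) -> None:
        manifest["stages"][stage] = status
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )

    try:
        subjects = simulate_cohort(
            cfg.n_subjects, hr_range=cfg.hr_range, seed=cfg.seed,
            n_frames=cfg.n_frames, fps=cfg.fps,
            include_flicker=cfg.include_flicker,
        )
        record("simulate", "ok")
    except Exception:
        record("simulate", "failed")
        raise

    rows = []
    try:
        for s in subjects:
            rows.append(_process_subject(s, cfg))
        record("analyze", "ok")
    except Exception:
        record("analyze", "failed")
        raise

    cohort = pd.DataFrame(rows)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    manifest["outputs"].append(str(cohort_path))

    try:
        report = build_report(cohort, qc_mode=cfg.qc_mode, qc_value=cfg.qc_value)
        write_report(report, out)
        manifest["outputs"] += [str(out / "report.json"), str(out / "report.md")]
        record("stats", "ok")
    except Exception:
        record("stats", "failed")
        raise

    record("done", "ok")
    return out
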