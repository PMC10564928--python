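"""Synthetic fundus-video phantom with known ground truth.

Renders dark vessels on bright tissue (reflectance at 570 nm, where blood
absorbs), modulates vessel intensity with a cardiac sinusoid, and adds the
nuisance effects a real acquisition shows: linear illumination drift,
frame-to-frame translation jitter, and sensor noise.  Every generated video
carries a sidecar with the generative truth (amplitude, frequency, phase,
per-frame shifts, masks), so each downstream stage — registration, ROI
construction, waveform fitting, vessel calipers — can be validated exactly.

Vessel cross-sections are Gaussian with FWHM equal to the nominal width,
which exercises the sub-pixel full-width-at-half-maximum caliper logic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import splev, splprep

from .imgproc import ImageSequence, translate_integer

__all__ = [
    "VesselSpec",
    "Scene",
    "PulsationGroundTruth",
    "FlickerGroundTruth",
    "PhantomVideo",
    "FlickerPair",
    "CohortSubject",
    "render_scene",
    "render_pulsation_video",
    "render_flicker_pair",
    "simulate_cohort",
    "demo_scene",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class VesselSpec:
    """A single vessel: spline centerline, Gaussian cross-section.

    ``width`` is the full width at half maximum of the intensity dip in
    pixels; ``contrast`` is the dip depth below background at the
    centerline (au).  ``label`` is the observer-supplied artery/vein class.
    """

    control_points: tuple[tuple[float, float], ...]
    width: float
    contrast: float
    label: str = "artery"
    name: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"vessel {self.name!r}: width must be > 0")
        if self.contrast <= 0:
            raise ValueError(f"vessel {self.name!r}: contrast must be > 0")
        if len(self.control_points) < 2:
            raise ValueError(f"vessel {self.name!r}: need >= 2 control points")
        if self.label not in ("artery", "vein"):
            raise ValueError(f"vessel {self.name!r}: label must be artery|vein")

    @property
    def sigma(self) -> float:
        return self.width / _FWHM_PER_SIGMA

    def polyline(self, n: int = 800) -> np.ndarray:
        """Densely resampled (y, x) polyline through the control points."""
        pts = np.asarray(self.control_points, dtype=float)
        if len(pts) == 2:
            t = np.linspace(0.0, 1.0, n)
            return pts[0] + t[:, None] * (pts[1] - pts[0])
        k = min(3, len(pts) - 1)
        tck, _ = splprep([pts[:, 0], pts[:, 1]], s=0.0, k=k)
        u = np.linspace(0.0, 1.0, n)
        ys, xs = splev(u, tck)
        return np.column_stack([ys, xs])


@dataclass(frozen=True)
class PulsationGroundTruth:
    """Generative parameters of the cardiac intensity modulation.

    The vessel-pixel waveform is
    ``offset_true + A_true * sin(2*pi*(f_true/60)*t + phase_true) + drift_slope*t``
    with ``f_true`` in beats per minute and ``t`` in seconds.  ONH tissue
    pixels may modulate independently via ``tissue_amplitude``/``tissue_phase``
    (the phase relation between tissue and vessels is not assumed).
    """

    A_true: float = 2.0
    f_true: float = 70.0
    phase_true: float = 0.0
    offset_true: float = 100.0
    drift_slope: float = 0.0
    jitter_sd: float = 0.0
    noise_sd: float = 0.0
    tissue_amplitude: float = 0.0
    tissue_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.A_true < 0:
            raise ValueError("A_true must be >= 0")
        if self.f_true <= 0:
            raise ValueError("f_true must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Closed-form vessel modulation (sinusoid only, no drift)."""
        omega = 2.0 * np.pi * self.f_true / 60.0
        return self.A_true * np.sin(omega * np.asarray(t) + self.phase_true)


@dataclass(frozen=True)
class FlickerGroundTruth:
    """Multiplicative vessel-width change during flicker stimulation."""

    dilation_factor_artery: float = 1.03
    dilation_factor_vein: float = 1.04

    def __post_init__(self) -> None:
        if self.dilation_factor_artery <= 0 or self.dilation_factor_vein <= 0:
            raise ValueError("dilation factors must be > 0")

    def factor(self, label: str) -> float:
        return (
            self.dilation_factor_artery
            if label == "artery"
            else self.dilation_factor_vein
        )


@dataclass
class Scene:
    """Static phantom geometry: vessels plus an optional ONH disc."""

    vessels: list[VesselSpec]
    canvas_size: tuple[int, int] = (256, 256)
    background: float = 100.0
    onh_center: tuple[float, float] | None = None
    onh_radius: float | None = None

    def fields(
        self, width_factors: dict[str, float] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Cached (depth, normalized-distance) fields for this geometry."""
        key = (
            tuple(self.vessels),
            self.canvas_size,
            None if width_factors is None else tuple(sorted(width_factors.items())),
        )
        cache = getattr(self, "_field_cache", None)
        if cache is None or cache[0] != key:
            fields = _vessel_fields(self.vessels, self.canvas_size, width_factors)
            object.__setattr__(self, "_field_cache", (key, fields))
            return fields
        return cache[1]

    def onh_mask(self) -> np.ndarray:
        mask = np.zeros(self.canvas_size, dtype=bool)
        if self.onh_center is not None and self.onh_radius is not None:
            yy, xx = np.mgrid[0 : self.canvas_size[0], 0 : self.canvas_size[1]]
            cy, cx = self.onh_center
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= self.onh_radius**2
        return mask

    def onh_polygon_vertices(self, n: int = 24) -> list[list[float]]:
        """Polygon approximating the ONH disc (for observer-input plumbing)."""
        if self.onh_center is None or self.onh_radius is None:
            raise ValueError("scene has no ONH disc")
        cy, cx = self.onh_center
        ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        r = self.onh_radius * 0.98
        return [[cy + r * np.sin(a), cx + r * np.cos(a)] for a in ang]


def _segment_distance_map(
    shape: tuple[int, int], polyline: np.ndarray, cutoff: float = np.inf
) -> np.ndarray:
    """Per-pixel Euclidean distance to a polyline.

    Distances are exact (point-to-segment) for every pixel closer than
    ``cutoff``; farther pixels keep a nearest-vertex upper bound, which is
    enough because nothing downstream depends on far-field precision.
    """
    from scipy.spatial import cKDTree

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2[ab2 == 0] = 1.0
    # nearest-vertex distance is an upper bound on the true curve distance
    coarse, _ = cKDTree(polyline).query(pix, workers=-1)
    out = coarse.copy()
    sel = np.flatnonzero(coarse <= cutoff + 1.0)
    chunk = 4096
    for s in range(0, sel.size, chunk):
        idx = sel[s : s + chunk]
        p = pix[idx]
        # projection parameter of each pixel onto each segment, clipped
        ap = p[:, None, :] - a[None, :, :]
        tproj = np.clip(np.einsum("pij,ij->pi", ap, ab) / ab2[None, :], 0.0, 1.0)
        close = a[None, :, :] + tproj[:, :, None] * ab[None, :, :]
        d2 = np.einsum("pij,pij->pi", p[:, None, :] - close, p[:, None, :] - close)
        out[idx] = np.sqrt(d2.min(axis=1))
    return out.reshape(shape)


def _vessel_fields(
    vessels: list[VesselSpec],
    canvas_size: tuple[int, int],
    width_factors: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel darkest-wins absorption depth and min normalized distance.

    Returns ``(depth, norm_dist)`` where ``depth`` is the intensity drop and
    ``norm_dist`` is distance to the nearest centerline divided by that
    vessel's half-width (so norm_dist <= 1 is the FWHM band).
    """
    depth = np.zeros(canvas_size, dtype=float)
    norm_dist = np.full(canvas_size, np.inf)
    for v in vessels:
        f = 1.0 if width_factors is None else width_factors.get(v.label, 1.0)
        pts = np.asarray(v.control_points, dtype=float)
        if (
            (pts[:, 0] < 0).any()
            or (pts[:, 1] < 0).any()
            or (pts[:, 0] > canvas_size[0] - 1).any()
            or (pts[:, 1] > canvas_size[1] - 1).any()
        ):
            raise ValueError(
                f"vessel {v.name or v.label!r}: control point outside canvas"
            )
        d = _segment_distance_map(canvas_size, v.polyline(),
                                  cutoff=3.0 * v.width * f)
        sigma = (v.width * f) / _FWHM_PER_SIGMA
        depth = np.maximum(depth, v.contrast * np.exp(-(d**2) / (2.0 * sigma**2)))
        norm_dist = np.minimum(norm_dist, d / (0.5 * v.width * f))
    return depth, norm_dist


def render_scene(
    vessels: list[VesselSpec],
    canvas_size: tuple[int, int] = (256, 256),
    background_level: float = 100.0,
    width_factors: dict[str, float] | None = None,
) -> np.ndarray:
    """Render one static frame: dark Gaussian ridges on a flat background.

    Overlapping vessels combine by darkest-wins (maximum absorption depth).
    """
    depth, _ = _vessel_fields(vessels, canvas_size, width_factors)
    return background_level - depth


def true_masks(
    vessels: list[VesselSpec],
    canvas_size: tuple[int, int],
    width_factors: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth masks: FWHM-band vessel mask and the wider modulation mask.

    ``vessel_mask`` holds pixels within half the FWHM of a centerline (the
    mask a correct segmentation should recover); ``modulation_mask`` extends
    to one FWHM and marks every pixel that receives the cardiac sinusoid.
    """
    _, nd = _vessel_fields(vessels, canvas_size, width_factors)
    return nd <= 1.0, nd <= 2.0


@dataclass
class PhantomVideo:
    """A rendered pulsation video plus its generative sidecar."""

    seq: ImageSequence
    truth: PulsationGroundTruth
    shifts: np.ndarray  # (T, 2) int, applied (dy, dx) jitter per frame
    vessel_mask: np.ndarray
    modulation_mask: np.ndarray
    onh_mask: np.ndarray
    scene: Scene

    def sidecar(self) -> dict:
        d = dataclasses.asdict(self.truth)
        d["shifts"] = self.shifts.tolist()
        d["fps"] = float(
            1.0 / np.median(np.diff(self.seq.timestamps))
        )
        d["n_frames"] = int(self.seq.frames.shape[0])
        return d

    def write(self, directory: str | Path, stem: str = "phantom") -> None:
        """Write TIFF video, JSON sidecar, and PNG truth masks."""
        import imageio.v3 as iio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.seq.to_tiff(directory / f"{stem}.tif")
        (directory / f"{stem}_truth.json").write_text(
            json.dumps(self.sidecar(), indent=2)
        )
        for name, mask in (
            ("vessel_mask", self.vessel_mask),
            ("modulation_mask", self.modulation_mask),
            ("onh_mask", self.onh_mask),
        ):
            iio.imwrite(
                directory / f"{stem}_{name}.png",
                (mask.astype(np.uint8) * 255),
            )


def render_pulsation_video(
    scene: Scene,
    gt: PulsationGroundTruth,
    n_frames: int = 72,
    fps: float = 24.0,
    seed: int = 0,
) -> PhantomVideo:
    """Render a pulsation acquisition (default 24 Hz x 3 s).

    Frame t gets: additive sinusoid on modulation-mask pixels (and an
    independent sinusoid on ONH tissue pixels if ``tissue_amplitude`` > 0),
    whole-frame linear drift, integer translation jitter (edge fill at
    background level), then i.i.d. Gaussian sensor noise.
    """
    if n_frames < 8:
        raise ValueError("n_frames must be >= 8")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    rng = np.random.default_rng(seed)
    depth, norm_dist = scene.fields()
    base = gt.offset_true - depth
    vessel_mask = norm_dist <= 1.0
    modulation_mask = norm_dist <= 2.0
    onh = scene.onh_mask()
    tissue_mask = onh & ~modulation_mask

    t = np.arange(n_frames) / fps
    omega = 2.0 * np.pi * gt.f_true / 60.0
    mod_v = gt.A_true * np.sin(omega * t + gt.phase_true)
    mod_t = gt.tissue_amplitude * np.sin(omega * t + gt.tissue_phase)

    shifts = np.zeros((n_frames, 2), dtype=int)
    if gt.jitter_sd > 0:
        # frame 0 defines the coordinate origin (sidecar masks align with it)
        shifts[1:] = np.rint(
            rng.normal(0.0, gt.jitter_sd, size=(n_frames - 1, 2))
        ).astype(int)

    frames = np.empty((n_frames,) + scene.canvas_size, dtype=float)
    for i in range(n_frames):
        f = base.copy()
        f[modulation_mask] += mod_v[i]
        if gt.tissue_amplitude:
            f[tissue_mask] += mod_t[i]
        f += gt.drift_slope * t[i]
        if shifts[i].any():
            fill = gt.offset_true + gt.drift_slope * t[i]
            f = translate_integer(f, shifts[i][0], shifts[i][1], fill=fill)
        if gt.noise_sd > 0:
            f += rng.normal(0.0, gt.noise_sd, size=f.shape)
        frames[i] = f

    seq = ImageSequence(frames=frames, timestamps=t)
    return PhantomVideo(
        seq=seq,
        truth=gt,
        shifts=shifts,
        vessel_mask=vessel_mask,
        modulation_mask=modulation_mask,
        onh_mask=onh,
        scene=scene,
    )


@dataclass
class FlickerPair:
    """Pre/during flicker frame sets with the generative dilation truth."""

    before: ImageSequence
    during: ImageSequence
    truth: FlickerGroundTruth
    scene: Scene
    true_widths_before: dict[str, list[float]] = field(default_factory=dict)
    true_widths_during: dict[str, list[float]] = field(default_factory=dict)


def render_flicker_pair(
    scene: Scene,
    gt: FlickerGroundTruth,
    seed: int = 0,
    n_frames: int = 10,
    fps: float = 10.0,
    noise_sd: float = 0.0,
) -> FlickerPair:
    """Render pre- and during-flicker sequences (default 10 Hz x 1 s).

    During flicker every vessel's width is multiplied by its label's
    dilation factor; contrast, geometry and noise statistics are unchanged.
    """
    labels = {v.label for v in scene.vessels}
    if not {"artery", "vein"} <= labels:
        raise ValueError("scene must contain at least one artery and one vein")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    factors = {
        "artery": gt.dilation_factor_artery,
        "vein": gt.dilation_factor_vein,
    }
    out = []
    for wf in (None, factors):
        depth, _ = scene.fields(wf)
        base = scene.background - depth
        frames = np.repeat(base[None], n_frames, axis=0).astype(float)
        if noise_sd > 0:
            frames += rng.normal(0.0, noise_sd, size=frames.shape)
        out.append(ImageSequence(frames=frames, timestamps=t.copy()))
    widths_b = {lab: [] for lab in ("artery", "vein")}
    widths_d = {lab: [] for lab in ("artery", "vein")}
    for v in scene.vessels:
        widths_b[v.label].append(v.width)
        widths_d[v.label].append(v.width * factors[v.label])
    return FlickerPair(
        before=out[0],
        during=out[1],
        truth=gt,
        scene=scene,
        true_widths_before=widths_b,
        true_widths_during=widths_d,
    )


def demo_scene(seed: int | None = None) -> Scene:
    """Default phantom: four major vessels crossing a central ONH disc.

    Veins are wider and darker than arteries, matching how observers
    classify them in fundus reflectance images.
    """
    vessels = [
        VesselSpec(
            control_points=((20.0, 90.0), (110.0, 118.0), (235.0, 95.0)),
            width=10.0,
            contrast=45.0,
            label="vein",
            name="vein_main",
        ),
        VesselSpec(
            control_points=((18.0, 150.0), (128.0, 140.0), (238.0, 170.0)),
            width=9.0,
            contrast=40.0,
            label="vein",
            name="vein_second",
        ),
        VesselSpec(
            control_points=((30.0, 60.0), (120.0, 95.0), (230.0, 60.0)),
            width=7.0,
            contrast=28.0,
            label="artery",
            name="artery_main",
        ),
        VesselSpec(
            control_points=((25.0, 200.0), (135.0, 168.0), (232.0, 210.0)),
            width=6.5,
            contrast=25.0,
            label="artery",
            name="artery_second",
        ),
    ]
    return Scene(
        vessels=vessels,
        canvas_size=(256, 256),
        background=100.0,
        onh_center=(128.0, 132.0),
        onh_radius=62.0,
    )


@dataclass
class CohortSubject:
    subject_id: str
    metrics: dict
    video: PhantomVideo
    flicker: FlickerPair | None = None


_GROUPS = ("ND", "NDR", "NPDR")
# population parameters emulate a mixed diabetic-retinopathy cohort:
# age 60+-12 y, MAP 99.9+-13.5 mmHg, IOP 14.5+-2.8 mmHg, HbA1c 5.5% in
# non-diabetics vs ~7.3-7.4% in diabetics, PA 1.83+-1.15 au
_HBA1C = {"ND": (5.5, 0.7), "NDR": (7.3, 1.2), "NPDR": (7.4, 1.5)}


def simulate_cohort(
    n_subjects: int,
    hr_range: tuple[float, float] = (55.0, 90.0),
    seed: int = 0,
    scene: Scene | None = None,
    n_frames: int = 72,
    fps: float = 24.0,
    include_flicker: bool = True,
    noise_frac: float = 0.05,
    drift_slope: float = 0.3,
    jitter_sd: float = 1.0,
) -> list[CohortSubject]:
    """Simulate a cohort of pulsation videos with PF truth tied to HR.

    Each subject's generative pulse frequency equals their recorded heart
    rate (drawn uniformly from ``hr_range``), so pipeline recovery of the
    PF~HR correlation is testable by construction.  Sensor noise defaults
    to ``noise_frac`` of the subject's modulation amplitude.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    rng = np.random.default_rng(seed)
    scene = scene or demo_scene()
    subjects = []
    for i in range(n_subjects):
        group = _GROUPS[i % 3]
        hr = float(rng.uniform(*hr_range))
        amp = float(np.clip(rng.normal(1.83, 1.15), 0.5, 5.0))
        map_ = float(rng.normal(99.9, 13.5))
        iop = float(np.clip(rng.normal(14.5, 2.8), 8.0, None))
        map_ = max(map_, iop + 20.0)
        mu, sd = _HBA1C[group]
        gt = PulsationGroundTruth(
            A_true=amp,
            f_true=hr,
            phase_true=float(rng.uniform(0.0, 2.0 * np.pi)),
            offset_true=scene.background,
            drift_slope=drift_slope,
            jitter_sd=jitter_sd,
            noise_sd=noise_frac * amp,
            tissue_amplitude=0.6 * amp,
            tissue_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
        )
        video = render_pulsation_video(
            scene, gt, n_frames=n_frames, fps=fps, seed=int(rng.integers(2**31))
        )
        flicker = None
        dar = dvr = np.nan
        if include_flicker:
            fgt = FlickerGroundTruth(
                dilation_factor_artery=float(np.clip(rng.normal(1.03, 0.04), 0.95, 1.12)),
                dilation_factor_vein=float(np.clip(rng.normal(1.04, 0.03), 0.95, 1.12)),
            )
            flicker = render_flicker_pair(
                scene, fgt, seed=int(rng.integers(2**31)), noise_sd=noise_frac
            )
            dar = fgt.dilation_factor_artery
            dvr = fgt.dilation_factor_vein
        metrics = {
            "subject_id": f"S{i + 1:03d}",
            "group": group,
            "age": float(np.clip(rng.normal(60.0, 12.0), 25.0, 88.0)),
            "HR": hr,
            "MAP": map_,
            "IOP": iop,
            "HbA1c": float(np.clip(rng.normal(mu, sd), 4.5, 12.0)),
            "f_true": hr,
            "A_true": amp,
            "D_A_R_true": dar,
            "D_V_R_true": dvr,
        }
        subjects.append(
            CohortSubject(
                subject_id=metrics["subject_id"],
                metrics=metrics,
                video=video,
                flicker=flicker,
            )
        )
    return subjects


def cohort_table(subjects: list[CohortSubject]):
    """Subject metrics as a DataFrame (one row per subject)."""
    import pandas as pd

    return pd.DataFrame([s.metrics for s in subjects])
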