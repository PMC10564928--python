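"""Image-sequence container, translation registration, average projection.

Registration is translation-only, found by normalized 2-D cross-correlation
of each frame against a reference frame (the normxcorr2 approach): the
reference, inset by the search range, is matched inside each frame so every
candidate offset correlates against real content; the best integer
displacement is inverted, and vacated border pixels are filled with the
frame's median so downstream ROI means are not biased toward zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.feature import match_template

__all__ = [
    "ImageSequence",
    "RegistrationResult",
    "register_sequence",
    "average_projection",
    "translate_integer",
]


@dataclass
class ImageSequence:
    """Ordered grayscale frames with timestamps.

    ``frames`` is a (T, H, W) float array in arbitrary intensity units;
    ``timestamps`` are seconds from the first frame and must be strictly
    increasing.  ``pixel_pitch`` (um/pixel) is optional pass-through
    metadata and is never used for computation.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.frames.shape[0] > 1 and not (np.diff(self.timestamps) > 0).all():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        fps: float | None = None,
        timestamps: np.ndarray | None = None,
        pixel_pitch: float | None = None,
    ) -> "ImageSequence":
        import tifffile

        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        if timestamps is None:
            timestamps = np.arange(frames.shape[0]) / (fps or 1.0)
        return cls(frames=frames, timestamps=timestamps, pixel_pitch=pixel_pitch)

    def to_tiff(self, path: str | Path, dtype: str = "float32") -> None:
        import tifffile

        tifffile.imwrite(path, self.frames.astype(dtype),
                         photometric="minisblack")


@dataclass
class RegistrationResult:
    """Per-frame integer shifts relative to the reference, plus the
    registered sequence.  ``shifts[i]`` is the detected displacement of
    frame i (the translation applied during registration is its negation).
    """

    shifts: np.ndarray  # (T, 2) int (dy, dx)
    registered: ImageSequence
    reference_index: int
    warnings: list[str] = field(default_factory=list)
    correlation_peaks: np.ndarray | None = None


def translate_integer(
    img: np.ndarray, dy: int, dx: int, fill: float
) -> np.ndarray:
    """Shift an image by integer pixels, filling vacated pixels with ``fill``."""
    out = np.full_like(img, fill)
    h, w = img.shape
    ys0, ys1 = max(0, dy), min(h, h + dy)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    if ys0 < ys1 and xs0 < xs1:
        out[ys0:ys1, xs0:xs1] = img[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def _best_shift(cc: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Argmax of a correlation surface with deterministic tie-breaking:
    ties (within 1e-9 of the peak) resolved by smallest shift magnitude,
    then row-major order."""
    cmax = cc.max()
    cand = np.argwhere(cc >= cmax - 1e-9)
    dy = cand[:, 0] - max_shift
    dx = cand[:, 1] - max_shift
    order = np.lexsort((cand[:, 1], cand[:, 0], dy * dy + dx * dx))
    k = order[0]
    return int(dy[k]), int(dx[k])


def register_sequence(
    seq: ImageSequence,
    reference_index: int = 0,
    max_shift: int | None = None,
    subpixel: bool = False,
) -> RegistrationResult:
    """Register a sequence to one of its frames by translation.

    Each frame's displacement relative to the reference is the integer
    translation maximizing the normalized cross-correlation; the frame is
    then shifted back by that displacement.  A constant (zero-variance)
    frame cannot be correlated: it is passed through with zero shift and a
    warning record.  With ``subpixel=True`` the integer peak is refined by
    parabolic interpolation of the correlation surface and the refinement
    is reported in ``correlation_peaks`` metadata (frames are still moved
    by the integer part, keeping registration exactly invertible).
    """
    if len(seq) < 2:
        raise ValueError("need >= 2 frames to register")
    ref = seq.frames[reference_index]
    if ref.std() == 0:
        raise ValueError("reference frame has zero intensity variance")
    if max_shift is None:
        max_shift = max(4, min(seq.shape) // 8)
    if 2 * max_shift >= min(seq.shape) - 8:
        raise ValueError("max_shift too large for the frame size")
    # the search template is the reference inset by max_shift on every side,
    # so each candidate offset correlates against real frame content only
    template = ref[max_shift:-max_shift, max_shift:-max_shift]
    template32 = template.astype(np.float32)

    n = len(seq)
    shifts = np.zeros((n, 2), dtype=int)
    sub = np.zeros((n, 2), dtype=float)
    registered = np.empty_like(seq.frames)
    warns: list[str] = []
    for i in range(n):
        frame = seq.frames[i]
        if i == reference_index:
            registered[i] = frame
            continue
        if frame.std() == 0:
            msg = f"frame {i} has zero variance; passed through unregistered"
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
            registered[i] = frame
            continue
        med = float(np.median(frame))
        cc = match_template(frame.astype(np.float32), template32)
        dy, dx = _best_shift(cc, max_shift)
        if subpixel:
            sub[i] = _parabolic_refine(cc, dy + max_shift, dx + max_shift)
        shifts[i] = (dy, dx)
        registered[i] = translate_integer(frame, -dy, -dx, fill=med)

    return RegistrationResult(
        shifts=shifts,
        registered=ImageSequence(
            frames=registered,
            timestamps=seq.timestamps.copy(),
            pixel_pitch=seq.pixel_pitch,
        ),
        reference_index=reference_index,
        warnings=warns,
        correlation_peaks=sub if subpixel else None,
    )


def _parabolic_refine(cc: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Sub-pixel peak offset from a 3-point parabola along each axis."""

    def axis_offset(m1: float, c0: float, p1: float) -> float:
        denom = m1 - 2.0 * c0 + p1
        if denom == 0:
            return 0.0
        return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))

    oy = ox = 0.0
    if 0 < iy < cc.shape[0] - 1:
        oy = axis_offset(cc[iy - 1, ix], cc[iy, ix], cc[iy + 1, ix])
    if 0 < ix < cc.shape[1] - 1:
        ox = axis_offset(cc[iy, ix - 1], cc[iy, ix], cc[iy, ix + 1])
    return oy, ox


def average_projection(seq: ImageSequence) -> np.ndarray:
    """Pixelwise arithmetic mean across frames."""
    return seq.frames.mean(axis=0)


def write_shifts_csv(result: RegistrationResult, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "frame": np.arange(len(result.shifts)),
            "dy": result.shifts[:, 0],
            "dx": result.shifts[:, 1],
        }
    ).to_csv(path, index=False)
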