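"""IPPG pulsation analysis: ROI waveform -> sinusoid fit -> PA, PF, R².

The per-frame mean ROI intensity is linearly detrended (slope removed,
mean retained, so the offset stays interpretable as mean reflectance),
smoothed with a centered five-point running mean whose two-point edge
buffers are dropped, and fitted by nonlinear least squares to

    y(t) = A*sin(B*t + C) + D

with A the pulsation amplitude (PA, au), B the angular frequency in
rad/s (PF = B*60/2pi in beats per minute), C the phase and D the offset.
For a 24 Hz, 3 s acquisition (72 frames) the smoothed waveform has 68
points.  Subjects with poor fits (low R²) are excluded by a fixed or
percentile criterion.

Note the running mean attenuates a sinusoid by the known gain
``sin(w*B*dt/2)/(w*sin(B*dt/2))`` for window w, so the fitted A estimates
the attenuated amplitude; :func:`moving_average_gain` gives the factor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .imgproc import ImageSequence

__all__ = [
    "IntensityWaveform",
    "SinusoidFit",
    "PulsationMetrics",
    "extract_waveform",
    "detrend_linear",
    "smooth_and_trim",
    "fit_sinusoid",
    "to_metrics",
    "qc_exclude",
    "moving_average_gain",
    "analyze_sequence",
]


@dataclass
class IntensityWaveform:
    """Mean ROI intensity vs. time through its processing states."""

    t: np.ndarray
    y_raw: np.ndarray
    roi_name: str = ""
    y_detrended: np.ndarray | None = None
    y_smoothed: np.ndarray | None = None
    t_smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y_raw = np.asarray(self.y_raw, dtype=float)
        if self.t.shape != self.y_raw.shape:
            raise ValueError("t and y_raw must have equal length")
        if len(self.t) > 1 and not (np.diff(self.t) > 0).all():
            raise ValueError("t must be strictly increasing")


@dataclass(frozen=True)
class SinusoidFit:
    """Canonical sinusoid coefficients: A >= 0, B > 0, C in [0, 2pi)."""

    A: float
    B: float
    C: float
    D: float
    r_squared: float
    status: str = "ok"  # ok | degenerate | failed
    diagnostics: dict = dataclasses.field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.A * np.sin(self.B * np.asarray(t) + self.C) + self.D


@dataclass(frozen=True)
class PulsationMetrics:
    PA: float
    PF: float  # beats per minute
    r_squared: float
    excluded: bool
    roi_name: str = ""


def extract_waveform(
    seq: ImageSequence, mask: np.ndarray, roi_name: str = ""
) -> IntensityWaveform:
    """Mean intensity over the mask for every frame of a registered sequence."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != seq.shape:
        raise ValueError("mask shape must match frame shape")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    y = seq.frames[:, mask].mean(axis=1)
    return IntensityWaveform(t=seq.timestamps.copy(), y_raw=y, roi_name=roi_name)


def detrend_linear(
    w: IntensityWaveform, keep_mean: bool = True
) -> IntensityWaveform:
    """Remove the least-squares linear trend from the raw waveform.

    The fitted slope (illumination drift) is subtracted; with
    ``keep_mean`` (default) the waveform mean is retained so absolute
    intensity remains meaningful.
    """
    if len(w.t) < 3:
        raise ValueError("need >= 3 points to detrend")
    slope, intercept = np.polyfit(w.t, w.y_raw, 1)
    resid = w.y_raw - (slope * w.t + intercept)
    y_det = resid + w.y_raw.mean() if keep_mean else resid
    return dataclasses.replace(w, y_detrended=y_det)


def smooth_and_trim(w: IntensityWaveform, window: int = 5) -> IntensityWaveform:
    """Centered unweighted running mean, evaluated only on full windows.

    The (window-1)/2 buffer points at each end have no full window and are
    removed, so the output is ``window - 1`` points shorter: 72 samples
    (3 s at 24 Hz) become 68 with the default 5-point window.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    y = w.y_detrended if w.y_detrended is not None else w.y_raw
    if len(y) < window:
        raise ValueError(f"need >= {window} points to smooth")
    b = (window - 1) // 2
    y_s = np.convolve(y, np.ones(window) / window, mode="valid")
    return dataclasses.replace(w, y_smoothed=y_s, t_smoothed=w.t[b:-b].copy())


def moving_average_gain(B: float, dt: float, window: int = 5) -> float:
    """Amplitude gain of a ``window``-point running mean on sin(B t)."""
    x = B * dt / 2.0
    if x == 0:
        return 1.0
    return float(np.sin(window * x) / (window * np.sin(x)))


def _canonicalize(A: float, B: float, C: float) -> tuple[float, float, float]:
    if B < 0:
        B, C = -B, np.pi - C
    if A < 0:
        A, C = -A, C + np.pi
    return A, B, C % (2.0 * np.pi)


def fit_sinusoid(
    w: IntensityWaveform, init_strategy: str = "fft"
) -> SinusoidFit:
    """Nonlinear least-squares fit of A*sin(B*t + C) + D to the smoothed data.

    Initialization: D0 = mean, A0 = sqrt(2)*sd, B0 from the dominant
    nonzero discrete-Fourier frequency, C0 the best of {0, pi/2, pi,
    3pi/2} by initial residual.  Sinusoid fitting is multimodal in B, so
    on failure the fit restarts over a B0 grid spanning +-50% in five
    steps and keeps the best solution.  R² is computed against the
    smoothed data (the data actually fitted) and is not clipped.
    """
    if w.y_smoothed is None or w.t_smoothed is None:
        raise ValueError("waveform must be smoothed before fitting")
    t, y = w.t_smoothed, w.y_smoothed
    if len(y) < 8:
        raise ValueError("need >= 8 smoothed points to fit")

    D0 = float(y.mean())
    ss_tot = float(((y - D0) ** 2).sum())
    if ss_tot < 1e-24 * max(1.0, D0**2):
        return SinusoidFit(
            A=0.0, B=np.nan, C=np.nan, D=D0, r_squared=np.nan,
            status="degenerate",
            diagnostics={"reason": "zero variance (SS_tot = 0)"},
        )

    A0 = float(np.sqrt(2.0) * y.std())
    dt = float(np.median(np.diff(t)))
    spec = np.abs(np.fft.rfft(y - D0))
    freqs = np.fft.rfftfreq(len(y), d=dt)
    k = 1 + int(np.argmax(spec[1:]))
    B0_fft = 2.0 * np.pi * freqs[k]

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.sin(p[1] * t + p[2]) + p[3] - y

    def try_fit(B0: float):
        c_grid = (0.0, np.pi / 2.0, np.pi, 1.5 * np.pi)
        C0 = min(c_grid, key=lambda c: float((resid([A0, B0, c, D0]) ** 2).sum()))
        try:
            res = least_squares(resid, [A0, B0, C0, D0], method="lm", max_nfev=2000)
        except Exception:
            return None
        return res if res.success else None

    best = None
    tried: list[float] = []
    for B0 in [B0_fft] + [B0_fft * f for f in (0.5, 0.75, 1.25, 1.5)]:
        if B0 <= 0:
            continue
        tried.append(B0)
        res = try_fit(B0)
        if res is not None and (best is None or res.cost < best.cost):
            best = res
        # accept the FFT start immediately when it already explains the data
        if best is not None and 1.0 - 2.0 * best.cost / ss_tot > 0.999:
            break
    if best is None:
        return SinusoidFit(
            A=np.nan, B=np.nan, C=np.nan, D=D0, r_squared=np.nan,
            status="failed",
            diagnostics={"reason": "no convergent start", "B0_grid": tried},
        )
    A, B, C = _canonicalize(*best.x[:3])
    ss_res = float((resid(best.x) ** 2).sum())
    return SinusoidFit(
        A=A, B=B, C=C, D=float(best.x[3]),
        r_squared=1.0 - ss_res / ss_tot,
        status="ok",
        diagnostics={"nfev": int(best.nfev), "B0": B0_fft},
    )


def to_metrics(fit: SinusoidFit, roi_name: str = "") -> PulsationMetrics:
    """PA = A (au); PF = B * 60 / 2pi (beats per minute)."""
    if not fit.ok:
        return PulsationMetrics(
            PA=np.nan, PF=np.nan, r_squared=fit.r_squared,
            excluded=True, roi_name=roi_name,
        )
    return PulsationMetrics(
        PA=fit.A,
        PF=fit.B * 60.0 / (2.0 * np.pi),
        r_squared=fit.r_squared,
        excluded=False,
        roi_name=roi_name,
    )


def qc_exclude(
    r_squared: np.ndarray,
    mode: str = "fixed",
    value: float = 0.23,
) -> np.ndarray:
    """Goodness-of-fit exclusion flags.

    ``r_squared`` is either a 1-D array (one flag per fit) or a 2-D
    (subjects x ROIs) array, in which case a subject is excluded when any
    of its ROI fits falls below the cutoff.  ``mode='fixed'`` uses
    ``value`` as the R² cutoff directly; ``mode='percentile'`` sets the
    cutoff at the given lower percentile (linear interpolation) of all
    finite R² values.  Non-finite R² (degenerate fits) is always excluded.
    """
    arr = np.asarray(r_squared, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one R^2 value")
    if mode == "fixed":
        cutoff = value
    elif mode == "percentile":
        finite = arr[np.isfinite(arr)]
        if finite.size == 0:
            return np.ones(arr.shape[0], dtype=bool)
        cutoff = float(np.percentile(finite, value))
    else:
        raise ValueError("mode must be fixed | percentile")
    below = ~np.isfinite(arr) | (arr < cutoff)
    return below.any(axis=1) if arr.ndim == 2 else below


def analyze_sequence(
    seq: ImageSequence,
    masks: dict[str, np.ndarray],
    window: int = 5,
    keep_mean: bool = True,
    median_prefilter: bool = False,
) -> dict[str, dict]:
    """Full waveform analysis per ROI of an already-registered sequence.

    Returns ``{roi_name: {"waveform", "fit", "metrics"}}``.  The optional
    median prefilter (3-point) can knock down residual motion spikes
    before the running mean; it is off by default.
    """
    out: dict[str, dict] = {}
    for name, mask in masks.items():
        w = extract_waveform(seq, mask, roi_name=name)
        if median_prefilter:
            from scipy.signal import medfilt

            w = dataclasses.replace(w, y_raw=medfilt(w.y_raw, 3))
        w = detrend_linear(w, keep_mean=keep_mean)
        w = smooth_and_trim(w, window=window)
        fit = fit_sinusoid(w)
        out[name] = {
            "waveform": w,
            "fit": fit,
            "metrics": to_metrics(fit, roi_name=name),
        }
    return out


def waveform_frame(w: IntensityWaveform):
    """Waveform states as a DataFrame (for CSV export)."""
    import pandas as pd

    df = pd.DataFrame({"t": w.t, "y_raw": w.y_raw})
    if w.y_detrended is not None:
        df["y_detrended"] = w.y_detrended
    if w.y_smoothed is not None:
        sm = np.full(len(w.t), np.nan)
        b = (len(w.t) - len(w.y_smoothed)) // 2
        sm[b : b + len(w.y_smoothed)] = w.y_smoothed
        df["y_smoothed"] = sm
    return df
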