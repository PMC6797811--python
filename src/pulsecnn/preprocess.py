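"""Pulse-signal preprocessing: denoise, segment, resample, normalize, rasterize.

The chain turns a raw multi-cycle record into per-cycle 200x200 grayscale
images:

1. wavelet denoising (soft universal thresholding of detail coefficients);
2. cycle segmentation at waveform feet (the local minimum before each
   maximal-slope systolic upstroke);
3. uniform-time resampling of each cycle to 200 points;
4. affine amplitude normalization to the range 0-200;
5. rasterization of the normalized cycle onto a 200x200 pixel grid with the
   trace drawn as a connected curve.

Amplitude and duration are deliberately discarded by steps 3-4: only the
cycle's shape survives, which is what the downstream classifier consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from PIL import Image
from scipy.signal import find_peaks, savgol_filter

from .synthetic import RawPulseSignal

__all__ = [
    "N_POINTS",
    "AMP_MAX",
    "PulseCycle",
    "NormalizedCycle",
    "PulseImage",
    "PreprocessConfig",
    "DegenerateCycleError",
    "denoise",
    "segment_cycles",
    "resample_cycle",
    "normalize_amplitude",
    "rasterize",
    "image_to_values",
    "preprocess_record",
    "write_png",
    "read_png",
]

N_POINTS = 200   # samples per normalized cycle
AMP_MAX = 200.0  # top of the normalized amplitude range


class DegenerateCycleError(ValueError):
    """Raised when a cycle cannot be normalized (constant amplitude)."""


@dataclass
class PulseCycle:
    """One segmented pulse cycle in raw amplitude units."""

    samples: np.ndarray
    fs: float
    subject_id: str | None = None
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) < 16:
            raise ValueError("a pulse cycle needs at least 16 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("cycle contains non-finite samples")


@dataclass
class NormalizedCycle:
    """A cycle resampled to 200 points with amplitude mapped to [0, 200]."""

    values: np.ndarray
    subject_id: str | None = None
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_POINTS,):
            raise ValueError(f"normalized cycle must have {N_POINTS} values")
        if self.values.min() < 0 or self.values.max() > AMP_MAX:
            raise ValueError("normalized values must lie in [0, 200]")


@dataclass
class PulseImage:
    """200x200 8-bit raster of one cycle: background 0, curve 255, row 0 on top."""

    pixels: np.ndarray
    label: str | None = None
    subject_id: str | None = None
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (N_POINTS, N_POINTS):
            raise ValueError(f"pulse image must be {N_POINTS}x{N_POINTS}")


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the preprocessing chain.

    ``level=None`` selects ceil(log2(fs / 8)), deep enough that the kept
    approximation band ends near 8 Hz and detail thresholding removes the
    high-frequency noise floor without blunting the systolic upstroke.
    """

    wavelet: str = "db4"
    level: int | None = None
    threshold_mode: str = "soft"
    n_points: int = N_POINTS


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------


def denoise(
    signal: RawPulseSignal,
    wavelet: str = "db4",
    level: int | None = None,
    threshold_mode: str = "soft",
) -> RawPulseSignal:
    """Wavelet-threshold denoising; preserves length and sampling rate.

    Detail coefficients at every level are soft-thresholded with the
    universal threshold sigma * sqrt(2 log n), sigma estimated from the
    finest-level median absolute deviation.  The approximation band is left
    untouched, so slow baseline drift survives (per-cycle normalization
    removes it later).
    """
    x = np.asarray(signal.samples, dtype=float)
    if level is None:
        level = max(1, math.ceil(math.log2(max(2.0, signal.fs / 8.0))))
    if len(x) < 2**level:
        raise ValueError(
            f"signal of length {len(x)} too short for decomposition level {level}"
        )
    coeffs = pywt.wavedec(x, wavelet, level=level)
    detail_fine = coeffs[-1]
    sigma = float(np.median(np.abs(detail_fine)) / 0.6745)
    thr = sigma * math.sqrt(2.0 * math.log(max(2, len(x))))
    if thr > 0:
        coeffs = [coeffs[0]] + [
            pywt.threshold(c, thr, mode=threshold_mode) for c in coeffs[1:]
        ]
    den = pywt.waverec(coeffs, wavelet)[: len(x)]
    return replace(signal, samples=den)


# ---------------------------------------------------------------------------
# Cycle segmentation
# ---------------------------------------------------------------------------


def _cycle_period(y: np.ndarray, fs: float) -> int | None:
    """Dominant cycle length in samples via the first prominent autocorrelation peak.

    The first peak at least half as high as the best peak in the plausible
    lag band (0.3-2.5 s) is taken, which avoids locking onto 2x/3x harmonics
    when beat-to-beat jitter smears the fundamental.
    """
    z = y - y.mean()
    n = len(z)
    f = np.fft.rfft(z, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n]
    lo = max(16, int(0.3 * fs))
    hi = min(n // 2, int(2.5 * fs))
    if hi <= lo:
        return None
    seg = acf[lo:hi]
    peaks, _ = find_peaks(seg)
    if len(peaks) == 0:
        return lo + int(np.argmax(seg))
    best = seg[peaks].max()
    for p in peaks:
        if seg[p] >= 0.5 * best:
            return lo + int(p)
    return lo + int(np.argmax(seg))


def segment_cycles(signal: RawPulseSignal) -> list[PulseCycle]:
    """Split a (denoised) record into foot-to-foot pulse cycles.

    Upstroke candidates are slope maxima; candidates closer than 60% of the
    autocorrelation-estimated cycle period are suppressed (keeping the
    steeper one, which discards dicrotic upslopes).  Each foot is then
    located on a lightly smoothed trace as the point where the pressure
    first exceeds the preceding valley baseline by 10% of the local pulse
    height — i.e. where the systolic rise begins.  Returns an empty list
    (with a warning) when no cycles are detectable, e.g. on a flat signal.
    """
    x = np.asarray(signal.samples, dtype=float)
    rng_amp = float(x.max() - x.min()) if len(x) else 0.0
    if len(x) < 32 or rng_amp < 1e-12 or rng_amp < 1e-6 * max(1.0, abs(float(x.max()))):
        warnings.warn("no detectable pulse cycles in record", stacklevel=2)
        return []

    win = min(9, len(x) if len(x) % 2 else len(x) - 1)
    y = savgol_filter(x, win, 2) if win >= 5 else x
    dx = np.gradient(y)
    if dx.max() <= 0:
        warnings.warn("no rising edges found in record", stacklevel=2)
        return []
    period = _cycle_period(y, signal.fs)
    if period is None:
        warnings.warn("record too short to estimate a cycle period", stacklevel=2)
        return []
    upstrokes, _ = find_peaks(dx, height=0.15 * float(dx.max()),
                              distance=max(1, int(0.6 * period)))
    if len(upstrokes) == 0:
        warnings.warn("no systolic upstrokes found in record", stacklevel=2)
        return []

    lookback = max(2, int(round(0.35 * period)))
    feet: list[int] = []
    for u in upstrokes:
        lo = max(0, u - lookback)
        if feet:
            lo = max(lo, feet[-1] + 1)
        if lo >= u:
            continue
        w = y[lo : u + 1]
        if lo == 0 and u < lookback:
            # record starts inside this upstroke's rise: no preceding valley
            foot = int(np.argmin(w))
        else:
            vbase = float(np.percentile(w, 10))
            peak = float(y[u : min(len(y), u + lookback)].max())
            thr = vbase + 0.10 * (peak - vbase)
            below = np.nonzero(w <= thr)[0]
            if len(below):
                i = int(below[-1])
                if i + 1 < len(w) and w[i + 1] > w[i]:  # sub-sample crossing
                    foot = lo + int(round(i + (thr - w[i]) / (w[i + 1] - w[i])))
                else:
                    foot = lo + i
            else:
                foot = lo + int(np.argmin(w))
        if not feet or foot > feet[-1]:
            feet.append(foot)

    if not feet:
        warnings.warn("no feet located in record", stacklevel=2)
        return []

    bounds = feet + [len(x)]
    cycles: list[PulseCycle] = []
    for i in range(len(feet)):
        seg = x[bounds[i] : bounds[i + 1]]
        if len(seg) >= 16:
            cycles.append(PulseCycle(
                samples=seg, fs=signal.fs,
                subject_id=signal.subject_id, cycle_index=len(cycles),
            ))
    return cycles


def segmentation_feet(cycles: list[PulseCycle], signal: RawPulseSignal) -> np.ndarray:
    """Reconstruct foot indices from segmented cycle lengths (for scoring)."""
    lengths = [len(c.samples) for c in cycles]
    if not lengths:
        return np.array([], dtype=int)
    total = len(signal.samples)
    start = total - sum(lengths)
    return start + np.concatenate(([0], np.cumsum(lengths)[:-1]))


# ---------------------------------------------------------------------------
# Resampling and normalization
# ---------------------------------------------------------------------------


def resample_cycle(cycle: PulseCycle | np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Piecewise-linear uniform-time resampling to ``n_points`` samples.

    Endpoints of the raw cycle are preserved exactly; linear segments are
    reproduced without deviation.
    """
    samples = cycle.samples if isinstance(cycle, PulseCycle) else np.asarray(cycle, dtype=float)
    if len(samples) < 2:
        raise ValueError("cannot resample a cycle shorter than 2 samples")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    src = np.linspace(0.0, 1.0, len(samples))
    dst = np.linspace(0.0, 1.0, n_points)
    return np.interp(dst, src, samples)


def normalize_amplitude(values: np.ndarray, subject_id: str | None = None,
                        cycle_index: int = 0) -> NormalizedCycle:
    """Affine map of a 200-point cycle onto [0, 200] (min -> 0, max -> 200)."""
    v = np.asarray(values, dtype=float)
    if v.shape != (N_POINTS,):
        raise ValueError(f"expected {N_POINTS} values, got shape {v.shape}")
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        raise DegenerateCycleError("constant cycle cannot be normalized to 0-200")
    out = np.clip((v - lo) * (AMP_MAX / (hi - lo)), 0.0, AMP_MAX)
    out[v == lo] = 0.0    # pin the extremes exactly despite rounding
    out[v == hi] = AMP_MAX
    return NormalizedCycle(out, subject_id, cycle_index)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def rasterize(cycle: NormalizedCycle) -> PulseImage:
    """Draw a normalized cycle as a connected curve on a 200x200 grid.

    Column x carries the curve at row 199 - round(value_x) (y axis upward,
    rounding half-up, rows clipped to the grid since 201 amplitude levels map
    onto 200 rows).  Connectivity fills run strictly downward from each
    column's own pixel, so the topmost foreground row of every column encodes
    that column's value exactly and the trace stays 8-connected.
    """
    v = cycle.values
    if v.min() < 0 or v.max() > AMP_MAX:
        raise ValueError("normalized values out of [0, 200]")
    rows = (199 - np.floor(v + 0.5)).astype(int)
    rows = np.clip(rows, 0, N_POINTS - 1)

    img = np.zeros((N_POINTS, N_POINTS), dtype=np.uint8)
    img[rows[0], 0] = 255
    for x in range(1, N_POINTS):
        r_prev, r_cur = rows[x - 1], rows[x]
        if r_cur < r_prev:      # value rising: extend this column down to meet x-1
            img[r_cur : r_prev + 1, x] = 255
        elif r_cur > r_prev:    # value falling: extend previous column down to meet x
            img[r_prev : r_cur + 1, x - 1] = 255
            img[r_cur, x] = 255
        else:
            img[r_cur, x] = 255
    return PulseImage(img, subject_id=cycle.subject_id, cycle_index=cycle.cycle_index)


def image_to_values(image: PulseImage) -> np.ndarray:
    """Invert :func:`rasterize`: per-column topmost foreground row -> value."""
    fg = image.pixels != 0
    if not fg.any(axis=0).all():
        raise ValueError("image has columns without foreground pixels")
    top = fg.argmax(axis=0)
    return (199 - top).astype(float)


# ---------------------------------------------------------------------------
# Chain + PNG IO
# ---------------------------------------------------------------------------


def preprocess_record(
    signal: RawPulseSignal, config: PreprocessConfig = PreprocessConfig()
) -> list[tuple[PulseCycle, NormalizedCycle, PulseImage]]:
    """Full chain on one record; degenerate cycles are skipped."""
    den = denoise(signal, wavelet=config.wavelet, level=config.level,
                  threshold_mode=config.threshold_mode)
    out = []
    for cyc in segment_cycles(den):
        try:
            norm = normalize_amplitude(
                resample_cycle(cyc, config.n_points), cyc.subject_id, cyc.cycle_index
            )
        except DegenerateCycleError:
            continue
        img = rasterize(norm)
        img.label = signal.true_label
        out.append((cyc, norm, img))
    return out


def write_png(image: PulseImage, path) -> None:
    Image.fromarray(image.pixels, mode="L").save(path, format="PNG")


def read_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
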