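"""Fluo-4 calcium trace extraction, correction and transient quantification.

The recording geometry: a time sequence of fluorescence frames (one frame
every ~345 ms) of a fluo-4-loaded cell while an AFM probe indents it.
Intensity is spatially averaged over a region of interest (a 5 um circle
at the indentation point for local responses, or an ellipse surrounding
the whole cell for global ones) and processed as:

1. extract the ROI mean trace;
2. normalize to the initial basal reading (corrects for dye loading);
3. correct for photobleaching (mono-exponential fitted to quiescent
   samples and divided out) and for the cantilever reflection artifact
   (the least-squares component of intensity linear in deflection,
   estimated on contact frames against a smooth interpolated background,
   subtracted);
4. estimate noise as the SD of the detrended intensity over the most
   linear 20-frame portion of the trace;
5. call a response positive when an increase over basal exceeds four-fold
   the noise (strict inequality).

Detected transients are quantified by relative amplitude (peak minus
basal, basal = 1 after normalization), duration (full width at half
maximum, linearly interpolated between frames) and amount (amplitude x
duration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import (
    AlignmentUndefinedError,
    CorrectionFailedError,
    CoverageError,
    DegenerateTraceError,
    GeometryError,
    NoiseUndefinedError,
    PreconditionError,
)

RAW = "raw"
NORMALIZED = "normalized"
CORRECTED = "corrected"

#: default ROI diameter, um (circle centered on the indentation point)
DEFAULT_ROI_DIAMETER_UM = 5.0
#: response threshold in units of the trace noise SD (strict inequality)
NOISE_MULTIPLE = 4.0


@dataclass
class ImageStack:
    """A fluorescence movie: (frame, row, col) intensities plus frame times."""

    frames: np.ndarray
    frame_times: np.ndarray
    pixel_size: float  # um / pixel

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise GeometryError(
                f"frames must be 3-D (frame, row, col), got shape {self.frames.shape}"
            )
        if len(self.frame_times) != self.frames.shape[0] or self.frames.shape[0] < 2:
            raise GeometryError("frame count must equal len(frame_times) >= 2")
        if np.any(np.diff(self.frame_times) <= 0):
            raise GeometryError("frame_times must be strictly increasing")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be > 0")


@dataclass(frozen=True)
class RoiSpec:
    """Circle or ellipse over which intensity is averaged.

    ``center`` is (row, col) in pixels; ``diameter`` (circle) or ``axes``
    (ellipse full axes, row x col) are in um.
    """

    shape: str
    center: tuple[float, float]
    diameter: Optional[float] = None  # um, circles
    axes: Optional[tuple[float, float]] = None  # um, ellipses

    def semi_axes_px(self, pixel_size: float) -> tuple[float, float]:
        if self.shape == "circle":
            if self.diameter is None:
                raise GeometryError("circle ROI requires a diameter")
            r = self.diameter / 2.0 / pixel_size
            return r, r
        if self.shape == "ellipse":
            if self.axes is None:
                raise GeometryError("ellipse ROI requires axes")
            return self.axes[0] / 2.0 / pixel_size, self.axes[1] / 2.0 / pixel_size
        raise GeometryError(f"unknown ROI shape {self.shape!r}")


@dataclass
class FluorescenceTrace:
    """A per-ROI intensity time series with its correction state.

    ``state`` advances raw -> normalized -> corrected; every operation
    appends itself to ``provenance``.
    """

    time: np.ndarray
    intensity: np.ndarray
    state: str = RAW
    noise: Optional[float] = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.time) != len(self.intensity):
            raise GeometryError("time and intensity lengths differ")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass(frozen=True)
class TransientEvent:
    """Index span of one supra-threshold excursion (start, peak, end)."""

    start: int
    peak: int
    end: int


@dataclass(frozen=True)
class Transient:
    """One quantified calcium response.

    amplitude is the increase over basal (dimensionless after
    normalization); duration is the FWHM in s; amount = amplitude x
    duration.  ``partial`` marks transients truncated by the recording
    boundary, for which duration and amount are absent.
    """

    onset_time: float
    peak_time: float
    amplitude: float
    duration: Optional[float]
    amount: Optional[float]
    partial: bool = False


# ---------------------------------------------------------------------------
# ROI extraction


def roi_mask(
    shape_px: tuple[int, int], roi: RoiSpec, pixel_size: float
) -> np.ndarray:
    """Boolean pixel mask using the pixel-center-inside test."""
    nrow, ncol = shape_px
    a, b = roi.semi_axes_px(pixel_size)  # semi-axes in px (row, col)
    r0, c0 = roi.center
    if r0 - a < -0.5 or r0 + a > nrow - 0.5 or c0 - b < -0.5 or c0 + b > ncol - 0.5:
        raise GeometryError("ROI extends outside image bounds")
    rows = np.arange(nrow)[:, None]
    cols = np.arange(ncol)[None, :]
    mask = ((rows - r0) / a) ** 2 + ((cols - c0) / b) ** 2 <= 1.0
    if not mask.any():
        raise GeometryError("ROI contains no pixel centers")
    return mask


def extract_roi_trace(stack: ImageStack, roi: RoiSpec) -> FluorescenceTrace:
    """Spatially averaged intensity over the ROI, one value per frame."""
    mask = roi_mask(stack.frames.shape[1:], roi, stack.pixel_size)
    intensity = stack.frames[:, mask].mean(axis=1)
    return FluorescenceTrace(
        time=stack.frame_times.copy(),
        intensity=intensity,
        state=RAW,
        provenance=[f"extract_roi_trace(shape={roi.shape}, n_px={int(mask.sum())})"],
    )


# ---------------------------------------------------------------------------
# Corrections


def normalize_baseline(
    trace: FluorescenceTrace, baseline_frames: int = 10
) -> FluorescenceTrace:
    """Divide by the mean over the initial basal window (dye-loading
    normalization); the output baseline mean is 1."""
    if baseline_frames < 5:
        raise PreconditionError("baseline window needs >= 5 frames")
    if len(trace) < baseline_frames:
        raise PreconditionError("trace shorter than the baseline window")
    b = float(trace.intensity[:baseline_frames].mean())
    if b <= 0:
        raise DegenerateTraceError(f"baseline mean must be > 0, got {b}")
    return FluorescenceTrace(
        time=trace.time.copy(),
        intensity=trace.intensity / b,
        state=NORMALIZED,
        noise=trace.noise,
        provenance=trace.provenance
        + [f"normalize_baseline(frames={baseline_frames}, mean={b:.6g})"],
    )


def _quiescent_mask(y: np.ndarray, cut: float = 2.5) -> np.ndarray:
    """Rough mask of samples not inside a sustained excursion.

    The noise scale comes from robust first differences (insensitive to
    smooth transients and to a trace that spends most of its frames
    elevated); the baseline level is the median of the lower cluster.
    Runs of two or more consecutive samples more than ``cut`` noise SDs
    above baseline are excluded.  Isolated supra-threshold frames are
    noise and stay included: removing them would top-censor any SD
    estimated from the remaining samples.
    """
    dy = np.diff(y)
    sd = 1.4826 * float(np.median(np.abs(dy - np.median(dy)))) / np.sqrt(2.0)
    if sd <= 0:
        return np.ones(y.size, dtype=bool)
    low = y <= np.percentile(y, 25) + 2.5 * sd
    base = float(np.median(y[low])) if low.any() else float(np.median(y))
    above = y > base + cut * sd
    prev = np.concatenate([[False], above[:-1]])
    nxt = np.concatenate([above[1:], [False]])
    sustained = above & (prev | nxt)
    return ~sustained


def correct_bleaching(
    trace: FluorescenceTrace,
    quiescent: Optional[np.ndarray] = None,
    anchor: Optional[np.ndarray] = None,
) -> FluorescenceTrace:
    """Divide out a mono-exponential photobleaching decay.

    The model A*exp(-b t) is fitted by log-linear least squares to
    quiescent samples and the trace is divided by it, flattening
    quiescent portions to 1.  Three ways to choose the quiescent set:

    * ``quiescent``: an exact boolean mask, used as given;
    * ``anchor``: a mask of samples known to be quiescent (e.g. the
      pre-stimulus window); the set is grown iteratively to all samples
      whose residual is consistent with the fit (within 2.5 robust SDs),
      so the decay is constrained over the whole recording without
      letting transients in;
    * neither: the anchor is found by iteratively re-fitting the whole
      trace and dropping samples more than 2.5 robust SDs above the fit
      (transients are positive excursions, so the clip is one-sided).
    """
    if trace.state not in (NORMALIZED, CORRECTED):
        raise PreconditionError("correct_bleaching requires a normalized trace")
    y = trace.intensity
    if np.any(y <= 0):
        raise CorrectionFailedError(
            "non-positive intensities; bleaching fit undefined", trace
        )
    ly_all = np.log(y)
    t_all = trace.time

    def fit(mask):
        if mask.sum() < 5:
            raise CorrectionFailedError(
                "too few quiescent samples to fit bleaching", trace
            )
        return np.polyfit(t_all[mask], ly_all[mask], 1)

    if quiescent is not None:
        mask = np.asarray(quiescent, bool)
        slope, intercept = fit(mask)
    elif anchor is not None:
        seed = np.asarray(anchor, bool)
        mask = seed.copy()
        slope, intercept = fit(mask)
        for _ in range(4):
            resid = ly_all - (intercept + slope * t_all)
            # residual scale from the anchor's currently-kept frames, so
            # an excursion inside the anchor (a spontaneous transient)
            # cannot set the band; outliers leave, consistent frames join
            ref = mask & seed
            if ref.sum() < 5:
                ref = seed
            med = np.median(resid[ref])
            sd = 1.4826 * np.median(np.abs(resid[ref] - med))
            if sd <= 0:
                break
            new = np.abs(resid - med) <= 2.5 * sd
            if new.sum() < 5 or np.array_equal(new, mask):
                break
            mask = new
            slope, intercept = fit(mask)
    else:
        mask = np.ones(y.size, dtype=bool)
        slope = intercept = 0.0
        for _ in range(6):
            slope, intercept = fit(mask)
            resid = ly_all - (intercept + slope * t_all)
            med = np.median(resid[mask])
            sd = 1.4826 * np.median(np.abs(resid[mask] - med))
            if sd <= 0:
                break
            new = resid <= med + 2.5 * sd
            if new.sum() < max(10, y.size // 5) or np.array_equal(new, mask):
                break
            mask = new
    model = np.exp(intercept + slope * trace.time)
    return FluorescenceTrace(
        time=trace.time.copy(),
        intensity=y / model,
        state=CORRECTED,
        noise=trace.noise,
        provenance=trace.provenance
        + [f"correct_bleaching(rate={-slope:.6g}/s, scale={math.exp(intercept):.6g})"],
    )


def _resample_deflection(
    trace: FluorescenceTrace, d_time: np.ndarray, d: np.ndarray
) -> np.ndarray:
    d_time = np.asarray(d_time, dtype=float)
    d = np.asarray(d, dtype=float)
    if d_time[0] > trace.time[0] + 1e-9 or d_time[-1] < trace.time[-1] - 1e-9:
        raise CoverageError(
            "deflection record does not span the trace "
            f"([{d_time[0]:.3f}, {d_time[-1]:.3f}] vs "
            f"[{trace.time[0]:.3f}, {trace.time[-1]:.3f}] s)"
        )
    return np.interp(trace.time, d_time, d)


def correct_reflection_artifact(
    trace: FluorescenceTrace,
    d_time: np.ndarray,
    deflection: np.ndarray,
    contact_fraction: float = 0.05,
    min_contact_frames: int = 2,
) -> FluorescenceTrace:
    """Remove the cantilever-reflection component of the signal.

    The artifact is modelled as linear in cantilever deflection.  Frames
    where |deflection| exceeds ``contact_fraction`` of its maximum are
    treated as contaminated; the underlying calcium signal there is
    estimated by linear interpolation from the surrounding clean frames,
    and the gain is the least-squares fit of the residual against
    deflection.  Fitting against the interpolated background (rather than
    regressing the whole trace on deflection) keeps a calcium transient
    that overlaps the contact window from biasing the gain, so transient
    amplitudes are preserved.
    """
    d = _resample_deflection(trace, d_time, deflection)
    # threshold on the original record's full swing: if the contact
    # window falls between frames the resampled series is all noise and
    # no frame counts as contaminated (gain estimate 0, output = input)
    dmax = float(np.max(np.abs(np.asarray(deflection, dtype=float))))
    contaminated = np.abs(d) > contact_fraction * dmax if dmax > 0 else np.zeros(len(d), bool)
    # fewer contact frames than this and the gain is unidentifiable at
    # frame resolution (a fit would absorb part of any overlapping
    # transient); leave the trace untouched instead
    if contaminated.sum() < min_contact_frames:
        contaminated = np.zeros(len(d), bool)
    if not contaminated.any():
        return replace(
            trace,
            time=trace.time.copy(),
            intensity=trace.intensity.copy(),
            state=CORRECTED,
            provenance=trace.provenance + ["correct_reflection_artifact(gain=0)"],
        )
    clean = ~contaminated
    if clean.sum() < 2:
        raise CorrectionFailedError("no clean frames to anchor the background", trace)
    background = np.interp(
        trace.time, trace.time[clean], trace.intensity[clean]
    )
    r = trace.intensity[contaminated] - background[contaminated]
    dc = d[contaminated]
    gain = float(np.dot(r, dc) / np.dot(dc, dc)) if dc.size else 0.0
    return FluorescenceTrace(
        time=trace.time.copy(),
        intensity=trace.intensity - gain * d,
        state=CORRECTED,
        noise=trace.noise,
        provenance=trace.provenance
        + [f"correct_reflection_artifact(gain={gain:.6g}/nm)"],
    )


def align_timebases(
    trace: FluorescenceTrace,
    d_time: np.ndarray,
    deflection: np.ndarray,
    max_lag: float,
) -> float:
    """Lag (s) of the trace's artifact component relative to deflection.

    Cross-correlates the mean-subtracted trace with the deflection
    envelope resampled to the frame grid, over integer frame shifts
    within +/- ``max_lag``.  A positive lag means the artifact appears in
    the trace ``lag`` seconds after the deflection record.  Flat inputs,
    or a best lag pinned at the search boundary (true shift outside the
    window), raise :class:`AlignmentUndefinedError`.
    """
    dt = trace.frame_interval
    span = trace.time[-1] - trace.time[0]
    if span <= 2 * max_lag:
        raise PreconditionError("trace must span more than 2 x max_lag")
    d_time = np.asarray(d_time, dtype=float)
    deflection = np.asarray(deflection, dtype=float)
    d = np.interp(trace.time, d_time, deflection, left=0.0, right=0.0)
    y = trace.intensity - trace.intensity.mean()
    d = d - d.mean()
    if np.allclose(y, 0) or np.allclose(d, 0):
        raise AlignmentUndefinedError("flat input: alignment undefined")
    max_shift = int(round(max_lag / dt))
    if max_shift < 1:
        raise PreconditionError("max_lag smaller than one frame interval")
    shifts = np.arange(-max_shift, max_shift + 1)
    scores = np.empty(shifts.size)
    n = y.size
    for j, k in enumerate(shifts):
        if k >= 0:
            a, b = y[k:], d[: n - k]
        else:
            a, b = y[: n + k], d[-k:]
        scores[j] = float(np.dot(a, b))
    best = int(shifts[int(np.argmax(scores))])
    if abs(best) == max_shift:
        raise AlignmentUndefinedError(
            f"best lag at the search boundary ({best} frames); "
            "true offset may exceed max_lag"
        )
    return best * dt


# ---------------------------------------------------------------------------
# Noise and transients


def estimate_noise(
    trace: FluorescenceTrace, window: int = 20, exclude: Optional[np.ndarray] = None
) -> FluorescenceTrace:
    """Noise = SD of detrended intensity over the most linear portion.

    Scans every contiguous ``window``-frame stretch (outside obvious
    excursions) and fits a line to each; the selected linear portion is
    the window with the smallest |slope|.  The reported SD pools the
    residual SDs (median) of the flattest quartile of windows: a single
    20-frame SD carries ~17% sampling error, which would make the
    4 x noise response threshold itself noisy.  The estimate is stored
    on the returned trace.
    """
    n = len(trace)
    if n < window:
        raise NoiseUndefinedError(f"trace has {n} < {window} frames")
    y = trace.intensity
    mask = _quiescent_mask(y) if exclude is None else ~np.asarray(exclude, bool)
    x = np.arange(window, dtype=float)
    x = x - x.mean()
    sxx = float(np.dot(x, x))

    def scan(valid) -> list[tuple[float, float, int]]:
        out = []  # (|slope|, sd, start)
        for start in range(0, n - window + 1):
            if not valid[start : start + window].all():
                continue
            w = y[start : start + window]
            slope = float(np.dot(x, w - w.mean())) / sxx
            resid = w - w.mean() - slope * x
            sd = float(np.sqrt(np.dot(resid, resid) / (window - 2)))
            out.append((abs(slope), sd, start))
        return out

    candidates = scan(mask)
    if candidates:
        candidates.sort()
        best = candidates[0]
        quartile = candidates[: max(1, len(candidates) // 4)]
        sd = float(np.median([c[1] for c in quartile]))
        detail = f"estimate_noise(window={window}, start={best[2]}, sd={sd:.6g})"
    else:
        # transients or isolated outliers can break every contiguous
        # 20-frame run; fall back to a difference-based estimate over
        # consecutive quiescent frame pairs (for white noise,
        # SD = robust SD of first differences / sqrt(2))
        pairs = mask[:-1] & mask[1:]
        if pairs.sum() < 10:
            raise NoiseUndefinedError("no quiescent window of the required length")
        diffs = np.diff(y)[pairs]
        med = np.median(diffs)
        sd = float(1.4826 * np.median(np.abs(diffs - med)) / np.sqrt(2.0))
        detail = f"estimate_noise(differences, n_pairs={int(pairs.sum())}, sd={sd:.6g})"
    return replace(
        trace,
        time=trace.time.copy(),
        intensity=trace.intensity.copy(),
        noise=sd,
        provenance=trace.provenance + [detail],
    )


def _split_event(y: np.ndarray, start: int, end: int, basal: float) -> list[tuple[int, int]]:
    """Split a multi-peak excursion at interior local minima that fall
    below half of the larger peak's amplitude."""
    seg = y[start : end + 1]
    peak_amp = seg.max() - basal
    half = basal + 0.5 * peak_amp
    interior = np.arange(1, seg.size - 1)
    minima = [
        i
        for i in interior
        if seg[i] < seg[i - 1] and seg[i] <= seg[i + 1] and seg[i] < half
    ]
    if not minima:
        return [(start, end)]
    cut = start + int(min(minima, key=lambda i: seg[i]))
    return _split_event(y, start, cut, basal) + _split_event(y, cut, end, basal)


def detect_transients(
    trace: FluorescenceTrace, basal: float = 1.0
) -> list[TransientEvent]:
    """Supra-threshold excursions: maximal contiguous stretches above
    basal whose peak increase strictly exceeds four-fold the noise."""
    if trace.noise is None:
        raise PreconditionError("noise must be estimated before detection")
    if trace.state != CORRECTED:
        raise PreconditionError("detection requires a corrected trace")
    y = trace.intensity
    above = y > basal
    events: list[TransientEvent] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [int(e) + 1 for e in edges if above[e + 1]]
    ends = [int(e) for e in edges if above[e]]
    if above[-1]:
        ends.append(len(y) - 1)
    for s, e in zip(starts, ends):
        for s2, e2 in _split_event(y, s, e, basal):
            peak = s2 + int(np.argmax(y[s2 : e2 + 1]))
            # strict threshold with a relative guard so float rounding at
            # exact equality cannot tip the comparison
            threshold = NOISE_MULTIPLE * trace.noise
            if y[peak] - basal > threshold * (1 + 1e-9):
                events.append(TransientEvent(start=s2, peak=peak, end=e2))
    events.sort(key=lambda ev: ev.start)
    return events


def _cross_time(t0, y0, t1, y1, level) -> float:
    """Time at which the segment (t0,y0)-(t1,y1) crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def characterize_transient(
    trace: FluorescenceTrace, event: TransientEvent, basal: float = 1.0
) -> Transient:
    """Amplitude, FWHM duration and amount of one detected transient.

    Duration is the full width at half-maximum amplitude with linear
    interpolation between frames.  A transient cut off by the recording
    boundary is flagged partial and gets no duration/amount.
    """
    t, y = trace.time, trace.intensity
    peak = event.peak
    amplitude = float(y[peak] - basal)
    if amplitude <= 0:
        raise PreconditionError("event peak does not rise above basal")
    half = basal + amplitude / 2.0

    # onset: crossing of basal just before the excursion starts
    if event.start > 0:
        onset = _cross_time(t[event.start - 1], y[event.start - 1], t[event.start], y[event.start], basal)
    else:
        onset = float(t[0])

    # left half-max crossing
    left = None
    for i in range(peak, 0, -1):
        if y[i - 1] <= half <= y[i]:
            left = _cross_time(t[i - 1], y[i - 1], t[i], y[i], half)
            break
    # right half-max crossing
    right = None
    for i in range(peak, len(y) - 1):
        if y[i + 1] <= half <= y[i]:
            right = _cross_time(t[i], y[i], t[i + 1], y[i + 1], half)
            break
    partial = left is None or right is None
    duration = None if partial else float(right - left)
    amount = None if partial else amplitude * duration
    return Transient(
        onset_time=float(onset),
        peak_time=float(t[peak]),
        amplitude=amplitude,
        duration=duration,
        amount=amount,
        partial=partial,
    )


def quantify_transients(
    trace: FluorescenceTrace, basal: float = 1.0
) -> list[Transient]:
    """Detect and characterize all transients on a corrected trace."""
    return [
        characterize_transient(trace, ev, basal)
        for ev in detect_transients(trace, basal)
    ]


def measure_series_amplitudes(
    trace: FluorescenceTrace,
    stimulation_onsets: Sequence[float],
    basal: float = 1.0,
) -> list[float]:
    """Per-stimulation response amplitudes for repeated stimulations.

    Consecutive transients at short recovery times overlap without the
    trace returning to basal, so whole-excursion detection would merge
    them; instead the amplitude of stimulation i is the maximum increase
    over basal between its onset and the next stimulation's onset (or
    the end of the recording), mirroring how overlaid force/fluorescence
    records are read out per indentation.
    """
    onsets = list(stimulation_onsets)
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise PreconditionError("stimulation onsets must be strictly increasing")
    amps = []
    bounds = onsets[1:] + [float(trace.time[-1]) + 1.0]
    for t0, t1 in zip(onsets, bounds):
        window = (trace.time >= t0) & (trace.time < t1)
        if not window.any():
            raise PreconditionError(
                f"no frames between stimulation onsets {t0:.3f} and {t1:.3f} s"
            )
        amps.append(float(trace.intensity[window].max() - basal))
    return amps


def flag_spontaneous(
    trace: FluorescenceTrace,
    pre_stimulus_window: tuple[float, float],
    basal: float = 1.0,
    min_duration: float = 0.0,
) -> bool:
    """True iff any supra-threshold (> 4 x noise, strict) excursion peaks
    inside the pre-stimulus window.  Flagged cells are excluded from the
    downstream statistics.  ``min_duration`` > 0 additionally requires a
    measurable FWHM of at least that many seconds, ignoring single-frame
    noise spikes."""
    t0, t1 = pre_stimulus_window
    if t0 < trace.time[0] - 1e-9 or t1 > trace.time[-1] + 1e-9 or t1 <= t0:
        raise GeometryError("pre-stimulus window outside the recording")
    for ev in detect_transients(trace, basal):
        if t0 <= trace.time[ev.peak] <= t1:
            if min_duration > 0:
                tr = characterize_transient(trace, ev, basal)
                if tr.duration is None or tr.duration < min_duration:
                    continue
            return True
    return False
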