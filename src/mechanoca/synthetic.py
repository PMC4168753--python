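"""Synthetic force curves, fluorescence traces and image stacks.

Generates data with the statistical structure the analysis assumes,
calibrated by default to the study conditions of the mechanostimulation
experiments this package analyses:

* low-load indentations peak near 400 nN with no rupture; high-load
  indentations peak near 2800 nN with a single membrane-rupture force
  drop at a force drawn from N(672, 100) nN (C2C12 preset) or
  N(516, 200) nN (primary-osteoblast preset), truncated at 100 nN;
* fluorescence frames arrive every 345 +/- 10 ms;
* local calcium transients start at probe contact, reach their maximum at
  maximum deflection, and have FWHM = 0.98 x contact_time + 0.60 s;
* consecutive local response amplitudes decay linearly in time at a rate
  alpha(rt) = a exp(-rt / tau) + c of the recovery time rt, with
  tau = 2.0 s, so responsiveness recovers exponentially;
* global (micro-injury) transients are delayed past probe release,
  independent of contact time, and suppressed within a 30 s refractory
  period; the membrane micro-injury seals within ~50 s;
* per-condition responder probabilities emulate control, Ca2+-free,
  Gd3+, PLC-inhibitor (Et-18-OCH3) and vehicle experiments.

Every generator returns machine-readable ground truth alongside the data
and is bit-deterministic under a fixed seed.

Transient pulse shape
---------------------
The pulse is piecewise linear: a rise from 0 at onset to the amplitude A
at the peak, a gentle shoulder declining 3% over ~0.4 s (so the sampled
maximum sits on a near-flat top rather than a cusp), then a linear decay
to zero whose length is chosen so the full width at half maximum equals
the target exactly.  FWHM, not shape, is the calibrated quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .calcium import FluorescenceTrace, ImageStack, RAW
from .errors import ConfigError, GeometryError, ScheduleError
from .force_curves import ForceCurve, ProbeMeta, HIGH_LOAD, LOW_LOAD

DEFAULT_SEED = 20140711


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class CurveConfig:
    """Force-curve generator parameters (units in field names' comments)."""

    speed: float = 20.0                 # um/s piezo speed
    dwell: float = 0.0                  # s at maximum extension
    contact_z: float = 2.0              # um, true contact point
    pre_contact_travel: float = 1.0     # um of free approach before contact
    cell_stiffness_slope: float = 400.0 # nN/um post-contact force slope
    max_force: float = 400.0            # nN target for low-load curves
    high_load_max_force: float = 2800.0 # nN target for high-load curves
    rupture_force_mean: float = 672.0   # nN (C2C12 default)
    rupture_force_sd: float = 100.0     # nN
    rupture_force_min: float = 100.0    # nN truncation floor
    rupture_drop_frac: float = 0.45     # fractional force drop at rupture
    force_noise_sd: float = 3.0         # nN additive Gaussian noise
    sample_rate: float = 1000.0         # Hz
    spring_constant: float = 39.0       # N/m
    retract_force_scale: float = 0.6    # retract force / approach force

    def __post_init__(self):
        for name in ("speed", "cell_stiffness_slope", "sample_rate",
                     "spring_constant", "rupture_force_sd", "force_noise_sd",
                     "dwell"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.retract_force_scale <= 1:
            raise ConfigError("retract_force_scale must be in (0, 1]")


@dataclass
class LocalTransientConfig:
    duration_slope: float = 0.98        # s per s of contact time
    duration_intercept: float = 0.60    # s
    amplitude: float = 1.0              # first-response relative amplitude


@dataclass
class GlobalTransientConfig:
    peak_delay_after_release: float = 2.0  # s from probe release to peak
    duration: float = 10.0                 # s FWHM
    amplitude: float = 2.0                 # median relative amplitude
    amplitude_logsd: float = 0.25          # log-normal spread (stand-in)
    seal_time: float = 50.0                # s for the micro-injury to seal
    refractory: float = 30.0               # s without re-response


@dataclass
class TraceConfig:
    frame_interval: float = 0.345       # s
    frame_jitter_sd: float = 0.010      # s
    baseline: float = 100.0             # a.u. basal fluorescence
    bleach_rate: float = 0.005          # 1/s photobleaching
    reflection_gain: float = 0.1        # a.u. per nm cantilever deflection
    noise_sd: float = 0.02              # relative to baseline
    pre_pad: float = 10.0               # s of recording before first contact
    post_pad: float = 15.0              # s after the last release
    shoulder: float = 0.4               # s near-flat pulse top
    shoulder_drop: float = 0.03         # fractional decline over the shoulder
    recovery_tau: float = 2.0           # s, exponential recovery constant
    recovery_a: float = -0.06           # s^-1, decay rate at zero recovery
    recovery_c: float = 0.0             # s^-1, decay rate asymptote
    amplitude_floor: float = 0.05       # relative floor for decayed responses
    local: LocalTransientConfig = field(default_factory=LocalTransientConfig)
    global_response: GlobalTransientConfig = field(
        default_factory=GlobalTransientConfig
    )

    def __post_init__(self):
        for name in ("frame_interval", "baseline"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("frame_jitter_sd", "bleach_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class ConditionPreset:
    """Responder probabilities and response scaling for one condition."""

    p_local: float = 0.8
    p_global: float = 0.9
    amount_scale: float = 1.0

    def __post_init__(self):
        if not (0 <= self.p_local <= 1 and 0 <= self.p_global <= 1):
            raise ConfigError("responder probabilities must lie in [0, 1]")


@dataclass
class PopulationConfig:
    n_cells: int = 20                   # per condition
    conditions: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDITIONS)
    )


@dataclass
class GeneratorConfig:
    seed: int = DEFAULT_SEED
    curve: CurveConfig = field(default_factory=CurveConfig)
    trace: TraceConfig = field(default_factory=TraceConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)


#: Ca2+-free and Gd3+ abolish both local and global responses; the PLC
#: inhibitor Et-18-OCH3 leaves responder fractions unchanged but reduces
#: the amount of Ca2+ released in global responses; vehicle matches control.
DEFAULT_CONDITIONS = {
    "control": ConditionPreset(0.8, 0.9, 1.0),
    "calcium_free": ConditionPreset(0.0, 0.0, 1.0),
    "gadolinium": ConditionPreset(0.0, 0.0, 1.0),
    "et18": ConditionPreset(0.8, 0.9, 0.4),
    "vehicle": ConditionPreset(0.8, 0.9, 1.0),
}


def _update_dataclass(obj, updates: dict):
    for key, value in updates.items():
        if not hasattr(obj, key):
            raise ConfigError(f"unknown config field {key!r} on {type(obj).__name__}")
        current = getattr(obj, key)
        if hasattr(current, "__dataclass_fields__") and isinstance(value, dict):
            _update_dataclass(current, value)
        elif key == "conditions" and isinstance(value, dict):
            obj.conditions = {
                name: ConditionPreset(**v) if isinstance(v, dict) else v
                for name, v in value.items()
            }
        else:
            setattr(obj, key, value)
    return obj


def config_from_dict(d: dict) -> GeneratorConfig:
    """Build a GeneratorConfig by overriding defaults with a nested dict."""
    return _update_dataclass(GeneratorConfig(), dict(d))


def load_preset(name: str) -> GeneratorConfig:
    """Load a named preset config shipped with the package."""
    import importlib.resources as resources

    import yaml

    ref = resources.files("mechanoca").joinpath(f"presets/{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise ConfigError(f"unknown preset {name!r}") from exc
    data = yaml.safe_load(text) or {}
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# Force curves


def _truncated_normal(rng, mean: float, sd: float, lower: float) -> float:
    if sd == 0:
        return max(mean, lower)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= lower:
            return float(v)
    return lower


def gen_force_curve(
    cfg: CurveConfig, load_class: str, rng: np.random.Generator
) -> tuple[ForceCurve, dict]:
    """One synthetic approach-dwell-retract indentation plus ground truth.

    The approach force is zero until the contact point, then rises at the
    cell stiffness slope; high-load curves insert a single force drop at
    a rupture force drawn from the configured truncated normal law.  The
    retract force is a scaled-down copy of the (continuous) loading line,
    so retraction never exceeds approach and the hysteresis area is
    positive.  Gaussian force noise is added through the deflection.
    """
    if load_class not in (LOW_LOAD, HIGH_LOAD):
        raise ConfigError(f"unknown load_class {load_class!r}")
    slope = cfg.cell_stiffness_slope
    cz = cfg.contact_z
    dt = 1.0 / cfg.sample_rate
    dz = cfg.speed * dt  # z spacing of approach/retract samples
    z_start = max(0.0, cz - cfg.pre_contact_travel)

    rupture_force = None
    if load_class == HIGH_LOAD:
        if cfg.high_load_max_force <= cfg.rupture_force_mean:
            raise ConfigError(
                "high_load_max_force must exceed rupture_force_mean"
            )
        target = cfg.high_load_max_force
        drawn = _truncated_normal(
            rng, cfg.rupture_force_mean, cfg.rupture_force_sd, cfg.rupture_force_min
        )
        # snap the rupture to the sample grid so the recorded pre-drop
        # force is exactly attained by one sample (no half-sample bias)
        k_rupture = int(round((cz + drawn / slope - z_start) / dz))
        z_rupture = z_start + k_rupture * dz
        rupture_force = slope * (z_rupture - cz)
        drop = cfg.rupture_drop_frac * rupture_force
        z_max_target = z_rupture + (target - (rupture_force - drop)) / slope
    else:
        target = cfg.max_force
        drop = 0.0
        z_rupture = None
        z_max_target = cz + target / slope

    n_app = max(2, int(math.ceil((z_max_target - z_start) / dz - 1e-9)))
    z_max = z_start + n_app * dz
    t_app = n_app * dt
    n_dwell = int(round(cfg.dwell / dt))

    def approach_force(z):
        f = np.clip(slope * (z - cz), 0.0, None)
        if z_rupture is not None:
            f = np.where(z > z_rupture + 0.5 * dz, f - drop, f)
        return f

    time_app = np.linspace(0.0, t_app, n_app + 1)
    z_app = z_start + dz * np.arange(n_app + 1)
    f_app = approach_force(z_app)

    t0 = t_app
    if n_dwell > 0:
        time_dw = t0 + np.arange(1, n_dwell + 1) * (cfg.dwell / n_dwell)
        z_dw = np.full(n_dwell, z_max)
        f_dw = np.full(n_dwell, f_app[-1])
        t0 = time_dw[-1]
    else:
        time_dw = np.empty(0)
        z_dw = np.empty(0)
        f_dw = np.empty(0)

    time_ret = t0 + np.linspace(0.0, t_app, n_app + 1)[1:]
    z_ret = z_max - dz * np.arange(1, n_app + 1)
    # unloading line from (z_max, max force) down to zero at the contact
    # point, scaled; clipped below the approach so retraction never
    # exceeds it and the hysteresis area is non-negative
    ret_slope = f_app[-1] / (z_max - cz)
    f_ret = cfg.retract_force_scale * np.clip(ret_slope * (z_ret - cz), 0.0, None)
    f_ret = np.minimum(f_ret, approach_force(z_ret))

    time = np.concatenate([time_app, time_dw, time_ret])
    z = np.concatenate([z_app, z_dw, z_ret])
    force = np.concatenate([f_app, f_dw, f_ret])
    deflection = force / cfg.spring_constant
    if cfg.force_noise_sd > 0:
        deflection = deflection + rng.normal(
            0.0, cfg.force_noise_sd / cfg.spring_constant, deflection.size
        )

    meta = ProbeMeta(
        spring_constant=cfg.spring_constant,
        indentation_speed=cfg.speed,
        dwell_time=cfg.dwell,
        tip_area_label="1 um^2 etched pyramid (synthetic)",
    )
    curve = ForceCurve(time=time, z=z, deflection=deflection, meta=meta)
    deformation = z_max - cz
    truth = {
        "load_class": load_class,
        "contact_z_um": cz,
        "z_max_um": float(z_max),
        "max_force_nN": float(force.max()),
        "rupture_force_nN": rupture_force,
        "rupture_z_um": z_rupture,
        "force_drop_nN": drop if rupture_force is not None else None,
        "deformation_extent_um": float(deformation),
        "penetration_depth_um": (
            float(z_max - z_rupture) if z_rupture is not None else None
        ),
        "contact_time_s": float(2.0 * deformation / cfg.speed + cfg.dwell),
        "sample_spacing_um": float(dz),
    }
    return curve, truth


# ---------------------------------------------------------------------------
# Stimulation schedules and traces


@dataclass(frozen=True)
class Stimulation:
    """One indentation in a recording: absolute contact onset time,
    total contact time (including dwell) and the dwell portion."""

    onset: float
    contact_time: float
    dwell: float = 0.0

    @property
    def release(self) -> float:
        return self.onset + self.contact_time

    @property
    def rise_time(self) -> float:
        """Time from contact to maximum deflection (end of dwell)."""
        return (self.contact_time - self.dwell) / 2.0 + self.dwell


def make_series_schedule(
    n_stimulations: int,
    contact_time: float,
    recovery_time: float,
    start: float = 10.0,
    dwell: Optional[float] = None,
) -> list[Stimulation]:
    """Evenly spaced consecutive stimulations with a fixed recovery time
    (time off contact) between them."""
    if dwell is None:
        dwell = max(0.0, contact_time - 0.1)
    period = contact_time + recovery_time
    return [
        Stimulation(onset=start + i * period, contact_time=contact_time, dwell=dwell)
        for i in range(n_stimulations)
    ]


def _pulse(
    t: np.ndarray,
    onset: float,
    peak: float,
    amplitude: float,
    fwhm: float,
    shoulder: float,
    shoulder_drop: float,
) -> np.ndarray:
    """Piecewise-linear transient with exact FWHM (see module docstring)."""
    rise = peak - onset
    if rise < 0:
        raise ScheduleError("pulse peak precedes its onset")
    room = fwhm - rise / 2.0
    if room <= 0.05:
        raise ScheduleError(
            f"FWHM {fwhm:.3g} s too short for a rise of {rise:.3g} s"
        )
    s = min(shoulder, max(0.0, room - 0.15))
    level = 1.0 - shoulder_drop
    tail = (room - s) * level / (level - 0.5)
    knots_t = np.array([onset, peak, peak + s, peak + s + tail])
    knots_v = amplitude * np.array([0.0, 1.0, level, 0.0])
    return np.interp(t, knots_t, knots_v, left=0.0, right=0.0)


def _frame_times(cfg: TraceConfig, duration: float, rng) -> np.ndarray:
    # the camera free-runs relative to the stimulation trigger, so the
    # first frame carries a uniform phase offset within one interval
    phase = rng.uniform(0.0, cfg.frame_interval)
    n = int(math.ceil(duration / cfg.frame_interval)) + 2
    steps = rng.normal(cfg.frame_interval, cfg.frame_jitter_sd, n)
    lo, hi = 0.5 * cfg.frame_interval, 1.5 * cfg.frame_interval
    steps = np.clip(steps, lo, hi)
    t = np.concatenate([[phase], phase + np.cumsum(steps)])
    return t[t <= duration]


def _deflection_envelope(
    schedule: list[Stimulation], duration: float, d_max: float, dt: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(0.0, duration + dt, dt)
    d = np.zeros_like(t)
    for stim in schedule:
        half = (stim.contact_time - stim.dwell) / 2.0
        knots_t = [stim.onset, stim.onset + half, stim.release - half, stim.release]
        knots_v = [0.0, d_max, d_max, 0.0]
        d += np.interp(t, knots_t, knots_v, left=0.0, right=0.0)
    return t, d


def _validate_schedule(cfg: TraceConfig, schedule: list[Stimulation]):
    if not schedule:
        raise ScheduleError("schedule must contain >= 1 stimulation")
    onsets = [s.onset for s in schedule]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ScheduleError("stimulation onsets must be strictly increasing")
    for a, b in zip(schedule, schedule[1:]):
        if b.onset < a.release:
            raise ScheduleError("stimulations overlap in time")
    if schedule[0].onset < 5 * cfg.frame_interval:
        raise ScheduleError(
            "first stimulation leaves fewer than 5 baseline frames"
        )


def _clean_signal(
    cfg: TraceConfig,
    schedule: list[Stimulation],
    response_mode: str,
    rng,
    respond: bool,
    amplitude_scale: float,
    frame_times: np.ndarray,
) -> tuple[np.ndarray, list[dict]]:
    """Sum of transient pulses on the frame grid, plus per-pulse truth."""
    s = np.zeros_like(frame_times)
    pulses: list[dict] = []
    if not respond:
        return s, pulses
    if response_mode == "local":
        loc = cfg.local
        first_peak = None
        for i, stim in enumerate(schedule):
            fwhm = loc.duration_slope * stim.contact_time + loc.duration_intercept
            peak = stim.onset + stim.rise_time
            if i == 0:
                amp = loc.amplitude * amplitude_scale
                first_peak = peak
            else:
                rt = stim.onset - schedule[i - 1].release
                alpha = cfg.recovery_a * math.exp(-rt / cfg.recovery_tau) + cfg.recovery_c
                amp = (
                    loc.amplitude
                    * amplitude_scale
                    * max(cfg.amplitude_floor, 1.0 + alpha * (peak - first_peak))
                )
            s += _pulse(
                frame_times, stim.onset, peak, amp, fwhm,
                cfg.shoulder, cfg.shoulder_drop,
            )
            pulses.append(
                {"onset_s": stim.onset, "peak_s": peak, "amplitude": amp,
                 "fwhm_s": fwhm, "mode": "local"}
            )
    elif response_mode == "global":
        glob = cfg.global_response
        last_release = None
        for stim in schedule:
            if last_release is not None and (
                stim.release - last_release
            ) <= glob.refractory:
                continue
            amp = (
                glob.amplitude
                * amplitude_scale
                * math.exp(rng.normal(0.0, glob.amplitude_logsd))
            )
            onset = stim.release
            peak = onset + glob.peak_delay_after_release
            s += _pulse(
                frame_times, onset, peak, amp, glob.duration,
                cfg.shoulder, cfg.shoulder_drop,
            )
            pulses.append(
                {"onset_s": onset, "peak_s": peak, "amplitude": amp,
                 "fwhm_s": glob.duration, "mode": "global"}
            )
            last_release = stim.release
    else:
        raise ConfigError(f"unknown response_mode {response_mode!r}")
    return s, pulses


def gen_trace(
    cfg: TraceConfig,
    schedule: list[Stimulation],
    response_mode: str = "local",
    rng: Optional[np.random.Generator] = None,
    respond: bool = True,
    amplitude_scale: float = 1.0,
    deflection_max_nm: float = 400.0 / 39.0,
    duration: Optional[float] = None,
    deflection_series: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> tuple[FluorescenceTrace, dict]:
    """One raw fluorescence trace plus ground truth.

    raw(t) = baseline x exp(-bleach_rate t) x (1 + sum of transients)
             + reflection_gain x deflection(t) + Gaussian noise.

    The reflection artifact follows the cantilever: by default a
    triangular deflection envelope built from the schedule; pass
    ``deflection_series`` (time s, deflection nm; zero outside its span)
    to drive it with an actual recorded deflection instead.
    """
    if rng is None:
        rng = np.random.default_rng(DEFAULT_SEED)
    _validate_schedule(cfg, schedule)
    span = schedule[-1].release + cfg.post_pad
    if duration is not None:
        if schedule[-1].release > duration:
            raise ScheduleError("schedule extends beyond the recording span")
        span = duration
    t = _frame_times(cfg, span, rng)
    s, pulses = _clean_signal(
        cfg, schedule, response_mode, rng, respond, amplitude_scale, t
    )
    if deflection_series is not None:
        d_time = np.asarray(deflection_series[0], dtype=float)
        d = np.asarray(deflection_series[1], dtype=float)
    else:
        d_time, d = _deflection_envelope(schedule, span, deflection_max_nm)
    d_frames = np.interp(t, d_time, d, left=0.0, right=0.0)
    raw = (
        cfg.baseline * np.exp(-cfg.bleach_rate * t) * (1.0 + s)
        + cfg.reflection_gain * d_frames
    )
    if cfg.noise_sd > 0:
        raw = raw + rng.normal(0.0, cfg.noise_sd * cfg.baseline, raw.size)
    trace = FluorescenceTrace(
        time=t, intensity=raw, state=RAW,
        provenance=[f"gen_trace(mode={response_mode}, respond={respond})"],
    )
    truth = {
        "response_mode": response_mode,
        "respond": bool(respond) and bool(pulses),
        "pulses": pulses,
        "schedule": [asdict(st) for st in schedule],
        "deflection_time_s": d_time,
        "deflection_nm": d,
        "noise_sd_relative": cfg.noise_sd,
        "bleach_rate": cfg.bleach_rate,
        "reflection_gain": cfg.reflection_gain,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# Image stacks


def gen_image_stack(
    cfg: TraceConfig,
    response_mode: str = "local",
    rng: Optional[np.random.Generator] = None,
    shape: tuple[int, int] = (48, 48),
    pixel_size: float = 0.5,
    schedule: Optional[list[Stimulation]] = None,
    indentation_point: Optional[tuple[float, float]] = None,
    spot_sigma_um: float = 0.6,
    cell_level: float = 100.0,
    background_level: float = 20.0,
    pixel_noise_sd: float = 4.0,
    flicker_sd: float = 0.01,
) -> tuple[ImageStack, dict]:
    """A small fluorescence movie of one cell plus ground truth.

    Local mode adds a Gaussian bright spot at the indentation point on a
    dim elliptical cell mask; global mode raises the whole cell mask.
    Per-frame multiplicative flicker emulates illumination fluctuations,
    so whole-cell noise does not average away with pixel count.
    """
    if rng is None:
        rng = np.random.default_rng(DEFAULT_SEED)
    if schedule is None:
        schedule = [Stimulation(onset=cfg.pre_pad, contact_time=1.0, dwell=0.9)]
    nrow, ncol = shape
    r0, c0 = (nrow - 1) / 2.0, (ncol - 1) / 2.0
    a, b = 0.38 * nrow, 0.28 * ncol  # cell semi-axes, px
    rows = np.arange(nrow)[:, None]
    cols = np.arange(ncol)[None, :]
    cell_mask = ((rows - r0) / a) ** 2 + ((cols - c0) / b) ** 2 <= 1.0
    if indentation_point is None:
        indentation_point = (r0 - a / 2.0, c0)
    pr, pc = indentation_point
    inside = ((pr - r0) / a) ** 2 + ((pc - c0) / b) ** 2 <= 1.0
    if not inside:
        raise GeometryError("indentation point lies outside the cell mask")

    _validate_schedule(cfg, schedule)
    span = schedule[-1].release + cfg.post_pad
    t = _frame_times(cfg, span, rng)
    s, pulses = _clean_signal(cfg, schedule, response_mode, rng, True, 1.0, t)

    sigma_px = spot_sigma_um / pixel_size
    spot = np.exp(-(((rows - pr) ** 2 + (cols - pc) ** 2) / (2 * sigma_px**2)))
    base = np.where(cell_mask, cell_level, background_level)
    frames = np.empty((t.size, nrow, ncol))
    for i in range(t.size):
        if response_mode == "local":
            img = base * (1.0 + s[i] * spot * cell_mask)
        else:
            img = base * (1.0 + 0.8 * s[i] * cell_mask)
        flicker = 1.0 + rng.normal(0.0, flicker_sd)
        frames[i] = img * flicker + rng.normal(0.0, pixel_noise_sd, (nrow, ncol))
    stack = ImageStack(frames=frames, frame_times=t, pixel_size=pixel_size)
    truth = {
        "response_mode": response_mode,
        "pulses": pulses,
        "indentation_point_px": (float(pr), float(pc)),
        "cell_center_px": (float(r0), float(c0)),
        "cell_axes_um": (2 * a * pixel_size, 2 * b * pixel_size),
        "schedule": [asdict(st) for st in schedule],
    }
    return stack, truth


# ---------------------------------------------------------------------------
# Multi-cell experiments


def gen_experiment(
    config: GeneratorConfig,
    outdir: str | Path,
    load_class: str = HIGH_LOAD,
    conditions: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> Path:
    """Generate a multi-cell, multi-condition experiment on disk.

    For each cell: one force curve of the requested load class, and one
    fluorescence trace whose response is drawn Bernoulli(responder
    probability of the condition).  Writes one curve CSV + meta JSON +
    trace CSV + schedule JSON + ground-truth JSON per cell and a manifest
    CSV; returns the manifest path.
    """
    from . import fileio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if conditions is None:
        conditions = config.population.conditions
    mode = "global" if load_class == HIGH_LOAD else "local"
    rows = []
    for condition, preset in conditions.items():
        if not isinstance(preset, ConditionPreset):
            preset = ConditionPreset(**preset)
        p = preset.p_global if mode == "global" else preset.p_local
        scale = preset.amount_scale if mode == "global" else 1.0
        for i in range(config.population.n_cells):
            cell_id = f"{condition}_{i:03d}"
            curve, ctruth = gen_force_curve(config.curve, load_class, rng)
            schedule = [
                Stimulation(
                    onset=config.trace.pre_pad,
                    contact_time=ctruth["contact_time_s"],
                    dwell=config.curve.dwell,
                )
            ]
            responded = bool(rng.random() < p)
            # drive the reflection artifact with the actual cantilever
            # deflection of this cell's curve, contact aligned to onset
            t_contact = (
                min(config.curve.pre_contact_travel, config.curve.contact_z)
                / config.curve.speed
            )
            d_series = (
                curve.time - t_contact + schedule[0].onset,
                curve.deflection,
            )
            trace, ttruth = gen_trace(
                config.trace,
                schedule,
                response_mode=mode,
                rng=rng,
                respond=responded,
                amplitude_scale=scale,
                deflection_series=d_series,
            )
            paths = {
                "curve_path": outdir / f"{cell_id}_curve.csv",
                "meta_path": outdir / f"{cell_id}_meta.json",
                "trace_or_stack_path": outdir / f"{cell_id}_trace.csv",
                "schedule_path": outdir / f"{cell_id}_schedule.json",
            }
            fileio.write_force_curve(paths["curve_path"], paths["meta_path"], curve)
            fileio.write_trace(paths["trace_or_stack_path"], trace)
            fileio.write_schedule(paths["schedule_path"], schedule)
            fileio.write_json(
                outdir / f"{cell_id}_truth.json",
                {
                    "curve": ctruth,
                    "trace": {
                        k: v
                        for k, v in ttruth.items()
                        if not isinstance(v, np.ndarray)
                    },
                    "responded": responded,
                },
            )
            rows.append(
                {
                    "cell_id": cell_id,
                    "condition": condition,
                    **{k: str(v) for k, v in paths.items()},
                    "roi_path": "",
                }
            )
    manifest = outdir / "manifest.csv"
    fileio.write_manifest(manifest, rows)
    return manifest
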