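"""AFM force-distance curve analysis.

One indentation cycle (approach - dwell - retract) is recorded as piezo
extension ``z`` (um, positive toward the cell) and cantilever deflection
``d`` (nm) versus time (s).  Force follows Hooke's law, F = k * d, with the
cantilever spring constant k in N/m, so forces come out directly in nN
(N/m x nm = nN).  From the force-extension record this module extracts the
mechanical anatomy of a stimulation:

* the contact point, where force first rises persistently above the
  pre-contact baseline;
* membrane rupture events, sudden drops in the force required to keep
  extending the piezo (tip penetration of the plasma membrane);
* deformation extent (contact point to maximum piezo extension) and, for
  penetrating indentations, penetration depth (first rupture to maximum
  extension), both in raw piezo-extension units;
* hysteresis energy, the area between approach and retraction curves
  (energy dissipated deforming / penetrating the cell), in fJ = nN*um;
* contact time, the net time the probe spends in contact with the cell,
  including any dwell at maximum extension;
* the load class: ``high_load`` if and only if a rupture occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    InvalidMetadataError,
    MalformedCurveError,
    PreconditionError,
)

APPROACH = "approach"
DWELL = "dwell"
RETRACT = "retract"

LOW_LOAD = "low_load"
HIGH_LOAD = "high_load"


@dataclass(frozen=True)
class ProbeMeta:
    """Cantilever and indentation-control metadata.

    Parameters
    ----------
    spring_constant : float
        Cantilever stiffness k in N/m (> 0).
    indentation_speed : float
        Piezo speed in um/s (> 0).
    dwell_time : float
        Extra time held at maximum piezo extension, s (>= 0).
    tip_area_label : str
        Free-text description of the tip contact area.
    """

    spring_constant: float
    indentation_speed: float
    dwell_time: float = 0.0
    tip_area_label: str = ""

    def __post_init__(self):
        if not np.isfinite(self.spring_constant) or self.spring_constant <= 0:
            raise InvalidMetadataError(
                f"spring_constant must be > 0 N/m, got {self.spring_constant}"
            )
        if not np.isfinite(self.indentation_speed) or self.indentation_speed <= 0:
            raise InvalidMetadataError(
                f"indentation_speed must be > 0 um/s, got {self.indentation_speed}"
            )
        if self.dwell_time < 0:
            raise InvalidMetadataError(
                f"dwell_time must be >= 0 s, got {self.dwell_time}"
            )


@dataclass
class ForceCurve:
    """One indentation's time-resolved piezo extension and deflection.

    ``time`` (s) must be strictly increasing; ``z`` (um) and ``deflection``
    (nm) must have the same length >= 4.
    """

    time: np.ndarray
    z: np.ndarray
    deflection: np.ndarray
    meta: ProbeMeta
    segment_labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        n = len(self.time)
        if not (len(self.z) == len(self.deflection) == n):
            raise MalformedCurveError("time, z and deflection lengths differ")
        if n < 4:
            raise MalformedCurveError(f"curve needs >= 4 samples, got {n}")
        if np.any(np.diff(self.time) <= 0):
            raise MalformedCurveError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def segments(self) -> np.ndarray:
        if self.segment_labels is None:
            self.segment_labels = segment_curve(self.time, self.z)
        return self.segment_labels


@dataclass(frozen=True)
class RuptureEvent:
    """A sudden force drop in the post-contact approach segment.

    ``force_before`` is the local pre-drop force: the membrane rupture
    force.  The post-drop force may be any lower value, so ``force_before
    >= force_drop`` is not required.
    """

    index: int
    z_at_rupture: float
    force_before: float
    force_drop: float


@dataclass
class CurveFeatures:
    """Derived mechanical quantities of one indentation."""

    contact_index: Optional[int]
    contact_z: Optional[float]
    max_force: float
    rupture: Optional[RuptureEvent]
    deformation_extent: Optional[float]
    penetration_depth: Optional[float]
    hysteresis_energy: Optional[float]
    contact_time: Optional[float]
    load_class: str
    ruptures: Sequence[RuptureEvent] = field(default_factory=tuple)


def compute_force(curve: ForceCurve) -> np.ndarray:
    """Convert deflection to force via Hooke's law, F = k * d.

    With k in N/m and d in nm the product is in nN, so no explicit unit
    factor is needed (k = 39 N/m at d = 10 nm gives 390 nN).
    """
    k = curve.meta.spring_constant
    if k <= 0:
        raise InvalidMetadataError(f"spring_constant must be > 0, got {k}")
    return k * curve.deflection


def segment_curve(
    time: np.ndarray, z: np.ndarray, plateau_tol: Optional[float] = None
) -> np.ndarray:
    """Label each sample as approach / dwell / retract.

    The approach runs up to and including the first attainment of maximum
    piezo extension; the dwell is the subsequent contiguous run of samples
    within ``plateau_tol`` of the maximum; the remainder is the retract.
    ``plateau_tol`` defaults to 1e-6 of the z range (effectively exact).
    """
    time = np.asarray(time, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(np.diff(time) <= 0):
        raise MalformedCurveError("time must be strictly increasing")
    n = len(z)
    zmax = z.max()
    if plateau_tol is None:
        zrange = zmax - z.min()
        plateau_tol = 1e-6 * zrange if zrange > 0 else 0.0
    at_max = z >= zmax - plateau_tol
    first = int(np.argmax(at_max))  # first attainment of the plateau
    labels = np.full(n, RETRACT, dtype="<U8")
    labels[: first + 1] = APPROACH
    i = first + 1
    while i < n and at_max[i]:
        labels[i] = DWELL
        i += 1
    return labels


def _approach_slice(curve: ForceCurve) -> slice:
    labels = curve.segments
    idx = np.flatnonzero(labels == APPROACH)
    return slice(0, int(idx[-1]) + 1) if idx.size else slice(0, 0)


def _retract_indices(curve: ForceCurve) -> np.ndarray:
    return np.flatnonzero(curve.segments == RETRACT)


def approach_baseline(
    curve: ForceCurve, force: Optional[np.ndarray] = None, fraction: float = 0.2
) -> tuple[float, float]:
    """Mean and SD of the pre-contact force baseline on the approach.

    The baseline window is the approach prefix before the force first
    rises above 5% of the curve's force range (with a small safety
    margin), so a deep indentation with little free travel does not
    contaminate the estimate; when that prefix is too short to be
    informative (e.g. a contact-free curve, where the 5% level sits
    inside the noise), the first ``fraction`` of approach samples is
    used instead.
    """
    if force is None:
        force = compute_force(curve)
    app = _approach_slice(curve)
    n_app = app.stop - app.start
    if n_app < 10:
        raise MalformedCurveError(
            f"approach segment needs >= 10 samples, got {n_app}"
        )
    f = force[app]
    frange = float(f.max() - f.min())
    end = 0
    if frange > 0:
        coarse = np.flatnonzero(f > f.min() + 0.05 * frange)
        if coarse.size:
            end = int(coarse[0]) - max(5, n_app // 50)
    if end < 10:
        end = max(3, int(round(fraction * n_app)))
    window = f[:end]
    # median/MAD so residual contamination by the earliest post-contact
    # samples cannot inflate the threshold
    med = float(np.median(window))
    sd = 1.4826 * float(np.median(np.abs(window - med)))
    return med, sd


def detect_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.2,
    threshold_sd: float = 3.0,
    persistence: int = 3,
) -> Optional[tuple[int, float]]:
    """Locate the contact point on the approach segment.

    The pre-contact baseline is the mean force over the first
    ``baseline_fraction`` of approach samples; contact requires force to
    exceed baseline + ``threshold_sd`` x baseline SD for ``persistence``
    consecutive samples.  The returned index is the last at-baseline
    sample before that persistent rise (the changepoint), so on a
    noiseless piecewise-linear curve the contact z is exact.

    Returns ``(contact_index, contact_z)``, or ``None`` when no sample
    satisfies the criterion (a no-contact result, not an error).
    """
    force = compute_force(curve)
    baseline, sd = approach_baseline(curve, force, baseline_fraction)
    threshold = baseline + threshold_sd * sd
    app = _approach_slice(curve)
    above = force[app] > threshold
    if persistence > 1:
        # run of `persistence` consecutive exceedances starting at i
        kernel = np.ones(persistence, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == persistence
        starts = np.flatnonzero(runs)
    else:
        starts = np.flatnonzero(above)
    if starts.size == 0:
        return None
    onset = int(starts[0])
    contact_index = max(onset - 1, 0)
    return contact_index, float(curve.z[contact_index])


def detect_rupture_events(
    curve: ForceCurve,
    contact_index: Optional[int],
    sd_multiple: float = 5.0,
    relative: float = 0.01,
) -> list[RuptureEvent]:
    """Detect membrane rupture events on the post-contact approach segment.

    A rupture is a force decrease between consecutive local extrema whose
    magnitude exceeds ``max(sd_multiple x baseline SD, relative x local
    pre-drop force)``.  Events are returned largest drop first; among
    equal drops the earliest wins.  ``force_before`` is the local pre-drop
    force (the membrane rupture force).
    """
    if contact_index is None:
        raise PreconditionError("rupture detection requires a detected contact")
    force = compute_force(curve)
    _, sd = approach_baseline(curve, force)
    app = _approach_slice(curve)
    f = force[contact_index : app.stop]
    if f.size < 3:
        return []
    # local extrema via sign changes of the first difference; plateaus break
    # ties toward the earliest sample
    df = np.diff(f)
    sign = np.sign(df)
    # propagate the previous nonzero sign through flat runs
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turning = np.flatnonzero(np.diff(sign) != 0) + 1
    # candidate maxima: turning points where slope goes + -> -
    events: list[RuptureEvent] = []
    for t in turning:
        if sign[t - 1] > 0 and sign[t] < 0:
            # falling stretch from local max t to the next turning point (or end)
            later = turning[turning > t]
            trough = int(later[0]) if later.size else f.size - 1
            drop = float(f[t] - f[trough])
            threshold = max(sd_multiple * sd, relative * float(f[t]))
            if drop > threshold:
                idx = contact_index + int(t)
                events.append(
                    RuptureEvent(
                        index=idx,
                        z_at_rupture=float(curve.z[idx]),
                        force_before=float(f[t]),
                        force_drop=drop,
                    )
                )
    events.sort(key=lambda e: (-e.force_drop, e.index))
    return events


def classify_load(rupture_events: Sequence[RuptureEvent]) -> str:
    """``high_load`` iff at least one rupture event is present."""
    return HIGH_LOAD if len(rupture_events) > 0 else LOW_LOAD


def measure_deformation_extent(
    curve: ForceCurve, contact_z: Optional[float]
) -> Optional[float]:
    """Distance between the contact point and the maximum piezo extension, um."""
    if contact_z is None:
        return None
    return float(curve.z.max() - contact_z)


def measure_penetration_depth(
    curve: ForceCurve, rupture_events: Sequence[RuptureEvent]
) -> Optional[float]:
    """Piezo extension from the first (earliest) rupture to maximum z, um.

    Absent for low-load (no-rupture) curves.
    """
    if not rupture_events:
        return None
    first = min(rupture_events, key=lambda e: e.index)
    return float(curve.z.max() - first.z_at_rupture)


def measure_hysteresis_energy(
    curve: ForceCurve, contact_index: Optional[int], contact_z: Optional[float]
) -> float:
    """Area between approach and retraction force curves over the contact
    region, in fJ (1 fJ = 1 nN*um).

    Approach and retract are interpolated onto their merged z grid within
    [contact_z, max z] and the difference is integrated by the trapezoid
    rule, so the result is exact for piecewise-linear curves and invariant
    under time reparameterization of the same (z, F) path.
    """
    if contact_index is None:
        raise PreconditionError("hysteresis energy requires a detected contact")
    force = compute_force(curve)
    app = _approach_slice(curve)
    ret = _retract_indices(curve)
    z_app = curve.z[contact_index : app.stop]
    f_app = force[contact_index : app.stop]
    if ret.size < 2 or z_app.size < 2:
        raise MalformedCurveError("approach/retract segments too short to integrate")
    # the retraction path starts at the apex sample (last dwell/approach
    # sample), otherwise the interval between z_max and the first retract
    # sample would be extrapolated
    ret_path = np.concatenate([[ret[0] - 1], ret]) if ret[0] > 0 else ret
    z_ret = curve.z[ret_path][::-1]  # retract z is non-increasing; flip
    f_ret = force[ret_path][::-1]
    zmax = float(curve.z.max())
    z0 = float(contact_z if contact_z is not None else z_app[0])
    grid = np.union1d(z_app, z_ret)
    grid = grid[(grid >= z0) & (grid <= zmax)]
    if grid.size < 2:
        raise MalformedCurveError("contact region too small to integrate")
    fa = np.interp(grid, z_app, f_app)
    fr = np.interp(grid, z_ret, f_ret)
    return float(np.trapezoid(fa - fr, grid))


def measure_contact_time(
    curve: ForceCurve,
    contact_index: Optional[int],
    end_threshold_sd: float = 3.0,
    persistence: int = 3,
) -> Optional[float]:
    """Net time the probe spends in contact with the cell, s.

    Runs from the contact sample on approach to the end of contact on
    retract, and therefore includes the dwell at maximum extension.  The
    end of contact mirrors the contact-point rule on the time-reversed
    retract segment: the changepoint before force (scanning backwards
    from the free end) persistently exceeds baseline +
    ``end_threshold_sd`` x baseline SD.  A single "last sample above
    baseline" rule would latch onto noise excursions anywhere in the free
    retract tail; the persistent-exceedance changepoint does not.
    """
    if contact_index is None:
        return None
    force = compute_force(curve)
    baseline, sd = approach_baseline(curve, force)
    ret = _retract_indices(curve)
    if ret.size == 0:
        return float(curve.time[-1] - curve.time[contact_index])
    f_rev = force[ret][::-1]  # free end first
    above = f_rev > baseline + end_threshold_sd * sd
    if persistence > 1:
        kernel = np.ones(persistence, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == persistence
        starts = np.flatnonzero(runs)
    else:
        starts = np.flatnonzero(above)
    if starts.size:
        end_index = int(ret[ret.size - 1 - int(starts[0])])
    else:
        end_index = int(ret[0])  # contact ended by the start of retract
    return float(curve.time[end_index] - curve.time[contact_index])


def analyze_curve(curve: ForceCurve) -> CurveFeatures:
    """Run the full force-curve pipeline and collect all derived features."""
    force = compute_force(curve)
    contact = detect_contact_point(curve)
    if contact is None:
        return CurveFeatures(
            contact_index=None,
            contact_z=None,
            max_force=float(force.max()),
            rupture=None,
            deformation_extent=None,
            penetration_depth=None,
            hysteresis_energy=None,
            contact_time=None,
            load_class=LOW_LOAD,
        )
    contact_index, contact_z = contact
    ruptures = detect_rupture_events(curve, contact_index)
    first_rupture = min(ruptures, key=lambda e: e.index) if ruptures else None
    return CurveFeatures(
        contact_index=contact_index,
        contact_z=contact_z,
        max_force=float(force.max()),
        rupture=first_rupture,
        deformation_extent=measure_deformation_extent(curve, contact_z),
        penetration_depth=measure_penetration_depth(curve, ruptures),
        hysteresis_energy=measure_hysteresis_energy(curve, contact_index, contact_z),
        contact_time=measure_contact_time(curve, contact_index),
        load_class=classify_load(ruptures),
        ruptures=tuple(ruptures),
    )
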