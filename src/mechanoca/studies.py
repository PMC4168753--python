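"""End-to-end study replications on synthetic data.

Each function generates a paper-calibrated synthetic cohort, runs the
full analysis pipeline on it, and returns the study-level statistic the
experiments report:

* the duration-vs-contact-time law (slope ~0.98, intercept ~0.60 s),
* the exponential recovery time constant of the amplitude decay rate
  (tau ~2 s),
* the mean membrane rupture force per cell-line preset
  (672 nN for C2C12-derived, 516 nN for primary osteoblasts),
* the per-condition responder-fraction pattern under channel blockers
  and the PLC inhibitor.

These are the same routines the acceptance checks run; they are exposed
here so scripts and notebooks can reproduce the numbers directly.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from . import calcium, pipeline, stats, synthetic
from .force_curves import HIGH_LOAD, LOW_LOAD, analyze_curve

#: contact-time levels (s) probed by the low-load stimulation protocol
CONTACT_TIME_GRID = (0.1, 0.2, 1.0, 1.1, 1.2, 2.0)
#: recovery times (s) probed by the repeated-stimulation protocol
RECOVERY_TIME_GRID = (0.9, 1.9, 4.8, 5.8, 9.0, 10.0)


def duration_vs_contact_study(
    rng: np.random.Generator,
    n_per_level: int = 34,
    grid: Sequence[float] = CONTACT_TIME_GRID,
    config: Optional[synthetic.GeneratorConfig] = None,
) -> tuple[stats.DurationFit, list[tuple[float, float]]]:
    """Low-load cohort: measured FWHM duration regressed on measured
    contact time.

    Each stimulation is one synthetic cell: a low-load force curve whose
    dwell sets the target contact time, and a fluorescence trace whose
    transient follows the generator's duration law.  Both are analyzed
    by the full pipeline (curve features; trace correction, detection,
    FWHM), and the regression uses only measured quantities.
    """
    cfg = config or synthetic.GeneratorConfig()
    points = []
    for _ in range(n_per_level):
        for target in grid:
            curve_cfg = replace(cfg.curve, dwell=max(0.0, target - 0.1))
            curve, ctruth = synthetic.gen_force_curve(curve_cfg, LOW_LOAD, rng)
            schedule = [
                synthetic.Stimulation(
                    onset=cfg.trace.pre_pad,
                    contact_time=ctruth["contact_time_s"],
                    dwell=curve_cfg.dwell,
                )
            ]
            trace, _ = synthetic.gen_trace(
                cfg.trace,
                schedule,
                "local",
                rng,
                deflection_max_nm=ctruth["max_force_nN"] / curve_cfg.spring_constant,
            )
            try:
                record = pipeline.analyze_cell(curve, trace, schedule)
            except Exception:
                continue
            if not record["transients"] or record["features"]["contact_time_s"] is None:
                continue
            principal = max(record["transients"], key=lambda t: t["amplitude"])
            points.append(
                (record["features"]["contact_time_s"], principal["duration"])
            )
    fit = stats.fit_duration_vs_contact(*zip(*points))
    return fit, points


def recovery_study(
    rng: np.random.Generator,
    n_replicates: int = 20,
    recovery_times: Sequence[float] = RECOVERY_TIME_GRID,
    series_per_time: int = 2,
    n_stimulations: int = 5,
    contact_time: float = 1.0,
    config: Optional[synthetic.GeneratorConfig] = None,
) -> tuple[np.ndarray, list[stats.RecoveryFit]]:
    """Repeated-stimulation series: per-series amplitude decay rates
    fitted with the exponential a*exp(-x b)+c over recovery time.

    Returns the recovered time constants tau = 1/b, one per replicate,
    and the full fits.
    """
    cfg = config or synthetic.GeneratorConfig()
    taus, fits = [], []
    for _ in range(n_replicates):
        xs, alphas = [], []
        for rt in recovery_times:
            for _ in range(series_per_time):
                schedule = synthetic.make_series_schedule(
                    n_stimulations, contact_time, rt, start=cfg.trace.pre_pad
                )
                trace, _ = synthetic.gen_trace(cfg.trace, schedule, "local", rng)
                corrected = calcium.correct_bleaching(
                    calcium.normalize_baseline(trace)
                )
                onsets = [s.onset for s in schedule]
                amplitudes = calcium.measure_series_amplitudes(corrected, onsets)
                fit = stats.decay_rate_from_amplitudes(onsets, amplitudes)
                xs.append(rt)
                alphas.append(fit.alpha)
        fit = stats.fit_recovery_exponential(xs, alphas)
        taus.append(fit.tau)
        fits.append(fit)
    return np.asarray(taus), fits


def rupture_force_study(
    rng: np.random.Generator,
    preset: str = "c2c12",
    n_curves: int = 200,
    config: Optional[synthetic.GeneratorConfig] = None,
) -> tuple[float, list[float]]:
    """High-load cohort: mean membrane rupture force detected by the
    contact + rupture pipeline over ``n_curves`` synthetic curves."""
    cfg = config or synthetic.load_preset(preset)
    detected = []
    for _ in range(n_curves):
        curve, _ = synthetic.gen_force_curve(cfg.curve, HIGH_LOAD, rng)
        features = analyze_curve(curve)
        if features.rupture is not None:
            detected.append(features.rupture.force_before)
    if not detected:
        raise RuntimeError("no rupture events detected in the cohort")
    return float(np.mean(detected)), detected


def condition_experiment(
    outdir,
    config: Optional[synthetic.GeneratorConfig] = None,
    conditions: Sequence[str] = ("control", "calcium_free", "gadolinium", "et18"),
    load_class: str = HIGH_LOAD,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Generate a multi-condition experiment on disk and run the full
    manifest-driven pipeline; returns the results bundle."""
    cfg = config or synthetic.GeneratorConfig()
    chosen = {name: cfg.population.conditions[name] for name in conditions}
    manifest = synthetic.gen_experiment(
        cfg, outdir, load_class=load_class, conditions=chosen, rng=rng
    )
    return pipeline.run_pipeline(manifest)
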