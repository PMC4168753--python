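"""Manifest-driven end-to-end analysis.

Each manifest row names one cell: a force curve (CSV + meta JSON), a
fluorescence trace (CSV) or image stack (TIFF + ROI JSON), and a
stimulation schedule (JSON).  For every cell the pipeline extracts curve
features, applies the trace-correction protocol (normalize to the basal
window, divide out photobleaching, subtract the cantilever-reflection
component), estimates noise, excludes cells with spontaneous
pre-stimulus activity, detects and quantifies transients, and finally
aggregates per-condition responder fractions and condition comparisons
(Fisher exact on fractions, Student's t on amounts).

Every exclusion and correction is recorded in the structured log; given
the same inputs the result bundle is byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import calcium, fileio, force_curves, stats
from .errors import MechanoCaError, PipelineError

logger = logging.getLogger("mechanoca")

SCHEMA_VERSION = 1


def _full_span_deflection(curve, features, schedule, trace):
    """Place the curve's deflection record at each scheduled contact and
    pad with zeros so the record covers the whole trace."""
    if features.contact_index is None:
        t = np.array([trace.time[0] - 1.0, trace.time[-1] + 1.0])
        return t, np.zeros(2)
    t_contact = curve.time[features.contact_index]
    pieces_t = [np.array([trace.time[0] - 1.0])]
    pieces_d = [np.array([0.0])]
    last = trace.time[0] - 1.0
    for stim in schedule:
        shifted = curve.time - t_contact + stim.onset
        keep = shifted > last + 1e-9
        pieces_t.append(shifted[keep])
        pieces_d.append(curve.deflection[keep])
        if shifted.size:
            last = shifted[keep][-1] if keep.any() else last
    pieces_t.append(np.array([trace.time[-1] + 1.0]))
    pieces_d.append(np.array([0.0]))
    return np.concatenate(pieces_t), np.concatenate(pieces_d)


def analyze_cell(
    curve: force_curves.ForceCurve,
    trace: calcium.FluorescenceTrace,
    schedule,
    log: Optional[list] = None,
    min_response_duration: float = 0.4,
) -> dict:
    """Run the per-cell pipeline; returns a JSON-serializable record.

    Photobleaching is fitted on a quiescent set grown from the
    pre-stimulus frames, which the schedule guarantees to be quiescent; a
    stimulated cell can spend most of the recording inside a transient,
    where a blind quiescent search is unreliable, while the pre-stimulus
    window alone is too short to pin the decay over the whole recording.  A transient counts as a response only when it peaks
    after the first contact and its FWHM is measurable and at least
    ``min_response_duration`` s, so a single supra-threshold noise frame
    (whose interpolated FWHM is at most about one frame interval) is not
    a response.
    """
    features = force_curves.analyze_curve(curve)
    first_onset = schedule[0].onset
    pre_stim = trace.time < first_onset
    n_baseline = int(pre_stim.sum())
    n_baseline = max(5, min(10, n_baseline))
    normalized = calcium.normalize_baseline(trace, baseline_frames=n_baseline)
    bleach_corrected = calcium.correct_bleaching(normalized, anchor=pre_stim)
    d_time, d = _full_span_deflection(curve, features, schedule, trace)
    corrected = calcium.correct_reflection_artifact(bleach_corrected, d_time, d)
    corrected = calcium.estimate_noise(corrected)
    spontaneous = False
    if first_onset - trace.time[0] > 2.0:
        spontaneous = calcium.flag_spontaneous(
            corrected,
            (float(trace.time[0]), float(first_onset) - 1e-6),
            min_duration=min_response_duration,
        )
    transients = calcium.quantify_transients(corrected)
    responses = [
        tr
        for tr in transients
        if tr.peak_time >= first_onset
        and tr.duration is not None
        and tr.duration >= min_response_duration
    ]
    record = {
        "features": fileio.features_to_dict(features),
        "noise": corrected.noise,
        "spontaneous": spontaneous,
        "transients": [asdict(tr) for tr in responses],
        "responded": len(responses) > 0,
        # the principal response: largest amplitude among quantified ones
        "amount": max(
            (tr for tr in responses if tr.amount is not None),
            key=lambda tr: tr.amplitude,
            default=None,
        ).amount
        if any(tr.amount is not None for tr in responses)
        else None,
        "provenance": corrected.provenance,
    }
    if log is not None:
        for step in corrected.provenance:
            log.append({"event": "correction", "detail": step})
    return record


def run_pipeline(manifest_path, control_condition: str = "control") -> dict:
    """Run the full analysis over a manifest; returns the results bundle."""
    manifest = fileio.read_manifest(manifest_path)
    log: list[dict] = []
    cells: dict[str, dict] = {}
    for _, row in manifest.iterrows():
        cell_id = str(row["cell_id"])
        try:
            curve = fileio.read_force_curve(
                fileio.resolve_path(manifest_path, row["curve_path"]),
                fileio.resolve_path(manifest_path, row["meta_path"]),
            )
            data_path = fileio.resolve_path(
                manifest_path, row["trace_or_stack_path"]
            )
            if str(data_path).endswith((".tif", ".tiff")):
                roi = fileio.read_roi(
                    fileio.resolve_path(manifest_path, row["roi_path"])
                )
                stack = fileio.read_stack(data_path, timing=0.345)
                trace = calcium.extract_roi_trace(stack, roi)
            else:
                trace = fileio.read_trace(data_path)
            schedule = fileio.read_schedule(
                fileio.resolve_path(manifest_path, row["schedule_path"])
            )
            record = analyze_cell(curve, trace, schedule, log)
        except MechanoCaError as exc:
            log.append(
                {"event": "cell_failed", "cell_id": cell_id, "error": str(exc)}
            )
            logger.warning("cell %s failed: %s", cell_id, exc)
            continue
        record["condition"] = str(row["condition"])
        if record["spontaneous"]:
            log.append({"event": "excluded_spontaneous", "cell_id": cell_id})
            logger.info("cell %s excluded: spontaneous pre-stimulus activity", cell_id)
        cells[cell_id] = record

    usable = {k: v for k, v in cells.items() if not v["spontaneous"]}
    if not usable:
        raise PipelineError("no usable cells survived the pipeline")

    conditions = sorted({v["condition"] for v in usable.values()})
    summaries = {}
    for cond in conditions:
        responded = [v["responded"] for v in usable.values() if v["condition"] == cond]
        summaries[cond] = asdict(stats.responder_fraction(responded, cond))

    comparisons = {}
    if control_condition in conditions:
        ctrl = summaries[control_condition]
        ctrl_amounts = [
            v["amount"]
            for v in usable.values()
            if v["condition"] == control_condition and v["amount"] is not None
        ]
        for cond in conditions:
            if cond == control_condition:
                continue
            s = summaries[cond]
            table = [
                [ctrl["responders"], ctrl["total"] - ctrl["responders"]],
                [s["responders"], s["total"] - s["responders"]],
            ]
            try:
                fisher_p = stats.fisher_exact(table)
            except MechanoCaError:
                fisher_p = 1.0  # degenerate margin: identical outcomes
            entry = {"fraction_fisher_p": fisher_p}
            amounts = [
                v["amount"]
                for v in usable.values()
                if v["condition"] == cond and v["amount"] is not None
            ]
            if len(amounts) >= 2 and len(ctrl_amounts) >= 2:
                res = stats.students_t(ctrl_amounts, amounts)
                entry["amount_t"] = res.t
                entry["amount_p"] = res.p
            comparisons[cond] = entry

    return {
        "schema_version": SCHEMA_VERSION,
        "cells": cells,
        "condition_summaries": summaries,
        "comparisons_vs_control": comparisons,
        "log": log,
        "n_excluded_spontaneous": sum(
            1 for v in cells.values() if v["spontaneous"]
        ),
    }


def write_results(path, results: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fileio.write_json(path, results)
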