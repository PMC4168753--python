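"""Readers and writers for the package's interchange formats.

All tabular files are comma-separated, '.'-decimal, UTF-8 CSV with a
header; floats are written with 12 significant digits so every
writer/reader pair round-trips losslessly at that precision.

* Force curve: CSV with columns ``time_s, z_um, deflection_nm`` plus a
  JSON sidecar with ``spring_constant_N_per_m``,
  ``indentation_speed_um_per_s``, ``dwell_time_s`` (one curve per pair).
* Trace: CSV with ``time_s, intensity`` (corrected traces add
  ``intensity_normalized`` / ``intensity_corrected`` columns).
* Image stack: multi-frame grayscale TIFF; frame times either from a
  uniform interval or a sidecar CSV with ``frame, time_s``.
* ROI: JSON ``{shape, center_px, diameter_um | axes_um}``.
* Curve features: JSON with fixed keys (see ``features_to_dict``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .calcium import FluorescenceTrace, ImageStack, RoiSpec, RAW
from .errors import SchemaError, UnsupportedFormatError
from .force_curves import CurveFeatures, ForceCurve, ProbeMeta
from .synthetic import Stimulation

FLOAT_FMT = "%.12g"

CURVE_COLUMNS = ("time_s", "z_um", "deflection_nm")
META_KEYS = (
    "spring_constant_N_per_m",
    "indentation_speed_um_per_s",
    "dwell_time_s",
)
MANIFEST_COLUMNS = (
    "cell_id",
    "condition",
    "curve_path",
    "meta_path",
    "trace_or_stack_path",
    "roi_path",
    "schedule_path",
)
SCHEMA_VERSION = 1


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Force curves


def write_force_curve(path_csv, path_meta, curve: ForceCurve) -> None:
    df = pd.DataFrame(
        {"time_s": curve.time, "z_um": curve.z, "deflection_nm": curve.deflection}
    )
    df.to_csv(path_csv, index=False, float_format=FLOAT_FMT)
    write_json(
        path_meta,
        {
            "spring_constant_N_per_m": curve.meta.spring_constant,
            "indentation_speed_um_per_s": curve.meta.indentation_speed,
            "dwell_time_s": curve.meta.dwell_time,
            "tip_area_label": curve.meta.tip_area_label,
        },
    )


def read_force_curve(path_csv, path_meta) -> ForceCurve:
    df = pd.read_csv(path_csv)
    _require_columns(df, CURVE_COLUMNS, path_csv)
    meta_raw = read_json(path_meta)
    for key in META_KEYS:
        if key not in meta_raw:
            raise SchemaError(f"{path_meta}: missing required field {key!r}")
    meta = ProbeMeta(
        spring_constant=float(meta_raw["spring_constant_N_per_m"]),
        indentation_speed=float(meta_raw["indentation_speed_um_per_s"]),
        dwell_time=float(meta_raw["dwell_time_s"]),
        tip_area_label=str(meta_raw.get("tip_area_label", "")),
    )
    return ForceCurve(
        time=df["time_s"].to_numpy(float),
        z=df["z_um"].to_numpy(float),
        deflection=df["deflection_nm"].to_numpy(float),
        meta=meta,
    )


def features_to_dict(features: CurveFeatures) -> dict:
    rupture = features.rupture
    return {
        "schema_version": SCHEMA_VERSION,
        "contact_z_um": features.contact_z,
        "max_force_nN": features.max_force,
        "rupture_force_nN": rupture.force_before if rupture else None,
        "force_drop_nN": rupture.force_drop if rupture else None,
        "deformation_extent_um": features.deformation_extent,
        "penetration_depth_um": features.penetration_depth,
        "hysteresis_energy_fJ": features.hysteresis_energy,
        "contact_time_s": features.contact_time,
        "load_class": features.load_class,
    }


def write_features(path, features: CurveFeatures) -> None:
    write_json(path, features_to_dict(features))


# ---------------------------------------------------------------------------
# Traces


def write_trace(path, trace: FluorescenceTrace, extra: Optional[dict] = None) -> None:
    data = {"time_s": trace.time, "intensity": trace.intensity}
    if extra:
        data.update(extra)
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trace(path) -> FluorescenceTrace:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "intensity"), path)
    return FluorescenceTrace(
        time=df["time_s"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
        state=RAW,
        provenance=[f"read_trace({path})"],
    )


# ---------------------------------------------------------------------------
# Image stacks


def write_stack(path, stack: ImageStack, times_path=None) -> None:
    import tifffile

    tifffile.imwrite(path, stack.frames.astype(np.float32))
    if times_path is not None:
        pd.DataFrame(
            {"frame": np.arange(len(stack.frame_times)), "time_s": stack.frame_times}
        ).to_csv(times_path, index=False, float_format=FLOAT_FMT)


def read_stack(
    path, timing: Union[float, str, Path], pixel_size: float = 0.5
) -> ImageStack:
    """Read a multi-frame grayscale TIFF.

    ``timing`` is either a uniform frame interval in seconds or the path
    of a sidecar CSV with columns ``frame, time_s``.
    """
    import tifffile

    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        if "S" in series.axes or any(
            page.photometric not in (0, 1) for page in tif.pages
        ):
            raise UnsupportedFormatError(
                f"{path}: RGB/multichannel TIFF not supported; "
                "expected grayscale frames"
            )
        frames = series.asarray()
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise UnsupportedFormatError(
            f"{path}: expected grayscale frames, got shape {frames.shape}"
        )
    if isinstance(timing, (int, float)):
        times = np.arange(frames.shape[0]) * float(timing)
    else:
        df = pd.read_csv(timing)
        _require_columns(df, ("frame", "time_s"), timing)
        times = df["time_s"].to_numpy(float)
        if times.size != frames.shape[0]:
            raise SchemaError(
                f"{timing}: {times.size} frame times for {frames.shape[0]} frames"
            )
    return ImageStack(frames=frames.astype(float), frame_times=times, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# ROI


def write_roi(path, roi: RoiSpec) -> None:
    obj = {"shape": roi.shape, "center_px": list(roi.center)}
    if roi.diameter is not None:
        obj["diameter_um"] = roi.diameter
    if roi.axes is not None:
        obj["axes_um"] = list(roi.axes)
    write_json(path, obj)


def read_roi(path) -> RoiSpec:
    obj = read_json(path)
    for key in ("shape", "center_px"):
        if key not in obj:
            raise SchemaError(f"{path}: missing required field {key!r}")
    return RoiSpec(
        shape=obj["shape"],
        center=tuple(obj["center_px"]),
        diameter=obj.get("diameter_um"),
        axes=tuple(obj["axes_um"]) if "axes_um" in obj else None,
    )


# ---------------------------------------------------------------------------
# Schedules and manifests


def write_schedule(path, schedule: list[Stimulation]) -> None:
    write_json(
        path,
        {
            "stimulations": [
                {
                    "onset_s": s.onset,
                    "contact_time_s": s.contact_time,
                    "dwell_s": s.dwell,
                }
                for s in schedule
            ]
        },
    )


def read_schedule(path) -> list[Stimulation]:
    obj = read_json(path)
    if "stimulations" not in obj:
        raise SchemaError(f"{path}: missing required field 'stimulations'")
    out = []
    for row in obj["stimulations"]:
        try:
            out.append(
                Stimulation(
                    onset=float(row["onset_s"]),
                    contact_time=float(row["contact_time_s"]),
                    dwell=float(row.get("dwell_s", 0.0)),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: stimulation missing field {exc}") from exc
    return out


def write_manifest(path, rows: list[dict]) -> None:
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, MANIFEST_COLUMNS, path)
    base = Path(path).parent
    for _, row in df.iterrows():
        for col in ("curve_path", "meta_path", "trace_or_stack_path", "schedule_path"):
            p = str(row[col])
            if not p:
                continue
            candidate = Path(p)
            if not candidate.is_absolute():
                candidate = base / candidate
            if not candidate.exists():
                raise SchemaError(f"{path}: referenced file does not exist: {p}")
    for condition, group in df.groupby("condition"):
        if group["cell_id"].duplicated().any():
            raise SchemaError(
                f"{path}: duplicate cell_id within condition {condition!r}"
            )
    return df


def resolve_path(manifest_path, p: str) -> Path:
    candidate = Path(p)
    if candidate.is_absolute():
        return candidate
    return Path(manifest_path).parent / candidate
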