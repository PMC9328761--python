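"""CSV schemas, config loading and run-logging shared by all stages.

All interchange is plain CSV with required headers (UTF-8, '.' decimal):

======================  ====================================================
table                   columns
======================  ====================================================
AFM trace               time_s, height_um, stress_pa
intensity trace         time_s, channel, density
rate table              stress_pa, channel, per_network_rate,
                        per_filament_rate, barbed_end_density_rel
molecule tracks         track_id, frame, time_s, x_um, y_um, intensity
quench curves           time_s, donor_intensity, condition
ratio dataset           stress_pa, ratio, error
======================  ====================================================
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, SchemaError
from .flux import AfmTrace, IntensityTrace
from .fret import QuenchCurve
from .single_molecule import MoleculeTrack

__all__ = [
    "read_afm_csv", "write_afm_csv",
    "read_intensity_csv", "write_intensity_csv",
    "read_tracks_csv", "write_tracks_csv",
    "read_quench_csv", "write_quench_csv",
    "read_table", "load_config", "config_from_mapping", "write_run_log",
]

_FLOAT_FMT = "%.9g"


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_table(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"{path}: not a readable CSV table ({exc})") from exc
    _require_columns(df, columns, path)
    return df


def _write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_afm_csv(path) -> AfmTrace:
    df = read_table(path, ["time_s", "height_um", "stress_pa"])
    return AfmTrace(
        time=df["time_s"].to_numpy(float),
        height=df["height_um"].to_numpy(float),
        stress=df["stress_pa"].to_numpy(float),
    )


def write_afm_csv(trace: AfmTrace, path, comment: str | None = None) -> None:
    _write_csv(
        pd.DataFrame(
            {"time_s": trace.time, "height_um": trace.height, "stress_pa": trace.stress}
        ),
        path, comment,
    )


def read_intensity_csv(path) -> dict[str, IntensityTrace]:
    df = read_table(path, ["time_s", "channel", "density"])
    out = {}
    for channel, grp in df.groupby("channel", sort=False):
        out[str(channel)] = IntensityTrace(
            time=grp["time_s"].to_numpy(float),
            channel=str(channel),
            density=grp["density"].to_numpy(float),
        )
    return out


def write_intensity_csv(traces: dict[str, IntensityTrace], path, comment=None) -> None:
    frames = [
        pd.DataFrame({"time_s": tr.time, "channel": name, "density": tr.density})
        for name, tr in traces.items()
    ]
    _write_csv(pd.concat(frames, ignore_index=True), path, comment)


def read_tracks_csv(path) -> list[MoleculeTrack]:
    df = read_table(path, ["track_id", "frame", "time_s", "x_um", "y_um", "intensity"])
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            MoleculeTrack(
                track_id=int(tid),
                time=grp["time_s"].to_numpy(float),
                intensity=grp["intensity"].to_numpy(float),
                x=grp["x_um"].to_numpy(float),
                y=grp["y_um"].to_numpy(float),
            )
        )
    return tracks


def write_tracks_csv(tracks, path, comment=None) -> None:
    rows = []
    for tr in tracks:
        for i in range(tr.time.size):
            rows.append(
                (tr.track_id, i, tr.time[i], tr.x[i], tr.y[i], tr.intensity[i])
            )
    df = pd.DataFrame(
        rows, columns=["track_id", "frame", "time_s", "x_um", "y_um", "intensity"]
    )
    _write_csv(df, path, comment)


def read_quench_csv(path) -> dict[str, QuenchCurve]:
    df = read_table(path, ["time_s", "donor_intensity", "condition"])
    out = {}
    for cond, grp in df.groupby("condition", sort=False):
        out[str(cond)] = QuenchCurve(
            time=grp["time_s"].to_numpy(float),
            donor_intensity=grp["donor_intensity"].to_numpy(float),
            condition=str(cond),
        )
    return out


def write_quench_csv(curves: dict[str, QuenchCurve], path, comment=None) -> None:
    frames = [
        pd.DataFrame(
            {"time_s": c.time, "donor_intensity": c.donor_intensity, "condition": name}
        )
        for name, c in curves.items()
    ]
    _write_csv(pd.concat(frames, ignore_index=True), path, comment)


def config_from_mapping(cls, mapping: dict, path: str = "<config>"):
    """Build a (possibly nested) dataclass from a mapping, rejecting unknown keys."""
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"{path}: expected a mapping, got {type(mapping).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown key(s): {', '.join(sorted(unknown))} "
            f"(valid: {', '.join(sorted(fields))})"
        )
    kwargs = {}
    for key, value in mapping.items():
        target = _nested_dataclass(cls, key)
        if target is not None and isinstance(value, dict):
            kwargs[key] = config_from_mapping(target, value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def _nested_dataclass(cls, key):
    for f in dataclasses.fields(cls):
        if f.name == key:
            default = f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
            if dataclasses.is_dataclass(default):
                return type(default)
    return None


def load_config(path, cls):
    """Load and validate a YAML config file into dataclass ``cls``."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_mapping(cls, data, str(path))


def write_run_log(path, stage: str, seed=None, config=None, extra: dict | None = None) -> None:
    """Structured provenance block: package version, stage, seed, config echo."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"stage: {stage}",
        f"package_version: {__version__}",
        f"seed: {seed}",
    ]
    if config is not None:
        if dataclasses.is_dataclass(config):
            config = dataclasses.asdict(config)
        lines.append("config:")
        dumped = yaml.safe_dump(_plain(config), sort_keys=True)
        lines.extend("  " + ln for ln in dumped.splitlines())
    for key, value in (extra or {}).items():
        lines.append(f"{key}: {value}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
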