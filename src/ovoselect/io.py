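"""Tabular file formats, manifests and schema validation.

All tables are plain CSV with documented columns; floating point values are
serialized at full (round-trip) precision, coordinates in micrometres, time
as 0-based frame indices (frame x interval hours from t=0 = c-17.5 dpc).
Missing columns raise a named-column error on read.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import PipelineConfig, SimConfig, config_hash, stage_label

__all__ = ["SCHEMAS", "write_table", "read_table", "save_ground_truth",
           "load_ground_truth", "write_manifest", "read_manifest",
           "stage_label_map"]

SCHEMAS: dict[str, list[str]] = {
    "objects": ["frame", "object_id", "z", "y", "x", "equivalent_diameter",
                "volume", "cls", "fl_lengths", "cfp_mean", "rfp_mean",
                "mito_density", "contact_ids", "agent_id"],
    "tracks": ["track_id", "frame", "object_id", "z", "y", "x",
               "equivalent_diameter", "cls", "agent_id"],
    "track_summary": ["track_id", "kind", "start", "end", "z", "y", "x",
                      "last_diameter", "end_reason", "complete"],
    "events": ["type", "frame", "track_a", "track_b", "payload",
               "member_tracks"],
    "stage_stats": ["window", "label", "n_start", "fl_ratio",
                    "od_event_freq", "death_freq", "mean_diameter",
                    "sd_diameter", "single_ratio", "purple_ratio"],
    "gt_oocytes": ["frame", "oocyte_id", "cyst_id", "z", "y", "x",
                   "diameter", "lineage", "engulf_count", "n_fl",
                   "fl_lengths", "cfp", "rfp", "mito_density", "n_bridges",
                   "observed", "death_mode"],
    "gt_debris": ["frame", "debris_id", "parent_id", "z", "y", "x",
                  "diameter", "mito_density", "cfp", "rfp", "status",
                  "observed"],
}

_STRING_COLS = {"fl_lengths", "contact_ids", "agent_id", "member_tracks",
                "death_mode", "label", "cls", "kind", "end_reason", "type",
                "lineage", "status"}


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a CSV; when a schema name is given, column presence and order
    are enforced first."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if schema is not None:
        cols = SCHEMAS[schema]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{schema} table missing column(s): {missing}")
        df = df[cols]
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path, schema: str | None = None) -> pd.DataFrame:
    """Read a CSV, validating required columns when a schema is named."""
    dtypes = {c: "string" for c in _STRING_COLS}
    df = pd.read_csv(path, dtype={k: v for k, v in dtypes.items()},
                     keep_default_na=False, na_values=["nan", "NaN", ""],
                     float_precision="round_trip")
    if schema is not None:
        missing = [c for c in SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise ValueError(
                f"{Path(path).name}: missing column(s) {missing} "
                f"for schema {schema!r}")
    for c in df.columns:
        if c in _STRING_COLS:
            df[c] = df[c].fillna("").astype(str)
    return df


def stage_label_map(n_windows: int, frame_interval: float) -> dict[str, str]:
    """Hour -> culture-stage label map serialized into manifests."""
    return {str(int(w * 24)): stage_label(w) for w in range(n_windows)}


def save_ground_truth(log, out_dir) -> None:
    """GroundTruthLog -> agents-per-frame CSVs + event CSV + config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(log.oocytes, out / "gt_oocytes.csv", "gt_oocytes")
    write_table(log.debris, out / "gt_debris.csv",
                "gt_debris" if len(log.debris) else None)
    log.events.to_csv(out / "gt_events.csv", index=False, float_format="%.17g")
    with open(out / "config.json", "w") as fh:
        json.dump({"config": log.config.to_dict(), "seed": log.seed,
                   "config_hash": config_hash(log.config)}, fh, indent=2)


def load_ground_truth(out_dir):
    """Inverse of :func:`save_ground_truth`."""
    from .sim import GroundTruthLog
    out = Path(out_dir)
    oo = read_table(out / "gt_oocytes.csv", "gt_oocytes")
    oo["observed"] = oo["observed"].astype(str).str.lower() == "true" \
        if oo["observed"].dtype == object else oo["observed"].astype(bool)
    od = read_table(out / "gt_debris.csv")
    ev = pd.read_csv(out / "gt_events.csv")
    with open(out / "config.json") as fh:
        blob = json.load(fh)
    cfg = SimConfig.from_dict(blob["config"])
    return GroundTruthLog(oo, od, ev, cfg, blob["seed"])


def write_manifest(path, pconfig: PipelineConfig, outputs: list[str],
                   extra: dict | None = None) -> None:
    """Run manifest: config echo + hash, seeds, package version, outputs,
    and the stage-label map. Re-running from the manifest reproduces all
    agent-level outputs bit-identically."""
    from . import __version__
    blob = {
        "package": "ovoselect",
        "version": __version__,
        "config": pconfig.to_dict(),
        "config_hash": config_hash(pconfig),
        "seeds": list(pconfig.seeds),
        "outputs": sorted(outputs),
        "stage_labels": stage_label_map(pconfig.sim.n_windows,
                                        pconfig.sim.frame_interval),
    }
    if extra:
        blob.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True)


def read_manifest(path) -> PipelineConfig:
    with open(path) as fh:
        blob = json.load(fh)
    return PipelineConfig.from_dict(blob["config"])
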