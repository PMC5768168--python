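"""Reading receiver exports and writing analysis outputs.

Detection logs are read from the CSV dialect exported by the receiver
vendor's database application (VUE): a header with date/time, receiver and
transmitter columns, one row per detection.  Column naming drifts between
versions, so several spellings are accepted.  All timestamps are treated as
UTC and hours are binned on the UTC hour.

Outputs are plain CSV and JSON with deterministic ordering; JSON reports
carry a configuration echo and the package version so a result can be traced
back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import __version__
from .cpdi import CPDIGrid
from .geometry import Environment, ReceiverSpec, heights_to_depths
from .range_analysis import MetaLogDay

log = logging.getLogger("cpditools")

__all__ = [
    "read_vue_csv",
    "read_tag_distances",
    "read_meta_log_csv",
    "write_grid_csv",
    "write_report_json",
    "write_metrics_csv",
    "RunConfig",
]

# accepted spellings for the mandatory VUE export columns
_VUE_COLUMNS = {
    "timestamp": ("date and time (utc)", "date/time", "date and time", "datetime",
                  "timestamp"),
    "receiver": ("receiver", "receiver sn", "station name"),
    "transmitter": ("transmitter", "transmitter id", "tag id"),
}


def _match_columns(header: Iterable[str]) -> dict[str, str]:
    lookup = {h.strip().lower(): h for h in header}
    resolved, missing = {}, []
    for canonical, variants in _VUE_COLUMNS.items():
        found = next((lookup[v] for v in variants if v in lookup), None)
        if found is None:
            missing.append(canonical)
        else:
            resolved[canonical] = found
    if missing:
        raise ValueError(
            f"detection log is missing mandatory column(s) {missing}; "
            f"accepted spellings: "
            + "; ".join(f"{k}: {list(v)}" for k, v in _VUE_COLUMNS.items() if k in missing)
        )
    return resolved


def read_vue_csv(path: str | Path) -> pd.DataFrame:
    """Read a VUE-dialect detection CSV into (timestamp, receiver, transmitter).

    Rows whose timestamp cannot be parsed are dropped with a logged count;
    extra sensor columns are ignored.
    """
    raw = pd.read_csv(path)
    cols = _match_columns(raw.columns)
    df = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(raw[cols["timestamp"]], errors="coerce",
                                        format="mixed"),
            "receiver": raw[cols["receiver"]].astype(str),
            "transmitter": raw[cols["transmitter"]].astype(str),
        }
    )
    bad = int(df["timestamp"].isna().sum())
    if bad:
        log.warning("%s: dropped %d row(s) with unparseable timestamps", path, bad)
        df = df.dropna(subset=["timestamp"])
    df.attrs["dropped_rows"] = bad
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def read_tag_distances(path: str | Path) -> dict[str, float]:
    """Read a (tag_id, distance_m) CSV into a mapping."""
    df = pd.read_csv(path)
    for col in ("tag_id", "distance_m"):
        if col not in df.columns:
            raise ValueError(f"tag-distance file needs a '{col}' column")
    return dict(zip(df["tag_id"].astype(str), df["distance_m"].astype(float)))


def read_meta_log_csv(path: str | Path) -> list[MetaLogDay]:
    """Read a daily meta-log CSV (date, detections, syncs, pings, checksum_rejects)."""
    df = pd.read_csv(path)
    needed = ["date", "detections", "syncs", "pings", "checksum_rejects"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"meta-log file is missing column(s) {missing}")
    return [
        MetaLogDay(
            date=row["date"],
            detections=int(row["detections"]),
            syncs=int(row["syncs"]),
            pings=int(row["pings"]),
            checksum_rejects=int(row["checksum_rejects"]),
        )
        for _, row in df.iterrows()
    ]


def write_grid_csv(grid: CPDIGrid, path: str | Path) -> None:
    """CPDI grid as CSV: range_m, tag_depth_m, cpdi (0/1), n_cat2."""
    grid.to_dataframe().to_csv(path, index=False)


def write_metrics_csv(per_day: pd.DataFrame, path: str | Path) -> None:
    per_day.to_csv(path, index=False)


def write_report_json(payload: Mapping, path: str | Path,
                      config: Mapping | None = None) -> None:
    """JSON report with a config echo and package version, deterministically
    ordered."""
    doc = {
        "package": "cpditools",
        "version": __version__,
        "config": dict(config) if config is not None else None,
        **payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")


@dataclass
class RunConfig:
    """Validated bundle of one run's parameters.

    Geometry may be given as depths below the surface or heights above the
    seafloor (heights win if both appear); all distances in metres, times in
    seconds, depths positive downward.
    """

    water_depth: float
    amdr: float
    sound_speed: float = 1530.0
    blanking_interval: float = 0.260
    pings_per_train: int = 8
    receiver_depth: float | None = None
    receiver_height: float | None = None
    tag_depths: tuple[float, ...] = ()
    tag_heights: tuple[float, ...] = ()
    max_range: float = 1000.0
    resolution: float = 1.0
    max_arrivals: int | None = None
    basis_dim: int = 6
    aic_window: float = 2.0
    threshold_fraction: float = 0.05
    se_width: float = 1.0
    nominal_interval: float = 60.0
    seed: int = 0

    def environment(self) -> Environment:
        return Environment(self.water_depth, self.sound_speed)

    def receiver_spec(self) -> ReceiverSpec:
        return ReceiverSpec(amdr=self.amdr, blanking_interval=self.blanking_interval,
                            pings_per_train=self.pings_per_train)

    def resolved_receiver_depth(self) -> float:
        env = self.environment()
        if self.receiver_height is not None:
            return heights_to_depths(env, 0.0, self.receiver_height)[1]
        if self.receiver_depth is None:
            raise ValueError("receiver_depth or receiver_height is required")
        if not 0 <= self.receiver_depth <= env.water_depth:
            raise ValueError(
                f"receiver_depth={self.receiver_depth} outside [0, {env.water_depth}]"
            )
        return self.receiver_depth

    def resolved_tag_depths(self) -> tuple[float, ...]:
        env = self.environment()
        if self.tag_heights:
            return tuple(heights_to_depths(env, h, 0.0)[0] for h in self.tag_heights)
        if not self.tag_depths:
            raise ValueError("tag_depths or tag_heights is required")
        for z in self.tag_depths:
            if not 0 <= z <= env.water_depth:
                raise ValueError(f"tag depth {z} outside [0, {env.water_depth}]")
        return tuple(self.tag_depths)

    def validate(self) -> "RunConfig":
        self.environment()
        self.receiver_spec()
        self.resolved_receiver_depth()
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        return self

    def echo(self) -> dict:
        return asdict(self)

    def provenance(self) -> str:
        digest = hashlib.sha256(
            json.dumps(self.echo(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        return f"config={digest} seed={self.seed} version={__version__}"
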