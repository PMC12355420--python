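"""Readers, writers and domain containers for every external format the pipeline touches.

Event-level flow-cytometry data arrive either as FCS 3.0/3.1 files or as plain
CSV event tables with one column per channel; both are mapped onto
:class:`EventTable`, the in-memory container the cytometry layer consumes.
Plate-screening tables, decay time courses, genotype tallies and Ct tables are
ordinary delimited text read through pandas.  The screening funnel is
serialized as JSON or TSV via :class:`FunnelReport`.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("defac")

REQUIRED_CHANNELS = ("gfp", "lc3", "viability")

__all__ = [
    "EventTable",
    "ScreenRecord",
    "DecayCourse",
    "GenotypeCounts",
    "FunnelStage",
    "FunnelReport",
    "read_events",
    "read_fcs",
    "read_screen_table",
    "read_decay_course",
    "read_genotype_counts",
    "write_funnel_report",
    "read_funnel_report",
    "load_config",
    "configure_logging",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Per-cell fluorescence events for one sample.

    ``events`` holds one row per cell with (at least) the columns ``gfp``,
    ``lc3`` and ``viability`` in arbitrary fluorescence units.  ``treatment``
    distinguishes the lysosome-inhibited (``"bafa1"``) arm from the untreated
    arm of the flux assay.
    """

    events: pd.DataFrame
    sample_id: str = ""
    construct: str = ""
    treatment: str = "untreated"
    replicate: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.treatment not in ("untreated", "bafa1"):
            raise ValueError(f"treatment must be 'untreated' or 'bafa1', got {self.treatment!r}")
        missing = [c for c in REQUIRED_CHANNELS if c not in self.events.columns]
        if missing:
            raise KeyError(f"event table missing required channel(s): {', '.join(missing)}")
        values = self.events[list(REQUIRED_CHANNELS)].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("event intensities must be finite")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def channel_names(self) -> set[str]:
        return set(self.events.columns)

    def with_events(self, events: pd.DataFrame) -> "EventTable":
        return replace(self, events=events)


@dataclass
class ScreenRecord:
    """One well of the drug-library plate: raw signals plus annotation."""

    drug_id: str
    drug_name: str = ""
    well: str = ""
    plate: str = "plate1"
    is_vehicle: bool = False
    category_tags: frozenset = frozenset()
    cellmask_raw: float = np.nan
    sdc1_raw: float = np.nan
    nluc_raw: float = np.nan  # may be NaN for plates lacking the reporter

    def __post_init__(self) -> None:
        for name in ("cellmask_raw", "sdc1_raw", "nluc_raw"):
            v = getattr(self, name)
            if v is not None and np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0 for {self.drug_id!r} (got {v})")


@dataclass
class DecayCourse:
    """A cycloheximide-chase time course.

    ``data`` columns: ``time_h``, ``value`` (relative abundance, the pre-chase
    point normalized to 100 %), ``replicate``.
    """

    data: pd.DataFrame
    series_id: str = ""

    def __post_init__(self) -> None:
        need = {"time_h", "value", "replicate"}
        missing = need - set(self.data.columns)
        if missing:
            raise KeyError(f"decay course missing column(s): {', '.join(sorted(missing))}")
        if (self.data["time_h"] < 0).any():
            raise ValueError("time_h must be >= 0")

    def replicates(self) -> list[int]:
        return sorted(self.data["replicate"].unique())


@dataclass
class GenotypeCounts:
    """Fetal genotype tally for one cross (wild-type / heterozygote / homozygote)."""

    n_wt: int
    n_het: int
    n_hom: int
    group_label: str = ""

    def __post_init__(self) -> None:
        counts = (self.n_wt, self.n_het, self.n_hom)
        if any(c < 0 for c in counts):
            raise ValueError("genotype counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("total genotype count must be >= 1")

    @property
    def total(self) -> int:
        return self.n_wt + self.n_het + self.n_hom

    def as_array(self) -> np.ndarray:
        return np.array([self.n_wt, self.n_het, self.n_hom], dtype=float)


@dataclass
class FunnelStage:
    stage_name: str
    n_in: int
    n_retained: int
    n_excluded: int
    retained_ids: list[str]
    excluded_ids: list[str]

    def validate(self) -> None:
        if self.n_retained + self.n_excluded != self.n_in:
            raise ValueError(
                f"stage {self.stage_name!r}: retained ({self.n_retained}) + "
                f"excluded ({self.n_excluded}) != input ({self.n_in})"
            )
        if len(self.retained_ids) != self.n_retained or len(self.excluded_ids) != self.n_excluded:
            raise ValueError(f"stage {self.stage_name!r}: id lists inconsistent with counts")


@dataclass
class FunnelReport:
    """Ordered stage-by-stage accounting of the screening triage."""

    stages: list[FunnelStage]

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("empty funnel")
        for stage in self.stages:
            stage.validate()
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if nxt.n_in != prev.n_retained:
                raise ValueError(
                    f"stage {nxt.stage_name!r} input ({nxt.n_in}) != previous "
                    f"stage retained ({prev.n_retained})"
                )

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.stage_name, s.n_in, s.n_retained) for s in self.stages]


# ---------------------------------------------------------------------------
# event-table input
# ---------------------------------------------------------------------------

def _apply_transform(df: pd.DataFrame, policy: str, cofactor: float = 150.0) -> tuple[pd.DataFrame, dict]:
    """Apply the intensity transform policy to the required channels.

    ``floor`` (default elsewhere) clips each channel at epsilon = smallest
    positive recorded value / 10 so geometric means are defined; ``arcsinh``
    applies arcsinh(x / cofactor); ``identity`` leaves values untouched.
    """
    meta: dict = {"transform": policy}
    df = df.copy()
    if policy == "identity":
        return df, meta
    if policy == "floor":
        eps_by_channel = {}
        for ch in REQUIRED_CHANNELS:
            pos = df[ch].to_numpy(dtype=float)
            pos = pos[pos > 0]
            eps = float(pos.min()) / 10.0 if pos.size else 1e-6
            df[ch] = np.maximum(df[ch].to_numpy(dtype=float), eps)
            eps_by_channel[ch] = eps
        meta["floor_epsilon"] = eps_by_channel
        return df, meta
    if policy == "arcsinh":
        for ch in REQUIRED_CHANNELS:
            df[ch] = np.arcsinh(df[ch].to_numpy(dtype=float) / cofactor)
        meta["arcsinh_cofactor"] = cofactor
        return df, meta
    raise ValueError(f"unknown transform policy {policy!r}")


def read_events(
    path: str | Path,
    format: str = "csv",
    channel_map: Mapping[str, str] | None = None,
    transform_policy: str = "floor",
    arcsinh_cofactor: float = 150.0,
    **sample_meta,
) -> EventTable:
    """Read an event table from CSV or FCS and map instrument channels.

    ``channel_map`` maps instrument channel names (e.g. ``FITC-A``) to the
    logical names ``gfp``, ``lc3``, ``viability``; it may be omitted for CSV
    files that already use logical column names.
    """
    path = Path(path)
    if format == "csv":
        raw = pd.read_csv(path, sep=None, engine="python")
        for col in raw.columns:
            if not pd.api.types.is_numeric_dtype(raw[col]):
                bad = raw[~pd.to_numeric(raw[col], errors="coerce").notna()]
                raise ValueError(
                    f"non-numeric event value in column {col!r}, first bad row index "
                    f"{bad.index[0] if len(bad) else '?'}"
                )
    elif format == "fcs":
        raw = read_fcs(path)
    else:
        raise ValueError(f"unknown event format {format!r}")

    if channel_map:
        missing_src = [src for src in channel_map if src not in raw.columns]
        if missing_src:
            raise KeyError(f"channel(s) not found in file: {', '.join(missing_src)}")
        raw = raw.rename(columns=dict(channel_map))
    missing = [c for c in REQUIRED_CHANNELS if c not in raw.columns]
    if missing:
        raise KeyError(f"missing required channel(s): {', '.join(missing)}")

    df, meta = _apply_transform(raw, transform_policy, arcsinh_cofactor)
    meta["source"] = str(path)
    table = EventTable(events=df, metadata=meta, **sample_meta)
    logger.info("read %d events from %s (%s)", len(table), path, transform_policy)
    return table


# ---------------------------------------------------------------------------
# minimal FCS 3.0 / 3.1 reader
# ---------------------------------------------------------------------------

def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read the DATA segment of an FCS 3.0/3.1 file into a DataFrame.

    Supports list-mode ($MODE L) float ($DATATYPE F/D) and integer
    ($DATATYPE I, byte-aligned widths) data in either byte order, which covers
    files exported by common cytometer software.  Compensation, analysis
    segments and multi-dataset files are not handled.
    """
    blob = Path(path).read_bytes()
    version = blob[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r} (need FCS3.0/3.1)")
    text_start = int(blob[10:18])
    text_end = int(blob[18:26])
    text = blob[text_start : text_end + 1].decode("utf-8", errors="replace")
    delim = text[0]
    fields = text[1:].split(delim)
    kv = {fields[i].strip(): fields[i + 1] for i in range(0, len(fields) - 1, 2)}

    n_par = int(kv["$PAR"])
    n_events = int(kv["$TOT"])
    datatype = kv["$DATATYPE"].strip().upper()
    mode = kv.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise ValueError(f"only list-mode FCS supported, got $MODE={mode}")
    byteord = kv["$BYTEORD"].strip()
    little = byteord.startswith("1")

    data_start = int(kv.get("$BEGINDATA") or blob[26:34])
    data_end = int(kv.get("$ENDDATA") or blob[34:42])
    raw = blob[data_start : data_end + 1]

    names = [kv.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
    bits = [int(kv[f"$P{i}B"]) for i in range(1, n_par + 1)]

    order = "<" if little else ">"
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise ValueError("$DATATYPE F requires 32-bit parameters")
        arr = np.frombuffer(raw[: n_events * n_par * 4], dtype=f"{order}f4")
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise ValueError("$DATATYPE D requires 64-bit parameters")
        arr = np.frombuffer(raw[: n_events * n_par * 8], dtype=f"{order}f8")
    elif datatype == "I":
        widths = {16: "u2", 32: "u4"}
        if len(set(bits)) != 1 or bits[0] not in widths:
            raise ValueError("integer FCS data must use uniform 16- or 32-bit widths")
        nbytes = bits[0] // 8
        arr = np.frombuffer(raw[: n_events * n_par * nbytes], dtype=f"{order}{widths[bits[0]]}")
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")

    if arr.size < n_events * n_par:
        raise ValueError("FCS data segment shorter than $TOT x $PAR")
    mat = np.asarray(arr[: n_events * n_par], dtype=float).reshape(n_events, n_par)
    return pd.DataFrame(mat, columns=names)


# ---------------------------------------------------------------------------
# screening / kinetics / genetics tables
# ---------------------------------------------------------------------------

def read_screen_table(
    path: str | Path,
    tag_delimiter: str = ";",
) -> list[ScreenRecord]:
    """Read a plate-screening table into ScreenRecords.

    Expected columns: ``drug_id``, ``drug_name``, ``well``, ``is_vehicle``,
    ``cellmask_raw``, ``sdc1_raw``; optional: ``plate``, ``nluc_raw``,
    ``category``.  Category tags are split on ``tag_delimiter``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"drug_id", "cellmask_raw", "sdc1_raw"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"screen table missing column(s): {', '.join(sorted(missing))}")

    records: list[ScreenRecord] = []
    for _, row in df.iterrows():
        tags = frozenset()
        cat = row.get("category")
        if isinstance(cat, str) and cat.strip():
            tags = frozenset(t.strip() for t in cat.split(tag_delimiter) if t.strip())
        is_vehicle = bool(row.get("is_vehicle", False))
        nluc = row.get("nluc_raw", np.nan)
        records.append(
            ScreenRecord(
                drug_id=str(row["drug_id"]),
                drug_name=str(row.get("drug_name", "")),
                well=str(row.get("well", "")),
                plate=str(row.get("plate", "plate1")),
                is_vehicle=is_vehicle,
                category_tags=tags,
                cellmask_raw=float(row["cellmask_raw"]),
                sdc1_raw=float(row["sdc1_raw"]),
                nluc_raw=float(nluc) if pd.notna(nluc) else np.nan,
            )
        )

    seen: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.is_vehicle:
            continue
        key = (rec.plate, rec.drug_id)
        if key in seen:
            raise ValueError(f"duplicate drug_id {rec.drug_id!r} on plate {rec.plate!r}")
        seen[key] = 1
    return records


def read_decay_course(path: str | Path, series_id: str = "") -> DecayCourse:
    df = pd.read_csv(path, sep=None, engine="python")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return DecayCourse(data=df[["time_h", "value", "replicate"]], series_id=series_id or Path(path).stem)


def read_genotype_counts(path: str | Path) -> list[GenotypeCounts]:
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for _, row in df.iterrows():
        out.append(
            GenotypeCounts(
                n_wt=int(row["n_wt"]),
                n_het=int(row["n_het"]),
                n_hom=int(row["n_hom"]),
                group_label=str(row.get("group", "")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# funnel report serialization
# ---------------------------------------------------------------------------

def write_funnel_report(report: FunnelReport, path: str | Path, format: str = "json") -> None:
    report.validate()
    path = Path(path)
    if format == "json":
        payload = [
            {
                "stage_name": s.stage_name,
                "n_in": s.n_in,
                "n_retained": s.n_retained,
                "n_excluded": s.n_excluded,
                "retained_ids": list(s.retained_ids),
                "excluded_ids": list(s.excluded_ids),
            }
            for s in report.stages
        ]
        path.write_text(json.dumps({"stages": payload}, indent=2))
    elif format == "tsv":
        rows = []
        for s in report.stages:
            rows.append(
                {
                    "stage_name": s.stage_name,
                    "n_in": s.n_in,
                    "n_retained": s.n_retained,
                    "n_excluded": s.n_excluded,
                    "retained_ids": ";".join(s.retained_ids),
                    "excluded_ids": ";".join(s.excluded_ids),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown funnel format {format!r}")


def read_funnel_report(path: str | Path, format: str = "json") -> FunnelReport:
    path = Path(path)
    stages: list[FunnelStage] = []
    if format == "json":
        payload = json.loads(path.read_text())
        for s in payload["stages"]:
            stages.append(FunnelStage(**s))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        for _, row in df.iterrows():
            split = lambda s: [x for x in str(s).split(";") if x]  # noqa: E731
            stages.append(
                FunnelStage(
                    stage_name=row["stage_name"],
                    n_in=int(row["n_in"]),
                    n_retained=int(row["n_retained"]),
                    n_excluded=int(row["n_excluded"]),
                    retained_ids=split(row["retained_ids"]),
                    excluded_ids=split(row["excluded_ids"]),
                )
            )
    else:
        raise ValueError(f"unknown funnel format {format!r}")
    report = FunnelReport(stages=stages)
    report.validate()
    return report


# ---------------------------------------------------------------------------
# config & logging
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML/key-value config (thresholds, gate boundaries, seeds, transform policy)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.WARNING)
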