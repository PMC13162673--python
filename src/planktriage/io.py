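"""File dialects and run configuration.

All pipeline artifacts are plain delimited text so they can be inspected,
diffed and version-controlled alongside the samples they describe:

* embedding tables — header ``object_id, sample_id, label, verified, t,
  v1..vd`` (label may be empty; verified is 0/1); comma or tab delimited,
  auto-detected, and the writer emits the dialect the reader saw;
* detection tables — ``object_id, image_id, x, y, w, h, confidence``;
* decision tables — one row per triaged object with route, proposed label,
  per-stage outcomes and certainty, machine-parseable for the loop;
* paired count tables — wide ``category, human, machine`` or long
  ``sample, category, observer, value``;
* agreement reports — flat ``key: value`` text that parses back.

Floats are written with 17 significant digits so a read/write round trip
is lossless at double precision.
"""

from __future__ import annotations

import csv
import dataclasses
import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import AgreementReport, PairedAbundanceTable
from .index import EmbeddingRecord
from .synthetic import SyntheticConfig
from .triage import DetectionRecord, TriageDecision, TriageParams

__all__ = [
    "RunConfig",
    "read_embeddings",
    "write_embeddings",
    "read_detections",
    "write_detections",
    "write_decisions",
    "read_decisions",
    "read_counts",
    "write_counts",
    "write_report",
    "parse_report",
    "load_config",
    "save_config",
]

_FMT = "%.17g"


def _fnum(x: float) -> str:
    return _FMT % x


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


# --------------------------------------------------------------------------
# embeddings


def read_embeddings(path) -> tuple[list[EmbeddingRecord], str]:
    """Read an embedding table; returns records and the detected delimiter."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file (no header)")
    delim = _sniff_delimiter(text.splitlines()[0])
    reader = csv.reader(_io.StringIO(text), delimiter=delim)
    header = next(reader)
    fixed = ["object_id", "sample_id", "label", "verified", "t"]
    if header[: len(fixed)] != fixed:
        raise ValueError(f"{path}: header must start with {fixed}, got {header[:5]}")
    vcols = header[len(fixed) :]
    dim = len(vcols)
    if dim < 1 or vcols != [f"v{i + 1}" for i in range(dim)]:
        raise ValueError(f"{path}: vector columns must be v1..v{dim}")
    records: list[EmbeddingRecord] = []
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields "
                f"(dimension {dim}), got {len(row)}"
            )
        try:
            vec = np.array([float(x) for x in row[len(fixed) :]])
            records.append(
                EmbeddingRecord(
                    object_id=row[0],
                    sample_id=row[1],
                    label=row[2] or None,
                    verified=row[3].strip() in ("1", "true", "True"),
                    timestamp=int(row[4]),
                    vector=vec,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    if not records:
        import warnings

        warnings.warn(f"{path}: valid header but no data rows", stacklevel=2)
    return records, delim


def write_embeddings(records, path, delimiter: str = ",") -> None:
    path = Path(path)
    records = list(records)
    dim = records[0].vector.shape[0] if records else 0
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(
            ["object_id", "sample_id", "label", "verified", "t"]
            + [f"v{i + 1}" for i in range(dim)]
        )
        for r in records:
            w.writerow(
                [
                    r.object_id,
                    r.sample_id,
                    r.label or "",
                    "1" if r.verified else "0",
                    str(r.timestamp),
                ]
                + [_fnum(x) for x in r.vector]
            )


# --------------------------------------------------------------------------
# detections


def read_detections(path) -> list[DetectionRecord]:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    reader = csv.reader(_io.StringIO(text), delimiter=delim)
    header = next(reader)
    expected = ["object_id", "image_id", "x", "y", "w", "h", "confidence"]
    if header != expected:
        raise ValueError(f"{path}: header must be {expected}")
    out = []
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 fields, got {len(row)}")
        try:
            out.append(
                DetectionRecord(
                    object_id=row[0],
                    image_id=row[1],
                    bbox=(float(row[2]), float(row[3]), float(row[4]), float(row[5])),
                    confidence=float(row[6]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return out


def write_detections(dets, path, delimiter: str = ",") -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["object_id", "image_id", "x", "y", "w", "h", "confidence"])
        for d in dets:
            w.writerow(
                [d.object_id, d.image_id]
                + [_fnum(v) for v in d.bbox]
                + [_fnum(d.confidence)]
            )


# --------------------------------------------------------------------------
# decisions


def write_decisions(decisions, path, delimiter: str = ",") -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(
            [
                "object_id",
                "route",
                "proposed_label",
                "detection_gate",
                "knn_outcome",
                "knn_label",
                "knn_query_distance",
                "knn_intra_label_mean",
                "cluster_membership",
                "certainty",
            ]
        )
        for d in decisions:
            t = d.stage_trace
            w.writerow(
                [
                    d.object_id,
                    d.route,
                    d.proposed_label or "",
                    t.detection_gate,
                    t.knn_outcome,
                    t.knn_label or "",
                    "" if t.knn_query_distance is None else _fnum(t.knn_query_distance),
                    "" if t.knn_intra_label_mean is None else _fnum(t.knn_intra_label_mean),
                    str(t.cluster_membership),
                    t.certainty if isinstance(t.certainty, str) else _fnum(t.certainty),
                ]
            )


def read_decisions(path) -> pd.DataFrame:
    """Decisions as a DataFrame (the loop only needs route + label columns)."""
    return pd.read_csv(path, dtype={"object_id": str}, keep_default_na=False)


# --------------------------------------------------------------------------
# paired counts


def read_counts(path) -> PairedAbundanceTable:
    """Read a paired count table, wide or long format."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"category", "human", "machine"} <= cols:
        cats = df["category"].astype(str).tolist()
        if len(set(cats)) != len(cats):
            raise ValueError(f"{path}: duplicate category rows")
        human = df["human"].to_numpy(dtype=float)
        machine = df["machine"].to_numpy(dtype=float)
    elif {"sample", "category", "observer", "value"} <= cols:
        if df["sample"].nunique() > 1:
            raise ValueError(f"{path}: long format must contain a single sample")
        if df.duplicated(["category", "observer"]).any():
            raise ValueError(f"{path}: duplicate category/observer rows")
        wide = df.pivot(index="category", columns="observer", values="value")
        if not {"human", "machine"} <= set(wide.columns):
            raise ValueError(f"{path}: observers must include 'human' and 'machine'")
        wide = wide.sort_index()
        cats = [str(c) for c in wide.index]
        human = wide["human"].to_numpy(dtype=float)
        machine = wide["machine"].to_numpy(dtype=float)
    else:
        raise ValueError(
            f"{path}: need columns (category, human, machine) or "
            "(sample, category, observer, value)"
        )
    if np.isnan(human).any() or np.isnan(machine).any():
        raise ValueError(f"{path}: missing values in count table")
    if (human < 0).any() or (machine < 0).any():
        raise ValueError(f"{path}: negative counts")
    return PairedAbundanceTable(tuple(cats), human, machine)


def write_counts(table: PairedAbundanceTable, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["category", "human", "machine"])
        for c, h, m in zip(table.categories, table.human, table.machine):
            w.writerow([c, _fnum(h), _fnum(m)])


# --------------------------------------------------------------------------
# agreement report


def write_report(report: AgreementReport, path) -> None:
    """Flat key-value text rendering of an agreement report."""
    ba = report.bland_altman
    lines = [
        f"n_categories: {report.n_categories}",
        f"human_mean: {_fnum(report.human_mean_sd[0])}",
        f"human_sd: {_fnum(report.human_mean_sd[1])}",
        f"machine_mean: {_fnum(report.machine_mean_sd[0])}",
        f"machine_sd: {_fnum(report.machine_mean_sd[1])}",
        f"perm_p: {_fnum(report.perm_p)}",
        f"wilcoxon_p: {'NA' if report.wilcoxon_p is None else _fnum(report.wilcoxon_p)}",
        f"mannwhitney_u: {_fnum(report.mannwhitney_u)}",
        f"mannwhitney_p: {_fnum(report.mannwhitney_p)}",
        f"pearson_r: {_fnum(report.pearson_r)}",
        f"bland_altman_bias: {_fnum(ba.bias)}",
        f"bland_altman_sd: {_fnum(ba.sd)}",
        f"bland_altman_lower: {_fnum(ba.lower)}",
        f"bland_altman_upper: {_fnum(ba.upper)}",
        f"bland_altman_excluded: {';'.join(ba.excluded)}",
        f"breakdown_equal: {_fnum(report.breakdown[0])}",
        f"breakdown_machine_lower: {_fnum(report.breakdown[1])}",
        f"breakdown_machine_higher: {_fnum(report.breakdown[2])}",
    ]
    for note in report.notes:
        lines.append(f"note: {note}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_report(path) -> dict[str, float | str]:
    """Parse a key-value report back; numeric fields become floats."""
    out: dict[str, float | str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition(":")
        val = val.strip()
        try:
            out[key.strip()] = float(val)
        except ValueError:
            out[key.strip()] = val
    return out


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Umbrella configuration: triage knobs + generator conditions + run paths."""

    triage: TriageParams = field(default_factory=TriageParams)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "."


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    tri = TriageParams(**(raw.get("triage") or {}))
    syn_raw = dict(raw.get("synthetic") or {})
    if syn_raw.get("class_weights") is not None:
        syn_raw["class_weights"] = tuple(syn_raw["class_weights"])
    if syn_raw.get("drift_schedule") is not None:
        syn_raw["drift_schedule"] = tuple(dict(r) for r in syn_raw["drift_schedule"])
    syn = SyntheticConfig(**syn_raw)
    return RunConfig(
        triage=tri,
        synthetic=syn,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        output_dir=str(raw.get("output_dir", ".")),
    )
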