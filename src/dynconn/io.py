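"""File I/O contracts: TSV time series, metadata tables, matrices, reports.

All numeric artifacts are plain TSV (UTF-8, '.' decimal); reports and the
pipeline manifest are JSON. Time-series files have a header row of node IDs
and one row per timepoint.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasMap
from .connectivity import NodeTimeSeries

FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_timeseries(ts: NodeTimeSeries, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ts.node_ids) + "\n")
        for t in range(ts.n_timepoints):
            fh.write("\t".join(FLOAT_FMT % v for v in ts.data[:, t]) + "\n")
    return path


def read_timeseries(
    path, tr_seconds: float, subject_id: str | None = None, atlas: AtlasMap | None = None
) -> NodeTimeSeries:
    """Read a node time-series TSV (header = node IDs, rows = timepoints).

    Raises with the offending line/column on ragged rows, non-numeric or
    non-finite cells; when an atlas is given the node set must match exactly.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        node_ids = header.split("\t")
        if len(node_ids) < 2:
            raise ValueError(f"{path}: header must list >= 2 node IDs")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if line.strip() == "":
                continue
            if len(cells) != len(node_ids):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(node_ids)} columns, got {len(cells)}"
                )
            vals = []
            for col, cell in enumerate(cells):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column "
                        f"{node_ids[col]!r}"
                    ) from None
                if not np.isfinite(v):
                    raise ValueError(
                        f"{path}:{lineno}: non-finite value in column {node_ids[col]!r}"
                    )
                vals.append(v)
            rows.append(vals)
    data = np.asarray(rows, dtype=float).T  # -> nodes x timepoints
    if atlas is not None:
        expected = set(atlas.node_ids)
        got = set(node_ids)
        if expected != got:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"{path}: node set mismatch with metadata; missing={missing[:5]}, "
                f"unexpected={extra[:5]}"
            )
    sid = subject_id if subject_id is not None else path.stem
    return NodeTimeSeries(sid, data, tr_seconds, node_ids)


def write_matrix(values: np.ndarray, node_ids, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(np.asarray(values), index=node_ids, columns=node_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_edges_long(values: np.ndarray, node_ids, path) -> Path:
    """Long-format upper triangle (node_i, node_j, value), i < j row-major."""
    path = Path(path)
    V = np.asarray(values)
    n = len(node_ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_i\tnode_j\tvalue\n")
        for i in range(n):
            for j in range(i + 1, n):
                fh.write(f"{node_ids[i]}\t{node_ids[j]}\t{'%.10g' % V[i, j]}\n")
    return path


def write_subjects(meta: pd.DataFrame, path) -> Path:
    path = Path(path)
    meta.to_csv(path, sep="\t", index=False)
    return path


def read_subjects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_nodes(atlas: AtlasMap, path) -> Path:
    path = Path(path)
    atlas.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_nodes(path) -> AtlasMap:
    return AtlasMap.from_frame(pd.read_csv(path, sep="\t"))


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
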