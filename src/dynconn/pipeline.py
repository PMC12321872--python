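"""End-to-end orchestration: simulate -> connect -> features -> stats -> classify.

The pipeline is fully deterministic under a fixed config: every random stage
carries an explicit seed and the manifest records SHA-256 hashes of every
output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as dio
from .classify import ModelSpec, cross_validate
from .connectivity import WindowSpec, dynamic_fc, edge_names, static_fc, upper_triangle
from .stats import chord_aggregate, combat, differential_connections
from .synthetic import CohortConfig, DynamicEdge, GroundTruth, StaticEdge, generate_cohort

log = logging.getLogger("dynconn")


@dataclass
class PipelineConfig:
    """Serializable pipeline configuration; every random stage has a seed."""

    out_dir: str = "pipeline_out"
    # cohort
    n_cn: int = 20
    n_smc: int = 10
    n_ci: int = 30
    n_gray: int = 40
    n_white: int = 24
    n_timepoints: int = 197
    tr_seconds: float = 3.0
    n_sites: int = 1
    # planted structure (edge lists as [i, j, {group: value}])
    static_edges: list = field(default_factory=list)
    dynamic_edges: list = field(default_factory=list)
    scale_loadings: dict = field(default_factory=lambda: {"mmse": 0.4, "cdr_sb": -0.4})
    # analysis
    windows: list = field(default_factory=lambda: ["gau20", "ham30"])
    bandpass: bool = False
    alpha: float = 0.05
    correction: str = "none"
    density: float = 0.15
    graph_features: bool = True
    folds: int = 5
    combat: bool = False
    smote: bool = True
    kernel: str = "rbf"
    classify_groups: list = field(default_factory=lambda: ["CN", "CI"])
    seeds: dict = field(default_factory=lambda: {"simulate": 1, "classify": 1})

    def __post_init__(self) -> None:
        for stage in ("simulate", "classify"):
            if stage not in self.seeds or self.seeds[stage] is None:
                raise ValueError(f"config must give an explicit seed for stage {stage!r}")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_cn=self.n_cn, n_smc=self.n_smc, n_ci=self.n_ci,
            n_gray=self.n_gray, n_white=self.n_white,
            n_timepoints=self.n_timepoints, tr_seconds=self.tr_seconds,
            n_sites=self.n_sites, seed=int(self.seeds["simulate"]),
        )

    def ground_truth(self) -> GroundTruth:
        statics = [StaticEdge(int(i), int(j), dict(c)) for i, j, c in self.static_edges]
        dynamics = [
            DynamicEdge(int(i), int(j), dict(c), **extra)
            for i, j, c, *rest in self.dynamic_edges
            for extra in [rest[0] if rest else {}]
        ]
        return GroundTruth(
            static_edges=statics, dynamic_edges=dynamics,
            scale_loadings=dict(self.scale_loadings),
        )


def default_demo_config(
    out_dir: str, seed: int = 1, n_gray: int = 40, n_white: int = 24
) -> PipelineConfig:
    """Small end-to-end demo: planted static + dynamic group differences.

    Planted edges connect the first gray nodes to the first white nodes, so
    they stay valid for any (n_gray, n_white) with at least 6 gray and 3
    white nodes."""
    g = n_gray  # first white node index
    return PipelineConfig(
        out_dir=out_dir,
        n_gray=n_gray,
        n_white=n_white,
        static_edges=[[0, g, {"CN": 0.4, "SMC": 0.4, "CI": 0.1}]],
        dynamic_edges=[
            [2, g + 1, {"CN": 0.0, "SMC": 0.3, "CI": 0.6}, {"period_tr": 60.0}],
            [5, g + 2, {"CN": 0.0, "SMC": 0.2, "CI": 0.5}, {"period_tr": 40.0}],
        ],
        seeds={"simulate": seed, "classify": seed + 1},
    )


def _square_from_triu(triu_values: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    M[iu] = triu_values
    return M + M.T


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seeds": dict(config.seeds), "stages": {}, "files": {}}
    t_all = time.time()

    def _record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
        log.info("stage %s done in %.2fs (%d files)", stage, time.time() - t0, len(paths))

    # --- simulate -----------------------------------------------------------
    t0 = time.time()
    subjects, meta, atlas = generate_cohort(config.cohort_config(), config.ground_truth())
    written = [dio.write_subjects(meta, out / "subjects.tsv"), dio.write_nodes(atlas, out / "nodes.tsv")]
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for ts in subjects:
        written.append(dio.write_timeseries(ts, ts_dir / f"{ts.subject_id}.tsv"))
    written.append(dio.write_json(
        {"static_edges": config.static_edges, "dynamic_edges": config.dynamic_edges,
         "scale_loadings": config.scale_loadings}, out / "truth.json"))
    _record("simulate", written, t0)

    # --- connect ------------------------------------------------------------
    t0 = time.time()
    from .connectivity import bandpass as bp

    if config.bandpass:
        subjects = [bp(ts) for ts in subjects]
    node_ids = atlas.node_ids
    enames = edge_names(node_ids)
    static_rows, dfc_rows = [], {w: [] for w in config.windows}
    written = []
    conn_dir = out / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    for ts in subjects:
        fc = static_fc(ts)
        static_rows.append(upper_triangle(fc.values))
        written.append(dio.write_matrix(fc.values, node_ids, conn_dir / f"{ts.subject_id}_static_z.tsv"))
        for wname in config.windows:
            spec = WindowSpec.from_name(wname)
            dv = dynamic_fc(ts, spec)
            dfc_rows[wname].append(upper_triangle(dv.values))
    _record("connect", written, t0)

    # --- features -----------------------------------------------------------
    t0 = time.time()
    written = []
    tables = {"static": pd.DataFrame(np.vstack(static_rows), index=meta["subject_id"], columns=enames)}
    for wname in config.windows:
        tables[f"dfc_sd_{wname}"] = pd.DataFrame(
            np.vstack(dfc_rows[wname]), index=meta["subject_id"], columns=enames
        )
    if config.combat and config.n_sites > 1:
        group_dummies = pd.get_dummies(meta["group"], drop_first=True).to_numpy(dtype=float)
        for key in tables:
            tables[key] = combat(tables[key], meta["site"].to_numpy(), group_dummies)
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    for key, tab in tables.items():
        p = feat_dir / f"{key}.tsv"
        tab.to_csv(p, sep="\t", float_format="%.10g")
        written.append(p)
    if config.graph_features:
        from .graphs import compute_metrics, threshold_graph

        rows = []
        for i, sid in enumerate(meta["subject_id"]):
            square = _square_from_triu(static_rows[i], len(node_ids))
            fs = compute_metrics(
                threshold_graph(square, config.density),
                seed=int(config.seeds["classify"]),
            )
            rows.append(fs.to_vector().rename(sid))
        gf = pd.DataFrame(rows)
        p = feat_dir / "graph_features.tsv"
        gf.to_csv(p, sep="\t", float_format="%.10g")
        written.append(p)
    _record("features", written, t0)

    # --- stats --------------------------------------------------------------
    t0 = time.time()
    written = []
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    pairs = [("CN", "SMC"), ("CN", "CI"), ("SMC", "CI")]
    for key, tab in tables.items():
        for a, b in pairs:
            ia = meta["group"].to_numpy() == a
            ib = meta["group"].to_numpy() == b
            if ia.sum() < 2 or ib.sum() < 2:
                continue
            diff = differential_connections(
                tab[ia], tab[ib], alpha=config.alpha, correction=config.correction,
                group_pair=(a, b),
            )
            p = stats_dir / f"diff_{a}_vs_{b}_{key}.tsv"
            diff.entries.to_csv(p, sep="\t", index=False, float_format="%.10g")
            written.append(p)
            chord = chord_aggregate(diff, atlas)
            pc = stats_dir / f"chord_{a}_vs_{b}_{key}.tsv"
            chord.to_csv(pc, sep="\t", float_format="%.10g")
            written.append(pc)
    _record("stats", written, t0)

    # --- classify -----------------------------------------------------------
    t0 = time.time()
    written = []
    ga, gb = config.classify_groups
    mask = meta["group"].isin([ga, gb]).to_numpy()
    y = (meta.loc[mask, "group"] == gb).astype(int).to_numpy()
    results = {}
    for key, tab in tables.items():
        spec = ModelSpec(kernel=config.kernel, smote=config.smote, lasso=True)
        report = cross_validate(
            tab[mask].to_numpy(), y, spec, folds=config.folds,
            seed=int(config.seeds["classify"]), feature_names=list(tab.columns),
        )
        results[key] = report.to_dict()
    p = out / "cv_report.json"
    written.append(dio.write_json(results, p))
    _record("classify", written, t0)

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    dio.write_json(manifest, out / "manifest.json")
    return manifest
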