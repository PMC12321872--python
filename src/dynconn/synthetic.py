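"""Synthetic multi-site, multi-group cohort generator with planted coupling.

Node signals follow a latent-factor model: each designated edge (i, j) shares
a latent factor f_e(t), and x_i(t) = sum_e lambda_ie(t) * f_e(t) + noise.
For a *static* edge the loading is constant over time and chosen so that the
expected correlation between the two nodes equals the configured coupling
(for edges not sharing nodes). For a *dynamic* edge the coupling follows a
sinusoidal (default) or two-state Markov-switching schedule, so the
windowed-correlation variability statistic has ground truth to detect.

Clinical scale scores (MMSE/MoCA/CDR-SB analogs) are linear in the subject's
true dynamic-edge modulation amplitude plus Gaussian noise, with configurable
loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AtlasMap, default_atlas
from .connectivity import NodeTimeSeries

GROUPS = ("CN", "SMC", "CI")

# group-level clinical score (mean, sd) used to place generated scales on a
# realistic scale; higher CDR-SB means worse, hence the negated loading below
CLINICAL_SCALES = {
    "mmse": {"CN": (29.0, 1.4), "SMC": (28.9, 1.1), "CI": (25.7, 3.8)},
    "moca": {"CN": (25.8, 2.3), "SMC": (26.1, 2.3), "CI": (21.2, 4.9)},
    "cdr_sb": {"CN": (0.09, 0.21), "SMC": (0.21, 0.72), "CI": (2.68, 2.18)},
}
APOE4_RATE = {"CN": 0.40, "SMC": 0.34, "CI": 0.57}
ABETA_RATE = {"CN": 0.30, "SMC": 0.30, "CI": 0.55}


@dataclass
class CohortConfig:
    """Cohort shape: group sizes, node counts, scan length, sites, seed."""

    n_cn: int = 20
    n_smc: int = 20
    n_ci: int = 20
    n_gray: int = 200
    n_white: int = 128
    n_timepoints: int = 197
    tr_seconds: float = 3.0
    n_sites: int = 1
    seed: int = 0
    noise_sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_cn", "n_smc", "n_ci", "n_gray", "n_white", "n_timepoints", "n_sites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")

    @property
    def n_nodes(self) -> int:
        return self.n_gray + self.n_white

    @property
    def n_subjects(self) -> int:
        return self.n_cn + self.n_smc + self.n_ci

    def group_labels(self) -> list[str]:
        return ["CN"] * self.n_cn + ["SMC"] * self.n_smc + ["CI"] * self.n_ci

    @classmethod
    def imbalanced_preset(
        cls, n_smc: int = 10, imbalance_ratio: float = 8.0, **kwargs
    ) -> "CohortConfig":
        """CI:SMC class imbalance preset (default ratio 8:1)."""
        return cls(n_smc=n_smc, n_ci=int(round(n_smc * imbalance_ratio)), **kwargs)


@dataclass
class StaticEdge:
    """Constant coupling on edge (i, j); per-group expected correlation."""

    i: int
    j: int
    coupling: dict[str, float]

    def coupling_for(self, group: str) -> float:
        return float(self.coupling.get(group, 0.0))


@dataclass
class DynamicEdge:
    """Time-modulated coupling on edge (i, j).

    The coupling schedule is ``baseline + a(t)`` where a(t) is a sinusoid of
    the given period (default) or a two-state Markov switch with mean dwell
    time period/2, scaled by the per-group modulation amplitude. Each
    subject's amplitude is drawn Uniform(amp*(1-jitter), amp*(1+jitter)) so
    cohorts carry inter-subject spread in true dynamic variability; set
    ``jitter=0`` for an exact planted amplitude.
    """

    i: int
    j: int
    amplitude: dict[str, float]
    period_tr: float = 60.0
    baseline: float = 0.0
    schedule: str = "sinusoid"
    jitter: float = 1.0

    def __post_init__(self) -> None:
        if self.period_tr < 2:
            raise ValueError(f"modulation period {self.period_tr} TR is sub-Nyquist (< 2)")
        if self.schedule not in ("sinusoid", "markov"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if any(a < 0 for a in self.amplitude.values()):
            raise ValueError("modulation amplitudes must be >= 0")
        if not (0.0 <= self.jitter <= 1.0):
            raise ValueError("jitter must be in [0, 1]")

    def amplitude_for(self, group: str) -> float:
        return float(self.amplitude.get(group, 0.0))


@dataclass
class GroundTruth:
    """Planted structure: static/dynamic edges, site effects, scale loadings."""

    static_edges: list[StaticEdge] = field(default_factory=list)
    dynamic_edges: list[DynamicEdge] = field(default_factory=list)
    site_additive: list[float] | None = None
    site_scale: list[float] | None = None
    scale_loadings: dict[str, float] = field(default_factory=dict)
    scale_edge: int = 0

    def __post_init__(self) -> None:
        for edges in (self.static_edges, self.dynamic_edges):
            pairs = [(min(e.i, e.j), max(e.i, e.j)) for e in edges]
            if len(pairs) != len(set(pairs)):
                raise ValueError("edge listed more than once")

    def max_node(self) -> int:
        nodes = [e.i for e in self.static_edges + self.dynamic_edges] + [
            e.j for e in self.static_edges + self.dynamic_edges
        ]
        return max(nodes) if nodes else -1


def _loading(c: np.ndarray | float) -> np.ndarray | float:
    """Factor loading giving expected correlation |c| between two nodes with
    unit noise: corr = lam^2/(lam^2+1) => lam = sqrt(|c|/(1-|c|))."""
    c = np.clip(np.abs(c), 0.0, 0.95)
    return np.sqrt(c / (1.0 - c))


def _coupling_schedule(edge: DynamicEdge, amp: float, T: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(T, dtype=float)
    if edge.schedule == "sinusoid":
        phase = rng.uniform(0, 2 * np.pi)
        mod = amp * np.sin(2 * np.pi * t / edge.period_tr + phase)
    else:
        # two-state switch, flip probability set so mean dwell = period/2 TRs
        p_flip = min(1.0, 2.0 / edge.period_tr)
        flips = rng.random(T) < p_flip
        state = np.cumsum(flips) % 2
        mod = amp * (state - 0.5)
    return np.clip(edge.baseline + mod, -0.95, 0.95)


def generate_cohort(
    config: CohortConfig, truth: GroundTruth
) -> tuple[list[NodeTimeSeries], pd.DataFrame, AtlasMap]:
    """Generate node time series, subject metadata, and the atlas map.

    Deterministic under fixed (config, truth): the same seed reproduces
    bit-identical output. Subjects are assigned to sites round-robin; site
    effects (additive offset, multiplicative scale on every node signal)
    apply only when configured in the ground truth.
    """
    if truth.max_node() >= config.n_nodes:
        raise ValueError(
            f"truth references node {truth.max_node()} but cohort has {config.n_nodes} nodes"
        )
    for sed in (truth.site_additive, truth.site_scale):
        if sed is not None and len(sed) != config.n_sites:
            raise ValueError("site effect list length must equal n_sites")
    rng = np.random.default_rng(config.seed)
    atlas = default_atlas(config.n_gray, config.n_white)
    groups = config.group_labels()
    T = config.n_timepoints
    n = config.n_nodes

    subjects: list[NodeTimeSeries] = []
    meta_rows = []
    true_amp = np.zeros(len(groups))  # per-subject amplitude on the scale_edge
    for s, group in enumerate(groups):
        site = s % config.n_sites
        X = rng.normal(0.0, config.noise_sigma, size=(n, T))
        for edge in truth.static_edges:
            c = edge.coupling_for(group)
            if c == 0.0:
                continue
            f = rng.standard_normal(T)
            lam = _loading(c)
            X[edge.i] += lam * f
            X[edge.j] += np.sign(c) * lam * f
        for k, edge in enumerate(truth.dynamic_edges):
            amp_mean = edge.amplitude_for(group)
            if amp_mean > 0:
                amp = amp_mean * (1.0 + edge.jitter * (2.0 * rng.random() - 1.0))
            else:
                amp = 0.0
            if k == truth.scale_edge:
                true_amp[s] = amp
            if amp == 0.0 and edge.baseline == 0.0:
                continue
            c_t = _coupling_schedule(edge, amp, T, rng)
            f = rng.standard_normal(T)
            lam = _loading(c_t)
            X[edge.i] += lam * f
            X[edge.j] += np.sign(c_t) * lam * f
        if truth.site_scale is not None:
            X *= truth.site_scale[site]
        if truth.site_additive is not None:
            X += truth.site_additive[site]
        subjects.append(
            NodeTimeSeries(f"sub{s + 1:04d}", X, config.tr_seconds, list(atlas.node_ids))
        )
        meta_rows.append(
            {
                "subject_id": f"sub{s + 1:04d}",
                "group": group,
                "site": site,
                "apoe4": int(rng.random() < APOE4_RATE[group]),
                "abeta": int(rng.random() < ABETA_RATE[group]),
                "true_amplitude": true_amp[s],
            }
        )
    meta = pd.DataFrame(meta_rows)

    # clinical scales: loading * z-scored true amplitude + orthogonal noise,
    # mapped to each scale's group-level mean/sd
    amp_sd = true_amp.std()
    amp_z = (true_amp - true_amp.mean()) / amp_sd if amp_sd > 0 else np.zeros_like(true_amp)
    for scale, by_group in CLINICAL_SCALES.items():
        loading = float(truth.scale_loadings.get(scale, 0.0))
        loading = float(np.clip(loading, -1.0, 1.0))
        noise = rng.standard_normal(len(groups))
        latent = loading * amp_z + np.sqrt(1.0 - loading**2) * noise
        vals = np.array(
            [by_group[g][0] + by_group[g][1] * latent[s] for s, g in enumerate(groups)]
        )
        meta[scale] = vals
    return subjects, meta, atlas


def generate_voxel_grid(
    n_voxels: int,
    n_clusters: int,
    separation: float,
    n_timepoints: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel time-series fixture with planted cluster structure.

    Voxels in the same true cluster share a latent signal scaled by
    ``separation``, plus unit Gaussian noise. Returns (matrix voxels x time,
    true labels).
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > n_voxels:
        raise ValueError("n_clusters cannot exceed n_voxels")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_voxels) % n_clusters
    latents = rng.standard_normal((n_clusters, n_timepoints))
    noise = rng.standard_normal((n_voxels, n_timepoints))
    data = separation * latents[labels] + noise
    return data, labels
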