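"""Static and tapered sliding-window dynamic functional connectivity.

The computational core of the pipeline: band-pass filtering of node BOLD
signals, (weighted) Pearson correlation, Fisher r-to-z transformation, and
the dynamic-variability statistic — the standard deviation of z-transformed
window-wise correlations across all sliding windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "NodeTimeSeries",
    "WindowSpec",
    "FCMatrix",
    "DFCVariability",
    "bandpass",
    "pearson_r",
    "fisher_z",
    "static_fc",
    "sliding_windows",
    "dynamic_fc",
]

#: correlations are clipped to +/- (1 - Z_CLIP) before arctanh so z stays finite
Z_CLIP = 1e-7


@dataclass
class NodeTimeSeries:
    """One subject's node-by-timepoint BOLD signal matrix.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    data : ndarray, shape (n_nodes, n_timepoints)
        BOLD signal, arbitrary units. Must be finite.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    node_ids : sequence of str
        Ordered node labels matching the atlas map.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (nodes x timepoints), got ndim={self.data.ndim}")
        if self.data.shape[0] < 2:
            raise ValueError("at least 2 nodes required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not self.node_ids:
            self.node_ids = [f"n{i + 1:03d}" for i in range(self.data.shape[0])]
        if len(self.node_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.node_ids)} node_ids for {self.data.shape[0]} data rows"
            )

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class WindowSpec:
    """Sliding-window taper specification.

    shape is one of ``hamming``, ``gaussian``, ``rectangular``; ``length_tr``
    and ``step_tr`` are in TR units. The Gaussian sigma defaults to
    ``length_tr / 6`` so +/-3 sigma spans the window.
    """

    shape: str = "hamming"
    length_tr: int = 30
    step_tr: int = 1
    gaussian_sigma_tr: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("hamming", "gaussian", "rectangular"):
            raise ValueError(f"unknown window shape {self.shape!r}")
        if self.length_tr < 2:
            raise ValueError(f"length_tr must be >= 2, got {self.length_tr}")
        if self.step_tr < 1:
            raise ValueError(f"step_tr must be >= 1, got {self.step_tr}")
        if self.gaussian_sigma_tr is None:
            self.gaussian_sigma_tr = self.length_tr / 6.0
        if self.gaussian_sigma_tr <= 0:
            raise ValueError("gaussian_sigma_tr must be positive")

    def weights(self) -> np.ndarray:
        """Taper weights: strictly positive, normalized to sum to 1."""
        L = self.length_tr
        if self.shape == "hamming":
            w = np.hamming(L)
        elif self.shape == "gaussian":
            w = sps.windows.gaussian(L, std=self.gaussian_sigma_tr)
        else:
            w = np.ones(L)
        return w / w.sum()

    @property
    def name(self) -> str:
        prefix = {"hamming": "ham", "gaussian": "gau", "rectangular": "rect"}[self.shape]
        return f"{prefix}{self.length_tr}"

    @classmethod
    def from_name(cls, name: str, step_tr: int = 1) -> "WindowSpec":
        """Parse short names like ``ham20``, ``gau30``, ``rect50``."""
        name = name.strip().lower()
        for prefix, shape in (("ham", "hamming"), ("gau", "gaussian"), ("rect", "rectangular")):
            if name.startswith(prefix):
                return cls(shape=shape, length_tr=int(name[len(prefix):]), step_tr=step_tr)
        raise ValueError(f"cannot parse window name {name!r}")


@dataclass
class FCMatrix:
    """Symmetric node x node matrix of Fisher-z correlation scores, zero diagonal."""

    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("FCMatrix values must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FCMatrix contains non-finite values")


@dataclass
class DFCVariability:
    """SD of Fisher-z correlations across sliding windows (symmetric, zero diagonal)."""

    values: np.ndarray
    n_windows: int
    window: WindowSpec
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def bandpass(ts: NodeTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08) -> NodeTimeSeries:
    """Zero-phase Butterworth band-pass of every node signal.

    The mean is removed first; forward-backward filtering (``sosfiltfilt``)
    gives zero phase distortion. Raises if the band exceeds the Nyquist
    frequency 1/(2*TR).
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low < high, got low={low_hz}, high={high_hz}")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below Nyquist={nyquist} for TR={ts.tr_seconds}s"
        )
    data = ts.data - ts.data.mean(axis=1, keepdims=True)
    if low_hz == 0:
        sos = sps.butter(4, high_hz, btype="low", fs=1.0 / ts.tr_seconds, output="sos")
    else:
        sos = sps.butter(
            4, [low_hz, high_hz], btype="band", fs=1.0 / ts.tr_seconds, output="sos"
        )
    filtered = sps.sosfiltfilt(sos, data, axis=1)
    return NodeTimeSeries(ts.subject_id, filtered, ts.tr_seconds, list(ts.node_ids))


def pearson_r(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Pearson correlation, optionally taper-weighted.

    With weights w (normalized to sum 1) the weighted mean, covariance and
    variances replace the plain ones; uniform weights reduce exactly to the
    unweighted formula. Zero-variance input yields r = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if weights is None:
        w = np.full(x.size, 1.0 / x.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise ValueError("weights must match data length")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        w = w / w.sum()
    xc = x - np.dot(w, x)
    yc = y - np.dot(w, y)
    vx = np.dot(w, xc * xc)
    vy = np.dot(w, yc * yc)
    if vx <= 0 or vy <= 0:
        warnings.warn("zero-variance input to pearson_r; returning r=0", RuntimeWarning)
        return 0.0
    r = np.dot(w, xc * yc) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def fisher_z(r):
    """Fisher r-to-z: z = 0.5 * ln((1+r)/(1-r)), with |r| clipped to 1 - 1e-7."""
    r = np.clip(np.asarray(r, dtype=float), -(1.0 - Z_CLIP), 1.0 - Z_CLIP)
    z = np.arctanh(r)
    if z.ndim == 0:
        return float(z)
    return z


def _corr_matrix(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted correlation matrix of rows of X; zero-variance rows give r=0."""
    mu = X @ w
    Xc = (X - mu[:, None]) * np.sqrt(w)
    C = Xc @ Xc.T
    d = np.sqrt(np.diag(C))
    bad = d <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} zero-variance node(s) in window; correlations set to 0",
            RuntimeWarning,
        )
        d = np.where(bad, 1.0, d)
    R = C / np.outer(d, d)
    if np.any(bad):
        R[bad, :] = 0.0
        R[:, bad] = 0.0
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def static_fc(ts: NodeTimeSeries) -> FCMatrix:
    """Whole-scan Pearson correlation of all node pairs, Fisher z-transformed.

    With 200 gray + 128 white nodes this is the combined 328 x 328 matrix.
    The diagonal is defined as 0.
    """
    w = np.full(ts.n_timepoints, 1.0 / ts.n_timepoints)
    R = _corr_matrix(ts.data, w)
    Z = fisher_z(R)
    np.fill_diagonal(Z, 0.0)
    Z = (Z + Z.T) / 2.0
    return FCMatrix(values=Z, node_ids=list(ts.node_ids))


def sliding_windows(T: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Ordered half-open 0-based (start, end) window ranges.

    Count = floor((T - L)/step) + 1; consecutive windows share a fraction
    (L - step)/L of their samples.
    """
    L, step = spec.length_tr, spec.step_tr
    if T < L:
        raise ValueError(f"T={T} is shorter than window length {L}")
    n = (T - L) // step + 1
    return [(i * step, i * step + L) for i in range(n)]


def window_overlap(spec: WindowSpec) -> float:
    """Fractional overlap of consecutive windows: (L - step)/L."""
    return (spec.length_tr - spec.step_tr) / spec.length_tr


def dynamic_fc(
    ts: NodeTimeSeries,
    spec: WindowSpec,
    *,
    ddof: int = 0,
    return_stack: bool = False,
):
    """Sliding-window dynamic FC variability.

    For each window the tapered Pearson correlation of every node pair is
    Fisher z-transformed; the dynamic variability of an edge is the standard
    deviation of its z values across all windows (population convention,
    divisor n_windows, by default; ``ddof=1`` for the sample convention).

    Returns a :class:`DFCVariability`, or ``(DFCVariability, z_stack)`` with
    the full (n_windows, n_nodes, n_nodes) z stack when ``return_stack``.
    """
    wins = sliding_windows(ts.n_timepoints, spec)
    if len(wins) < 2:
        raise ValueError(f"only {len(wins)} window(s); SD undefined for < 2")
    w = spec.weights()
    stack = np.empty((len(wins), ts.n_nodes, ts.n_nodes))
    for k, (s, e) in enumerate(wins):
        Z = fisher_z(_corr_matrix(ts.data[:, s:e], w))
        np.fill_diagonal(Z, 0.0)
        stack[k] = (Z + Z.T) / 2.0
    sd = stack.std(axis=0, ddof=ddof)
    np.fill_diagonal(sd, 0.0)
    result = DFCVariability(
        values=sd, n_windows=len(wins), window=spec, node_ids=list(ts.node_ids)
    )
    if return_stack:
        return result, stack
    return result


def upper_triangle(values: np.ndarray) -> np.ndarray:
    """Vectorized strict upper triangle (i < j, row-major), the edge feature order."""
    iu = np.triu_indices(values.shape[0], k=1)
    return np.asarray(values)[iu]


def edge_names(node_ids: list[str]) -> list[str]:
    """Edge labels ``a-b`` in the same i < j row-major order as :func:`upper_triangle`."""
    n = len(node_ids)
    return [f"{node_ids[i]}-{node_ids[j]}" for i in range(n) for j in range(i + 1, n)]
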