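"""Temporal cleaning, correlation matrices, and sparsity binarization.

The chain mirrors the standard resting-state functional-connectivity
recipe: per-region linear detrending, an ideal FFT band-pass restricted
to the low-frequency BOLD band (0.01-0.1 Hz), Pearson correlation over
all region pairs, and binarization of the correlation matrix at a sweep
of sparsity (edge-density) thresholds, by default 0.10 to 0.50 in steps
of 0.01 (41 levels).

Binarization keeps the top ``round_half_up(s * N(N-1)/2)`` off-diagonal
pairs ranked by *signed* correlation (strong negative correlations are
not edges), with ties broken lexicographically by (i, j) so the result
is fully deterministic.  Because every threshold keeps a prefix of the
same ranking, edge sets are nested across the sweep by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atlas import ConfigurationError, TimeSeriesMatrix, ValidationError


@dataclass(frozen=True)
class SparsityGrid:
    """Strictly increasing sparsity thresholds in (0, 1)."""

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size < 1 or not np.all(np.diff(t) > 0):
            raise ConfigurationError("sparsity grid must be strictly increasing")
        if t[0] <= 0 or t[-1] >= 1:
            raise ConfigurationError("sparsity thresholds must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.thresholds)

    def __iter__(self):
        return iter(self.thresholds)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.thresholds, dtype=float)

    @classmethod
    def default(cls) -> "SparsityGrid":
        return cls.from_spec(10, 50, 1)

    @classmethod
    def from_spec(cls, start_pct: int, stop_pct: int, step_pct: int) -> "SparsityGrid":
        """Build from integer percent bounds, e.g. (10, 50, 1) -> 0.10..0.50."""
        pts = np.arange(start_pct, stop_pct + 1, step_pct) / 100.0
        return cls(tuple(float(p) for p in pts))

    @classmethod
    def parse(cls, text: str) -> "SparsityGrid":
        """Parse 'start:stop:step' in fractional units, e.g. '0.10:0.50:0.01'."""
        try:
            a, b, c = (float(x) for x in text.split(":"))
        except ValueError:
            raise ConfigurationError(f"bad grid spec {text!r}") from None
        return cls.from_spec(round(a * 100), round(b * 100), round(c * 100))


@dataclass
class CorrelationMatrix:
    subject_id: str
    values: np.ndarray  # N x N, symmetric, unit diagonal
    n_timepoints: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("correlation matrix must be square")
        if not np.isfinite(v).all():
            raise ValidationError("correlation matrix contains non-finite values")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected unweighted graph at one sparsity level.

    ``adjacency`` is a symmetric boolean matrix with zero diagonal;
    ``edges`` lists the kept pairs as 0-based (i, j), i < j, in ranking
    order (highest correlation first).
    """

    subject_id: str
    adjacency: np.ndarray
    sparsity: float  # source threshold s
    edges: np.ndarray = field(repr=False)  # (m, 2) int array

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def achieved_sparsity(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / (n * (n - 1))


def discard_initial(ts: TimeSeriesMatrix, n_volumes: int) -> TimeSeriesMatrix:
    """Drop the first ``n_volumes`` time points (scanner equilibration)."""
    if n_volumes < 0 or ts.n_timepoints - n_volumes < 3:
        raise ValidationError(
            f"{ts.subject_id}: cannot discard {n_volumes} of {ts.n_timepoints} volumes"
        )
    if n_volumes == 0:
        return ts
    return TimeSeriesMatrix(ts.subject_id, ts.data[n_volumes:], ts.tr_seconds)


def detrend_linear(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Remove the least-squares line (slope + intercept) from each column."""
    T = ts.n_timepoints
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t])
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return TimeSeriesMatrix(ts.subject_id, resid, ts.tr_seconds)


def bandpass(ts: TimeSeriesMatrix, low_hz: float = 0.01, high_hz: float = 0.1) -> TimeSeriesMatrix:
    """Ideal FFT band-pass: keep bins with low <= f <= high, zero the rest.

    The DC bin is always removed, so the output is zero-mean.  The ideal
    (brick-wall) filter is exactly reproducible and has no order/ripple
    parameters; ringing at the record edges is accepted at these lengths.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not 0 <= low_hz < high_hz:
        raise ConfigurationError("need 0 <= low < high")
    if high_hz >= nyquist:
        raise ConfigurationError(
            f"high cutoff {high_hz} Hz >= Nyquist {nyquist} Hz for TR={ts.tr_seconds}s"
        )
    T = ts.n_timepoints
    freqs = np.fft.rfftfreq(T, d=ts.tr_seconds)
    spectrum = np.fft.rfft(ts.data, axis=0)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    spectrum[~keep, :] = 0.0
    out = np.fft.irfft(spectrum, n=T, axis=0)
    return TimeSeriesMatrix(ts.subject_id, out, ts.tr_seconds)


def correlation_matrix(ts: TimeSeriesMatrix, atlas=None) -> CorrelationMatrix:
    """Pearson correlation over all region pairs; diagonal set to 1."""
    zero = np.flatnonzero(np.ptp(ts.data, axis=0) == 0)
    if zero.size:
        name = atlas.abbrevs[zero[0]] if atlas is not None else f"column {zero[0]}"
        raise ValidationError(
            f"{ts.subject_id}: zero-variance region {name}; cannot correlate"
        )
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(ts.subject_id, r, ts.n_timepoints)


def target_edge_count(s: float, n_nodes: int) -> int:
    """Edges kept at sparsity s: round-half-up of s * N(N-1)/2."""
    if not 0 < s < 1:
        raise ConfigurationError(f"sparsity must be in (0, 1), got {s}")
    m_possible = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(s * m_possible + 0.5))


def rank_edge_order(values: np.ndarray) -> np.ndarray:
    """All off-diagonal upper-triangle pairs ordered by signed value
    descending, ties by (i, j) lexicographic.  Returns an (M, 2) array."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    r = values[iu, ju]
    order = np.lexsort((ju, iu, -r))
    return np.column_stack([iu[order], ju[order]])


def _adjacency_from_edges(edges: np.ndarray, n: int) -> np.ndarray:
    A = np.zeros((n, n), dtype=bool)
    if len(edges):
        A[edges[:, 0], edges[:, 1]] = True
        A[edges[:, 1], edges[:, 0]] = True
    return A


def binarize_at_sparsity(corr: CorrelationMatrix, s: float) -> BinaryNetwork:
    """Keep the top target_edge_count(s, N) pairs by signed correlation."""
    ranked = rank_edge_order(corr.values)
    m = target_edge_count(s, corr.n_regions)
    edges = ranked[:m]
    return BinaryNetwork(
        subject_id=corr.subject_id,
        adjacency=_adjacency_from_edges(edges, corr.n_regions),
        sparsity=s,
        edges=edges,
    )


def binarize_sweep(corr: CorrelationMatrix, grid: SparsityGrid) -> list[BinaryNetwork]:
    """Binarize at every grid threshold, ranking the pairs once.

    Edge sets are prefixes of one ranking, hence nested across the grid.
    """
    ranked = rank_edge_order(corr.values)
    nets = []
    for s in grid:
        m = target_edge_count(s, corr.n_regions)
        edges = ranked[:m]
        nets.append(
            BinaryNetwork(
                subject_id=corr.subject_id,
                adjacency=_adjacency_from_edges(edges, corr.n_regions),
                sparsity=s,
                edges=edges,
            )
        )
    return nets


def clean_timeseries(ts: TimeSeriesMatrix, *, low_hz: float = 0.01,
                     high_hz: float = 0.1, n_discard: int = 0) -> TimeSeriesMatrix:
    """discard -> detrend -> band-pass, the full temporal cleaning chain."""
    return bandpass(detrend_linear(discard_initial(ts, n_discard)), low_hz, high_hz)


def build_networks(ts: TimeSeriesMatrix, grid: SparsityGrid, *,
                   low_hz: float = 0.01, high_hz: float = 0.1,
                   n_discard: int = 0, atlas=None) -> list[BinaryNetwork]:
    """Full per-subject chain: clean -> correlate -> binarize over the grid."""
    clean = clean_timeseries(ts, low_hz=low_hz, high_hz=high_hz, n_discard=n_discard)
    corr = correlation_matrix(clean, atlas=atlas)
    return binarize_sweep(corr, grid)


def write_correlation(corr: CorrelationMatrix, path) -> None:
    np.savetxt(path, corr.values, fmt="%.17g", delimiter="\t")


def write_edge_list(net: BinaryNetwork, path) -> None:
    """Edge list, one 'i<TAB>j' pair per line, i < j, 1-based atlas indices."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in sorted(map(tuple, net.edges)):
            fh.write(f"{i + 1}\t{j + 1}\n")


def read_edge_list(path, n_nodes: int, sparsity: float = 0.0,
                   subject_id: str = "") -> BinaryNetwork:
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            i, j = (int(x) for x in line.split())
            if not 1 <= i < j <= n_nodes:
                raise ValidationError(f"{path}: bad edge {i} {j}")
            pairs.append((i - 1, j - 1))
    edges = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return BinaryNetwork(
        subject_id=subject_id,
        adjacency=_adjacency_from_edges(edges, n_nodes),
        sparsity=sparsity,
        edges=edges,
    )
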