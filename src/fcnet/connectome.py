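"""From regional time series to thresholded weighted networks.

The construction chain is the standard one for weighted resting-state
connectomes: optional band-pass of the regional signals, Pearson
correlation between every pair of regions, Fisher r-to-z
variance stabilization, nuisance regression of age/gender/education
from every edge across subjects, and proportional-sparsity
thresholding (keep the top fraction of edges by weight) over a sweep
of sparsity levels, 10-40% in 1% steps by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_SPARSITY_MIN = 0.10
DEFAULT_SPARSITY_MAX = 0.40
DEFAULT_SPARSITY_STEP = 0.01

#: band retained by default, in Hz (slow spontaneous fluctuations).
DEFAULT_BAND = (0.01, 0.08)

DEFAULT_COVARIATES = ("age", "gender", "education")


@dataclass
class ROITimeSeries:
    """T x N matrix of regional signals for one subject."""

    values: np.ndarray
    region_names: list[str]
    sampling_interval: float = 2.0  # seconds (repetition time)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D array")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.values.shape[1] != len(self.region_names):
            raise ValueError(
                f"{self.values.shape[1]} columns vs {len(self.region_names)} region names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")


@dataclass
class ConnectivityMatrix:
    """N x N symmetric Fisher-z edge-weight matrix, zero diagonal."""

    z: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity matrix contains non-finite values")
        if not self.region_names:
            self.region_names = [f"R{i + 1:03d}" for i in range(n)]

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class SparsityGraph:
    """Top-K edges of a connectivity matrix at one sparsity level.

    Edge arrays are aligned: ``(i[k], j[k], w[k])`` with ``i < j``.
    """

    sparsity: float
    n_nodes: int
    i: np.ndarray
    j: np.ndarray
    w: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.w)

    def to_matrix(self) -> np.ndarray:
        mat = np.zeros((self.n_nodes, self.n_nodes))
        mat[self.i, self.j] = self.w
        mat[self.j, self.i] = self.w
        return mat

    def edge_set(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))


def bandpass(
    ts: ROITimeSeries,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    transition_hz: float = 0.005,
) -> ROITimeSeries:
    """Zero-phase frequency-domain band-pass with a cosine taper.

    Column means (the DC component) are removed; content outside
    ``[low_hz, high_hz]`` is attenuated, with a raised-cosine
    transition of half-width ``transition_hz`` on either side.
    """
    nyquist = 0.5 / ts.sampling_interval
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    x = ts.values - ts.values.mean(axis=0, keepdims=True)
    t = x.shape[0]
    freqs = np.fft.rfftfreq(t, d=ts.sampling_interval)
    gain = np.zeros_like(freqs)
    w = transition_hz
    inside = (freqs >= low_hz) & (freqs <= high_hz)
    gain[inside] = 1.0
    lo_ramp = (freqs > low_hz - w) & (freqs < low_hz)
    gain[lo_ramp] = 0.5 * (1 + np.cos(np.pi * (low_hz - freqs[lo_ramp]) / w))
    hi_ramp = (freqs > high_hz) & (freqs < high_hz + w)
    gain[hi_ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_ramp] - high_hz) / w))
    gain[0] = 0.0  # DC always removed
    spec = np.fft.rfft(x, axis=0)
    filtered = np.fft.irfft(spec * gain[:, None], n=t, axis=0)
    return ROITimeSeries(filtered, list(ts.region_names), ts.sampling_interval)


def pearson_connectivity(ts: ROITimeSeries) -> np.ndarray:
    """Pairwise Pearson correlation of the regional signals."""
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.region_names[k] for k in dead]
        raise ValueError(f"zero-variance time series for region(s): {names}")
    corr = np.corrcoef(ts.values, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def fisher_z(
    corr: np.ndarray, region_names: Sequence[str] | None = None
) -> ConnectivityMatrix:
    """Fisher r-to-z transform, ``z = atanh(r)``, with zero diagonal.

    Off-diagonal correlations within 1e-7 of +/-1 are clipped before
    the transform so the result stays finite.
    """
    corr = np.asarray(corr, dtype=float)
    clipped = np.clip(corr, -1.0 + 1e-7, 1.0 - 1e-7)
    z = np.arctanh(clipped)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, list(region_names or []))


def connectivity_from_timeseries(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation followed by the Fisher transform."""
    return fisher_z(pearson_connectivity(ts), ts.region_names)


def regress_covariates(
    matrices: Sequence[ConnectivityMatrix],
    covariates: pd.DataFrame,
    columns: Sequence[str] = DEFAULT_COVARIATES,
) -> list[ConnectivityMatrix]:
    """Remove nuisance covariates from every edge across subjects.

    For each edge, the Fisher-z weights are regressed on an intercept
    plus the mean-centered covariates by ordinary least squares; the
    corrected weight is the residual plus the intercept (the edge mean),
    so corrected weights keep the Fisher-z scale while being
    uncorrelated with every covariate.  Constant covariate columns are
    dropped with a warning.
    """
    n_sub = len(matrices)
    if n_sub != len(covariates):
        raise ValueError("covariate table must have one row per subject")
    keep = []
    for col in columns:
        vals = np.asarray(covariates[col], dtype=float)
        if np.ptp(vals) == 0:
            warnings.warn(
                f"covariate {col!r} is constant across subjects; dropped from the model",
                stacklevel=2,
            )
        else:
            keep.append(col)
    p = len(keep)
    if n_sub < p + 2:
        raise ValueError(
            f"need at least {p + 2} subjects to regress {p} covariates, got {n_sub}"
        )
    n = matrices[0].n_regions
    iu = np.triu_indices(n, k=1)
    y = np.stack([m.z[iu] for m in matrices])  # subjects x edges
    design = np.ones((n_sub, p + 1))
    for k, col in enumerate(keep):
        vals = np.asarray(covariates[col], dtype=float)
        design[:, k + 1] = vals - vals.mean()
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    corrected = y - design @ beta + beta[0]  # residual + intercept
    out = []
    for s, m in enumerate(matrices):
        z = np.zeros_like(m.z)
        z[iu] = corrected[s]
        z = z + z.T
        out.append(ConnectivityMatrix(z, list(m.region_names)))
    return out


def edge_count(n_nodes: int, sparsity: float) -> int:
    """Edges retained at a sparsity level: round half away from zero."""
    total = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * total + 0.5))


def threshold_sparsity(
    m: ConnectivityMatrix, sparsity: float, absolute: bool = False
) -> SparsityGraph:
    """Keep the top-K weighted edges at the given sparsity.

    K = round(sparsity * N(N-1)/2), half away from zero.  Edges are
    ranked by signed weight (or by magnitude with ``absolute=True``);
    ties at the cutoff break by ascending (i, j) order.  Retaining a
    non-positive weight in signed mode is an error, because the
    downstream metrics require positive weights.
    """
    if not (0.0 < sparsity <= 1.0):
        raise ValueError("sparsity must lie in (0, 1]")
    n = m.n_regions
    iu, ju = np.triu_indices(n, k=1)
    w = m.z[iu, ju]
    k = edge_count(n, sparsity)
    rank_w = np.abs(w) if absolute else w
    order = np.lexsort((ju, iu, -rank_w))
    sel = order[:k]
    wi, wj, ww = iu[sel], ju[sel], w[sel]
    if not absolute and k > 0 and ww.min() <= 0:
        raise ValueError(
            f"sparsity {sparsity:.2f} would retain a non-positive weight "
            f"({ww.min():.4g}); use absolute-value ranking or a lower sparsity"
        )
    resort = np.lexsort((wj, wi))
    return SparsityGraph(sparsity, n, wi[resort], wj[resort], ww[resort])


def sparsity_grid(
    s_min: float = DEFAULT_SPARSITY_MIN,
    s_max: float = DEFAULT_SPARSITY_MAX,
    step: float = DEFAULT_SPARSITY_STEP,
) -> np.ndarray:
    if step <= 0:
        raise ValueError("step must be positive")
    if s_min > s_max:
        raise ValueError("s_min must not exceed s_max")
    n_steps = int(round((s_max - s_min) / step))
    grid = s_min + step * np.arange(n_steps + 1)
    return np.round(grid, 10)


def sparsity_sweep(
    m: ConnectivityMatrix,
    s_min: float = DEFAULT_SPARSITY_MIN,
    s_max: float = DEFAULT_SPARSITY_MAX,
    step: float = DEFAULT_SPARSITY_STEP,
    absolute: bool = False,
) -> list[SparsityGraph]:
    """One thresholded graph per sparsity level, endpoints inclusive.

    Because edge sets are nested across the sweep, the edge ranking is
    computed once and each level takes a prefix; results are identical
    to thresholding each level independently.
    """
    grid = sparsity_grid(s_min, s_max, step)
    n = m.n_regions
    iu, ju = np.triu_indices(n, k=1)
    w = m.z[iu, ju]
    rank_w = np.abs(w) if absolute else w
    order = np.lexsort((ju, iu, -rank_w))
    out = []
    for s in grid:
        k = edge_count(n, s)
        sel = order[:k]
        wi, wj, ww = iu[sel], ju[sel], w[sel]
        if not absolute and k > 0 and ww.min() <= 0:
            raise ValueError(
                f"sparsity {s:.2f} would retain a non-positive weight "
                f"({ww.min():.4g}); use absolute-value ranking or a lower sparsity"
            )
        resort = np.lexsort((wj, wi))
        out.append(SparsityGraph(float(s), n, wi[resort], wj[resort], ww[resort]))
    return out
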