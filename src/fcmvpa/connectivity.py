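"""Task-dependent (PPI-style) node time-series and connectivity features.

The chain, per node and per subject:

1. extract the 27 voxel-wise BOLD series of the node cube;
2. deconvolve each series against the canonical HRF to estimate the
   underlying neural-level signal (ridge-regularized Toeplitz inversion,
   penalty chosen by generalized cross-validation);
3. detrend (remove intercept + linear drift);
4. multiply elementwise by the psychological factor: +1 sticks at
   Remember-hit onsets, -1 at Know-hit onsets, 0 elsewhere;
5. re-convolve with the canonical HRF (causal, truncated to run length)
   and detrend again;
6. average the 27 voxel series into one representative node series.

Pairwise zero-lag Pearson correlations between the 16 node series over
the whole run give the connectivity matrix; the lower triangle (120
values for 16 nodes) is the subject's feature vector.  Raw r values are
used throughout — no Fisher z transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.signal
from scipy import stats

from .nodes import VoxelTimeSeriesBlock

__all__ = [
    "HRFKernel",
    "PsychFactor",
    "NodeSignalSet",
    "ConnectivityFeatures",
    "canonical_hrf",
    "make_psych_factor",
    "deconvolve_bold",
    "detrend",
    "ppi_node_series",
    "connectivity_features",
    "lower_triangle_pairs",
    "edge_name",
]

# ---------------------------------------------------------------------------
# Canonical HRF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HRFKernel:
    """Double-gamma hemodynamic response kernel sampled at TR resolution.

    The default parameterization is the canonical one: response peak at
    6 s, undershoot peak at 16 s, unit dispersions, peak:undershoot ratio
    6, kernel length 32 s.  Values are scaled so the kernel maximum is 1.
    """

    values: np.ndarray
    tr: float
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0 or not np.all(np.isfinite(v)):
            raise ValueError("kernel values must be a finite 1-D array")
        if v.sum() <= 0:
            raise ValueError("kernel must sum to a positive value")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def canonical_hrf(
    tr: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    ratio: float = 6.0,
    length: float = 32.0,
) -> HRFKernel:
    """Sample the canonical double-gamma HRF on the TR grid 0..length.

    h(t) = Gamma(t; peak_delay/disp, disp) - Gamma(t; u_delay/u_disp, u_disp)/ratio,
    normalized to unit maximum.  With the defaults the mode of the
    positive lobe sits just under 5 s.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, length + tr / 2, tr)
    h = stats.gamma.pdf(
        t, peak_delay / peak_dispersion, scale=peak_dispersion
    ) - stats.gamma.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    ) / ratio
    h = h / np.max(h)
    return HRFKernel(
        values=h,
        tr=float(tr),
        peak_delay=peak_delay,
        undershoot_delay=undershoot_delay,
        peak_dispersion=peak_dispersion,
        undershoot_dispersion=undershoot_dispersion,
        ratio=ratio,
        length=length,
    )


# ---------------------------------------------------------------------------
# Psychological factor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychFactor:
    """Condition-contrast stick vector: +1 at R-hit onsets, -1 at K-hit onsets."""

    values: np.ndarray  # length n_volumes, entries in {+1, 0, -1}
    tr: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isin(v, (-1.0, 0.0, 1.0))):
            raise ValueError("psych factor entries must be in {+1, -1, 0}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def make_psych_factor(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    positive_label: str = "R-hit",
    negative_label: str = "K-hit",
) -> PsychFactor:
    """Build the R-hit/K-hit contrast stick vector at TR resolution.

    Onsets are binned to the nearest TR index (no microtime upsampling).
    Trials with any other label contribute nothing.  Two opposite-sign
    onsets landing in the same bin make the stick ambiguous and raise,
    reporting the offending trial row indices.
    """
    values = np.zeros(int(n_volumes))
    sign_of = {positive_label: 1.0, negative_label: -1.0}
    claimed: dict[int, tuple[float, int]] = {}
    for row_idx, row in enumerate(events.itertuples(index=False)):
        sign = sign_of.get(row.trial_type)
        if sign is None:
            continue
        b = int(np.floor(row.onset / tr + 0.5))
        if not 0 <= b < n_volumes:
            raise ValueError(
                f"trial {row_idx} onset {row.onset} s falls outside the run"
            )
        if b in claimed and claimed[b][0] != sign:
            raise ValueError(
                f"opposite-sign onsets share TR bin {b}: "
                f"trials {claimed[b][1]} and {row_idx}"
            )
        claimed[b] = (sign, row_idx)
        values[b] = sign
    return PsychFactor(values=values, tr=float(tr))


# ---------------------------------------------------------------------------
# Deconvolution and detrending
# ---------------------------------------------------------------------------

#: Relative ridge grid for GCV, scaled by the largest squared singular value.
_GCV_GRID = np.logspace(-12.0, 1.0, 40)


def _design_matrix(kernel: np.ndarray, n_obs: int, n_out: int) -> np.ndarray:
    col = np.zeros(n_obs)
    upto = min(kernel.size, n_obs)
    col[:upto] = kernel[:upto]
    return scipy.linalg.toeplitz(col, np.zeros(n_out))


_SVD_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _design_svd(kernel: np.ndarray, n_obs: int, n_out: int):
    """SVD of the convolution design, cached per (kernel, shape).

    The same kernel and run length recur for every voxel of every subject,
    so one 360x360 SVD serves the whole cohort.
    """
    key = (kernel.tobytes(), n_obs, n_out)
    if key not in _SVD_CACHE:
        if len(_SVD_CACHE) > 8:
            _SVD_CACHE.clear()
        A = _design_matrix(kernel, n_obs, n_out)
        _SVD_CACHE[key] = np.linalg.svd(A, full_matrices=False)
    return _SVD_CACHE[key]


def deconvolve_bold(
    series: np.ndarray,
    hrf: HRFKernel,
    lam: float | str = "gcv",
    n_out: int | None = None,
) -> np.ndarray:
    """Estimate the neural-level signal whose HRF convolution gives ``series``.

    Solves the ridge-penalized least-squares inverse of the causal Toeplitz
    convolution operator.  ``lam`` is either a fixed penalty or ``"gcv"``
    (default), which minimizes generalized cross-validation per series over
    a log-spaced grid.  ``n_out`` is the length of the neural estimate:
    by default ``len(series) - len(hrf) + 1`` (the fully determined inverse
    of a full-mode convolution); pass ``n_out=len(series)`` to deconvolve a
    run in place, accepting an edge effect in the final samples.

    Accepts a 1-D series or a stack of series in the rows of a 2-D array.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[None, :]
    n_obs = y.shape[1]
    kernel = hrf.values
    if n_obs < kernel.size:
        raise ValueError("series must be at least as long as the HRF kernel")
    if n_out is None:
        n_out = n_obs - kernel.size + 1
    if not 1 <= n_out <= n_obs:
        raise ValueError("n_out must lie in [1, len(series)]")

    U, s, Vt = _design_svd(kernel, n_obs, n_out)
    if isinstance(lam, str):
        if lam != "gcv":
            raise ValueError("lam must be a number or 'gcv'")
        lam_values = _gcv_lambda(U, s, y)
    else:
        lam = float(lam)
        if lam < 0:
            raise ValueError("lam must be non-negative")
        if lam == 0 and s[-1] < 1e-10 * s[0]:
            raise ValueError(
                "convolution operator is numerically singular at lam=0; "
                "pass a positive ridge penalty (or lam='gcv')"
            )
        lam_values = np.full(y.shape[0], lam)

    z = y @ U  # (m, r) coefficients in the left singular basis
    shrink = s[None, :] / (s[None, :] ** 2 + lam_values[:, None])
    out = (z * shrink) @ Vt
    return out[0] if squeeze else out


def _gcv_lambda(U: np.ndarray, s: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-series GCV-minimizing ridge penalty over a relative log grid."""
    n_obs = y.shape[1]
    z = y @ U
    total = np.sum(y**2, axis=1)
    resid0 = np.maximum(total - np.sum(z**2, axis=1), 0.0)  # outside col space
    grid = _GCV_GRID * s[0] ** 2
    best_lam = np.full(y.shape[0], grid[0])
    best_gcv = np.full(y.shape[0], np.inf)
    for lam in grid:
        f = lam / (s**2 + lam)  # shrinkage residual factors
        rss = resid0 + np.sum((z * f[None, :]) ** 2, axis=1)
        df = n_obs - np.sum(s**2 / (s**2 + lam))
        gcv = n_obs * rss / df**2
        better = gcv < best_gcv
        best_gcv[better] = gcv[better]
        best_lam[better] = lam
    return best_lam


def detrend(series: np.ndarray) -> np.ndarray:
    """Remove intercept and linear trend (least squares) along the last axis."""
    y = np.asarray(series, dtype=float)
    if y.shape[-1] < 3:
        raise ValueError("series must have length >= 3")
    return scipy.signal.detrend(y, axis=-1, type="linear")


def _causal_convolve(rows: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution of each row, truncated to the input length."""
    n = rows.shape[-1]
    full = scipy.signal.fftconvolve(rows, kernel[None, :], axes=-1)
    return full[..., :n]


# ---------------------------------------------------------------------------
# PPI node series
# ---------------------------------------------------------------------------


def ppi_node_series(
    block: VoxelTimeSeriesBlock,
    psych: PsychFactor,
    hrf: HRFKernel,
    lam: float | str = "gcv",
) -> np.ndarray:
    """One node's task-dependent series: the voxel-average PPI time-series.

    Per voxel: deconvolve -> detrend -> multiply by the psych sticks ->
    re-convolve with the HRF (causal, run length) -> detrend; the 27 voxel
    series are averaged last.

    The raw voxel series are detrended once before deconvolution: the
    convolution model has no intercept, so a scanner baseline or slow
    drift would otherwise deconvolve into a structured artifact shared by
    every voxel and inflate all pairwise correlations.
    """
    n_vol = block.series.shape[1]
    if len(psych) != n_vol:
        raise ValueError("psych factor length must match the number of volumes")
    neural = deconvolve_bold(detrend(block.series), hrf, lam=lam, n_out=n_vol)
    neural = detrend(neural)
    interaction = neural * psych.values[None, :]
    bold_like = _causal_convolve(interaction, hrf.values)
    bold_like = detrend(bold_like)
    return bold_like.mean(axis=0)


@dataclass
class NodeSignalSet:
    """The per-subject stack of task-dependent node series (nodes x volumes)."""

    subject_id: str
    signals: np.ndarray  # (n_nodes, n_volumes)
    node_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a nodes x volumes matrix")
        if self.signals.shape[0] != len(self.node_names):
            raise ValueError("one name per node series required")

    @property
    def n_nodes(self) -> int:
        return self.signals.shape[0]


# ---------------------------------------------------------------------------
# Connectivity features
# ---------------------------------------------------------------------------


def lower_triangle_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """Row-major lower-triangle index pairs (i, j) with i > j."""
    return [(i, j) for i in range(1, n_nodes) for j in range(i)]


def edge_name(names: Sequence[str], i: int, j: int) -> str:
    """Human-readable edge label; the lower-index node is named first."""
    a, b = sorted((i, j))
    return f"{names[a]} ~ {names[b]}"


@dataclass
class ConnectivityFeatures:
    """Lower-triangle Pearson r features for one subject."""

    subject_id: str
    values: np.ndarray  # length n_nodes*(n_nodes-1)/2
    edge_pairs: tuple[tuple[int, int], ...]
    edge_names: tuple[str, ...]
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.edge_pairs):
            raise ValueError("one value per edge required")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("Pearson r values must lie in [-1, 1]")


def connectivity_features(signals: NodeSignalSet) -> ConnectivityFeatures:
    """Full pairwise Pearson correlation matrix, vectorized lower triangle.

    Raises if any node series is constant (its correlation is undefined),
    naming the node.
    """
    X = signals.signals
    sd = X.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [signals.node_names[i] for i in constant]
        raise ValueError(f"constant node series (r undefined): {names}")
    R = np.corrcoef(X)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    pairs = lower_triangle_pairs(signals.n_nodes)
    values = np.array([R[i, j] for i, j in pairs])
    names = tuple(edge_name(signals.node_names, i, j) for i, j in pairs)
    return ConnectivityFeatures(
        subject_id=signals.subject_id,
        values=values,
        edge_pairs=tuple(pairs),
        edge_names=names,
        matrix=R,
    )
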