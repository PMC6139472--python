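"""Synthetic two-group event-related fMRI cohorts with known coupling effects.

The generator emulates the statistical structure the PPI pipeline
measures: each subject performs a Remember/Know recognition test run
(120 old + 60 new items, back-to-back 4-s trials, TR = 2 s, 360 volumes)
while 16 latent node signals evolve with condition-dependent inter-node
correlation.  On designated "effect" edges the Remember-hit epochs of
one group (PP by convention, for positive delta_rho) are generated at
``base_rho + delta_rho`` while Know-hit epochs and all other edges stay
at ``base_rho``; the Remember-minus-Know coupling difference therefore
differs between groups by exactly ``delta_rho``, which is the quantity
the downstream PPI contrast estimates.

Latent signals are rendered to 4D BOLD by convolving with the canonical
HRF and adding the node signal to all 27 voxels of its cube, on top of a
baseline + linear drift + white Gaussian noise background.  Everything is
a pure function of the config (master seed included): per-subject seeds
are derived deterministically, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .connectivity import HRFKernel, canonical_hrf
from .nodes import NodeSpec, build_node_cube

__all__ = [
    "SimCohortConfig",
    "SimSubject",
    "default_affine",
    "synthetic_node_centers",
    "generate_events",
    "simulate_node_neural",
    "render_bold",
    "generate_cohort",
    "iter_cohort",
]

# Trial outcome labels on the recognition test:
OLD_LABELS = ("R-hit", "K-hit", "miss")
NEW_LABELS = ("CR", "FA")


def default_affine(grid_shape: Sequence[int], voxel_size: float = 3.0) -> np.ndarray:
    """Diagonal RAS+ affine with the mm origin at the grid centre."""
    shape = np.asarray(grid_shape, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * voxel_size
    aff[:3, 3] = -voxel_size * (shape - 1) / 2.0
    return aff


def synthetic_node_centers(
    n_nodes: int, grid_shape: Sequence[int], voxel_size: float = 3.0
) -> np.ndarray:
    """Evenly spaced, non-overlapping cube centres inside a grid (mm, RAS+).

    A convenience for tests and demos on compact grids where anatomical
    coordinates would not fit; centres sit on a 3-voxel lattice with a
    1-voxel margin so every 3x3x3 cube is interior and disjoint.
    """
    shape = np.asarray(grid_shape, dtype=int)
    axes = [np.arange(1, s - 1, 3) for s in shape]
    lattice = np.array(
        [(i, j, k) for i in axes[0] for j in axes[1] for k in axes[2]], dtype=float
    )
    if len(lattice) < n_nodes:
        raise ValueError(
            f"grid {tuple(shape)} fits only {len(lattice)} disjoint cubes, "
            f"{n_nodes} requested"
        )
    # spread picks across the lattice rather than filling one corner
    picks = np.linspace(0, len(lattice) - 1, n_nodes).round().astype(int)
    aff = default_affine(shape, voxel_size)
    return lattice[picks] @ aff[:3, :3].T + aff[:3, 3]


@dataclass(frozen=True)
class SimCohortConfig:
    """Cohort-level simulation parameters (defaults emulate the study protocol)."""

    n_ctrl: int = 27
    n_pp: int = 25
    n_volumes: int = 360
    tr_seconds: float = 2.0
    n_old_items: int = 120
    n_new_items: int = 60
    trial_duration_s: float = 4.0
    node_centers: tuple[tuple[float, float, float], ...] | None = None
    node_names: tuple[str, ...] | None = None
    effect_edges: tuple[tuple[tuple[int, int], float], ...] = ()
    base_rho: float = 0.1
    noise_sd: float = 0.5
    drift_amplitude: float = 1.0
    signal_scale: float = 1.0
    baseline: float = 100.0
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size: float = 3.0
    # old-item response mix (R-hit, K-hit, miss) and new-item FA rate
    response_props: tuple[float, float, float] = (0.45, 0.35, 0.20)
    fa_rate: float = 0.10
    n_nodes: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ctrl, self.n_pp) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.tr_seconds <= 0 or self.trial_duration_s <= 0:
            raise ValueError("tr_seconds and trial_duration_s must be positive")
        run_s = self.n_volumes * self.tr_seconds
        need_s = (self.n_old_items + self.n_new_items) * self.trial_duration_s
        if need_s > run_s:
            raise ValueError(
                f"run too short: {self.n_old_items + self.n_new_items} trials x "
                f"{self.trial_duration_s} s = {need_s} s exceed the "
                f"{run_s} s run ({self.n_volumes} volumes x {self.tr_seconds} s)"
            )
        if not -1 < self.base_rho < 1:
            raise ValueError("base_rho must lie in (-1, 1)")
        for (i, j), delta in self.effect_edges:
            if i == j:
                raise ValueError(f"effect edge ({i}, {j}) is a self-loop")
            if not -1 < self.base_rho + delta < 1:
                raise ValueError(
                    f"effect edge ({i}, {j}): base_rho + delta_rho = "
                    f"{self.base_rho + delta} outside (-1, 1)"
                )
        if abs(sum(self.response_props) - 1.0) > 1e-9 or min(self.response_props) < 0:
            raise ValueError("response_props must be non-negative and sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.grid_shape, self.voxel_size)

    def resolve_node_centers(self) -> np.ndarray:
        if self.node_centers is not None:
            centers = np.asarray(self.node_centers, dtype=float)
            if len(centers) != self.n_nodes:
                raise ValueError("node_centers length must equal n_nodes")
            return centers
        return synthetic_node_centers(self.n_nodes, self.grid_shape, self.voxel_size)

    def resolve_node_names(self) -> tuple[str, ...]:
        if self.node_names is not None:
            if len(self.node_names) != self.n_nodes:
                raise ValueError("node_names length must equal n_nodes")
            return self.node_names
        return tuple(f"node{i:02d}" for i in range(self.n_nodes))

    def node_specs(self) -> list[NodeSpec]:
        centers = self.resolve_node_centers()
        names = self.resolve_node_names()
        aff = self.affine
        return [
            build_node_cube(c, aff, self.grid_shape, name=n)
            for c, n in zip(centers, names)
        ]

    def to_manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["node_centers"] = (
            None
            if self.node_centers is None
            else [list(c) for c in self.node_centers]
        )
        d["effect_edges"] = [
            {"edge": [int(i), int(j)], "delta_rho": float(delta)}
            for (i, j), delta in self.effect_edges
        ]
        return d


@dataclass
class SimSubject:
    """One simulated participant: BOLD run, events, label, and ground truth."""

    subject_id: str
    group_label: str  # "CTRL" or "PP"
    bold_run: np.ndarray  # (x, y, z, t) float32
    affine: np.ndarray
    tr: float
    events: pd.DataFrame
    true_node_signals: np.ndarray  # (n_nodes, n_volumes) latent matrix
    seed: int


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------


def generate_events(config: SimCohortConfig, seed: int | None = None) -> pd.DataFrame:
    """One recognition-test event table: back-to-back trials, shuffled order.

    Old items receive R-hit / K-hit / miss outcomes with the configured
    proportions; new items receive CR / FA with the configured false-alarm
    rate.  Columns are BIDS-style: onset (s), duration (s), trial_type.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    old = rng.choice(OLD_LABELS, size=config.n_old_items, p=config.response_props)
    new = rng.choice(
        NEW_LABELS, size=config.n_new_items, p=(1 - config.fa_rate, config.fa_rate)
    )
    labels = np.concatenate([old, new])
    rng.shuffle(labels)
    onsets = np.arange(len(labels)) * config.trial_duration_s
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.full(len(labels), config.trial_duration_s),
            "trial_type": labels,
        }
    )


# ---------------------------------------------------------------------------
# Latent neural signals
# ---------------------------------------------------------------------------


def _correlation_matrix(
    config: SimCohortConfig, condition: str, group_label: str
) -> np.ndarray:
    """Unit-variance correlation matrix for one trial condition and group."""
    n = config.n_nodes
    C = np.full((n, n), config.base_rho)
    np.fill_diagonal(C, 1.0)
    if group_label == "PP" and condition == "R-hit":
        for (i, j), delta in config.effect_edges:
            C[i, j] = C[j, i] = config.base_rho + delta
    return C


def _cholesky_or_raise(C: np.ndarray, config: SimCohortConfig, label: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        edges = [list(e) for e, _ in config.effect_edges]
        raise ValueError(
            f"requested correlation matrix for {label} is not positive definite; "
            f"check base_rho={config.base_rho} and effect edges {edges}"
        ) from None


def _bin_conditions(
    events: pd.DataFrame, config: SimCohortConfig
) -> np.ndarray:
    """Per-TR condition label: trial epochs (onset -> onset+duration), nearest-TR."""
    cond = np.full(config.n_volumes, "base", dtype=object)
    tr = config.tr_seconds
    for row in events.itertuples(index=False):
        b0 = int(np.floor(row.onset / tr + 0.5))
        b1 = b0 + max(int(round(row.duration / tr)), 1)
        cond[b0 : min(b1, config.n_volumes)] = row.trial_type
    return cond


def simulate_node_neural(
    config: SimCohortConfig,
    events: pd.DataFrame,
    group_label: str,
    seed: int,
) -> np.ndarray:
    """Draw the latent node x time matrix with condition-switched coupling.

    Each TR bin is an independent draw from a zero-mean unit-variance
    correlated Gaussian; the correlation matrix is switched per trial
    epoch (R-hit epochs of the effect group carry base_rho + delta_rho on
    the effect edges, everything else base_rho).
    """
    if group_label not in ("CTRL", "PP"):
        raise ValueError("group_label must be 'CTRL' or 'PP'")
    rng = np.random.default_rng(seed)
    cond = _bin_conditions(events, config)
    chol = {}
    for c in ("base", "R-hit", "K-hit"):
        C = _correlation_matrix(config, c, group_label)
        chol[c] = _cholesky_or_raise(C, config, f"{group_label}/{c}")
    z = rng.standard_normal((config.n_volumes, config.n_nodes))
    out = np.empty_like(z)
    for c, L in chol.items():
        mask = cond == c if c != "base" else ~np.isin(cond, ("R-hit", "K-hit"))
        if mask.any():
            out[mask] = z[mask] @ L.T
    return out.T  # (n_nodes, n_volumes)


# ---------------------------------------------------------------------------
# BOLD rendering
# ---------------------------------------------------------------------------


def render_bold(
    latent: np.ndarray,
    node_table: Sequence[NodeSpec],
    grid_shape: Sequence[int],
    config: SimCohortConfig,
    seed: int = 0,
    hrf: HRFKernel | None = None,
) -> np.ndarray:
    """Render latent node signals into a 4D BOLD grid (float32).

    Each node's latent series is convolved with the canonical HRF
    (causal, truncated to run length), scaled by ``signal_scale``, and
    added identically to all 27 voxels of its cube.  Every voxel carries
    baseline + linear drift (peak-to-peak ``drift_amplitude``) + white
    Gaussian noise of sd ``noise_sd``.
    """
    latent = np.asarray(latent, dtype=float)
    n_nodes, n_vol = latent.shape
    if n_vol != config.n_volumes:
        raise ValueError("latent length must equal config n_volumes")
    shape = tuple(int(s) for s in grid_shape)
    for node in node_table:
        cube = node.voxel_cube
        if np.any(cube < 0) or np.any(cube >= np.asarray(shape)[None, :]):
            raise ValueError(f"node {node.name!r}: cube outside grid {shape}")
    if hrf is None:
        hrf = canonical_hrf(config.tr_seconds)
    rng = np.random.default_rng(seed)

    t = np.arange(n_vol, dtype=np.float32)
    drift = config.drift_amplitude * (t / max(n_vol - 1, 1) - 0.5)
    bold = np.empty(shape + (n_vol,), dtype=np.float32)
    bold[...] = (config.baseline + drift).astype(np.float32)
    if config.noise_sd > 0:
        bold += rng.normal(0.0, config.noise_sd, size=bold.shape).astype(np.float32)
    for node, sig in zip(node_table, latent):
        hemodynamic = np.convolve(sig, hrf.values)[:n_vol] * config.signal_scale
        cube = node.voxel_cube
        bold[cube[:, 0], cube[:, 1], cube[:, 2], :] += hemodynamic.astype(np.float32)
    return bold


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def _subject_seeds(config: SimCohortConfig, n: int) -> np.ndarray:
    """Deterministic per-subject seeds derived from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    return ss.generate_state(n, dtype=np.uint64) % (2**31)


def iter_cohort(config: SimCohortConfig) -> Iterator[SimSubject]:
    """Yield subjects one at a time (CTRL block first, then PP)."""
    nodes = config.node_specs()
    groups = ["CTRL"] * config.n_ctrl + ["PP"] * config.n_pp
    seeds = _subject_seeds(config, len(groups))
    hrf = canonical_hrf(config.tr_seconds)
    for idx, (group, seed) in enumerate(zip(groups, seeds)):
        seed = int(seed)
        events = generate_events(config, seed=seed)
        latent = simulate_node_neural(config, events, group, seed=seed + 1)
        bold = render_bold(
            latent, nodes, config.grid_shape, config, seed=seed + 2, hrf=hrf
        )
        yield SimSubject(
            subject_id=f"sub-{idx + 1:03d}",
            group_label=group,
            bold_run=bold,
            affine=config.affine,
            tr=config.tr_seconds,
            events=events,
            true_node_signals=latent,
            seed=seed,
        )


def generate_cohort(config: SimCohortConfig) -> tuple[list[SimSubject], dict]:
    """Materialize the whole cohort plus a manifest of all parameters.

    Note: every subject's 4D grid is held in memory; for large grids use
    :func:`iter_cohort` and stream subjects to disk.
    """
    subjects = list(iter_cohort(config))
    seeds = _subject_seeds(config, config.n_ctrl + config.n_pp)
    manifest = {
        "config": config.to_manifest_dict(),
        "n_subjects": len(subjects),
        "subjects": [
            {
                "subject_id": s.subject_id,
                "group": s.group_label,
                "seed": int(seed),
            }
            for s, seed in zip(subjects, seeds)
        ],
    }
    return subjects, manifest
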