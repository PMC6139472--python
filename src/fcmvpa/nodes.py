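"""ROI nodes: stereotaxic coordinates, cube construction, time-series extraction.

Connectivity nodes are 3x3x3-voxel cubes centred on stereotaxic peak
coordinates (one cube per region).  Coordinates may be supplied in
Talairach or MNI space; Talairach coordinates are converted to MNI with
the Lacadie et al. best-fit affine before voxel snapping.

Conventions (used by every reader/writer in this package):

* millimetre coordinates are RAS+;
* voxel indices are 0-based;
* coordinates are converted to MNI first, then snapped to the voxel grid;
* the voxel nearest the centre is chosen by rounding each fractional
  voxel coordinate half-away-from-zero (deterministic tie-break);
* the 27 voxels of a cube are stored in lexicographic (i, j, k) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeSpec",
    "VoxelTimeSeriesBlock",
    "LACADIE_MNI2TAL",
    "LACADIE_TAL2MNI",
    "tal2mni",
    "mni2tal",
    "brett_mni2tal",
    "build_node_cube",
    "extract_block",
    "read_node_table",
    "write_node_table",
    "node_table_to_specs",
    "nodes_mask",
]

# ---------------------------------------------------------------------------
# Talairach <-> MNI conversion
# ---------------------------------------------------------------------------

#: Best-fit MNI -> Talairach affine (Lacadie et al., "More accurate Talairach
#: coordinates for neuroimaging"), row-major homogeneous form.
LACADIE_MNI2TAL = np.array(
    [
        [0.9357, 0.0029, -0.0072, -1.0423],
        [-0.0065, 0.9396, -0.0726, -1.3940],
        [0.0103, 0.0752, 0.8967, 3.6475],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

#: Exact matrix inverse of :data:`LACADIE_MNI2TAL`.
LACADIE_TAL2MNI = np.linalg.inv(LACADIE_MNI2TAL)

Transform = np.ndarray | Callable[[np.ndarray], np.ndarray]


def _apply_affine(mat: np.ndarray, coord: np.ndarray) -> np.ndarray:
    coord = np.asarray(coord, dtype=float)
    return mat[:3, :3] @ coord + mat[:3, 3]


def _resolve(transform: Transform | str, default: np.ndarray) -> Transform:
    if isinstance(transform, str):
        if transform != "lacadie":
            raise ValueError(f"unknown transform strategy {transform!r}")
        return default
    return transform


def tal2mni(coord_tal: Sequence[float], transform: Transform | str = "lacadie") -> np.ndarray:
    """Convert a Talairach mm coordinate to MNI space.

    ``transform`` is pluggable: the default is the inverse of the published
    Lacadie best-fit affine; a 4x4 homogeneous matrix or a callable taking
    and returning a length-3 array may be substituted.
    """
    coord = np.asarray(coord_tal, dtype=float)
    if coord.shape != (3,) or not np.all(np.isfinite(coord)):
        raise ValueError("coordinate must be a finite (x, y, z) triple")
    tf = _resolve(transform, LACADIE_TAL2MNI)
    if callable(tf):
        return np.asarray(tf(coord), dtype=float)
    return _apply_affine(np.asarray(tf, dtype=float), coord)


def mni2tal(coord_mni: Sequence[float], transform: Transform | str = "lacadie") -> np.ndarray:
    """Inverse of :func:`tal2mni` (MNI mm -> Talairach mm)."""
    coord = np.asarray(coord_mni, dtype=float)
    if coord.shape != (3,) or not np.all(np.isfinite(coord)):
        raise ValueError("coordinate must be a finite (x, y, z) triple")
    tf = _resolve(transform, LACADIE_MNI2TAL)
    if callable(tf):
        return np.asarray(tf(coord), dtype=float)
    return _apply_affine(np.asarray(tf, dtype=float), coord)


def brett_mni2tal(coord_mni: Sequence[float]) -> np.ndarray:
    """Brett piecewise-affine MNI -> Talairach mapping.

    Kept as an independent cross-check for the Lacadie transform; the two
    agree to within a few millimetres over typical cortical coordinates.
    """
    x, y, z = np.asarray(coord_mni, dtype=float)
    tx = 0.99 * x
    if z >= 0:
        ty = 0.9688 * y + 0.0460 * z
        tz = -0.0485 * y + 0.9189 * z
    else:
        ty = 0.9688 * y + 0.0420 * z
        tz = -0.0485 * y + 0.8390 * z
    return np.array([tx, ty, tz])


# ---------------------------------------------------------------------------
# Node cubes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    """A named connectivity node: centre coordinate plus its 27-voxel cube."""

    name: str
    center_mni: tuple[float, float, float]
    voxel_cube: np.ndarray  # (27, 3) int voxel indices, lexicographic order
    center_tal: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        cube = np.asarray(self.voxel_cube)
        if cube.shape != (27, 3):
            raise ValueError(f"node {self.name!r}: cube must contain exactly 27 voxels")

    @property
    def center_voxel(self) -> np.ndarray:
        return self.voxel_cube[13]  # centre of the lexicographic 3x3x3 block


@dataclass
class VoxelTimeSeriesBlock:
    """27 voxel-wise BOLD series extracted from one node."""

    node: NodeSpec
    series: np.ndarray  # (27, n_volumes)
    tr: float

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[0] != 27:
            raise ValueError("series must be a 27 x n_volumes matrix")
        if not np.all(np.isfinite(self.series)):
            raise ValueError(f"node {self.node.name!r}: series contains non-finite values")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (np.round ties to even)."""
    return np.trunc(x + np.copysign(0.5, x)).astype(int)


_CUBE_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=int
)


def build_node_cube(
    center_mni: Sequence[float],
    affine: np.ndarray,
    grid_shape: Sequence[int],
    name: str = "node",
    center_tal: Sequence[float] | None = None,
) -> NodeSpec:
    """Snap an MNI centre to the voxel grid and build its 3x3x3 cube.

    Raises ``ValueError`` (naming the node) if any cube voxel would fall
    outside ``grid_shape`` — cubes are never silently truncated.
    """
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    center_vox = _round_half_away(_apply_affine(inv, np.asarray(center_mni, dtype=float)))
    cube = center_vox[None, :] + _CUBE_OFFSETS
    shape = np.asarray(grid_shape, dtype=int)
    if np.any(cube < 0) or np.any(cube >= shape[None, :]):
        raise ValueError(
            f"node {name!r}: cube around voxel {tuple(center_vox)} does not fit "
            f"inside grid {tuple(shape)}"
        )
    return NodeSpec(
        name=name,
        center_mni=tuple(float(c) for c in np.asarray(center_mni, dtype=float)),
        voxel_cube=cube,
        center_tal=None if center_tal is None else tuple(float(c) for c in center_tal),
    )


def extract_block(bold_run, node: NodeSpec, tr: float | None = None) -> VoxelTimeSeriesBlock:
    """Extract the 27 voxel time-series of ``node`` from a 4D run.

    ``bold_run`` may be a 4D numpy array (x, y, z, t) or a nibabel image;
    for an image the TR is read from the header zooms unless given.
    """
    if hasattr(bold_run, "get_fdata"):
        data = np.asarray(bold_run.get_fdata())
        if tr is None:
            zooms = bold_run.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) > 3 else 1.0
    else:
        data = np.asarray(bold_run)
        if tr is None:
            tr = 1.0
    if data.ndim != 4:
        raise ValueError("bold_run must be 4-dimensional (x, y, z, t)")
    cube = node.voxel_cube
    if np.any(cube < 0) or np.any(cube >= np.asarray(data.shape[:3])[None, :]):
        raise ValueError(f"node {node.name!r}: cube lies outside the image grid")
    series = data[cube[:, 0], cube[:, 1], cube[:, 2], :].astype(float)
    return VoxelTimeSeriesBlock(node=node, series=series, tr=float(tr))


# ---------------------------------------------------------------------------
# Node table I/O (CSV: name, x, y, z, space in {TAL, MNI})
# ---------------------------------------------------------------------------


def default_node_table() -> pd.DataFrame:
    """The 16-region node table shipped with the package.

    Region names follow the subjective-recollection network labels; the
    coordinates are SYNTHETIC stand-ins (plausible anatomical locations,
    not the meta-analytic peaks, which are not published in this data
    set) — supply your own CSV for real analyses.
    """
    return read_node_table(Path(__file__).parent / "data" / "synthetic_nodes.csv")


def read_node_table(path: str | Path) -> pd.DataFrame:
    """Read a node table CSV with columns name, x, y, z, space."""
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z", "space"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"node table {path}: missing columns {sorted(missing)}")
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"node table {path}: duplicate node names {dupes}")
    bad = ~df["space"].isin(["TAL", "MNI"])
    if bad.any():
        raise ValueError(f"node table {path}: space must be TAL or MNI")
    return df


def write_node_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a node table CSV with both coordinate spaces filled in.

    Coordinates are RAS+ millimetres; the MNI column set is authoritative
    for voxel snapping.
    """
    out = df.copy()
    mni = np.zeros((len(out), 3))
    tal = np.zeros((len(out), 3))
    for idx, row in enumerate(out.itertuples(index=False)):
        c = np.array([row.x, row.y, row.z], dtype=float)
        if row.space == "TAL":
            tal[idx] = c
            mni[idx] = tal2mni(c)
        else:
            mni[idx] = c
            tal[idx] = mni2tal(c)
    out["mni_x"], out["mni_y"], out["mni_z"] = mni.T
    out["tal_x"], out["tal_y"], out["tal_z"] = tal.T
    out.to_csv(path, index=False)


def node_table_to_specs(
    df: pd.DataFrame, affine: np.ndarray, grid_shape: Sequence[int]
) -> list[NodeSpec]:
    """Build NodeSpecs from a node table, converting TAL rows to MNI first."""
    specs = []
    for row in df.itertuples(index=False):
        c = np.array([row.x, row.y, row.z], dtype=float)
        if row.space == "TAL":
            center_tal, center_mni = c, tal2mni(c)
        else:
            center_tal, center_mni = None, c
        specs.append(
            build_node_cube(
                center_mni, affine, grid_shape, name=str(row.name), center_tal=center_tal
            )
        )
    return specs


def nodes_mask(nodes: Sequence[NodeSpec], grid_shape: Sequence[int]) -> np.ndarray:
    """Integer label volume of all node cubes (1-based labels), for visual QC."""
    mask = np.zeros(tuple(grid_shape), dtype=np.int16)
    for label, node in enumerate(nodes, start=1):
        cube = node.voxel_cube
        mask[cube[:, 0], cube[:, 1], cube[:, 2]] = label
    return mask
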