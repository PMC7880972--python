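"""Seed-based random-walker whole-liver segmentation.

The walker solves the combinatorial Dirichlet problem on the 6-connected
voxel graph: edge weights are ``w_ij = exp(-beta * (g_i - g_j)^2) + eps``
on intensities min-max normalised to [0, 1]; foreground seeds are clamped
to probability 1, background seeds to 0, and all remaining voxels solve
the graph-Laplacian linear system.  The mask thresholds the foreground
probability at 0.5 (ties go to foreground).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve

from .grid import VolumeGrid

__all__ = [
    "SeedSet",
    "SegmentationResult",
    "random_walker_segment",
    "refine_mask",
    "propagate_mask",
]

FOREGROUND = 1
BACKGROUND = 0

# unknowns below this count use a sparse direct solve; above it, CG
_DIRECT_SOLVE_LIMIT = 20000
_EDGE_EPS = 1e-10


@dataclass
class SeedSet:
    """Labelled voxel coordinates (0-based) seeding the walker.

    ``labels`` are 1 for foreground (inside the organ) and 0 for
    background (outside the organ or inside vessels).
    """

    coordinates: np.ndarray  # (n, 3) int
    labels: np.ndarray  # (n,) in {0, 1}

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=int))
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.coordinates.shape[0] != self.labels.shape[0]:
            raise ValueError("coordinates and labels length mismatch")
        if self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        if not set(np.unique(self.labels)) <= {FOREGROUND, BACKGROUND}:
            raise ValueError("labels must be 0 (background) or 1 (foreground)")
        if FOREGROUND not in self.labels or BACKGROUND not in self.labels:
            raise ValueError("need at least one foreground and one background seed")
        fg = {tuple(c) for c, l in zip(self.coordinates, self.labels) if l == FOREGROUND}
        bg = {tuple(c) for c, l in zip(self.coordinates, self.labels) if l == BACKGROUND}
        if fg & bg:
            raise ValueError(f"{len(fg & bg)} coordinate(s) carry both labels")

    def check_in_grid(self, shape: tuple[int, int, int]) -> None:
        if np.any(self.coordinates < 0) or np.any(self.coordinates >= np.asarray(shape)):
            raise ValueError("seed coordinates fall outside the grid")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.coordinates, columns=["x", "y", "z"])
        df["label"] = self.labels
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SeedSet":
        df = pd.read_csv(path)
        return cls(df[["x", "y", "z"]].to_numpy(), df["label"].to_numpy())


@dataclass
class SegmentationResult:
    probability: VolumeGrid
    mask: VolumeGrid
    beta: float
    solver_tol: float
    edits: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def _laplacian_6conn(norm: np.ndarray, beta: float) -> sparse.csr_matrix:
    """Sparse graph Laplacian with Gaussian edge weights, face connectivity."""
    shape = norm.shape
    n = norm.size
    idx = np.arange(n).reshape(shape)
    rows, cols, w = [], [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        a = idx[tuple(sl_a)].ravel()
        b = idx[tuple(sl_b)].ravel()
        diff = norm[tuple(sl_a)].ravel() - norm[tuple(sl_b)].ravel()
        wt = np.exp(-beta * diff**2) + _EDGE_EPS
        rows.append(a)
        cols.append(b)
        w.append(wt)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.concatenate(w)
    adj = sparse.coo_matrix((w, (rows, cols)), shape=(n, n))
    adj = adj + adj.T
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return (sparse.diags(deg) - adj).tocsr()


def random_walker_segment(
    image: VolumeGrid,
    seeds: SeedSet,
    beta: float = 130.0,
    solver_tol: float = 1e-5,
) -> SegmentationResult:
    """Segment ``image`` from seed points with the random-walker algorithm.

    Returns per-voxel foreground probability (exactly 1/0 at seeds) and the
    thresholded binary mask.
    """
    vals = np.asarray(image.values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("image contains non-finite values")
    seeds.check_in_grid(image.shape)

    vmin, vmax = vals.min(), vals.max()
    norm = (vals - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(vals)

    n = vals.size
    flat = np.ravel_multi_index(seeds.coordinates.T, image.shape)
    seed_prob = np.zeros(n)
    seed_prob[flat] = seeds.labels
    is_seed = np.zeros(n, dtype=bool)
    is_seed[flat] = True

    prob = np.empty(n)
    prob[is_seed] = seed_prob[is_seed]

    free = np.flatnonzero(~is_seed)
    if free.size:
        lap = _laplacian_6conn(norm, beta)
        l_uu = lap[free][:, free]
        rhs = -lap[free][:, is_seed] @ seed_prob[is_seed]
        if free.size <= _DIRECT_SOLVE_LIMIT:
            x = spsolve(l_uu.tocsc(), rhs)
        else:
            x, info = cg(l_uu, rhs, rtol=solver_tol * 1e-2, maxiter=5000)
            if info != 0:
                x = spsolve(l_uu.tocsc(), rhs)
        prob[free] = np.clip(x, 0.0, 1.0)

    prob_grid = image.like(prob.reshape(image.shape))
    mask_grid = image.like((prob.reshape(image.shape) >= 0.5).astype(np.uint8))
    return SegmentationResult(prob_grid, mask_grid, beta=beta, solver_tol=solver_tol)


def refine_mask(
    result: SegmentationResult,
    add: set[tuple[int, int, int]] | None = None,
    remove: set[tuple[int, int, int]] | None = None,
) -> SegmentationResult:
    """Apply manual voxel edits to the mask; probabilities are untouched."""
    add = set(add or ())
    remove = set(remove or ())
    if add & remove:
        raise ValueError(f"{len(add & remove)} voxel(s) appear in both add and remove sets")
    shape = result.mask.shape
    for c in add | remove:
        if any(i < 0 or i >= s for i, s in zip(c, shape)):
            raise ValueError(f"edit coordinate {c} outside grid {shape}")

    mask = np.array(result.mask.values, dtype=np.uint8, copy=True)
    if add:
        mask[tuple(np.array(sorted(add)).T)] = 1
    if remove:
        mask[tuple(np.array(sorted(remove)).T)] = 0

    warnings = list(result.warnings)
    if mask.sum() == 0:
        warnings.append("mask empty after edits")
    edits = list(result.edits) + [{"add": sorted(add), "remove": sorted(remove)}]
    return SegmentationResult(
        result.probability,
        result.mask.like(mask),
        beta=result.beta,
        solver_tol=result.solver_tol,
        edits=edits,
        warnings=warnings,
    )


def propagate_mask(mask: VolumeGrid, target: VolumeGrid) -> VolumeGrid:
    """Re-associate a binary mask with ``target``'s grid.

    Grids acquired in the same scan are congruent and the mask transfers
    voxelwise; otherwise the mask is resampled nearest-neighbour through
    the two affines.  Disjoint physical extents are an error.
    """
    if mask.congruent(target):
        return VolumeGrid(np.asarray(mask.values).copy(), target.spacing, target.affine.copy())

    # target voxel centres -> physical mm -> mask voxel indices
    ti = np.indices(target.shape).reshape(3, -1)
    ones = np.ones((1, ti.shape[1]))
    phys = target.affine @ np.vstack([ti, ones])
    mi = np.linalg.inv(mask.affine) @ phys
    mi = np.round(mi[:3]).astype(int)

    inside = np.all((mi >= 0) & (mi < np.asarray(mask.shape)[:, None]), axis=0)
    if not inside.any():
        raise ValueError("mask and target grids have disjoint physical extents")

    out = np.zeros(ti.shape[1], dtype=np.uint8)
    src = np.asarray(mask.values)
    out[inside] = src[tuple(mi[:, inside])]
    return VolumeGrid(out.reshape(target.shape), target.spacing, target.affine.copy())
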