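"""Whole-liver histogram and GLCM texture features from a masked T1 map.

Twelve parameters per volume: 8 histogram-based (volume, mean, SD, median,
5th/95th percentiles, skewness, excess kurtosis) and 4 co-occurrence-based
(entropy, contrast, diff-entropy, diff-variance), all computed over the T1
values inside the liver mask.

Conventions (recorded in the extraction metadata, configurable where it
matters): 32 equal-width gray levels over the masked min-max range; 13
unique 3D unit offsets pooled into one symmetric GLCM per liver; log base
2; kurtosis reported as excess kurtosis; diff-variance is the variance of
the gray-level-difference distribution.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .grid import VolumeGrid

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "FeatureVector",
    "QuantizedVolume",
    "GlcmMatrix",
    "histogram_features",
    "quantize",
    "glcm",
    "texture_features",
    "extract_all",
    "default_offsets",
]

FEATURE_NAMES = [
    "volume",
    "mean",
    "sd",
    "median",
    "p5",
    "p95",
    "skewness",
    "kurtosis",
    "entropy",
    "contrast",
    "diff_entropy",
    "diff_variance",
]

#: Label stored outside the mask in a quantized volume.
QUANT_SENTINEL = -1


def default_offsets() -> tuple[tuple[int, int, int], ...]:
    """The 13 unique 3D direction offsets at Chebyshev distance 1."""
    offs = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
    return tuple(offs)


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction conventions; hashed into the output for provenance."""

    n_levels: int = 32
    range_rule: str = "min-max"  # or "fixed"
    fixed_range: tuple[float, float] | None = None
    offsets: tuple[tuple[int, int, int], ...] = field(default_factory=default_offsets)
    symmetric: bool = True
    kurtosis_convention: str = "excess"
    log_base: int = 2

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "n_levels": self.n_levels,
                "range_rule": self.range_rule,
                "fixed_range": self.fixed_range,
                "offsets": [list(o) for o in self.offsets],
                "symmetric": self.symmetric,
                "kurtosis_convention": self.kurtosis_convention,
                "log_base": self.log_base,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class FeatureVector:
    volume: float
    mean: float
    sd: float
    median: float
    p5: float
    p95: float
    skewness: float
    kurtosis: float
    entropy: float
    contrast: float
    diff_entropy: float
    diff_variance: float
    config_hash: str = ""

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass
class QuantizedVolume:
    labels: np.ndarray  # int, QUANT_SENTINEL outside mask
    n_levels: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if len(self.bin_edges) != self.n_levels + 1:
            raise ValueError("bin_edges must have length n_levels + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        inside = self.labels != QUANT_SENTINEL
        if inside.any():
            lab = self.labels[inside]
            if lab.min() < 0 or lab.max() >= self.n_levels:
                raise ValueError("labels out of range inside mask")


@dataclass
class GlcmMatrix:
    p: np.ndarray  # (N_g, N_g) joint probability
    p_diff: np.ndarray  # (N_g,) |i-j| difference distribution
    mu_diff: float
    offsets: tuple[tuple[int, int, int], ...]
    symmetric: bool


def _masked_values(t1_map: VolumeGrid, mask: VolumeGrid) -> np.ndarray:
    m = np.asarray(mask.values).astype(bool)
    vals = np.asarray(t1_map.values, dtype=float)[m]
    # invalid-flagged voxels (negative sentinel) never enter statistics
    return vals[np.isfinite(vals) & (vals >= 0)]


def histogram_features(t1_map: VolumeGrid, mask: VolumeGrid) -> dict[str, float]:
    """The 8 first-order parameters over the masked T1 sample.

    Volume is valid-voxel count times voxel volume, in cm^3.  SD is the
    sample standard deviation (ddof=1); percentiles interpolate linearly;
    skewness is the standardised third central moment and kurtosis is
    excess kurtosis.  A single-voxel mask yields sd=0 with skewness and
    kurtosis flagged NaN.
    """
    vals = _masked_values(t1_map, mask)
    if vals.size == 0:
        raise ValueError("mask is empty (or contains only invalid voxels)")
    out = {
        "volume": vals.size * t1_map.voxel_volume_mm3 / 1000.0,
        "mean": float(np.mean(vals)),
        "median": float(np.median(vals)),
        "p5": float(np.percentile(vals, 5)),
        "p95": float(np.percentile(vals, 95)),
    }
    if vals.size == 1:
        out.update(sd=0.0, skewness=float("nan"), kurtosis=float("nan"))
        return out
    out["sd"] = float(np.std(vals, ddof=1))
    if out["sd"] == 0.0:
        out.update(skewness=0.0, kurtosis=0.0)
    else:
        out["skewness"] = float(sps.skew(vals))
        out["kurtosis"] = float(sps.kurtosis(vals))  # excess kurtosis
    return out


def quantize(
    t1_map: VolumeGrid,
    mask: VolumeGrid,
    n_levels: int = 32,
    range_rule: str = "min-max",
    fixed_range: tuple[float, float] | None = None,
) -> QuantizedVolume:
    """Equal-width gray-level quantisation of the masked T1 values.

    The top of the range maps into the last bin.  A constant masked image
    is valid and puts every voxel in bin 0.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    m = np.asarray(mask.values).astype(bool)
    vals = np.asarray(t1_map.values, dtype=float)
    valid = m & np.isfinite(vals) & (vals >= 0)
    if not valid.any():
        raise ValueError("mask is empty (or contains only invalid voxels)")

    if range_rule == "fixed":
        if fixed_range is None:
            raise ValueError("fixed range_rule requires fixed_range")
        lo, hi = map(float, fixed_range)
    elif range_rule == "min-max":
        lo, hi = float(vals[valid].min()), float(vals[valid].max())
    else:
        raise ValueError(f"unknown range_rule {range_rule!r}")
    if hi <= lo:
        hi = lo + 1.0  # constant image: degenerate but valid bins

    edges = np.linspace(lo, hi, n_levels + 1)
    labels = np.full(vals.shape, QUANT_SENTINEL, dtype=np.int64)
    scaled = (vals[valid] - lo) / (hi - lo) * n_levels
    labels[valid] = np.clip(np.floor(scaled).astype(np.int64), 0, n_levels - 1)
    return QuantizedVolume(labels, n_levels, edges)


def glcm(
    q: QuantizedVolume,
    offsets: tuple[tuple[int, int, int], ...] | None = None,
    symmetric: bool = True,
) -> GlcmMatrix:
    """Pooled gray-level co-occurrence matrix over a set of 3D offsets.

    A voxel pair contributes only when both ends lie inside the mask.
    Counts from all offsets accumulate into one matrix, which is
    symmetrised when requested and normalised to a joint probability.
    """
    offsets = tuple(offsets) if offsets is not None else default_offsets()
    if any(o == (0, 0, 0) for o in offsets):
        raise ValueError("offsets must be nonzero")
    lab = q.labels
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    for off in offsets:
        src = tuple(
            slice(max(0, -d), lab.shape[ax] - max(0, d)) for ax, d in enumerate(off)
        )
        dst = tuple(
            slice(max(0, d), lab.shape[ax] - max(0, -d)) for ax, d in enumerate(off)
        )
        a = lab[src].ravel()
        b = lab[dst].ravel()
        ok = (a != QUANT_SENTINEL) & (b != QUANT_SENTINEL)
        if ok.any():
            np.add.at(counts, (a[ok], b[ok]), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError(
            "no valid co-occurring pairs: mask voxels are isolated for every offset"
        )
    if symmetric:
        counts = counts + counts.T
    p = counts / counts.sum()

    k = np.abs(np.subtract.outer(np.arange(ng), np.arange(ng)))
    p_diff = np.bincount(k.ravel(), weights=p.ravel(), minlength=ng)
    mu_diff = float(np.sum(np.arange(ng) * p_diff))
    return GlcmMatrix(p, p_diff, mu_diff, offsets, symmetric)


def texture_features(g: GlcmMatrix) -> dict[str, float]:
    """Entropy, contrast, diff-entropy and diff-variance of a GLCM.

    entropy        = -sum_ij p(i,j) log2 p(i,j)      (0*log0 = 0)
    contrast       =  sum_ij (i-j)^2 p(i,j)
    diff_entropy   = -sum_k p_diff(k) log2 p_diff(k)
    diff_variance  =  sum_k (k - mu_diff)^2 p_diff(k)
    """
    p = g.p
    ng = p.shape[0]
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    ij = np.subtract.outer(np.arange(ng), np.arange(ng))
    contrast = float(np.sum(ij**2 * p))
    pd = g.p_diff
    nzd = pd > 0
    diff_entropy = float(-np.sum(pd[nzd] * np.log2(pd[nzd])))
    k = np.arange(ng)
    diff_variance = float(np.sum((k - g.mu_diff) ** 2 * pd))
    return {
        "entropy": entropy,
        "contrast": contrast,
        "diff_entropy": diff_entropy,
        "diff_variance": diff_variance,
    }


def extract_all(
    t1_map: VolumeGrid,
    mask: VolumeGrid,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Full 12-parameter vector for one masked T1 volume."""
    config = config or FeatureConfig()
    hist = histogram_features(t1_map, mask)
    q = quantize(
        t1_map, mask, config.n_levels, config.range_rule, config.fixed_range
    )
    tex = texture_features(glcm(q, config.offsets, config.symmetric))
    return FeatureVector(**hist, **tex, config_hash=config.config_hash())
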