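"""Synthetic phantoms and clinical cohorts with known ground truth.

A phantom is a crudely liver-shaped union of ellipsoids holding a
stationary correlated T1 field (white noise smoothed by a Gaussian kernel
of width ``heterogeneity_length``, rescaled to the requested mean/SD),
low-T1 vessels excluded from the truth mask, a linear B1 gradient, and
the two forward-simulated SPGR magnitude images.  Seed points are placed
automatically: foreground on three axial slices near the top, middle and
bottom of the liver, background outside the liver and inside vessels.

A cohort is a table of subjects with a latent low / intermediate-to-high
risk label, group-conditional labs, an elastography series, and one
phantom parameterisation per subject shifted by a feature-effect map.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

from .grid import VolumeGrid
from .segment import SeedSet
from .t1map import AcquisitionParams, spgr_signal

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "generate_feature_table",
    "default_liver_geometry",
]

# Table-like defaults for the two latent groups: (mean, sd) or probability.
# Albumin is stored in g/dL.
DEFAULT_GROUP_PARAMS = {
    "low": {
        "age": (46.0, 15.0),
        "male_p": 0.545,
        "bmi": (25.38, 2.70),
        "dm_p": 0.121,
        "ast": (46.0, 34.0),
        "alt": (69.0, 62.0),
        "platelets": (227.0, 48.0),
        "albumin": (4.7, 0.3),
        "lsm_median": 5.5,
        "fat_fraction": (12.98, 6.0),
    },
    "high": {
        "age": (43.0, 15.0),
        "male_p": 0.65,
        "bmi": (27.07, 2.98),
        "dm_p": 0.45,
        "ast": (62.0, 23.0),
        "alt": (89.0, 53.0),
        "platelets": (183.0, 73.0),
        "albumin": (4.7, 0.3),
        "lsm_median": 12.0,
        "fat_fraction": (19.31, 6.0),
    },
}

# physiologic floors for truncated-normal draws
_FLOORS = {"age": 18.0, "bmi": 15.0, "ast": 5.0, "alt": 5.0, "platelets": 20.0,
           "albumin": 2.5, "fat_fraction": 0.5}

# per-group phantom-parameter shifts (field -> (low value, high value)).
# The high-risk group gets a SHORTER correlation length: a more erratic
# field raises entropy/diff-entropy, matching the reported separation
# direction under per-volume min-max binning.
DEFAULT_PHANTOM_EFFECTS = {
    "t1_liver_mean": (954.25, 1265.9),
    "t1_liver_sd": (278.17, 351.06),
    "heterogeneity_length": (7.0, 4.0),
}


def default_liver_geometry(
    grid_shape: tuple[int, int, int],
    voxel_spacing: tuple[float, float, float],
) -> tuple[tuple[tuple[float, ...], tuple[float, ...]], ...]:
    """Two overlapping ellipsoids (center_mm, semiaxes_mm) filling ~the grid."""
    extent = [n * s for n, s in zip(grid_shape, voxel_spacing)]
    c = [e / 2 for e in extent]
    ax1 = tuple(0.33 * e for e in extent)
    ax2 = tuple(0.22 * e for e in extent)
    c2 = (c[0] + 0.18 * extent[0], c[1] - 0.08 * extent[1], c[2])
    return ((tuple(c), ax1), (c2, ax2))


@dataclass
class PhantomSpec:
    """Parameters of one synthetic liver phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    liver_geometry: tuple = None  # type: ignore[assignment]
    t1_liver_mean: float = 954.25
    t1_liver_sd: float = 278.17
    heterogeneity_length: float = 6.0  # mm
    t1_background: float = 300.0
    vessel_count: int = 2
    vessel_radius: float = 3.0  # mm
    noise_sd: float = 1.0  # signal units on the SPGR magnitudes
    b1_gradient: float = 0.1
    m0: float = 1000.0
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 8 per axis")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        for name in ("t1_liver_mean", "t1_background", "heterogeneity_length",
                     "vessel_radius", "m0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t1_liver_sd < 0 or self.noise_sd < 0:
            raise ValueError("t1_liver_sd and noise_sd must be non-negative")
        if self.liver_geometry is None:
            self.liver_geometry = default_liver_geometry(self.grid_shape, self.voxel_spacing)

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class PhantomBundle:
    spgr_low: VolumeGrid
    spgr_high: VolumeGrid
    b1_map: VolumeGrid
    truth_mask: VolumeGrid
    truth_t1: VolumeGrid
    seeds: SeedSet
    acq: AcquisitionParams

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("spgr_low", "spgr_high", "b1_map", "truth_t1"):
            paths[name] = getattr(self, name).to_nifti(out / f"{name}.nii.gz")
        mask = self.truth_mask
        paths["truth_mask"] = VolumeGrid(
            np.asarray(mask.values, dtype=np.uint8), mask.spacing, mask.affine
        ).to_nifti(out / "truth_mask.nii.gz")
        paths["seeds"] = self.seeds.to_csv(out / "seeds.csv")
        return paths


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    shape = spec.grid_shape
    sp = spec.voxel_spacing
    extent = [n * s for n, s in zip(shape, sp)]
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    for gi, (center, axes) in enumerate(spec.liver_geometry):
        for ax_i, (c, a, e) in enumerate(zip(center, axes, extent)):
            if c - a < 0 or c + a > e:
                raise ValueError(
                    f"ellipsoid {gi}: semi-axis {ax_i} ({a} mm at center {c} mm) "
                    f"does not fit the {e} mm grid extent"
                )
        d = ((xx - center[0]) / axes[0]) ** 2 + ((yy - center[1]) / axes[1]) ** 2 \
            + ((zz - center[2]) / axes[2]) ** 2
        mask |= d <= 1.0
    return mask


def _vessel_mask(spec: PhantomSpec, liver: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random tubes through the liver, clipped to the liver."""
    if spec.vessel_count == 0:
        return np.zeros_like(liver)
    sp = spec.voxel_spacing
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(spec.grid_shape, sp)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    pts = np.argwhere(liver)
    vessels = np.zeros_like(liver)
    for _ in range(spec.vessel_count):
        p0_idx = pts[rng.integers(len(pts))]
        p0 = (p0_idx + 0.5) * np.asarray(sp)
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        rel = np.stack([xx - p0[0], yy - p0[1], zz - p0[2]], axis=-1)
        t = rel @ d
        perp = rel - t[..., None] * d
        dist = np.linalg.norm(perp, axis=-1)
        vessels |= dist <= spec.vessel_radius
    return vessels & liver


def _correlated_field(
    spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.standard_normal(spec.grid_shape)
    sigma = [spec.heterogeneity_length / s for s in spec.voxel_spacing]
    smooth = ndimage.gaussian_filter(noise, sigma)
    inside = smooth[mask]
    sd = inside.std()
    if spec.t1_liver_sd == 0.0 or sd == 0.0:
        return np.full(spec.grid_shape, spec.t1_liver_mean)
    z = (smooth - inside.mean()) / sd
    t1 = spec.t1_liver_mean + spec.t1_liver_sd * z
    return np.maximum(t1, 50.0)  # keep T1 physical


def _auto_seeds(
    truth_mask: np.ndarray, liver: np.ndarray, vessels: np.ndarray,
    rng: np.random.Generator,
) -> SeedSet:
    zs = np.flatnonzero(truth_mask.any(axis=(0, 1)))
    fg: list[tuple[int, int, int]] = []
    for frac in (0.15, 0.5, 0.85):
        z = int(zs[int(round(frac * (len(zs) - 1)))])
        sl = truth_mask[:, :, z]
        core = ndimage.binary_erosion(sl, iterations=2)
        if not core.any():
            core = sl
        cand = np.argwhere(core)
        picks = cand[rng.choice(len(cand), size=min(3, len(cand)), replace=False)]
        fg.extend((int(x), int(y), z) for x, y in picks)

    bg: list[tuple[int, int, int]] = []
    outside = ~ndimage.binary_dilation(liver, iterations=1)
    cand = np.argwhere(outside)
    picks = cand[rng.choice(len(cand), size=min(9, len(cand)), replace=False)]
    bg.extend(map(tuple, picks.astype(int)))
    if vessels.any():
        vcand = np.argwhere(vessels)
        vpicks = vcand[rng.choice(len(vcand), size=min(3, len(vcand)), replace=False)]
        bg.extend(map(tuple, vpicks.astype(int)))

    coords = np.array(fg + bg, dtype=int)
    labels = np.array([1] * len(fg) + [0] * len(bg), dtype=int)
    return SeedSet(coords, labels)


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Forward-simulate one phantom from its spec.  Deterministic per seed."""
    rng = np.random.default_rng(spec.rng_seed)
    liver = _ellipsoid_mask(spec)
    vessels = _vessel_mask(spec, liver, rng)
    truth_mask = liver & ~vessels

    t1 = _correlated_field(spec, truth_mask, rng)
    t1 = np.where(truth_mask, t1, spec.t1_background)

    n0 = spec.grid_shape[0]
    ramp = (np.arange(n0) / max(n0 - 1, 1)) - 0.5
    b1 = 1.0 + spec.b1_gradient * ramp[:, None, None] * np.ones(spec.grid_shape)

    f_low, f_high = sorted(spec.acq.flip_angles)
    s_low = spgr_signal(t1, spec.m0, f_low, b1, spec.acq.tr)
    s_high = spgr_signal(t1, spec.m0, f_high, b1, spec.acq.tr)
    if spec.noise_sd > 0:
        s_low = np.abs(s_low + spec.noise_sd * rng.standard_normal(spec.grid_shape))
        s_high = np.abs(s_high + spec.noise_sd * rng.standard_normal(spec.grid_shape))

    grid = VolumeGrid(t1, spec.voxel_spacing)
    seeds = _auto_seeds(truth_mask, liver, vessels, rng)
    return PhantomBundle(
        spgr_low=grid.like(s_low),
        spgr_high=grid.like(s_high),
        b1_map=grid.like(b1),
        truth_mask=grid.like(truth_mask.astype(np.uint8)),
        truth_t1=grid.like(t1),
        seeds=seeds,
        acq=spec.acq,
    )


# --------------------------------------------------------------- cohorts
@dataclass
class CohortSpec:
    """Parameters of a synthetic clinical cohort."""

    n_subjects: int = 53
    frac_intermediate_high: float = 20 / 53
    group_params: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_GROUP_PARAMS)))
    phantom_effects: dict = field(default_factory=lambda: dict(DEFAULT_PHANTOM_EFFECTS))
    phantom_base: PhantomSpec = field(default_factory=PhantomSpec)
    label_fidelity: float = 1.0
    n_lsm: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.frac_intermediate_high <= 1.0:
            raise ValueError("frac_intermediate_high must lie in [0, 1]")
        if not 0.0 <= self.label_fidelity <= 1.0:
            raise ValueError("label_fidelity must lie in [0, 1]")
        for grp in self.group_params.values():
            for key, val in grp.items():
                if isinstance(val, (tuple, list)) and val[1] < 0:
                    raise ValueError(f"sd for {key} must be >= 0")


def _trunc_normal(rng, mean, sd, floor):
    if sd == 0:
        return float(mean)
    a = (floor - mean) / sd
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _lsm_series(rng, target_median: float, n: int) -> np.ndarray:
    vals = target_median * np.exp(0.08 * rng.standard_normal(n))
    vals *= target_median / np.median(vals)  # pin the series median
    return vals


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, list[PhantomSpec]]:
    """Draw a cohort table plus one phantom spec per subject.

    Each subject carries a latent group label (0 low / 1 intermediate-to-
    high).  Labs come from the group-conditional truncated normals, sex and
    diabetes from Bernoulli prevalences, and the LSM series from a
    log-normal pinned at a group-dependent median.  With probability
    ``label_fidelity`` the two-step stratification is made to recover the
    latent label (bumping AST into the first-line band and drawing the LSM
    median on the correct side of 8 kPa); otherwise the opposite side is
    drawn.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_subjects
    n_high = int(round(spec.frac_intermediate_high * n))
    labels = np.array([1] * n_high + [0] * (n - n_high))
    rng.shuffle(labels)

    rows = []
    phantoms = []
    for i, lab in enumerate(labels):
        g = spec.group_params["high" if lab else "low"]
        age = _trunc_normal(rng, *g["age"], _FLOORS["age"])
        bmi = _trunc_normal(rng, *g["bmi"], _FLOORS["bmi"])
        ast = _trunc_normal(rng, *g["ast"], _FLOORS["ast"])
        alt = _trunc_normal(rng, *g["alt"], _FLOORS["alt"])
        plate = _trunc_normal(rng, *g["platelets"], _FLOORS["platelets"])
        alb = _trunc_normal(rng, *g["albumin"], _FLOORS["albumin"])
        ff = _trunc_normal(rng, *g["fat_fraction"], _FLOORS["fat_fraction"])
        sex = "M" if rng.random() < g["male_p"] else "F"
        dm = int(rng.random() < g["dm_p"])

        consistent = rng.random() < spec.label_fidelity
        want_positive = bool(lab) == consistent
        if want_positive:
            # first line must not be low, and the first-line rule reads the
            # "or" literally (either low band => low): push BOTH scores out
            # of their low bands by raising AST (which enters both formulas)
            fib4_val = age * ast / (plate * np.sqrt(alt))
            if fib4_val < 1.3:
                ast = 1.35 * plate * np.sqrt(alt) / age
            nfs_val = (-1.675 + 0.037 * age + 0.094 * bmi + 1.13 * dm
                       + 0.99 * ast / alt - 0.013 * plate - 0.66 * alb)
            if nfs_val < -1.455:
                ast += (-1.40 - nfs_val) / 0.99 * alt
            med = float(np.clip(spec.group_params["high"]["lsm_median"]
                                * np.exp(0.2 * rng.standard_normal()), 8.5, 40.0))
        else:
            med = float(np.clip(spec.group_params["low"]["lsm_median"]
                                * np.exp(0.2 * rng.standard_normal()), 1.5, 7.5))
        lsm = _lsm_series(rng, med, spec.n_lsm)

        rows.append(
            {
                "subject_id": f"S{i:03d}",
                "latent_group": int(lab),
                "age": age,
                "sex": sex,
                "bmi": bmi,
                "dm": dm,
                "ast": ast,
                "alt": alt,
                "platelets": plate,
                "albumin": alb,
                "fat_fraction": ff,
                "lsm_values": ";".join(f"{v:.3f}" for v in lsm),
            }
        )
        kw = {f: vals[1] if lab else vals[0] for f, vals in spec.phantom_effects.items()}
        phantoms.append(spec.phantom_base.replace(rng_seed=spec.rng_seed + 1000 + i, **kw))

    return pd.DataFrame(rows), phantoms


def generate_feature_table(
    n_subjects: int = 200,
    frac_positive: float = 20 / 53,
    informative: dict[str, tuple[float, float, float, float]] | None = None,
    n_noise: int = 5,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Feature table with one informative signal among pure-noise columns.

    ``informative`` maps a feature name to (mean_low, sd_low, mean_high,
    sd_high); the default calibrates diff_entropy to the observed group
    marginals (1.27 +/- 0.27 vs 1.67 +/- 0.35).  Used for statistical
    power/selection calibration without running the imaging chain.
    """
    informative = informative or {"diff_entropy": (1.27, 0.27, 1.67, 0.35)}
    rng = np.random.default_rng(rng_seed)
    n_pos = int(round(frac_positive * n_subjects))
    y = np.array([1] * n_pos + [0] * (n_subjects - n_pos))
    rng.shuffle(y)
    data = {"label": y}
    for name, (m0, s0, m1, s1) in informative.items():
        data[name] = np.where(y == 1, m1 + s1 * rng.standard_normal(n_subjects),
                              m0 + s0 * rng.standard_normal(n_subjects))
    for j in range(n_noise):
        data[f"noise_{j}"] = rng.standard_normal(n_subjects)
    return pd.DataFrame(data)
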