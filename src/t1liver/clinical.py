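"""Blood fibrosis scores, LSM reliability, and two-step risk stratification.

First line: NFS and FIB-4 band each subject as low / intermediate / high
risk of advanced fibrosis.  A subject whose first-line band is low is
final-low without consulting elastography; otherwise a reliable liver
stiffness measurement (LSM) series determines the final band
(< 8 kPa low, 8-10 kPa intermediate, >= 10 kPa high).  The binary outcome
is low vs intermediate-to-high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalRecord",
    "RiskLabel",
    "LsmAssessment",
    "nfs",
    "fib4",
    "lsm_reliable",
    "fib4_band",
    "nfs_band",
    "lsm_band",
    "stratify",
    "stratify_frame",
]

LOW, INTERMEDIATE, HIGH = "low", "intermediate", "high"
_SEVERITY = {LOW: 0, INTERMEDIATE: 1, HIGH: 2}

# first-line thresholds
FIB4_LOW, FIB4_HIGH = 1.3, 3.25          # intermediate band is closed: [1.3, 3.25]
NFS_LOW, NFS_HIGH = -1.455, 0.672        # intermediate band is closed: [-1.455, 0.672]
# second-line LSM bands (kPa): [0,8) low, [8,10) intermediate, [10,inf) high
LSM_LOW_KPA, LSM_HIGH_KPA = 8.0, 10.0
# reliability rule
LSM_MIN_VALID = 10
LSM_IQR_RATIO_MAX = 0.30
LSM_RELIABLE_MEDIAN_KPA = 7.1


@dataclass
class ClinicalRecord:
    """One subject's demographics, labs and elastography series.

    Albumin is stored in g/dL (the score's units); use
    ``albumin_g_l * 0.1`` on ingest when the source table reports g/L.
    """

    age: float
    sex: str  # "M" / "F"
    bmi: float
    dm: bool
    ast: float
    alt: float
    platelets: float  # 10^9 / L
    albumin: float  # g/dL
    lsm_values: list[float] = field(default_factory=list)
    fat_fraction: float | None = None  # %
    subject_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("age", "bmi", "ast", "alt", "platelets", "albumin"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v <= 0 for v in self.lsm_values):
            raise ValueError("lsm values must be positive")


@dataclass
class LsmAssessment:
    reliable: bool
    median: float
    iqr_ratio: float
    n: int


@dataclass
class RiskLabel:
    first_line: str
    final: str
    binary: bool  # True = intermediate-to-high
    basis: str

    def __post_init__(self) -> None:
        if self.first_line == LOW and self.final != LOW:
            raise ValueError("first-line low must imply final low")
        if self.binary != (self.final != LOW):
            raise ValueError("binary must equal (final != low)")


def nfs(record: ClinicalRecord) -> float:
    """NAFLD fibrosis score.

    -1.675 + 0.037*age + 0.094*BMI + 1.13*DM + 0.99*AST/ALT
    - 0.013*platelets - 0.66*albumin[g/dL]
    """
    if record.alt <= 0:
        raise ValueError("alt must be positive (AST/ALT ratio undefined)")
    if not (1.0 <= record.albumin <= 7.0):
        raise ValueError(
            f"albumin {record.albumin} outside [1, 7] g/dL — if the source is in "
            "g/L, convert with a factor of 0.1"
        )
    return (
        -1.675
        + 0.037 * record.age
        + 0.094 * record.bmi
        + 1.13 * (1 if record.dm else 0)
        + 0.99 * (record.ast / record.alt)
        - 0.013 * record.platelets
        - 0.66 * record.albumin
    )


def fib4(record: ClinicalRecord) -> float:
    """Fibrosis-4 index: age * AST / (platelets * sqrt(ALT))."""
    if record.alt <= 0 or record.platelets <= 0:
        raise ValueError("fib4 denominator requires alt > 0 and platelets > 0")
    return record.age * record.ast / (record.platelets * math.sqrt(record.alt))


def lsm_reliable(lsm_values: list[float]) -> LsmAssessment:
    """Reliability of an elastography series.

    Reliable iff there are at least 10 valid measurements AND either
    IQR/median <= 0.30 or the median is below 7.1 kPa.
    """
    vals = np.asarray(lsm_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty LSM series")
    med = float(np.median(vals))
    iqr = float(np.percentile(vals, 75) - np.percentile(vals, 25))
    ratio = iqr / med if med > 0 else float("inf")
    ok = vals.size >= LSM_MIN_VALID and (
        ratio <= LSM_IQR_RATIO_MAX or med < LSM_RELIABLE_MEDIAN_KPA
    )
    return LsmAssessment(bool(ok), med, ratio, int(vals.size))


def fib4_band(score: float) -> str:
    if score < FIB4_LOW:
        return LOW
    return INTERMEDIATE if score <= FIB4_HIGH else HIGH


def nfs_band(score: float) -> str:
    if score < NFS_LOW:
        return LOW
    return INTERMEDIATE if score <= NFS_HIGH else HIGH


def lsm_band(median_kpa: float) -> str:
    if median_kpa < LSM_LOW_KPA:
        return LOW
    return INTERMEDIATE if median_kpa < LSM_HIGH_KPA else HIGH


def _first_line(f_band: str | None, n_band: str | None) -> str:
    """Combine the two blood-score bands.

    The "or" of the first-line rule is read literally: either score in
    its low band makes the subject low; otherwise the more severe band
    wins.  At least one band must be available.
    """
    bands = [b for b in (f_band, n_band) if b is not None]
    if not bands:
        raise ValueError("no first-line score computable")
    if LOW in bands:
        return LOW
    return max(bands, key=_SEVERITY.__getitem__)


def stratify(record: ClinicalRecord) -> RiskLabel:
    """Two-step low / intermediate / high risk label for one subject.

    Raises when the first line is not low and the LSM series is missing
    or unreliable (such subjects were excluded from the cohort design).
    """
    try:
        f_band = fib4_band(fib4(record))
    except ValueError:
        f_band = None
    try:
        n_band = nfs_band(nfs(record))
    except ValueError:
        n_band = None
    first = _first_line(f_band, n_band)

    if first == LOW:
        return RiskLabel(first, LOW, False, basis="first-line blood scores")
    if not record.lsm_values:
        raise ValueError("first-line not low and no LSM series available")
    lsm = lsm_reliable(record.lsm_values)
    if not lsm.reliable:
        raise ValueError(
            f"first-line not low and LSM unreliable (n={lsm.n}, "
            f"IQR/median={lsm.iqr_ratio:.2f}, median={lsm.median:.1f} kPa)"
        )
    final = lsm_band(lsm.median)
    return RiskLabel(first, final, final != LOW, basis="second-line LSM")


def record_from_row(row: pd.Series) -> ClinicalRecord:
    """Build a record from one cohort-CSV row (albumin column in g/dL)."""
    lsm = [float(v) for v in str(row["lsm_values"]).split(";") if v]
    return ClinicalRecord(
        age=float(row["age"]),
        sex=str(row["sex"]),
        bmi=float(row["bmi"]),
        dm=bool(int(row["dm"])),
        ast=float(row["ast"]),
        alt=float(row["alt"]),
        platelets=float(row["platelets"]),
        albumin=float(row["albumin"]),
        lsm_values=lsm,
        fat_fraction=float(row["fat_fraction"]) if "fat_fraction" in row else None,
        subject_id=str(row.get("subject_id", "")),
    )


def stratify_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorised stratification of a cohort table; one output row each."""
    rows = []
    for _, r in cohort.iterrows():
        rec = record_from_row(r)
        f = fib4(rec)
        n = nfs(rec)
        lsm = lsm_reliable(rec.lsm_values) if rec.lsm_values else None
        label = stratify(rec)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "fib4": f,
                "nfs": n,
                "fib4_band": fib4_band(f),
                "nfs_band": nfs_band(n),
                "first_line": label.first_line,
                "lsm_median": lsm.median if lsm else np.nan,
                "lsm_iqr_ratio": lsm.iqr_ratio if lsm else np.nan,
                "lsm_reliable": lsm.reliable if lsm else False,
                "final": label.final,
                "binary": int(label.binary),
                "basis": label.basis,
            }
        )
    return pd.DataFrame(rows)
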