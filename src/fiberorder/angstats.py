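"""Statistics on axis-relative fiber angles and distance comparisons.

Perturbation experiments (threads, elongated "sausage" aggregates,
stretched samples) yield manual measurements of the acute angle between
the actin pattern and a reference axis, in [0°, 90°].  Uniformity is
assessed by normalizing to [0, 1] and applying a one-sample two-sided
Kolmogorov–Smirnov test; group differences use the two-sided
Mann–Whitney U test; angles are also binned into parallel (0–30°),
diagonal (30–60°) and orthogonal (60–90°) categories.  Measurement
points are treated as independent (in the source data they are more
than 200 μm apart, beyond the angle correlation length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

BIN_EDGES_DEG = (0.0, 30.0, 60.0, 90.0)
BIN_NAMES = ("parallel", "diagonal", "orthogonal")


def fold_axial(angles_deg: np.ndarray) -> np.ndarray:
    """Fold director angles to the acute axis-relative value in [0, 90].

    |θ| mod 180, reflected: both 150° and −30° map to 30°.
    """
    a = np.mod(np.abs(np.asarray(angles_deg, dtype=float)), 180.0)
    return np.minimum(a, 180.0 - a)


@dataclass
class AngleMeasurementSet:
    """Axis-relative angle measurements with sample and region tags."""

    angles_deg: np.ndarray
    sample_id: np.ndarray
    region: np.ndarray

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.sample_id = np.asarray(self.sample_id)
        self.region = np.asarray(self.region)
        if not (len(self.angles_deg) == len(self.sample_id) == len(self.region)):
            raise ValueError("angles, sample_id and region must have equal length")
        bad = np.nonzero((self.angles_deg < 0) | (self.angles_deg > 90))[0]
        if bad.size:
            raise ValueError(
                f"angles outside [0, 90] at indices {bad.tolist()[:10]}"
            )

    def __len__(self) -> int:
        return len(self.angles_deg)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AngleMeasurementSet":
        return cls(
            angles_deg=df["angle_deg"].to_numpy(float),
            sample_id=df["sample_id"].to_numpy(),
            region=df["region"].to_numpy() if "region" in df else np.array([""] * len(df)),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "AngleMeasurementSet":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "region": self.region,
                "angle_deg": self.angles_deg,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class BinnedHistogram:
    """Counts in the parallel / diagonal / orthogonal angle categories."""

    counts: tuple[int, int, int]
    edges: tuple[float, float, float, float] = BIN_EDGES_DEG
    n: int = 0

    @property
    def parallel_orthogonal_ratio(self) -> float | None:
        return None if self.counts[2] == 0 else self.counts[0] / self.counts[2]


def bin_angles(measurements: AngleMeasurementSet) -> BinnedHistogram:
    """Bin angles into [0,30), [30,60), [60,90] (last bin closed).

    The category labels overlap at the printed edges; the convention
    here is left-closed/right-open with the final bin closed at 90°.
    """
    a = measurements.angles_deg
    if len(a) == 0:
        raise ValueError("empty measurement set")
    parallel = int(np.count_nonzero(a < 30.0))
    diagonal = int(np.count_nonzero((a >= 30.0) & (a < 60.0)))
    orthogonal = int(np.count_nonzero(a >= 60.0))
    return BinnedHistogram(counts=(parallel, diagonal, orthogonal), n=len(a))


def ks_uniformity(measurements: AngleMeasurementSet) -> tuple[float, float]:
    """Two-sided one-sample KS test of angles against uniformity.

    Angles are normalized to [0, 1] by dividing by 90; the exact
    Kolmogorov–Smirnov null distribution is used for n ≤ 100 (the
    source sample sizes are 32–103), the asymptotic one beyond.
    """
    a = measurements.angles_deg
    if len(a) < 5:
        raise ValueError("need at least 5 measurements for the KS test")
    x = a / 90.0
    method = "exact" if len(x) <= 100 else "asymp"
    res = stats.kstest(x, "uniform", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when min(n, m) ≤ 8 and there are no ties; normal
    approximation with tie correction otherwise.  Two identical constant
    sets return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both sets must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return len(a) * len(b) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def tip_defect_proximity(
    tip_to_defect_dists, half_interdefect_dists
) -> tuple[float, float, str]:
    """Are structure tips closer to +1 defects than a random point would be?

    Compares measured tip-to-nearest-defect distances against half
    inter-defect distances (the expected distance from a random point to
    the closest defect) with a two-sided Mann–Whitney test.  Returns
    (U, p, which) with ``which`` naming the stochastically smaller set
    by rank-sum comparison ("tips", "null", or "neither").
    """
    tips = np.asarray(tip_to_defect_dists, dtype=float)
    null = np.asarray(half_interdefect_dists, dtype=float)
    u, p = mann_whitney(tips, null)
    ranks = stats.rankdata(np.concatenate([tips, null]))
    mean_tip, mean_null = ranks[: len(tips)].mean(), ranks[len(tips):].mean()
    if mean_tip < mean_null:
        which = "tips"
    elif mean_null < mean_tip:
        which = "null"
    else:
        which = "neither"
    return u, p, which
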