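"""Cohort statistics: per-subject correlation, Fisher-Z averaging, CoV and
Mann-Whitney comparisons."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .grid import CANONICAL_GRID, is_canonical
from .oct import EccentricityProfile

logger = logging.getLogger(__name__)

#: Largest n_a * n_b for which the exact Mann-Whitney null is enumerated.
EXACT_MW_LIMIT = 400


@dataclass
class SubjectResult:
    """One subject's paired thickness/intensity profiles and their correlation."""

    subject_id: str
    thickness: EccentricityProfile
    intensity: EccentricityProfile
    r: float = field(init=False)
    z: float = field(init=False)

    def __post_init__(self) -> None:
        if self.thickness.kind != "thickness" or self.intensity.kind != "intensity":
            raise ValueError("profiles have the wrong kinds")
        if not (is_canonical(self.thickness.grid)
                and is_canonical(self.intensity.grid)):
            raise ValueError("profiles must be on the canonical grid")
        self.r = pearson_r(self.thickness.values, self.intensity.values)
        self.z = float(np.arctanh(self.r)) if abs(self.r) < 1 else np.inf


@dataclass
class CohortSummary:
    """Pooled central tendency, per-eccentricity CoV and Fisher-averaged R."""

    n_subjects: int
    thickness_median: float
    thickness_q25: float
    thickness_q75: float
    intensity_median: float
    intensity_q25: float
    intensity_q75: float
    cov_by_eccentricity: np.ndarray       # CoV (%) of intensity per grid point
    mean_r: float
    r_squared: float
    n_excluded_r: int = 0

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "thickness_median": self.thickness_median,
            "thickness_q25": self.thickness_q25,
            "thickness_q75": self.thickness_q75,
            "intensity_median": self.intensity_median,
            "intensity_q25": self.intensity_q25,
            "intensity_q75": self.intensity_q75,
            "cov_by_eccentricity": [round(float(v), 10)
                                    for v in self.cov_by_eccentricity],
            "eccentricity_deg": [float(e) for e in CANONICAL_GRID],
            "mean_r": self.mean_r,
            "r_squared": self.r_squared,
            "n_excluded_r": self.n_excluded_r,
        }


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation of two grid vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("inputs must share a length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return max(-1.0, min(1.0, r))


def fisher_average(r_values) -> tuple[float, float]:
    """Average correlations through Fisher-Z: tanh(mean(atanh(r))).

    Subjects with |r| = 1 (infinite z) are excluded with a warning rather
    than silently propagating infinities.
    """
    r_values = np.asarray(list(r_values), dtype=float)
    finite = np.abs(r_values) < 1.0
    if not finite.all():
        logger.warning("excluding %d correlation(s) with |r| = 1 from "
                       "Fisher averaging", int((~finite).sum()))
    if not finite.any():
        raise ValueError("no |r| < 1 values to average")
    mean_r = float(np.tanh(np.mean(np.arctanh(r_values[finite]))))
    return mean_r, mean_r ** 2


def coefficient_of_variation(values) -> float:
    """CoV as a percentage: 100 * sample SD (ddof=1) / mean."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("CoV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CoV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test; returns (U_a, p).

    Uses the exact permutation null when ``n_a * n_b <= 400`` and there are
    no ties, otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and a.size * b.size <= EXACT_MW_LIMIT:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """(median, q25, q75) with linear interpolation between order statistics."""
    q25, med, q75 = np.percentile(values, [25, 50, 75], method="linear")
    return float(med), float(q25), float(q75)


def summarize_cohort(results: list[SubjectResult]) -> CohortSummary:
    """Pool subject-by-eccentricity values and Fisher-average correlations."""
    if len(results) < 2:
        raise ValueError("a cohort summary needs at least 2 subjects")
    thickness = np.vstack([s.thickness.values for s in results])
    intensity = np.vstack([s.intensity.values for s in results])
    t_med, t_q25, t_q75 = _quartiles(thickness.ravel())
    i_med, i_q25, i_q75 = _quartiles(intensity.ravel())
    cov = np.array([coefficient_of_variation(intensity[:, j])
                    for j in range(intensity.shape[1])])
    rs = np.array([s.r for s in results])
    mean_r, r_squared = fisher_average(rs)
    return CohortSummary(
        n_subjects=len(results),
        thickness_median=t_med, thickness_q25=t_q25, thickness_q75=t_q75,
        intensity_median=i_med, intensity_q25=i_q25, intensity_q75=i_q75,
        cov_by_eccentricity=cov, mean_r=mean_r, r_squared=r_squared,
        n_excluded_r=int((np.abs(rs) >= 1).sum()),
    )
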