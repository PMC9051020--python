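"""Directional-OCT stage: boundary traces to a four-meridian thickness profile.

Two b-scans acquired with opposite pupil offsets along one meridian delineate
complementary halves of the anterior and posterior layer boundaries.  Merging
them, subtracting the boundaries, localizing the fovea from the outer-segment
band and sampling on the canonical eccentricity grid yields, after averaging
the four half-meridians, one thickness profile per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .grid import CANONICAL_GRID, UM_PER_DEGREE, MERIDIANS, is_canonical

logger = logging.getLogger(__name__)

#: OCT image quality cutoff (dB); strictly greater-than is required to keep.
OCT_QUALITY_MIN_DB = 20.0

#: Moving-average width (columns, odd) used before fovea localization.
FOVEA_SMOOTH_WIDTH = 11

#: Fraction of columns allowed to be unusable before combination fails.
MAX_BAD_COLUMN_FRACTION = 0.10


class BoundaryError(ValueError):
    """Boundary traces are inconsistent or insufficient for combination."""


class MissingMeridianError(ValueError):
    """A four-meridian average was requested with a meridian absent."""


@dataclass
class BoundaryTrace:
    """Per-column depth samples for one layer boundary of one b-scan.

    Parameters
    ----------
    columns : ndarray of int
        Lateral pixel indices, strictly increasing.
    depths : ndarray of float
        Axial depth (or band length, for ``os_band``) per column, in pixels.
    valid : ndarray of bool
        Per-column validity mask (which side a grader could segment).
    boundary_name : str
        One of ``anterior``, ``posterior``, ``os_band``.
    """

    columns: np.ndarray
    depths: np.ndarray
    valid: np.ndarray
    boundary_name: str

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        self.depths = np.asarray(self.depths, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.columns.shape == self.depths.shape == self.valid.shape):
            raise BoundaryError("columns, depths and valid must share a shape")
        if self.columns.size >= 2 and not np.all(np.diff(self.columns) > 0):
            raise BoundaryError("columns must be strictly increasing")
        if not np.all(np.isfinite(self.depths[self.valid])):
            raise BoundaryError("depths must be finite where valid")


@dataclass(frozen=True)
class ScanMeta:
    """Acquisition metadata for one directional b-scan."""

    meridian: str                 # "horizontal" | "vertical"
    offset_mm: float              # signed pupil-entry offset
    axial_um_per_px: float
    lateral_um_per_px: float
    quality_db: float
    eye: str = "OD"

    def to_dict(self) -> dict:
        return {
            "meridian": self.meridian,
            "offset_mm": self.offset_mm,
            "axial_um_per_px": self.axial_um_per_px,
            "lateral_um_per_px": self.lateral_um_per_px,
            "quality_db": self.quality_db,
            "eye": self.eye,
        }


@dataclass
class ThicknessProfile:
    """HFL thickness per lateral column along one scanned meridian."""

    columns: np.ndarray
    thickness_px: np.ndarray
    meridian: str
    axial_um_per_px: float
    lateral_um_per_px: float
    n_floored: int = 0

    @property
    def thickness_um(self) -> np.ndarray:
        return self.thickness_px * self.axial_um_per_px

    def eccentricity_deg(self, foveal_col: float) -> np.ndarray:
        """Signed eccentricity of each column relative to ``foveal_col``."""
        return (self.columns - foveal_col) * self.lateral_um_per_px / UM_PER_DEGREE


@dataclass
class EccentricityProfile:
    """A quantity sampled on the canonical 12-point eccentricity grid."""

    values: np.ndarray
    kind: str                               # "thickness" | "intensity"
    meridian: str | None = None
    grid: np.ndarray = field(default_factory=lambda: CANONICAL_GRID.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values and grid must share a shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")


def qc_filter_oct(quality_db: float) -> bool:
    """Keep a scan only if its quality metric strictly exceeds 20 dB."""
    if not np.isfinite(quality_db):
        raise ValueError("quality_db must be finite")
    return quality_db > OCT_QUALITY_MIN_DB


def merge_offset_traces(a: BoundaryTrace, b: BoundaryTrace) -> BoundaryTrace:
    """Merge the same boundary from two opposite-offset scans.

    Depth is taken from whichever scan is valid at each column; columns valid
    in both are averaged.  The merged mask is the union.
    """
    if a.boundary_name != b.boundary_name:
        raise BoundaryError("cannot merge different boundaries "
                            f"({a.boundary_name!r} vs {b.boundary_name!r})")
    if not np.array_equal(a.columns, b.columns):
        raise BoundaryError("column axes disagree between offset scans")
    both = a.valid & b.valid
    depths = np.where(a.valid, a.depths, b.depths)
    depths = np.where(both, 0.5 * (a.depths + b.depths), depths)
    return BoundaryTrace(a.columns.copy(), depths, a.valid | b.valid,
                         a.boundary_name)


def combine_boundaries(anterior: BoundaryTrace, posterior: BoundaryTrace,
                       meta: ScanMeta) -> ThicknessProfile:
    """Subtract merged anterior from posterior boundary to get thickness.

    Columns where either boundary is missing, or where the boundaries cross
    (negative thickness), are tolerated up to 10% of the scan; crossings are
    floored at zero and counted.
    """
    if not np.array_equal(anterior.columns, posterior.columns):
        raise BoundaryError("anterior and posterior column axes disagree")
    n = anterior.columns.size
    usable = anterior.valid & posterior.valid
    n_missing = int(n - usable.sum())
    if n_missing > MAX_BAD_COLUMN_FRACTION * n:
        raise BoundaryError(
            f"no valid source for a boundary on {n_missing}/{n} columns")
    thickness = posterior.depths - anterior.depths
    thickness[~usable] = np.nan
    # interpolate over the few missing columns
    if n_missing:
        good = np.flatnonzero(usable)
        thickness = np.interp(np.arange(n), good, thickness[good])
    negative = thickness < 0
    n_neg = int(negative.sum())
    if n_neg > MAX_BAD_COLUMN_FRACTION * n:
        raise BoundaryError(
            f"boundaries cross on {n_neg}/{n} columns (> 10%)")
    if n_neg:
        logger.warning("floored %d negative thickness columns at 0", n_neg)
        thickness = np.where(negative, 0.0, thickness)
    return ThicknessProfile(anterior.columns.copy(), thickness, meta.meridian,
                            meta.axial_um_per_px, meta.lateral_um_per_px,
                            n_floored=n_neg)


def locate_fovea_oct(os_band: BoundaryTrace) -> int:
    """Foveal column: argmax of the smoothed outer-segment length trace.

    The trace is smoothed with an 11-column moving average; ties are broken
    toward the column nearest the scan center.
    """
    if os_band.valid.sum() < 3:
        raise BoundaryError("os_band needs at least 3 valid columns")
    cols = os_band.columns[os_band.valid]
    vals = os_band.depths[os_band.valid]
    smooth = uniform_filter1d(vals, size=FOVEA_SMOOTH_WIDTH, mode="nearest")
    peak = np.flatnonzero(smooth == smooth.max())
    center = (os_band.columns[0] + os_band.columns[-1]) / 2.0
    best = peak[np.lexsort((cols[peak], np.abs(cols[peak] - center)))][0]
    return int(cols[best])


_HALF_MERIDIANS = {
    # scan meridian -> (negative-side label, positive-side label)
    "horizontal": ("temporal", "nasal"),
    "vertical": ("superior", "inferior"),
}


def sample_thickness(profile: ThicknessProfile, foveal_col: float,
                     meta: ScanMeta) -> tuple[EccentricityProfile,
                                              EccentricityProfile]:
    """Sample thickness (px) on the canonical grid on both sides of the fovea.

    Grid eccentricities are converted to lateral offsets at 320 um/deg and the
    per-column profile is read by linear interpolation.  Returns one profile
    per half-meridian (negative side first).
    """
    if meta.meridian not in _HALF_MERIDIANS:
        raise ValueError(f"unknown meridian {meta.meridian!r}")
    offsets_px = CANONICAL_GRID * UM_PER_DEGREE / meta.lateral_um_per_px
    lo, hi = profile.columns[0], profile.columns[-1]
    if foveal_col - offsets_px[-1] < lo or foveal_col + offsets_px[-1] > hi:
        raise ValueError("scan does not span 3 deg on both sides of the fovea")
    neg_label, pos_label = _HALF_MERIDIANS[meta.meridian]
    out = []
    for sign, label in ((-1, neg_label), (+1, pos_label)):
        cols = foveal_col + sign * offsets_px
        vals = np.interp(cols, profile.columns, profile.thickness_px)
        out.append(EccentricityProfile(vals, kind="thickness", meridian=label))
    return out[0], out[1]


def average_meridians(profiles: list[EccentricityProfile]) -> EccentricityProfile:
    """Pointwise mean of the temporal, superior, nasal and inferior profiles."""
    seen = {p.meridian for p in profiles}
    missing = set(MERIDIANS) - seen
    if missing or len(profiles) != 4:
        raise MissingMeridianError(
            f"need exactly the 4 meridians, missing: {sorted(missing)}")
    for p in profiles:
        if not is_canonical(p.grid):
            raise ValueError("profiles must be on the canonical grid")
    mean = np.mean([p.values for p in profiles], axis=0)
    return EccentricityProfile(mean, kind="thickness", meridian="average")


def subject_thickness(scan_pairs: dict, metas: dict) -> EccentricityProfile:
    """Full OCT stage for one subject.

    ``scan_pairs`` maps meridian name to a dict with merged or per-offset
    traces: ``{"anterior": (t_plus, t_minus), "posterior": (...),
    "os_band": trace}``.  Returns the four-meridian average thickness profile
    in pixels on the canonical grid.
    """
    halves: list[EccentricityProfile] = []
    for meridian, parts in scan_pairs.items():
        anterior = merge_offset_traces(*parts["anterior"])
        posterior = merge_offset_traces(*parts["posterior"])
        profile = combine_boundaries(anterior, posterior, metas[meridian])
        fovea = locate_fovea_oct(parts["os_band"])
        halves.extend(sample_thickness(profile, fovea, metas[meridian]))
    return average_meridians(halves)
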