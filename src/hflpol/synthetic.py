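"""Forward simulator: SLP retardation maps and directional-OCT boundary data.

Virtual subjects carry a known radial HFL thickness profile (zero at the
foveal center, peaking near 2 deg) and a known linear thickness-to-retardance
coupling.  The HFL acts as a radially oriented linear retarder; under fixed
corneal compensation it is composed with a residual corneal retarder, which
produces the macular cross, while under variable compensation the residual is
zero and an annulus results.  Directional-OCT b-scans are represented by
their boundary traces with side-dependent validity, standing in for manual
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import UM_PER_DEGREE, MERIDIANS
from .oct import BoundaryTrace, ScanMeta
from .slp import RetardationMap

#: Imaging wavelength (nm) used to convert retardance between nm and radians.
WAVELENGTH_NM = 780.0

#: Pupil-entry offset magnitude for directional scans (mm).
PUPIL_OFFSET_MM = 3.0

# Directional-OCT raster geometry (1536 a-scans across 30 deg).
OCT_N_COLUMNS = 1536
OCT_SPAN_DEG = 30.0
OCT_LATERAL_UM_PER_PX = OCT_SPAN_DEG * UM_PER_DEGREE / OCT_N_COLUMNS   # 6.25
OCT_AXIAL_UM_PER_PX = 3.87
#: Traces cover only the central +/- 4 deg of the scan (the layer thins to
#: nothing beyond the macula and would not be segmented there).
OCT_TRACE_HALFSPAN_PX = 205

# Between-subject perturbation scales used by simulate_cohort.
SUBJECT_TMAX_LOG_SD = 0.08
SUBJECT_SHAPE_SD = 0.2
SUBJECT_RPEAK_SD = 0.08
SUBJECT_AXIS_SD_DEG = 5.0

# Outer-segment band model (px): base + peak * exp(-(ecc/width)^2).
_OS_BASE_PX = 10.0
_OS_PEAK_PX = 8.0
_OS_WIDTH_DEG = 0.3

# Deterministic RNG stream tags.
_STREAM_SLP = 0
_STREAM_ANATOMY = 1
_STREAM_SCAN = 2
_STREAM_SUBJECT = 3


def nm_to_rad(nm):
    return 2.0 * np.pi * np.asarray(nm, dtype=float) / WAVELENGTH_NM


def rad_to_nm(rad):
    return np.asarray(rad, dtype=float) * WAVELENGTH_NM / (2.0 * np.pi)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the virtual-subject forward model.

    Defaults follow the instrument constants where published (60 nm
    single-pass corneal residual with slow axis 15 deg nasally downward in
    fixed mode; 20 x 40 deg field) and are otherwise free model parameters.
    """

    t_max: float = 30.0                 # peak HFL thickness (um)
    r_peak: float = 2.0                 # eccentricity of the peak (deg)
    shape: float = 1.5                  # radial-profile shape exponent
    meridian_mod: tuple = (0.0, 0.0, 0.0, 0.0)   # (T, S, N, I) fractional
    coupling: float = 0.6               # retardance per unit thickness (nm/um)
    corneal_residual_nm: float = 60.0   # residual corneal retardance (nm)
    corneal_axis_deg: float = 15.0      # residual slow axis (deg)
    corneal_between_subject_sd: float = 30.0     # nm, across subjects
    noise_sd: float = 1.5               # additive intensity noise SD
    gain: float = 1.5                   # intensity units per nm
    fov_deg: tuple = (20.0, 40.0)       # (vertical, horizontal)
    deg_per_px: float = 20.0 / 256.0
    trace_jitter_px: float = 0.15       # boundary-trace depth jitter SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_max <= 0 or self.r_peak <= 0 or self.shape <= 0:
            raise ValueError("t_max, r_peak and shape must be positive")
        if self.coupling < 0 or self.corneal_residual_nm < 0:
            raise ValueError("coupling and corneal_residual_nm must be >= 0")
        if self.deg_per_px <= 0:
            raise ValueError("deg_per_px must be positive")
        if min(self.noise_sd, self.corneal_between_subject_sd,
               self.trace_jitter_px) < 0:
            raise ValueError("noise SDs must be >= 0")
        if len(self.meridian_mod) != 4:
            raise ValueError("meridian_mod needs one value per meridian")

    @property
    def map_shape(self) -> tuple[int, int]:
        return (int(round(self.fov_deg[0] / self.deg_per_px)),
                int(round(self.fov_deg[1] / self.deg_per_px)))


@dataclass
class GroundTruth:
    """Known truth carried alongside each simulated subject."""

    thickness_by_meridian: dict            # meridian -> (r_deg, thickness_um)
    foveal_center_px: tuple[float, float]  # (row, col) in the SLP image
    retardance_map_nm: np.ndarray          # noise-free net retardance (nm)
    params: dict = field(default_factory=dict)


@dataclass
class OctScan:
    """One simulated directional b-scan: three traces plus metadata."""

    anterior: BoundaryTrace
    posterior: BoundaryTrace
    os_band: BoundaryTrace
    meta: ScanMeta
    true_foveal_col: int


def _radial_thickness(config: SimConfig, r) -> np.ndarray:
    """Unmodulated radial thickness: gamma-shaped, zero at r=0, peak at r_peak."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("eccentricity must be non-negative")
    x = r / config.r_peak
    return config.t_max * x ** config.shape * np.exp(config.shape * (1.0 - x))


def _azimuthal_modulation(config: SimConfig, phi) -> np.ndarray:
    """Trigonometric interpolation of the 4 per-meridian modulations.

    Meridian azimuths (math convention, right eye): nasal 0, superior pi/2,
    temporal pi, inferior 3*pi/2.
    """
    m_t, m_s, m_n, m_i = config.meridian_mod
    a0 = (m_t + m_s + m_n + m_i) / 4.0
    a1 = (m_n - m_t) / 2.0
    b1 = (m_s - m_i) / 2.0
    a2 = (m_n + m_t - m_s - m_i) / 4.0
    phi = np.asarray(phi, dtype=float)
    return a0 + a1 * np.cos(phi) + b1 * np.sin(phi) + a2 * np.cos(2 * phi)


_MERIDIAN_AZIMUTH = {"temporal": np.pi, "superior": np.pi / 2,
                     "nasal": 0.0, "inferior": 3 * np.pi / 2}


def hfl_thickness_profile(config: SimConfig, r, meridian_index: int):
    """Ground-truth HFL thickness (um) at eccentricity ``r`` on one meridian."""
    if meridian_index not in range(4):
        raise ValueError("meridian_index must be 0..3")
    base = _radial_thickness(config, r)
    return base * (1.0 + config.meridian_mod[meridian_index])


def _jones_retarder(delta, theta):
    """2x2 complex Jones matrix of a linear retarder (slow axis ``theta``)."""
    delta = np.asarray(delta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    ch, sh = np.cos(delta / 2.0), np.sin(delta / 2.0)
    c2, s2 = np.cos(2.0 * theta), np.sin(2.0 * theta)
    j00 = ch - 1j * sh * c2
    j01 = -1j * sh * s2
    j11 = ch + 1j * sh * c2
    return j00, j01, j01, j11


def composite_retardance(delta1, theta1, delta2, theta2):
    """Net retardance (rad, in [0, pi]) of two composed linear retarders.

    The retarders are multiplied as unitary Jones matrices and the equivalent
    retardance is the phase difference between the eigenvalues of the product
    (an SU(2) element), folded into [0, pi].  Broadcasts over array inputs.
    """
    delta1 = np.asarray(delta1, dtype=float)
    delta2 = np.asarray(delta2, dtype=float)
    if np.any(delta1 < 0) or np.any(delta2 < 0):
        raise ValueError("retardances must be non-negative")
    a00, a01, a10, a11 = _jones_retarder(delta2, theta2)
    b00, b01, b10, b11 = _jones_retarder(delta1, theta1)
    m00 = a00 * b00 + a01 * b10
    m01 = a00 * b01 + a01 * b11
    m10 = a10 * b00 + a11 * b10
    m11 = a10 * b01 + a11 * b11
    trace = m00 + m11
    det = m00 * m11 - m01 * m10
    disc = np.sqrt(trace * trace - 4.0 * det + 0j)
    lam_p = (trace + disc) / 2.0
    lam_m = (trace - disc) / 2.0
    d = np.abs(np.angle(lam_p) - np.angle(lam_m))
    d = np.minimum(d, 2.0 * np.pi - d)
    return d if d.ndim else float(d)


def _pixel_geometry(config: SimConfig, center: tuple[float, float]):
    nrow, ncol = config.map_shape
    dy = -(np.arange(nrow)[:, None] - center[0])      # up = positive
    dx = np.arange(ncol)[None, :] - center[1]
    r_deg = np.hypot(dx, dy) * config.deg_per_px
    phi = np.arctan2(dy, dx)
    return r_deg, phi


def _draw_corneal(config: SimConfig, rng: np.random.Generator) -> float:
    if config.corneal_between_subject_sd == 0:
        return config.corneal_residual_nm
    return float(max(rng.normal(config.corneal_residual_nm,
                                config.corneal_between_subject_sd), 0.0))


def simulate_retardation_map(config: SimConfig, mode: str,
                             subject_seed: int) -> tuple[RetardationMap,
                                                         GroundTruth]:
    """Render one subject's 8-bit retardation map plus its ground truth.

    In fixed mode the radially oriented HFL retarder is composed with the
    subject's residual corneal retarder; in variable mode the residual is
    zero.  Intensity is ``clip(gain * net_retardance_nm + noise, 0, 255)``,
    quantized to 8 bits.
    """
    if mode not in ("fixed", "variable"):
        raise ValueError(f"unknown compensation mode {mode!r}")
    if min(config.fov_deg) / 2.0 < 3.25:
        raise ValueError("field of view too small for the 3 deg analysis radius")
    rng = np.random.default_rng([config.seed, subject_seed, _STREAM_SLP])
    nrow, ncol = config.map_shape
    jitter = 0.5 / config.deg_per_px
    center = ((nrow - 1) / 2.0 + rng.uniform(-jitter, jitter),
              (ncol - 1) / 2.0 + rng.uniform(-jitter, jitter))
    r_deg, phi = _pixel_geometry(config, center)
    thickness = _radial_thickness(config, r_deg) \
        * (1.0 + _azimuthal_modulation(config, phi))
    hfl_nm = config.coupling * thickness
    if mode == "fixed":
        corneal_nm = _draw_corneal(config, rng)
        net_rad = composite_retardance(nm_to_rad(hfl_nm), phi,
                                       nm_to_rad(corneal_nm),
                                       np.deg2rad(config.corneal_axis_deg))
        net_nm = rad_to_nm(net_rad)
    else:
        net_nm = hfl_nm
    intensity = config.gain * net_nm
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd,
                                           size=intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, 255)
    r_dense = np.arange(0.0, 3.51, 0.01)
    truth = GroundTruth(
        thickness_by_meridian={
            m: (r_dense, hfl_thickness_profile(config, r_dense, i))
            for i, m in enumerate(MERIDIANS)},
        foveal_center_px=center,
        retardance_map_nm=net_nm,
        params={"mode": mode, "t_max": config.t_max, "r_peak": config.r_peak,
                "shape": config.shape,
                "corneal_residual_nm": (corneal_nm if mode == "fixed"
                                        else 0.0)},
    )
    rmap = RetardationMap(pixels, config.deg_per_px, mode)
    return rmap, truth


_SCAN_HALVES = {
    # meridian -> (negative-side meridian index, positive-side index)
    "horizontal": (0, 2),      # temporal, nasal
    "vertical": (1, 3),        # superior, inferior
}


def _true_foveal_cols(config: SimConfig, subject_seed: int) -> dict:
    """Per-meridian true foveal column, shared by both offsets of a meridian."""
    rng = np.random.default_rng([config.seed, subject_seed, _STREAM_ANATOMY])
    return {m: OCT_N_COLUMNS // 2 + int(rng.integers(-16, 17))
            for m in ("horizontal", "vertical")}


def simulate_oct_boundaries(config: SimConfig, meridian: str, offset_sign: int,
                            subject_seed: int,
                            quality_db: float = 30.0) -> OctScan:
    """Simulate one directional b-scan's anterior/posterior/OS-band traces.

    The posterior HFL boundary is valid only on the distal side of the pupil
    offset and the anterior boundary only on the proximal side; the
    outer-segment band peaks at the true foveal column.
    """
    if meridian not in _SCAN_HALVES:
        raise ValueError(f"unknown meridian {meridian!r}")
    if offset_sign not in (-1, 1):
        raise ValueError("offset_sign must be +1 or -1")
    fovea_col = _true_foveal_cols(config, subject_seed)[meridian]
    m_idx = 0 if meridian == "horizontal" else 1
    s_idx = 0 if offset_sign > 0 else 1
    rng = np.random.default_rng(
        [config.seed, subject_seed, _STREAM_SCAN, m_idx, s_idx])

    mid = OCT_N_COLUMNS // 2
    cols = np.arange(mid - OCT_TRACE_HALFSPAN_PX,
                     mid + OCT_TRACE_HALFSPAN_PX + 1)
    ecc = (cols - fovea_col) * OCT_LATERAL_UM_PER_PX / UM_PER_DEGREE
    neg_idx, pos_idx = _SCAN_HALVES[meridian]
    half_index = np.where(ecc < 0, neg_idx, pos_idx)
    t_um = _radial_thickness(config, np.abs(ecc)) * \
        (1.0 + np.asarray(config.meridian_mod)[half_index])
    anterior_depth = 150.0 + 0.003 * (cols - OCT_N_COLUMNS / 2.0)
    posterior_depth = anterior_depth + t_um / OCT_AXIAL_UM_PER_PX
    os_len = _OS_BASE_PX + _OS_PEAK_PX * np.exp(-(ecc / _OS_WIDTH_DEG) ** 2)
    if config.trace_jitter_px > 0:
        anterior_depth = anterior_depth + rng.normal(
            0.0, config.trace_jitter_px, cols.size)
        posterior_depth = posterior_depth + rng.normal(
            0.0, config.trace_jitter_px, cols.size)
        os_len = os_len + rng.normal(
            0.0, 0.3 * config.trace_jitter_px, cols.size)

    rel = cols - fovea_col
    posterior_valid = rel * offset_sign <= 0      # distal side
    anterior_valid = rel * offset_sign >= 0       # proximal side
    meta = ScanMeta(meridian=meridian,
                    offset_mm=offset_sign * PUPIL_OFFSET_MM,
                    axial_um_per_px=OCT_AXIAL_UM_PER_PX,
                    lateral_um_per_px=OCT_LATERAL_UM_PER_PX,
                    quality_db=quality_db)
    return OctScan(
        anterior=BoundaryTrace(cols, anterior_depth, anterior_valid, "anterior"),
        posterior=BoundaryTrace(cols, posterior_depth, posterior_valid,
                                "posterior"),
        os_band=BoundaryTrace(cols, os_len, np.ones(cols.size, bool),
                              "os_band"),
        meta=meta,
        true_foveal_col=fovea_col,
    )


def draw_subject(config: SimConfig, mode: str, subject_seed: int) -> SimConfig:
    """Concrete per-subject parameters drawn from the cohort distributions.

    Thickness-profile perturbations: log-normal peak-thickness scale,
    Gaussian shape and peak-eccentricity jitter.  In fixed mode the corneal
    residual magnitude (truncated Gaussian) and axis are drawn per subject;
    in variable mode the residual is exactly zero (idealized compensation).
    """
    rng = np.random.default_rng([config.seed, subject_seed, _STREAM_SUBJECT])
    t_max = config.t_max * float(np.exp(rng.normal(0.0, SUBJECT_TMAX_LOG_SD)))
    shape = float(max(rng.normal(config.shape, SUBJECT_SHAPE_SD), 0.5))
    r_peak = float(max(rng.normal(config.r_peak, SUBJECT_RPEAK_SD), 0.5))
    if mode == "fixed" and config.corneal_between_subject_sd > 0:
        corneal_nm = _draw_corneal(config, rng)
        axis = float(rng.normal(config.corneal_axis_deg, SUBJECT_AXIS_SD_DEG))
    elif mode == "fixed":
        corneal_nm, axis = config.corneal_residual_nm, config.corneal_axis_deg
    else:
        corneal_nm, axis = 0.0, config.corneal_axis_deg
    return replace(config, t_max=t_max, shape=shape, r_peak=r_peak,
                   corneal_residual_nm=corneal_nm, corneal_axis_deg=axis,
                   corneal_between_subject_sd=0.0)


@dataclass
class SubjectBundle:
    """In-memory simulation products for one virtual subject."""

    subject_id: str
    config: SimConfig                    # concrete per-subject parameters
    rmap: RetardationMap
    truth: GroundTruth
    scans: dict                          # (meridian, sign) -> OctScan
    slp_quality: float = 10.0


def simulate_subject(config: SimConfig, mode: str,
                     subject_seed: int) -> SubjectBundle:
    """Draw one subject and render its SLP map and four directional scans."""
    subj_cfg = draw_subject(config, mode, subject_seed)
    rmap, truth = simulate_retardation_map(subj_cfg, mode, subject_seed)
    scans = {(m, s): simulate_oct_boundaries(subj_cfg, m, s, subject_seed)
             for m in ("horizontal", "vertical") for s in (+1, -1)}
    return SubjectBundle(subject_id=f"sub{subject_seed:03d}", config=subj_cfg,
                         rmap=rmap, truth=truth, scans=scans)


def simulate_cohort(config: SimConfig, n_subjects: int, mode: str,
                    seed: int | None = None,
                    out_dir=None) -> list[SubjectBundle]:
    """Simulate a cohort of virtual subjects; optionally write it to disk.

    With ``out_dir`` set, writes each subject's SLP image, boundary-trace
    CSVs and metadata sidecars plus a cohort manifest in the external
    interchange formats (see :mod:`hflpol.io`).  Fully deterministic for a
    given seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if seed is not None:
        config = replace(config, seed=seed)
    bundles = [simulate_subject(config, mode, i) for i in range(n_subjects)]
    if out_dir is not None:
        from .io import write_cohort
        write_cohort(bundles, mode, out_dir)
    return bundles
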