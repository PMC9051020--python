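"""End-to-end orchestration: simulate/load, QC, OCT and SLP stages, statistics.

The pipeline consumes either a simulation block (cohorts are generated,
written to disk in the interchange formats and read back, so the analysis
path is identical for synthetic and external data) or pre-existing cohort
manifests.  Outputs are per-subject profile CSVs, a cohort summary JSON, a
Table-1-style CoV CSV and a Markdown report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .grid import CANONICAL_GRID
from .oct import (EccentricityProfile, average_meridians, combine_boundaries,
                  locate_fovea_oct, merge_offset_traces, qc_filter_oct,
                  sample_thickness)
from .slp import locate_macular_center, qc_filter_slp, ring_statistics
from .stats import CohortSummary, SubjectResult, mann_whitney, summarize_cohort
from .synthetic import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

_PAIRS = {"horizontal": ("h_plus", "h_minus"),
          "vertical": ("v_plus", "v_minus")}

VALID_STATISTICS = ("ring_mean", "cross_amplitude")


class PipelineError(RuntimeError):
    pass


@dataclass
class CohortSpec:
    label: str
    mode: str | None = None          # simulation mode, if simulated
    n_subjects: int | None = None
    manifest: str | None = None      # path, if loaded from disk


@dataclass
class PipelineConfig:
    cohorts: list[CohortSpec]
    out_dir: Path
    seed: int = 0
    statistic: str = "ring_mean"
    sim: SimConfig = field(default_factory=SimConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.statistic not in VALID_STATISTICS:
            raise ValueError(f"statistic must be one of {VALID_STATISTICS}")
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        for c in self.cohorts:
            simulated = c.mode is not None and c.n_subjects is not None
            if simulated == (c.manifest is not None):
                raise ValueError(
                    f"cohort {c.label!r}: exactly one input source required "
                    "(mode+n_subjects, or manifest)")


def load_pipeline_config(path, out_dir=None, seed=None) -> PipelineConfig:
    """Parse the YAML pipeline config; CLI flags override file values."""
    raw = yaml.safe_load(Path(path).read_text())
    cohorts = [CohortSpec(label=c["label"], mode=c.get("mode"),
                          n_subjects=c.get("n_subjects"),
                          manifest=c.get("manifest"))
               for c in raw.get("cohorts", [])]
    sim = SimConfig(**raw.get("sim", {}))
    cfg = PipelineConfig(
        cohorts=cohorts,
        out_dir=Path(out_dir if out_dir is not None
                     else raw.get("out_dir", "results")),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        statistic=raw.get("statistic", "ring_mean"),
        sim=sim,
        log_level=raw.get("log_level", "INFO"),
    )
    return cfg


def oct_stage_subject(scans: dict) -> EccentricityProfile:
    """Merged-offset OCT stage for one subject -> averaged thickness (px)."""
    halves = []
    for meridian, (kp, km) in _PAIRS.items():
        plus, minus = scans[kp], scans[km]
        anterior = merge_offset_traces(plus["anterior"], minus["anterior"])
        posterior = merge_offset_traces(plus["posterior"], minus["posterior"])
        profile = combine_boundaries(anterior, posterior, plus["meta"])
        os_band = merge_offset_traces(plus["os_band"], minus["os_band"])
        fovea = locate_fovea_oct(os_band)
        halves.extend(sample_thickness(profile, fovea, plus["meta"]))
    return average_meridians(halves)


def slp_stage_subject(rmap, statistic: str = "ring_mean"):
    """SLP stage: localize the center, extract the intensity profile + table."""
    center = locate_macular_center(rmap)
    rows = ring_statistics(rmap, center)
    values = np.array([row[statistic] for row in rows])
    return EccentricityProfile(values, kind="intensity"), rows, center


def process_subject(subject: dict, statistic: str) -> dict:
    """QC + both stages for one manifest subject.

    Returns ``{"result": SubjectResult, "rows": [...]}`` or
    ``{"excluded": reason}``.
    """
    sid = subject["subject_id"]
    for key, scan in subject["scans"].items():
        if not qc_filter_oct(scan["meta"].quality_db):
            return {"excluded": f"OCT scan {key} quality "
                                f"{scan['meta'].quality_db} dB <= 20 dB"}
    rmap, sidecar = hio.read_retardation_map(subject["slp_path"])
    if not qc_filter_slp(rmap.quality_score):
        return {"excluded": f"SLP quality score {rmap.quality_score} < 8"}
    thickness = oct_stage_subject(subject["scans"])
    intensity, rows, center = slp_stage_subject(rmap, statistic)
    for row, t in zip(rows, thickness.values):
        row["thickness_px"] = float(t)
        row["subject_id"] = sid
    result = SubjectResult(subject_id=sid, thickness=thickness,
                           intensity=intensity)
    return {"result": result, "rows": rows, "center": center}


def _cohort_tables(results: list[SubjectResult]) -> dict:
    t = np.vstack([s.thickness.values for s in results])
    i = np.vstack([s.intensity.values for s in results])
    return {
        "eccentricity_deg": CANONICAL_GRID.tolist(),
        "thickness_mean": t.mean(axis=0).tolist(),
        "thickness_sd": t.std(axis=0, ddof=1).tolist(),
        "intensity_mean": i.mean(axis=0).tolist(),
        "intensity_sd": i.std(axis=0, ddof=1).tolist(),
    }


def _render_report(cohort_data: dict, comparisons: dict,
                   statistic: str) -> str:
    lines = ["# HFL thickness vs. phase-retardation pipeline report", ""]
    lines.append(f"Intensity statistic: `{statistic}`")
    lines.append("")
    for label, data in cohort_data.items():
        s: CohortSummary = data["summary"]
        lines.append(f"## Cohort `{label}` (n = {s.n_subjects})")
        if data["excluded"]:
            lines.append("")
            lines.append(f"Excluded subjects: "
                         + "; ".join(f"{sid} ({why})"
                                     for sid, why in data["excluded"]))
        lines.append("")
        lines.append(f"- Pooled thickness median [q25, q75]: "
                     f"{s.thickness_median:.3f} [{s.thickness_q25:.3f}, "
                     f"{s.thickness_q75:.3f}] px")
        lines.append(f"- Pooled intensity median [q25, q75]: "
                     f"{s.intensity_median:.3f} [{s.intensity_q25:.3f}, "
                     f"{s.intensity_q75:.3f}]")
        lines.append(f"- Fisher-averaged R = {s.mean_r:.4f}, "
                     f"R^2 = {s.r_squared:.4f}")
        lines.append("")
        lines.append("| ecc (deg) | thickness mean (px) | thickness SD | "
                     "intensity mean | intensity SD | intensity CoV (%) |")
        lines.append("|---|---|---|---|---|---|")
        tab = data["tables"]
        for j, e in enumerate(tab["eccentricity_deg"]):
            lines.append(
                f"| {e:.2f} | {tab['thickness_mean'][j]:.3f} | "
                f"{tab['thickness_sd'][j]:.3f} | "
                f"{tab['intensity_mean'][j]:.3f} | "
                f"{tab['intensity_sd'][j]:.3f} | "
                f"{s.cov_by_eccentricity[j]:.2f} |")
        lines.append("")
    if comparisons:
        lines.append("## Between-cohort comparisons (Mann-Whitney, two-sided)")
        lines.append("")
        lines.append("| quantity | U | p |")
        lines.append("|---|---|---|")
        for name, (u, p) in comparisons.items():
            lines.append(f"| {name} | {u:.1f} | {p:.4g} |")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns a dict of output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_data: dict = {}
    for spec in config.cohorts:
        if spec.manifest is not None:
            manifest_path = Path(spec.manifest)
        else:
            in_dir = out / "inputs" / spec.label
            logger.info("simulating cohort %s (%d subjects, %s mode)",
                        spec.label, spec.n_subjects, spec.mode)
            simulate_cohort(config.sim, spec.n_subjects, spec.mode,
                            seed=config.seed + _cohort_offset(spec.label),
                            out_dir=in_dir)
            manifest_path = in_dir / "manifest.json"
        cohort = hio.read_manifest(manifest_path)
        results, rows, excluded = [], [], []
        for subject in cohort["subjects"]:
            outcome = process_subject(subject, config.statistic)
            if "excluded" in outcome:
                logger.warning("cohort %s: excluding %s: %s", spec.label,
                               subject["subject_id"], outcome["excluded"])
                excluded.append((subject["subject_id"], outcome["excluded"]))
                continue
            logger.info("cohort %s: subject %s r=%.4f", spec.label,
                        subject["subject_id"], outcome["result"].r)
            results.append(outcome["result"])
            rows.extend(outcome["rows"])
        if len(results) < 2:
            raise PipelineError(
                f"cohort {spec.label!r}: fewer than 2 subjects passed QC")
        summary = summarize_cohort(results)
        cohort_dir = out / spec.label
        cohort_dir.mkdir(exist_ok=True)
        hio.write_profile_csv(rows, cohort_dir / "subject_profiles.csv")
        (cohort_dir / "summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n")
        cov_lines = ["eccentricity_deg,cov_cohort"]
        cov_lines += [f"{e:.2f},{c:.4f}" for e, c in
                      zip(CANONICAL_GRID, summary.cov_by_eccentricity)]
        (cohort_dir / "cov.csv").write_text("\n".join(cov_lines) + "\n")
        cohort_data[spec.label] = {"summary": summary, "results": results,
                                   "tables": _cohort_tables(results),
                                   "excluded": excluded}

    comparisons: dict = {}
    labels = list(cohort_data)
    if len(labels) >= 2:
        a, b = cohort_data[labels[0]], cohort_data[labels[1]]
        ta = np.vstack([s.thickness.values for s in a["results"]]).ravel()
        tb = np.vstack([s.thickness.values for s in b["results"]]).ravel()
        ia = np.vstack([s.intensity.values for s in a["results"]]).ravel()
        ib = np.vstack([s.intensity.values for s in b["results"]]).ravel()
        comparisons = {
            "thickness": mann_whitney(ta, tb),
            "intensity": mann_whitney(ia, ib),
            "cov": mann_whitney(a["summary"].cov_by_eccentricity,
                                b["summary"].cov_by_eccentricity),
        }
        (out / "comparisons.json").write_text(json.dumps(
            {k: {"U": u, "p": p} for k, (u, p) in comparisons.items()},
            indent=2, sort_keys=True) + "\n")

    report = _render_report(cohort_data, comparisons, config.statistic)
    (out / "report.md").write_text(report)
    paths = {"report": out / "report.md",
             "summaries": {label: out / label / "summary.json"
                           for label in cohort_data}}
    if comparisons:
        paths["comparisons"] = out / "comparisons.json"
    return paths


def _cohort_offset(label: str) -> int:
    """Stable small offset so distinct cohorts get distinct seed streams."""
    return sum(label.encode()) % 1000
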