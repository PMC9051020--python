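"""Interchange formats: images, boundary-trace CSVs, sidecars and manifests.

All writers are deterministic (sorted JSON keys, fixed float formatting) so
identical simulations produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .oct import BoundaryTrace, EccentricityProfile, ScanMeta
from .slp import RetardationMap

_BOUNDARIES = ("anterior", "posterior", "os_band")
_SCAN_KEYS = {("horizontal", 1): "h_plus", ("horizontal", -1): "h_minus",
              ("vertical", 1): "v_plus", ("vertical", -1): "v_minus"}


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_retardation_map(rmap: RetardationMap, image_path,
                          quality_score: float = 10.0,
                          center_hint=None, eye: str = "OD") -> None:
    """8-bit grayscale PNG plus a JSON sidecar next to it."""
    image_path = Path(image_path)
    iio.imwrite(image_path, rmap.pixels.astype(np.uint8))
    sidecar = {
        "mode": rmap.mode,
        "deg_per_px": rmap.deg_per_px,
        "fov_deg": [rmap.pixels.shape[0] * rmap.deg_per_px,
                    rmap.pixels.shape[1] * rmap.deg_per_px],
        "quality_score": quality_score,
        "eye": eye,
        "center_hint": list(center_hint) if center_hint is not None else None,
    }
    _dump_json(sidecar, image_path.with_suffix(".json"))


def read_retardation_map(image_path) -> tuple[RetardationMap, dict]:
    image_path = Path(image_path)
    sidecar = json.loads(image_path.with_suffix(".json").read_text())
    pixels = iio.imread(image_path)
    rmap = RetardationMap(np.asarray(pixels, dtype=float),
                          deg_per_px=float(sidecar["deg_per_px"]),
                          mode=sidecar["mode"],
                          quality_score=float(sidecar["quality_score"]))
    return rmap, sidecar


def write_boundary_trace(trace: BoundaryTrace, path) -> None:
    """CSV with header ``column_px,depth_px,valid`` (valid as 0/1)."""
    lines = ["column_px,depth_px,valid"]
    lines += [f"{c},{d:.6f},{int(v)}"
              for c, d, v in zip(trace.columns, trace.depths, trace.valid)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_boundary_trace(path, boundary_name: str) -> BoundaryTrace:
    df = pd.read_csv(path)
    return BoundaryTrace(df["column_px"].to_numpy(),
                         df["depth_px"].to_numpy(),
                         df["valid"].to_numpy().astype(bool),
                         boundary_name)


def write_scan_meta(meta: ScanMeta, path) -> None:
    _dump_json(meta.to_dict(), Path(path))


def read_scan_meta(path) -> ScanMeta:
    d = json.loads(Path(path).read_text())
    return ScanMeta(meridian=d["meridian"], offset_mm=float(d["offset_mm"]),
                    axial_um_per_px=float(d["axial_um_per_px"]),
                    lateral_um_per_px=float(d["lateral_um_per_px"]),
                    quality_db=float(d["quality_db"]), eye=d.get("eye", "OD"))


def write_cohort(bundles, mode: str, out_dir) -> Path:
    """Write a simulated cohort in the interchange layout; return manifest path.

    Layout: ``<out_dir>/<subject_id>/slp.png`` (+ ``slp.json``), one
    directory per scan (``h_plus`` etc.) holding the three boundary CSVs and
    ``meta.json``, plus a cohort ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"cohort_label": mode, "mode": mode, "subjects": []}
    for b in bundles:
        subj_dir = out_dir / b.subject_id
        subj_dir.mkdir(exist_ok=True)
        write_retardation_map(b.rmap, subj_dir / "slp.png",
                              quality_score=b.slp_quality)
        entry = {"subject_id": b.subject_id,
                 "slp_image": f"{b.subject_id}/slp.png",
                 "scans": {}}
        for (meridian, sign), scan in sorted(
                b.scans.items(), key=lambda kv: _SCAN_KEYS[kv[0]]):
            key = _SCAN_KEYS[(meridian, sign)]
            scan_dir = subj_dir / key
            scan_dir.mkdir(exist_ok=True)
            for name in _BOUNDARIES:
                write_boundary_trace(getattr(scan, name),
                                     scan_dir / f"{name}.csv")
            write_scan_meta(scan.meta, scan_dir / "meta.json")
            entry["scans"][key] = f"{b.subject_id}/{key}"
        truth = {"foveal_center_px": list(b.truth.foveal_center_px),
                 "true_foveal_cols": {m: s.true_foveal_col
                                      for (m, sg), s in b.scans.items()
                                      if sg == 1},
                 "params": b.truth.params}
        _dump_json(truth, subj_dir / "truth.json")
        manifest["subjects"].append(entry)
    manifest_path = out_dir / "manifest.json"
    _dump_json(manifest, manifest_path)
    return manifest_path


def read_manifest(manifest_path) -> dict:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    subjects = []
    for entry in manifest["subjects"]:
        slp_path = root / entry["slp_image"]
        if not slp_path.exists():
            raise FileNotFoundError(f"missing SLP image: {slp_path}")
        scans = {}
        for key, rel in entry["scans"].items():
            scan_dir = root / rel
            meta_path = scan_dir / "meta.json"
            if not meta_path.exists():
                raise FileNotFoundError(f"missing scan metadata: {meta_path}")
            scans[key] = {
                "meta": read_scan_meta(meta_path),
                **{name: read_boundary_trace(scan_dir / f"{name}.csv", name)
                   for name in _BOUNDARIES},
            }
        subjects.append({"subject_id": entry["subject_id"],
                         "slp_path": slp_path, "scans": scans})
    return {"label": manifest.get("cohort_label", "cohort"),
            "mode": manifest.get("mode"), "subjects": subjects}


def write_profile_csv(profiles: list[dict], path) -> None:
    """Per-subject per-eccentricity table (thickness and intensity columns)."""
    df = pd.DataFrame(profiles)
    df.to_csv(path, index=False, float_format="%.6f")


def write_eccentricity_profile(profile: EccentricityProfile, path) -> None:
    lines = ["eccentricity_deg,value,kind,meridian"]
    lines += [f"{e:.2f},{v:.6f},{profile.kind},{profile.meridian or ''}"
              for e, v in zip(profile.grid, profile.values)]
    Path(path).write_text("\n".join(lines) + "\n")
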