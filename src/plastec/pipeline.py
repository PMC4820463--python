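"""Per-subject orchestration: load -> matrices -> search -> estimates -> reports.

Also owns the on-disk result layout used by the CLI:

* ``srps.tsv``      one row per surviving sub-regional pair
* ``summary.json``  plasticity estimates + config echo
* ``baseline.tsv``  averaging and edge-count baselines
* ``rois.tsv``      the ROI voxel tables (needed to re-index results)
* ``manifest.json`` config echo, seed, version, timestamp, status
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import averaging_connectivity, edge_count_change
from .connectivity import build_binary_matrix
from .consistency import compare_runs
from .encoding import SubRegion, SubRegionalPair
from .io import ROIDefinition, VoxelGrid, load_inputs, read_roi_table, save_json, write_roi_table, write_srp_label_map
from .plasticity import estimate_plasticity
from .search import ECConfig, ECResult, detect_all_srps
from .plasticity import PlasticityEstimate

__all__ = ["analyze_subject", "run_subject", "write_results", "read_srps_tsv", "aggregate_runs"]

logger = logging.getLogger(__name__)


def analyze_subject(grid, roi_a, roi_b, series, cfg: ECConfig, q: float = 0.05) -> dict:
    """Full in-memory analysis for one subject and ROI pair."""
    ts_a1 = series[(roi_a.name, 1)]
    ts_a2 = series[(roi_a.name, 2)]
    ts_b1 = series[(roi_b.name, 1)]
    ts_b2 = series[(roi_b.name, 2)]

    m1 = build_binary_matrix(ts_a1, ts_b1, q=q, session_id=1)
    m2 = build_binary_matrix(ts_a2, ts_b2, q=q, session_id=2)
    result = detect_all_srps(m1, m2, roi_a, roi_b, cfg, grid=grid)
    estimate = estimate_plasticity(result.srps, len(roi_a), len(roi_b))

    r1, z1 = averaging_connectivity(ts_a1, ts_b1)
    r2, z2 = averaging_connectivity(ts_a2, ts_b2)
    gl2 = edge_count_change(m1, m2)
    baselines = pd.DataFrame(
        [
            {"method": "averaging", "session1_stat": r1, "session2_stat": r2, "gl2": ""},
            {"method": "edge_count", "session1_stat": m1.n_edges, "session2_stat": m2.n_edges, "gl2": gl2},
        ]
    )
    return {
        "M1": m1,
        "M2": m2,
        "ec_result": result,
        "estimate": estimate,
        "baselines": baselines,
        "gl2": gl2,
    }


def _fmt_voxels(voxels: np.ndarray) -> str:
    return ";".join(",".join(str(int(c)) for c in v) for v in voxels)


def srps_table(result: ECResult, roi_a: ROIDefinition, roi_b: ROIDefinition) -> pd.DataFrame:
    rows = []
    for srp in result.srps:
        rows.append(
            {
                "level": srp.level,
                "sign": srp.sign,
                "NC1": srp.NC1,
                "NC2": srp.NC2,
                "TC": srp.TC,
                "Z": srp.Z,
                "p_raw": srp.p_raw,
                "p_corrected": srp.p_corrected,
                "root_a": ",".join(str(c) for c in srp.subA.root_voxel),
                "root_b": ",".join(str(c) for c in srp.subB.root_voxel),
                "members_a": _fmt_voxels(roi_a.voxels[srp.subA.members]),
                "members_b": _fmt_voxels(roi_b.voxels[srp.subB.members]),
            }
        )
    cols = [
        "level", "sign", "NC1", "NC2", "TC", "Z", "p_raw", "p_corrected",
        "root_a", "root_b", "members_a", "members_b",
    ]
    return pd.DataFrame(rows, columns=cols)


def _parse_voxels(text: str) -> np.ndarray:
    return np.array([[int(c) for c in v.split(",")] for v in text.split(";")])


def read_srps_tsv(path: str | Path, roi_a: ROIDefinition, roi_b: ROIDefinition) -> list[SubRegionalPair]:
    """Reconstruct surviving pairs (geometry + counts) from a results table."""
    df = pd.read_csv(path, sep="\t")
    idx_a = roi_a.index_of
    idx_b = roi_b.index_of
    srps = []
    for _, row in df.iterrows():
        mem_a = np.array([idx_a[tuple(v)] for v in _parse_voxels(row["members_a"]).tolist()])
        mem_b = np.array([idx_b[tuple(v)] for v in _parse_voxels(row["members_b"]).tolist()])
        root_a = tuple(int(c) for c in str(row["root_a"]).split(","))
        root_b = tuple(int(c) for c in str(row["root_b"]).split(","))
        srps.append(
            SubRegionalPair(
                subA=SubRegion(roi_name=roi_a.name, root_voxel=root_a, members=mem_a),
                subB=SubRegion(roi_name=roi_b.name, root_voxel=root_b, members=mem_b),
                NC1=int(row["NC1"]), NC2=int(row["NC2"]),
                Z=float(row["Z"]), fitness=abs(float(row["Z"])),
                sign=int(row["sign"]), p_raw=float(row["p_raw"]),
                p_corrected=float(row["p_corrected"]), level=int(row["level"]),
            )
        )
    return srps


def write_results(
    out_dir: str | Path,
    grid: VoxelGrid,
    roi_a: ROIDefinition,
    roi_b: ROIDefinition,
    analysis: dict,
    cfg: ECConfig,
    q: float,
    seed: int,
    write_maps: bool = False,
    status: str = "complete",
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: ECResult = analysis["ec_result"]
    estimate: PlasticityEstimate = analysis["estimate"]

    srps_table(result, roi_a, roi_b).to_csv(out / "srps.tsv", sep="\t", index=False)
    analysis["baselines"].to_csv(out / "baseline.tsv", sep="\t", index=False)
    write_roi_table(out / "rois.tsv", [roi_a, roi_b])
    save_json(
        out / "summary.json",
        {
            "roi_a": roi_a.name,
            "roi_b": roi_b.name,
            "n_roi_a": len(roi_a),
            "n_roi_b": len(roi_b),
            "n_srps_detected": len(result.detected),
            "n_srps_surviving": len(result.srps),
            "n_levels": result.n_levels,
            "gl2": analysis["gl2"],
            **estimate.to_dict(),
        },
    )
    if write_maps:
        write_srp_label_map(
            out / "srp_map_roi_a.nii.gz", grid, roi_a, [s.subA.members for s in result.srps]
        )
        write_srp_label_map(
            out / "srp_map_roi_b.nii.gz", grid, roi_b, [s.subB.members for s in result.srps]
        )
    save_json(
        out / "manifest.json",
        {
            "software": "plastec",
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "seed": seed,
            "q": q,
            "config": cfg.to_dict(),
            "status": status,
        },
    )
    return out


def run_subject(
    session1_path,
    session2_path,
    labels_path,
    roi_a_label: int,
    roi_b_label: int,
    out_dir,
    cfg: ECConfig,
    q: float = 0.05,
    write_maps: bool = False,
) -> dict:
    """Load a subject from disk, analyze, and write the result directory."""
    grid, (roi_a, roi_b), series = load_inputs(
        session1_path, session2_path, labels_path, roi_a_label, roi_b_label
    )
    analysis = analyze_subject(grid, roi_a, roi_b, series, cfg, q=q)
    write_results(out_dir, grid, roi_a, roi_b, analysis, cfg, q, cfg.rng_seed, write_maps)
    return analysis


def aggregate_runs(run_dirs: list[Path]) -> dict:
    """Mean/SD plasticity over independent runs plus run-overlap metrics."""
    import json

    summaries = [json.loads((Path(d) / "summary.json").read_text()) for d in run_dirs]
    rois = read_roi_table(Path(run_dirs[0]) / "rois.tsv")
    roi_a, roi_b = rois[0], rois[1]
    runs = [read_srps_tsv(Path(d) / "srps.tsv", roi_a, roi_b) for d in run_dirs]

    pos = np.array([s["pct_positive"] for s in summaries])
    neg = np.array([s["pct_negative"] for s in summaries])
    out = {
        "n_runs": len(run_dirs),
        "pct_positive_mean": float(pos.mean()),
        "pct_positive_sd": float(pos.std()),
        "pct_negative_mean": float(neg.mean()),
        "pct_negative_sd": float(neg.std()),
        "per_run": summaries,
    }
    if len(runs) >= 2:
        out["comparison"] = compare_runs(runs, len(roi_a), len(roi_b))
    return out
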