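"""End-to-end orchestration: simulate → preprocess → connectivity →
sparsity sweep → group statistics → classification, with a run manifest.

Every stage's randomness flows from one master seed through named
substreams, so a rerun with the same configuration and seed reproduces
identical artifact checksums.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassificationConfig, classify_cohort
from .connectivity import (
    fisher_z,
    fisher_z_inverse,
    group_average,
    pearson_matrix,
    roi_matrix,
)
from .graphmetrics import sparsity_sweep, sweep_to_frame
from .groupstats import (
    connectionwise_tests,
    extract_features,
    metric_group_table,
    power_two_sample,
    two_sample_t,
)
from .io import sha256_of, spec_from_dict, write_matrix, write_recording
from .montage import load_montage
from .preprocess import ExtinctionTable, PreprocessConfig, preprocess_recording
from .synthetic import simulate_cohort

logger = logging.getLogger(__name__)

_SUBSTREAMS = {"simulate": 0, "network": 1, "classify": 2}


class PipelineConfigError(ValueError):
    pass


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2**31) from the master seed."""
    child = np.random.SeedSequence(master_seed).spawn(len(_SUBSTREAMS))[_SUBSTREAMS[stage]]
    return int(child.generate_state(1)[0] % (2**31))


def _network_cfg(config: dict) -> dict:
    net = dict(config.get("network", {}))
    return {
        "s_min": net.get("s_min", 0.05),
        "s_max": net.get("s_max", 0.40),
        "s_step": net.get("s_step", 0.01),
        "ensemble_count": net.get("ensemble_count", 100),
        "swap_multiplier": net.get("swap_multiplier", 10),
        "modularity_restarts": net.get("modularity_restarts", 10),
    }


def run_all(config: dict, seed: int, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    t0 = time.time()
    montage_path = config.get("montage")
    if montage_path is not None and not Path(montage_path).exists():
        raise PipelineConfigError(f"montage file not found: {montage_path}")
    montage = load_montage(montage_path)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    chromophore = config.get("chromophore", "HbR")

    # --- simulate -----------------------------------------------------
    spec_dict = dict(config.get("cohort", {}))
    spec_dict["seed"] = derive_seed(seed, "simulate")
    spec = spec_from_dict(spec_dict)
    cohort = simulate_cohort(spec, montage)
    if config.get("write_recordings", False):
        rec_dir = out_dir / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in cohort.recordings:
            artifacts.append(write_recording(rec, rec_dir / f"{rec.subject_id}_intensity.tsv"))

    # --- preprocess ---------------------------------------------------
    pre_cfg = PreprocessConfig(**config.get("preprocess", {}))
    ext = ExtinctionTable(**config.get("extinction", {}))
    hemo = [preprocess_recording(r, montage, pre_cfg, ext) for r in cohort.recordings]

    # --- connectivity -------------------------------------------------
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    z_by_group: dict[str, list] = {"patient": [], "control": []}
    roi_by_group: dict[str, list] = {"patient": [], "control": []}
    for rec in hemo:
        z = fisher_z(pearson_matrix(rec, chromophore))
        z_by_group[rec.group].append(z)
        roi_by_group[rec.group].append(fisher_z(roi_matrix(rec, montage, chromophore)))
        artifacts.append(write_matrix(z, mat_dir / f"{rec.subject_id}_z.tsv"))

    summary: dict = {"group_connectivity": {}}
    for group, mats in z_by_group.items():
        # grand-average on the r scale, as connectivity means are reported
        r_mats = [fisher_z_inverse(m) for m in mats]
        ga = group_average(r_mats)
        summary["group_connectivity"][group] = {
            "mean_r": ga.mean_offdiag,
            "sd_r": ga.sd_offdiag,
        }
    p_ctrl = summary["group_connectivity"]["control"]
    p_pat = summary["group_connectivity"]["patient"]
    summary["power_normal_pct"] = 100.0 * power_two_sample(
        p_ctrl["mean_r"],
        p_pat["mean_r"],
        max(p_ctrl["sd_r"], p_pat["sd_r"]),
        spec.n_per_group,
    )

    # --- network sweep ------------------------------------------------
    net_cfg = _network_cfg(config)
    net_seed = derive_seed(seed, "network")
    frames = []
    for k, (group, mats) in enumerate(sorted(z_by_group.items())):
        for i, z in enumerate(mats):
            metrics = sparsity_sweep(z, seed=net_seed + 1000 * k + i, **net_cfg)
            frames.append(sweep_to_frame(metrics, z.subject_id, group, chromophore))
    sweep = pd.concat(frames, ignore_index=True)
    sweep_path = out_dir / "metrics.tsv"
    sweep.to_csv(sweep_path, sep="\t", index=False, float_format="%.10g")
    artifacts.append(sweep_path)

    # --- statistics ---------------------------------------------------
    conn = connectionwise_tests(z_by_group["patient"], z_by_group["control"])
    conn_path = out_dir / "connection_tests.tsv"
    conn.table.to_csv(conn_path, sep="\t", index=False, float_format="%.10g")
    artifacts.append(conn_path)
    summary["connection_tests"] = {
        "n_sig_05": conn.n_sig_05,
        "n_sig_01": conn.n_sig_01,
        "n_sig_fdr_05": conn.n_sig_fdr_05,
        "n_sig_fdr_01": conn.n_sig_fdr_01,
    }
    roi_conn = connectionwise_tests(roi_by_group["patient"], roi_by_group["control"])
    roi_path = out_dir / "roi_tests.tsv"
    roi_conn.table.to_csv(roi_path, sep="\t", index=False, float_format="%.10g")
    artifacts.append(roi_path)

    grid = metric_group_table(sweep)
    grid_path = out_dir / "feature_grid_tests.tsv"
    grid.to_csv(grid_path, sep="\t", index=False, float_format="%.10g")
    artifacts.append(grid_path)

    # --- classification -----------------------------------------------
    table = extract_features(sweep)
    feat_path = out_dir / "features.tsv"
    feat_out = table.features.copy()
    feat_out.insert(0, "group", table.labels)
    feat_out.to_csv(feat_path, sep="\t", float_format="%.10g")
    artifacts.append(feat_path)

    clf_cfg_dict = dict(config.get("classify", {}))
    clf_cfg_dict["seed"] = derive_seed(seed, "classify")
    clf_cfg = ClassificationConfig(**clf_cfg_dict)
    result = classify_cohort(table, clf_cfg)
    summary["classification"] = {
        "best_accuracy": result.best_accuracy,
        "mean_accuracy": result.mean_accuracy,
        "sd_accuracy": result.sd_accuracy,
        "accuracies": result.accuracies.tolist(),
        "chosen_c": result.chosen_c,
        "family_auc": {k: v.auc for k, v in result.family_roc.items()},
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1), encoding="utf-8")
    artifacts.append(summary_path)

    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": {s: derive_seed(seed, s) for s in _SUBSTREAMS},
        "config": _jsonable(config),
        "resolved": {
            "cohort": dataclasses.asdict(spec),
            "preprocess": dataclasses.asdict(pre_cfg),
            "extinction": dataclasses.asdict(ext),
            "network": net_cfg,
            "classify": dataclasses.asdict(clf_cfg),
        },
        "artifacts": {str(p.relative_to(out_dir)): sha256_of(p) for p in artifacts},
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
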