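"""End-to-end orchestration with provenance manifests.

``run_all`` executes simulate (optional) -> extract-events -> preprocess ->
epoch -> stats -> cluster -> validate, writing each stage's table under the
output directory together with a JSON manifest of parameters, seeds,
package version and input hashes, so a run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .behavior import EventCriteria, extract_events, merge_bouts, participant_gate, read_annotations, write_annotations
from .cluster import load_adjacency
from .epoching import EpochParams
from .preprocess import PreprocParams, RecordingRejected, preprocess
from .simulate import SimConfig, simulate_behavior, simulate_recording, write_ground_truth, write_recording_csv
from .stats import SustainedAttentionModel, load_roi_map
from .validation import run_validation

log = logging.getLogger("natattn")

__all__ = ["simulate_to_dir", "run_all"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        d = dataclasses.asdict(obj)
        return {k: _asdict(v) for k, v in d.items()}
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def simulate_to_dir(cfg: SimConfig, out_dir) -> dict:
    """Simulate the whole study and write annotations, recordings, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_bouts = []
    files = {}
    for pid in cfg.participant_ids():
        bouts = simulate_behavior(cfg, pid)
        rec, gt = simulate_recording(cfg, bouts, pid)
        rec_path = out / f"{pid}_intensity.csv"
        write_recording_csv(rec, rec_path)
        write_ground_truth(gt, out / f"{pid}_truth.json")
        all_bouts.extend(bouts)
        files[pid] = str(rec_path)
        log.info("simulated %s: %d bouts", pid, len(bouts))
    ann_path = out / "annotations.tsv"
    write_annotations(all_bouts, ann_path)
    manifest = {
        "stage": "simulate",
        "version": __version__,
        "config": _asdict(cfg),
        "annotations": str(ann_path),
        "recordings": files,
    }
    (out / "simulate_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def run_all(
    out_dir,
    sim_config: SimConfig | None = None,
    annotations_path=None,
    recordings: dict | None = None,
    criteria: EventCriteria = EventCriteria(),
    preproc: PreprocParams = PreprocParams(),
    epoch: EpochParams = EpochParams(),
    roi_map_path=None,
    adjacency_path=None,
    n_perm: int = 1000,
    seed: int = 0,
    validate: bool = True,
) -> dict:
    """Full pipeline; returns the provenance manifest (also written to disk).

    Either supply ``sim_config`` (synthetic study, generated in memory) or
    ``annotations_path`` plus ``recordings`` (participant -> Recording).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}

    if sim_config is not None:
        from .simulate import simulate_study

        study = simulate_study(sim_config, raw=True)
        bouts = [b for _, pb, _, _ in study for b in pb]
        recordings = {pid: rec for pid, _, rec, _ in study}
        manifest["stages"]["simulate"] = {"config": _asdict(sim_config)}
    else:
        if annotations_path is None or recordings is None:
            raise FileNotFoundError("need annotations_path and recordings when not simulating")
        annotations_path = Path(annotations_path)
        if not annotations_path.exists():
            raise FileNotFoundError(f"annotation file not found: {annotations_path}")
        bouts = read_annotations(annotations_path)
        manifest["stages"]["extract_events"] = {"annotations_sha256": _sha256(annotations_path)}

    merged = merge_bouts(bouts, criteria.gap_merge_ms)
    events = extract_events(merged, criteria)
    kept, report = participant_gate(events, criteria)
    events = [ev for ev in events if ev.participant_id in kept]
    report.to_csv(out / "participant_report.csv", index=False)
    manifest["stages"]["extract_events"] = {
        **manifest["stages"].get("extract_events", {}),
        "criteria": _asdict(criteria),
        "n_events": len(events),
        "participants_kept": sorted(kept),
    }
    log.info("events: %d across %d participants", len(events), len(kept))

    hb_by_pid = {}
    pruned_counts = {}
    for pid, rec in recordings.items():
        if pid not in kept:
            continue
        try:
            hb = preprocess(rec, preproc)
        except RecordingRejected as exc:
            log.warning("recording rejected: %s", exc)
            continue
        hb_by_pid[pid] = hb
        pruned_counts[pid] = int((~hb.channel_ok).sum())
    manifest["stages"]["preprocess"] = {
        "params": _asdict(preproc),
        "pruned_channels": pruned_counts,
        "participants": sorted(hb_by_pid),
    }

    roi_map = load_roi_map(roi_map_path)
    adjacency = load_adjacency(adjacency_path)
    from .epoching import apply_shift, exclude_short_isi, extract_blocks, peak_window_mean

    shifted = exclude_short_isi(apply_shift(events, epoch), epoch)
    blocks = []
    for pid, hb in hb_by_pid.items():
        blocks.extend(extract_blocks(hb, [e for e in shifted if e.participant_id == pid], epoch))
    responses = peak_window_mean(blocks, epoch, "hbo")
    responses.to_csv(out / "responses_hbo.csv", index=False)
    responses_hbr = peak_window_mean(blocks, epoch, "hbr")
    responses_hbr.to_csv(out / "responses_hbr.csv", index=False)
    manifest["stages"]["epoch"] = {"params": _asdict(epoch), "n_blocks": len(blocks)}

    model = SustainedAttentionModel(responses, roi_map, adjacency)
    res = model.fit(n_perm=n_perm, seed=seed)
    res.roi_table.to_csv(out / "roi_stats_hbo.csv", index=False)
    res.channel_table.to_csv(out / "channel_stats_hbo.csv", index=False)
    model_hbr = SustainedAttentionModel(responses_hbr, roi_map, adjacency, chromophore="hbr")
    res_hbr = model_hbr.fit(n_perm=n_perm, seed=seed)
    res_hbr.roi_table.to_csv(out / "roi_stats_hbr.csv", index=False)
    cluster_json = [
        {
            "channels": sorted(c.channels),
            "mass": c.mass,
            "p": c.p_cluster,
            "n_perm": c.n_perm,
            "exhaustive": c.exhaustive,
            "null_distribution": list(map(float, c.null_distribution)),
        }
        for c in (res.clusters or [])
    ]
    (out / "clusters_hbo.json").write_text(json.dumps(cluster_json, indent=1))
    manifest["stages"]["stats"] = {
        "significant_rois_hbo": res.significant_rois(),
        "clusters": [{k: v for k, v in c.items() if k != "null_distribution"} for c in cluster_json],
    }

    if validate:
        vrep = run_validation(
            hb_by_pid, events, seed=seed, roi_map=roi_map, adjacency=adjacency,
            params=epoch, n_perm=n_perm,
        )
        vrep.roi_t.to_csv(out / "validation_roi_t.csv")
        vrep.latency.to_csv(out / "validation_peak_latency.csv")
        vrep.cluster_mass.to_frame("max_cluster_mass").to_csv(out / "validation_cluster_mass.csv")
        manifest["stages"]["validate"] = {
            "significant_rois": vrep.significant_rois,
            "cluster_mass": {k: float(v) for k, v in vrep.cluster_mass.items()},
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
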