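"""Desk-scale simulation experiments verifying the protocol's operating
characteristics.

Each routine runs the pipeline on freshly generated synthetic studies under
the default study conditions (12 participants, 44 channels, 20-minute
sessions at 5 Hz, three adjacent active channels) and measures an error
rate or recovery property:

* :func:`cluster_type1_study` -- cluster-level false-positive rate on null
  data (no active channels), which should sit near the nominal alpha.
* :func:`recovery_study` -- how often the +3 s protocol recovers the truly
  active cluster from raw intensities, across seeds.
* :func:`random_onset_study` -- how often randomized onsets (+/- 15-30 s)
  leave no FDR-significant ROI, the protocol's negative control.
* :func:`latency_shift_study` -- the block-average peak-latency difference
  between the +0 and +3 onset definitions (should equal the 3 s shift).

Null-rate studies use the generator's concentration-domain path (the optics
round trip is deterministic and exactly invertible, so it carries no
information about null behavior); the recovery study exercises the full
raw-intensity chain including motion correction.
"""

from __future__ import annotations

import numpy as np

from .behavior import extract_events, merge_bouts, participant_gate
from .cluster import cluster_test, load_adjacency
from .epoching import EpochParams, apply_shift, exclude_short_isi, extract_blocks, peak_window_mean
from .preprocess import preprocess
from .simulate import SimConfig, simulate_study
from .validation import run_condition

__all__ = [
    "study_responses",
    "cluster_type1_study",
    "recovery_study",
    "random_onset_study",
    "latency_shift_study",
]


def _study_events(runs):
    bouts = [b for _, pb, _, _ in runs for b in pb]
    events = extract_events(merge_bouts(bouts))
    kept, _ = participant_gate(events)
    return [ev for ev in events if ev.participant_id in kept]


def study_responses(cfg: SimConfig, raw: bool = True, params: EpochParams = EpochParams()):
    """Simulate a study and return (tidy HbO responses, events, truths)."""
    runs = simulate_study(cfg, raw=raw)
    if raw:
        hb = {pid: preprocess(rec) for pid, _, rec, _ in runs}
    else:
        hb = {pid: series for pid, _, series, _ in runs}
    events = _study_events(runs)
    shifted = exclude_short_isi(apply_shift(events, params), params)
    blocks = []
    for pid, series in hb.items():
        blocks.extend(extract_blocks(series, [e for e in shifted if e.participant_id == pid], params))
    responses = peak_window_mean(blocks, params)
    truths = {pid: gt for pid, _, _, gt in runs}
    return responses, events, truths


def cluster_type1_study(
    n_datasets: int = 200,
    base_seed: int = 0,
    alpha: float = 0.05,
    adjacency=None,
) -> float:
    """Cluster-level false-positive rate over null synthetic studies.

    Each dataset is a full 12-participant study with *no* active channels;
    a dataset counts as a false positive when any cluster reaches
    p < ``alpha``.  Returns the rejection rate.
    """
    adjacency = adjacency if adjacency is not None else load_adjacency()
    rejections = 0
    for i in range(n_datasets):
        cfg = SimConfig(seed=base_seed + i, active_channels=frozenset(), effect_amplitude_uM=0.0)
        runs = simulate_study(cfg, raw=False)
        hb = {pid: series for pid, _, series, _ in runs}
        events = _study_events(runs)
        shifted = exclude_short_isi(apply_shift(events))
        blocks = []
        for pid, series in hb.items():
            blocks.extend(extract_blocks(series, [e for e in shifted if e.participant_id == pid]))
        responses = peak_window_mean(blocks)
        clusters = cluster_test(responses, adjacency, seed=base_seed + i)
        if any(c.p_cluster < alpha for c in clusters):
            rejections += 1
    return rejections / n_datasets


def recovery_study(
    n_seeds: int = 50,
    base_seed: int = 0,
    alpha: float = 0.05,
    adjacency=None,
) -> float:
    """Fraction of seeds where the +3 s protocol recovers the active cluster.

    Runs the full raw-intensity pipeline (forward optics, motion correction,
    band-pass, MBLL) per seed; success means a significant cluster covering
    at least two truly active adjacent channels.
    """
    adjacency = adjacency if adjacency is not None else load_adjacency()
    hits = 0
    for i in range(n_seeds):
        cfg = SimConfig(seed=base_seed + 1000 + i)
        responses, _, truths = study_responses(cfg, raw=True)
        active = next(iter(truths.values())).active_channels
        clusters = cluster_test(responses, adjacency, seed=base_seed + i)
        if any(c.p_cluster < alpha and len(c.channels & active) >= 2 for c in clusters):
            hits += 1
    return hits / n_seeds


def random_onset_study(
    n_studies: int = 6,
    n_seeds_per_study: int = 100,
    base_seed: int = 0,
    alpha: float = 0.05,
    adjacency=None,
    clusters_per_study: int = 5,
) -> dict:
    """Negative control: randomized onsets should abolish significance.

    Simulates ``n_studies`` full studies (with the usual active channels)
    and reruns the random +/- 15-30 s onset condition with
    ``n_seeds_per_study`` different shift seeds on each.  Returns the
    fraction of draws with no FDR-significant ROI, the per-ROI uncorrected
    rejection rate (should sit near ``alpha``), and -- on the costlier
    cluster test, run for the first ``clusters_per_study`` seeds of each
    study -- the fraction with no significant cluster.
    """
    adjacency = adjacency if adjacency is not None else load_adjacency()
    no_roi = 0
    no_cluster = 0
    n_cluster_draws = 0
    roi_uncorrected = []
    for s in range(n_studies):
        cfg = SimConfig(seed=base_seed + 7 + 101 * s)
        runs = simulate_study(cfg, raw=True)
        hb = {pid: preprocess(rec) for pid, _, rec, _ in runs}
        events = _study_events(runs)
        for i in range(n_seeds_per_study):
            with_clusters = i < clusters_per_study
            res = run_condition(
                hb,
                events,
                "random",
                seed=base_seed + 1000 * s + i,
                adjacency=adjacency if with_clusters else None,
                n_perm=500,
            )
            if not (res.roi_table.q < alpha).any():
                no_roi += 1
            roi_uncorrected.append(float((res.roi_table.p < alpha).mean()))
            if with_clusters:
                n_cluster_draws += 1
                if res.min_cluster_p >= alpha:
                    no_cluster += 1
    n_total = n_studies * n_seeds_per_study
    return {
        "n_draws": n_total,
        "no_significant_roi_rate": no_roi / n_total,
        "roi_uncorrected_rejection_rate": float(np.mean(roi_uncorrected)),
        "no_significant_cluster_rate": no_cluster / max(n_cluster_draws, 1),
        "n_cluster_draws": n_cluster_draws,
    }


def latency_shift_study(seed: int = 0, adjacency=None) -> dict:
    """Peak-latency comparison of the +0 and +3 onset definitions.

    Returns the group-mean block-average peak latencies on the truly active
    channels and their difference, which should equal the 3 s shift (the
    underlying response is fixed; only the time origin moves).
    """
    cfg = SimConfig(seed=seed)
    runs = simulate_study(cfg, raw=True)
    hb = {pid: preprocess(rec) for pid, _, rec, _ in runs}
    events = _study_events(runs)
    act = sorted(cfg.active_channels)
    lat = {}
    for mode in (0.0, 3.0):
        res = run_condition(hb, events, mode, seed=seed)
        lat[mode] = float(res.mean_peak_latency()[act].mean())
    return {
        "latency_plus0_s": lat[0.0],
        "latency_plus3_s": lat[3.0],
        "difference_s": lat[0.0] - lat[3.0],
    }
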