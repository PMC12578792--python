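"""Shared fixtures: one fully processed synthetic study reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import natattn as na


@pytest.fixture(scope="session")
def default_cfg() -> na.SimConfig:
    """The emulated study conditions (12 participants, 44 ch, 20 min, 5 Hz)."""
    return na.SimConfig(seed=11)


@pytest.fixture(scope="session")
def study(default_cfg):
    """Simulated raw study plus preprocessed series and extracted events.

    Returns (cfg, hb_by_pid, events, truths).
    """
    runs = na.simulate_study(default_cfg, raw=True)
    hb = {pid: na.preprocess(rec) for pid, _, rec, _ in runs}
    bouts = [b for _, pb, _, _ in runs for b in pb]
    events = na.extract_events(na.merge_bouts(bouts))
    kept, _ = na.participant_gate(events)
    events = [ev for ev in events if ev.participant_id in kept]
    truths = {pid: gt for pid, _, _, gt in runs}
    return default_cfg, hb, events, truths


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
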