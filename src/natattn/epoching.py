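"""Event-locked epoching of concentration series.

Sustained-attention events are aligned to the hemodynamic series with a
configurable onset shift (+3 s by default: the first 3 s of a look serve as
an active baseline covering pre-attention and attention orienting), events
whose baselines would overlap the previous event's delayed response are
excluded (5 s minimum interstimulus interval between the previous block's
end and the next baseline's start), 18-s blocks (3 s baseline + 15 s
post-stimulus) are extracted and baseline-corrected, and the per-channel
response statistic is the mean over +/-2.5 s around the block-average peak
(maximum for HbO, minimum for HbR) inside the activation window.

Sample conventions: onsets map to the nearest sample; windows are half-open
[start, end), so an 18-s block at 5 Hz has 90 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .behavior import AttentionEvent
from .preprocess import HbSeries

__all__ = [
    "EpochParams",
    "Block",
    "apply_shift",
    "exclude_short_isi",
    "extract_blocks",
    "block_average",
    "peak_window_mean",
    "response_matrix",
]


@dataclass(frozen=True)
class EpochParams:
    """Epoching parameters (seconds).

    ``shift_s`` moves each behavioral look onset into the look before
    alignment ("random" draws per-event shifts of magnitude
    ``random_shift_range_s`` with random sign); the block spans
    [-baseline_s, +block_s) around the shifted onset; the peak statistic
    averages ``peak_halfwidth_s`` either side of the block-average peak found
    inside ``activation_window_s`` (post-stimulus time).
    """

    shift_s: float | str = 3.0
    baseline_s: float = 3.0
    block_s: float = 15.0
    min_isi_s: float = 5.0
    peak_halfwidth_s: float = 2.5
    activation_window_s: tuple[float, float] = (0.0, 15.0)
    random_shift_range_s: tuple[float, float] = (15.0, 30.0)

    def __post_init__(self) -> None:
        if self.baseline_s <= 0:
            raise ValueError("baseline_s must be positive")
        if self.peak_halfwidth_s > self.block_s / 2:
            raise ValueError("peak_halfwidth_s must be at most half the block")
        w0, w1 = self.activation_window_s
        if not 0 <= w0 < w1 <= self.block_s:
            raise ValueError("activation window must lie within the block")
        if isinstance(self.shift_s, str) and self.shift_s != "random":
            raise ValueError("shift_s must be a number or 'random'")


@dataclass
class Block:
    """One baseline-corrected event-locked segment ([-baseline_s, +block_s))."""

    event: AttentionEvent
    hbo: np.ndarray  # (n_channels, n_samples)
    hbr: np.ndarray
    sample_rate_hz: float
    baseline_samples: int
    baseline_corrected: bool = True


def apply_shift(
    events: list[AttentionEvent],
    params: EpochParams = EpochParams(),
    rng: np.random.Generator | None = None,
) -> list[AttentionEvent]:
    """Set each event's onset shift.

    Fixed mode adds ``params.shift_s`` for every event; random mode draws a
    per-event magnitude uniformly from ``random_shift_range_s`` with an
    equiprobable sign (requires ``rng``).
    """
    if params.shift_s == "random":
        if rng is None:
            raise ValueError("random shift mode requires an rng")
        lo, hi = params.random_shift_range_s
        out = []
        for ev in events:
            mag = rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            out.append(replace(ev, shift_s=sign * mag))
        return out
    return [replace(ev, shift_s=float(params.shift_s)) for ev in events]


def exclude_short_isi(
    events: list[AttentionEvent], params: EpochParams = EpochParams()
) -> list[AttentionEvent]:
    """Drop events whose baseline starts too soon after the previous block.

    The delayed hemodynamic response to one event must not bleed into the
    next event's baseline, so an event is excluded when the gap between the
    previous *kept* event's block end (shifted onset + block_s) and its own
    baseline start (shifted onset - baseline_s) is below ``min_isi_s``.
    Applied per participant in shifted-onset order.
    """
    kept: list[AttentionEvent] = []
    last_block_end: dict[str, float] = {}
    for ev in sorted(events, key=lambda e: (e.participant_id, e.shifted_onset_s)):
        baseline_start = ev.shifted_onset_s - params.baseline_s
        prev_end = last_block_end.get(ev.participant_id)
        if prev_end is not None and baseline_start - prev_end < params.min_isi_s:
            continue
        kept.append(ev)
        last_block_end[ev.participant_id] = ev.shifted_onset_s + params.block_s
    return kept


def extract_blocks(
    hb: HbSeries,
    events: list[AttentionEvent],
    params: EpochParams = EpochParams(),
    baseline_correct: bool = True,
) -> list[Block]:
    """Cut baseline-corrected blocks around each event's shifted onset.

    Blocks truncated by the recording edges are discarded (not an error).
    Baseline correction subtracts the mean of the ``baseline_s`` window per
    channel and chromophore and is idempotent.
    """
    fs = hb.sample_rate_hz
    n_base = int(round(params.baseline_s * fs))
    n_post = int(round(params.block_s * fs))
    blocks = []
    for ev in events:
        onset = int(round(ev.shifted_onset_s * fs))
        i0, i1 = onset - n_base, onset + n_post
        if i0 < 0 or i1 > hb.n_samples:
            continue
        hbo = hb.hbo[:, i0:i1].copy()
        hbr = hb.hbr[:, i0:i1].copy()
        if baseline_correct:
            hbo -= hbo[:, :n_base].mean(axis=1, keepdims=True)
            hbr -= hbr[:, :n_base].mean(axis=1, keepdims=True)
        blocks.append(Block(ev, hbo, hbr, fs, n_base, baseline_corrected=baseline_correct))
    return blocks


def block_average(blocks: list[Block], chromophore: str = "hbo") -> np.ndarray:
    """Average block segments: (n_channels, block_samples)."""
    if not blocks:
        raise ValueError("no blocks to average")
    data = np.stack([getattr(b, chromophore) for b in blocks])
    return data.mean(axis=0)


def peak_window_mean(
    blocks: list[Block],
    params: EpochParams = EpochParams(),
    chromophore: str = "hbo",
    peak_mode: str = "group",
) -> pd.DataFrame:
    """Per participant x channel peak-window response statistic.

    Blocks are averaged per participant.  With ``peak_mode='group'`` (the
    default) the peak is located per channel on the grand block average
    (unweighted mean of participant averages; argmax for HbO, argmin for
    HbR) inside the activation window, and each participant's response is
    the mean of their own block average over ``peak_halfwidth_s`` either
    side of the peak, clipped to the block.  Crucially the peak used for
    participant i is taken from the *leave-one-out* grand average (all
    other participants): a window position chosen independently of
    participant i's own noise leaves their response exactly mean-zero under
    the null, so downstream t-tests and sign-flip permutations keep their
    nominal error rates.  The reported ``peak_latency_s`` uses the
    full-sample grand average (one latency per channel).
    ``peak_mode='participant'`` locates the peak separately on each
    participant's own average instead; that variant is positively biased by
    max selection and is provided for sensitivity analyses only.

    Channels whose series are undefined (pruned) for a participant yield no
    row for that participant.  Columns: participant, channel, response,
    n_blocks, peak_latency_s (peak time relative to the shifted onset).
    """
    if chromophore not in ("hbo", "hbr"):
        raise ValueError("chromophore must be 'hbo' or 'hbr'")
    if peak_mode not in ("group", "participant"):
        raise ValueError("peak_mode must be 'group' or 'participant'")
    by_pid: dict[str, list[Block]] = {}
    for b in blocks:
        by_pid.setdefault(b.event.participant_id, []).append(b)
    if not by_pid:
        return pd.DataFrame(
            columns=["participant", "channel", "response", "n_blocks", "peak_latency_s"]
        )
    first = next(iter(by_pid.values()))[0]
    fs = first.sample_rate_hz
    n_base = first.baseline_samples
    w0, w1 = params.activation_window_s
    j0 = n_base + int(round(w0 * fs))
    j1 = n_base + int(round(w1 * fs))
    half = int(round(params.peak_halfwidth_s * fs))

    averages = {
        pid: block_average(pblocks, chromophore) for pid, pblocks in sorted(by_pid.items())
    }

    def _peak(avg_ch: np.ndarray) -> int | None:
        seg = avg_ch[j0:j1]
        if not np.all(np.isfinite(seg)):
            return None
        rel = np.argmin(seg) if chromophore == "hbr" else np.argmax(seg)
        return j0 + int(rel)

    grand_peaks: dict[int, int | None] = {}
    loo_peaks: dict[tuple[str, int], int | None] = {}
    if peak_mode == "group":
        import warnings

        stack = np.stack(list(averages.values()))  # (n_participants, n_ch, T)
        pids = list(averages)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN channels
            finite = np.isfinite(stack)
            total = np.where(finite, stack, 0.0).sum(axis=0)
            count_full = finite.sum(axis=0)
            grand = np.where(count_full > 0, total / np.maximum(count_full, 1), np.nan)
        for ch in range(grand.shape[0]):
            grand_peaks[ch] = _peak(grand[ch])
        if len(pids) > 1:
            for k, pid in enumerate(pids):
                own = stack[k]
                own_ok = np.isfinite(own)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    rest_count = count_full - own_ok.astype(int)
                    rest = np.where(
                        rest_count > 0,
                        (total - np.where(own_ok, own, 0.0)) / np.maximum(rest_count, 1),
                        np.nan,
                    )
                for ch in range(rest.shape[0]):
                    loo_peaks[(pid, ch)] = _peak(rest[ch])
        else:  # single participant: no leave-one-out trace exists
            for ch in grand_peaks:
                loo_peaks[(pids[0], ch)] = grand_peaks[ch]

    rows = []
    for pid, avg in averages.items():
        n_blocks = len(by_pid[pid])
        for ch in range(avg.shape[0]):
            if not np.all(np.isfinite(avg[ch, j0:j1])):
                continue
            peak = loo_peaks.get((pid, ch)) if peak_mode == "group" else _peak(avg[ch])
            if peak is None:
                continue
            lo = max(0, peak - half)
            hi = min(avg.shape[1], peak + half + 1)
            latency_peak = grand_peaks[ch] if peak_mode == "group" else peak
            rows.append(
                {
                    "participant": pid,
                    "channel": ch,
                    "response": float(avg[ch, lo:hi].mean()),
                    "n_blocks": n_blocks,
                    "peak_latency_s": (latency_peak - n_base) / fs,
                }
            )
    return pd.DataFrame(
        rows, columns=["participant", "channel", "response", "n_blocks", "peak_latency_s"]
    )


def response_matrix(responses: pd.DataFrame, n_channels: int | None = None) -> pd.DataFrame:
    """Pivot the tidy response table to participants x channels (NaN = missing)."""
    wide = responses.pivot(index="participant", columns="channel", values="response")
    if n_channels is not None:
        wide = wide.reindex(columns=range(n_channels))
    return wide
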