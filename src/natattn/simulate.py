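"""Synthetic naturalistic infant fNIRS sessions with known ground truth.

Emulates the structure of a toy-play session: lognormal look bouts to a
toy-dominant set of targets, a canonical double-gamma hemodynamic response
time-locked ~5 s into sufficiently long looks in designated active channels,
HbR as a scaled negative copy of HbO, and a two-wavelength optical forward
projection (same extinction table, pathlength and DPF as the inverse step)
onto a baseline intensity with 1/f drift, Mayer-wave and respiratory
oscillations, white noise, and spike/shift motion artifacts.

Because forward and inverse share the optics, the generator gives every
downstream stage a testable ground truth: latent concentrations, active
channels, and the event timeline.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.stats import gamma as gamma_dist

from .behavior import LookBout
from .preprocess import Recording, extinction_matrix

__all__ = [
    "NoiseSpec",
    "ArtifactSpec",
    "SimConfig",
    "GroundTruth",
    "double_gamma_hrf",
    "simulate_behavior",
    "latent_concentrations",
    "simulate_recording",
    "simulate_hb",
    "simulate_study",
    "write_recording_csv",
    "read_recording_csv",
    "write_recording_snirf",
    "read_recording_snirf",
    "write_ground_truth",
]

DEFAULT_TARGET_WEIGHTS = {
    "toy": 0.70,
    "mom": 0.08,
    "mbody": 0.06,
    "bbody": 0.06,
    "cables": 0.04,
    "curtain": 0.03,
    "door": 0.03,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological/instrumental noise amplitudes, in optical-density units.

    Drift is low-pass-filtered Gaussian noise (1/f-like below ~0.02 Hz);
    Mayer waves (~0.1 Hz) and respiration (~0.4 Hz) are random-phase
    sinusoids with per-channel amplitude jitter; white noise is i.i.d.
    """

    drift_sd: float = 1.0e-3
    mayer_amp: float = 5.0e-4
    mayer_freq_hz: float = 0.1
    resp_amp: float = 3.0e-4
    resp_freq_hz: float = 0.4
    white_sd: float = 3.0e-4

    def disabled(self) -> "NoiseSpec":
        return NoiseSpec(0.0, 0.0, self.mayer_freq_hz, 0.0, self.resp_freq_hz, 0.0)


@dataclass(frozen=True)
class ArtifactSpec:
    """Motion-artifact process: exponential spikes and sustained baseline shifts."""

    spike_rate_per_min: float = 0.5
    spike_amp: float = 0.02
    spike_decay_s: float = 0.5
    shift_rate_per_min: float = 0.2
    shift_amp: float = 0.01

    def disabled(self) -> "ArtifactSpec":
        return ArtifactSpec(0.0, 0.0, self.spike_decay_s, 0.0, 0.0)


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Defaults encode the emulated study conditions: 12 participants, 44
    channels at 5 Hz for a 20-minute session, sustained-attention HRFs in
    three adjacent active channels, attention onset ~5 s into a look, toy
    bouts averaging ~5 s (other targets ~3 s) with ~3 s gaps, and a 0.3 uM
    HbO peak effect with 0.1 uM between-participant variability.
    """

    n_participants: int = 12
    n_channels: int = 44
    sample_rate_hz: float = 5.0
    session_length_s: float = 1200.0
    active_channels: frozenset[int] = field(default_factory=lambda: frozenset({8, 9, 10}))
    effect_amplitude_uM: float = 0.3
    effect_between_sd_uM: float = 0.1
    hbr_ratio: float = 1.0 / 3.0
    hrf_peak_delay_s: float = 5.5
    hrf_undershoot_delay_s: float = 15.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    hrf_onset_lag_s: float = 5.0
    event_threshold_s: float = 8.0
    bout_duration_lognorm: tuple[float, float] = (1.4, 0.6)
    nontoy_duration_lognorm: tuple[float, float] = (1.0, 0.6)
    gap_duration_lognorm: tuple[float, float] = (0.9, 0.7)
    target_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_WEIGHTS)
    )
    noise: NoiseSpec = NoiseSpec()
    artifact: ArtifactSpec = ArtifactSpec()
    baseline_intensity: float = 5.0
    wavelengths_nm: tuple[float, float] = (763.0, 841.0)
    dpf: tuple[float, float] = (5.1, 5.1)
    distance_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.session_length_s < 0:
            raise ValueError("session_length_s must be non-negative")
        if self.effect_amplitude_uM < 0:
            raise ValueError("effect_amplitude_uM must be non-negative")
        if any(not 0 <= c < self.n_channels for c in self.active_channels):
            raise ValueError("active_channels must lie in [0, n_channels)")
        for f in (self.noise.mayer_freq_hz, self.noise.resp_freq_hz):
            if f >= self.sample_rate_hz / 2:
                raise ValueError("noise oscillation frequency must be below Nyquist")

    def participant_ids(self) -> list[str]:
        return [f"p{i + 1:02d}" for i in range(self.n_participants)]


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    participant_id: str
    bouts: list[LookBout]
    active_channels: frozenset[int]
    latent_hbo: np.ndarray  # (n_channels, n_samples), mol/L, noise-free
    latent_hbr: np.ndarray
    effect_amplitude_uM: float


def _participant_rng(seed: int, participant_id: str, stream: int = 0) -> np.random.Generator:
    # stable across sessions/platforms: participant identity enters via CRC32
    tag = zlib.crc32(participant_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed, tag, stream])


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay_s: float = 5.5,
    undershoot_delay_s: float = 15.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF, normalized to unit peak.

    Gamma pdfs with unit scale peak at (shape - 1), so shapes are chosen as
    delay + 1; the undershoot is subtracted at ``undershoot_ratio``.
    """
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak_delay_s + 1.0) - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_delay_s + 1.0
    )
    peak = h.max()
    return h / peak if peak > 0 else h


def simulate_behavior(cfg: SimConfig, participant_id: str) -> list[LookBout]:
    """Draw one participant's look-bout timeline.

    Alternates lognormal gaps and lognormal bouts until the session ends;
    targets are sampled from the toy-dominant weights, with toy bouts drawn
    from a longer-duration lognormal than other targets.  Deterministic for
    a given (cfg.seed, participant_id).
    """
    rng = _participant_rng(cfg.seed, participant_id, stream=0)
    targets = list(cfg.target_weights)
    w = np.array([cfg.target_weights[k] for k in targets], dtype=float)
    w = w / w.sum()
    bouts: list[LookBout] = []
    t = 0.0
    while True:
        t += rng.lognormal(*cfg.gap_duration_lognorm)
        target = targets[rng.choice(len(targets), p=w)]
        mu, sigma = (
            cfg.bout_duration_lognorm if target == "toy" else cfg.nontoy_duration_lognorm
        )
        dur = rng.lognormal(mu, sigma)
        if t + dur > cfg.session_length_s:
            break
        bouts.append(LookBout(participant_id, target, round(t, 3), round(t + dur, 3)))
        t += dur
    return bouts


def latent_concentrations(
    cfg: SimConfig, bouts: list[LookBout], amplitude_uM: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (hbo, hbr) series implied by the bout timeline.

    For every bout longer than ``event_threshold_s``, a boxcar starting
    ``hrf_onset_lag_s`` into the bout and lasting to its end is convolved
    with the double-gamma HRF and scaled so each event's response peaks at
    ``amplitude_uM``; responses are summed onto the active channels.  HbR is
    a negative scaled copy.  Inactive channels are exactly zero.
    """
    fs = cfg.sample_rate_hz
    n_t = int(round(cfg.session_length_s * fs))
    amp = cfg.effect_amplitude_uM if amplitude_uM is None else amplitude_uM
    hbo = np.zeros((cfg.n_channels, n_t))
    kernel_t = np.arange(0, 32.0, 1.0 / fs)
    kernel = double_gamma_hrf(
        kernel_t, cfg.hrf_peak_delay_s, cfg.hrf_undershoot_delay_s, cfg.hrf_undershoot_ratio
    )
    signal = np.zeros(n_t)
    for b in bouts:
        if b.duration_s <= cfg.event_threshold_s:
            continue
        i0 = int(round((b.start_s + cfg.hrf_onset_lag_s) * fs))
        i1 = int(round(b.end_s * fs))
        if i1 <= i0 or i0 >= n_t:
            continue
        box = np.zeros(n_t)
        box[i0 : min(i1, n_t)] = 1.0
        resp = np.convolve(box, kernel)[:n_t]
        m = resp.max()
        if m > 0:
            signal += resp * (amp * 1e-6 / m)
    for ch in cfg.active_channels:
        hbo[ch] = signal
    hbr = -cfg.hbr_ratio * hbo
    return hbo, hbr


def _noise_od(cfg: SimConfig, rng: np.random.Generator, n_ch: int, n_t: int) -> np.ndarray:
    """Additive OD-domain noise for (n_ch, 2 wavelengths, n_t)."""
    ns = cfg.noise
    fs = cfg.sample_rate_hz
    t = np.arange(n_t) / fs
    out = np.zeros((n_ch, 2, n_t))
    if ns.white_sd > 0:
        out += rng.normal(0.0, ns.white_sd, size=out.shape)
    if ns.drift_sd > 0 and n_t > 30:
        w = rng.normal(size=(n_ch, 2, n_t))
        b, a = butter(2, min(0.02 / (fs / 2), 0.99), btype="lowpass")
        drift = filtfilt(b, a, w, axis=-1)
        sd = drift.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        out += drift / sd * ns.drift_sd
    for amp, freq in ((ns.mayer_amp, ns.mayer_freq_hz), (ns.resp_amp, ns.resp_freq_hz)):
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 2, 1))
            jitter = rng.uniform(0.7, 1.3, size=(n_ch, 2, 1))
            out += amp * jitter * np.sin(2 * np.pi * freq * t[None, None, :] + phase)
    return out


def _artifact_od(cfg: SimConfig, rng: np.random.Generator, n_ch: int, n_t: int) -> np.ndarray:
    ar = cfg.artifact
    fs = cfg.sample_rate_hz
    minutes = n_t / fs / 60.0
    t = np.arange(n_t) / fs
    out = np.zeros((n_ch, 2, n_t))
    for ch in range(n_ch):
        n_spk = rng.poisson(ar.spike_rate_per_min * minutes) if ar.spike_rate_per_min > 0 else 0
        for _ in range(n_spk):
            t0 = rng.uniform(0, n_t / fs)
            sign = rng.choice([-1.0, 1.0])
            pulse = sign * ar.spike_amp * np.exp(-np.abs(t - t0) / ar.spike_decay_s)
            out[ch] += pulse[None, :]  # motion affects both wavelengths together
        n_shf = rng.poisson(ar.shift_rate_per_min * minutes) if ar.shift_rate_per_min > 0 else 0
        for _ in range(n_shf):
            i0 = rng.integers(0, n_t)
            sign = rng.choice([-1.0, 1.0])
            out[ch, :, i0:] += sign * ar.shift_amp
    return out


def forward_project(
    cfg: SimConfig, hbo: np.ndarray, hbr: np.ndarray
) -> np.ndarray:
    """Concentrations (mol/L) to OD at both wavelengths via Beer-Lambert."""
    e = extinction_matrix(cfg.wavelengths_nm)
    pathlength = (cfg.distance_mm / 10.0) * np.asarray(cfg.dpf)  # cm * DPF, per wavelength
    conc = np.stack([hbo, hbr], axis=1)  # (n_ch, 2, n_t)
    od = np.einsum("ij,cjt->cit", e, conc) * pathlength[None, :, None]
    return od


def simulate_recording(
    cfg: SimConfig, bouts: list[LookBout], participant_id: str | None = None
) -> tuple[Recording, GroundTruth]:
    """Raw two-wavelength intensity recording for one participant's timeline.

    Latent concentrations are forward-projected to OD, noise and artifacts
    are added in the OD domain, and the result is exponentiated onto the
    baseline intensity: I = I0 * 10**(-OD).
    """
    if participant_id is None:
        participant_id = bouts[0].participant_id if bouts else "p01"
    for a, b in zip(bouts, bouts[1:]):
        if b.start_s < a.end_s:
            raise ValueError("bouts must be non-overlapping and sorted")
    rng = _participant_rng(cfg.seed, participant_id, stream=1)
    amp = cfg.effect_amplitude_uM
    if cfg.effect_between_sd_uM > 0:
        amp = max(0.0, rng.normal(cfg.effect_amplitude_uM, cfg.effect_between_sd_uM))
    hbo, hbr = latent_concentrations(cfg, bouts, amplitude_uM=amp)
    n_t = hbo.shape[1]
    od = forward_project(cfg, hbo, hbr)
    od += _noise_od(cfg, rng, cfg.n_channels, n_t)
    od += _artifact_od(cfg, rng, cfg.n_channels, n_t)
    intensity = cfg.baseline_intensity * 10.0 ** (-od)
    rec = Recording(
        participant_id=participant_id,
        intensity=intensity,
        sample_rate_hz=cfg.sample_rate_hz,
        wavelengths_nm=cfg.wavelengths_nm,
        channels=[(i, i, cfg.distance_mm) for i in range(cfg.n_channels)],
    )
    gt = GroundTruth(participant_id, list(bouts), cfg.active_channels, hbo, hbr, amp)
    return rec, gt


def simulate_hb(
    cfg: SimConfig, bouts: list[LookBout], participant_id: str | None = None
):
    """Concentration-domain shortcut: latent series plus band-limited noise.

    Skips the optics round trip (which forward/inverse sharing makes exactly
    invertible) and returns an :class:`~natattn.preprocess.HbSeries` whose
    noise is the Beer-Lambert inversion of the OD-domain noise model, plus
    the ground truth.  Used for large repeated-simulation studies.
    """
    from .preprocess import HbSeries, bandpass, mbll

    if participant_id is None:
        participant_id = bouts[0].participant_id if bouts else "p01"
    rng = _participant_rng(cfg.seed, participant_id, stream=1)
    amp = cfg.effect_amplitude_uM
    if cfg.effect_between_sd_uM > 0:
        amp = max(0.0, rng.normal(cfg.effect_amplitude_uM, cfg.effect_between_sd_uM))
    hbo, hbr = latent_concentrations(cfg, bouts, amplitude_uM=amp)
    noise_od = _noise_od(cfg, rng, cfg.n_channels, hbo.shape[1])
    noise_od = bandpass(noise_od, cfg.sample_rate_hz)
    n_hbo, n_hbr = mbll(noise_od, cfg.dpf, cfg.distance_mm, cfg.wavelengths_nm)
    gt = GroundTruth(participant_id, list(bouts), cfg.active_channels, hbo, hbr, amp)
    return (
        HbSeries(participant_id, hbo + n_hbo, hbr + n_hbr, cfg.sample_rate_hz),
        gt,
    )


def simulate_study(cfg: SimConfig, raw: bool = True):
    """Simulate every participant; yields (participant_id, bouts, data, truth).

    ``data`` is a raw :class:`Recording` when ``raw`` else an
    :class:`~natattn.preprocess.HbSeries` from the concentration-domain path.
    """
    out = []
    for pid in cfg.participant_ids():
        bouts = simulate_behavior(cfg, pid)
        if raw:
            data, gt = simulate_recording(cfg, bouts, pid)
        else:
            data, gt = simulate_hb(cfg, bouts, pid)
        out.append((pid, bouts, data, gt))
    return out


# ---------------------------------------------------------------------------
# serialization


def write_recording_csv(rec: Recording, path) -> None:
    """Long-format CSV: time_s, channel, wavelength_nm, intensity."""
    n_ch, n_wl, n_t = rec.intensity.shape
    t = np.arange(n_t) / rec.sample_rate_hz
    frames = []
    for w, wl in enumerate(rec.wavelengths_nm):
        df = pd.DataFrame(rec.intensity[:, w, :].T, columns=range(n_ch))
        df.insert(0, "time_s", t)
        df = df.melt(id_vars="time_s", var_name="channel", value_name="intensity")
        df["wavelength_nm"] = wl
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out[["time_s", "channel", "wavelength_nm", "intensity"]].to_csv(path, index=False)


def read_recording_csv(path, participant_id: str = "unknown", sample_rate_hz: float = 5.0) -> Recording:
    df = pd.read_csv(path)
    wls = sorted(df["wavelength_nm"].unique())
    chans = sorted(df["channel"].unique())
    times = np.sort(df["time_s"].unique())
    arr = np.empty((len(chans), len(wls), len(times)))
    for w, wl in enumerate(wls):
        sub = df[df["wavelength_nm"] == wl].pivot(
            index="channel", columns="time_s", values="intensity"
        )
        arr[:, w, :] = sub.loc[chans, times].to_numpy()
    if len(times) > 1:
        sample_rate_hz = 1.0 / np.median(np.diff(times))
    return Recording(
        participant_id=participant_id,
        intensity=arr,
        sample_rate_hz=float(sample_rate_hz),
        wavelengths_nm=tuple(float(w) for w in wls),
    )


def write_recording_snirf(rec: Recording, path) -> None:
    """Minimal SNIRF (HDF5) writer: one data block of raw CW amplitudes."""
    import h5py

    n_ch, n_wl, n_t = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs1")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=np.bytes_(rec.participant_id))
        meta.create_dataset("LengthUnit", data=np.bytes_("mm"))
        meta.create_dataset("TimeUnit", data=np.bytes_("s"))
        data = nirs.create_group("data1")
        series = rec.intensity.reshape(n_ch * n_wl, n_t).T  # (time, measurement)
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(n_t) / rec.sample_rate_hz)
        k = 1
        for ch in range(n_ch):
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=rec.channels[ch][0] + 1)
                ml.create_dataset("detectorIndex", data=rec.channels[ch][1] + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
        n_opt = max(max(s, d) for s, d, _ in rec.channels) + 1
        pos = np.zeros((n_opt, 3))
        pos[:, 0] = np.arange(n_opt) * 30.0
        probe.create_dataset("sourcePos3D", data=pos)
        det = pos.copy()
        det[:, 1] = 20.0
        probe.create_dataset("detectorPos3D", data=det)


def read_recording_snirf(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs1"]
        pid = nirs["metaDataTags/SubjectID"][()].decode()
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        wavelengths = tuple(float(w) for w in np.asarray(nirs["probe/wavelengths"]))
        n_wl = len(wavelengths)
        keys = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda s: int(s[len("measurementList"):]),
        )
        pairs = []
        for k in keys:
            ml = data[k]
            pairs.append(
                (int(ml["sourceIndex"][()]) - 1, int(ml["detectorIndex"][()]) - 1,
                 int(ml["wavelengthIndex"][()]) - 1)
            )
    n_ch = len(pairs) // n_wl
    arr = np.empty((n_ch, n_wl, series.shape[0]))
    chan_of_pair: dict[tuple[int, int], int] = {}
    channels: list[tuple[int, int, float]] = []
    for col, (s, d, w) in enumerate(pairs):
        if (s, d) not in chan_of_pair:
            chan_of_pair[(s, d)] = len(channels)
            channels.append((s, d, 20.0))
        arr[chan_of_pair[(s, d)], w, :] = series[:, col]
    fs = 1.0 / np.median(np.diff(time)) if len(time) > 1 else 5.0
    return Recording(
        participant_id=pid,
        intensity=arr,
        sample_rate_hz=float(fs),
        wavelengths_nm=wavelengths,
        channels=channels,
    )


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Sidecar JSON with the event timeline and active-channel truth."""
    payload = {
        "participant_id": gt.participant_id,
        "active_channels": sorted(gt.active_channels),
        "effect_amplitude_uM": gt.effect_amplitude_uM,
        "bouts": [
            {"target": b.target, "start_s": b.start_s, "end_s": b.end_s}
            for b in gt.bouts
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
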