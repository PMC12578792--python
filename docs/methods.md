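# Methods

This note documents the models, parameters and design choices behind
`natattn`, in the order data flows through the package.

## Behavioral events

Video-coded look bouts arrive as tab-delimited rows
(`participant, target, start_s, end_s`; seconds, session-relative).
Consecutive same-target bouts separated by ≤ 100 ms are merged before any
duration rule is applied: 100 ms is the lower bound of saccade-planning
latency, so a shorter look-away does not indicate an attention shift. The
merge is exposed as an explicit operation so that corpora in which coders
already applied the rule and corpora in which they did not are both
reproducible.

Sustained-attention events are merged bouts **strictly longer than 8 s**
("more than 8 s" is read as a strict inequality; an 8.000 s bout is not an
event), capped at 15 s to bound intra-subject variability. Non-toy targets
are excluded by configuration (`allowed_targets`), not hard-coded: long
looks at people do occur but are typically too sparse to analyze.
Participants with fewer than 5 events are excluded; the gate emits a
per-participant report so attrition is auditable.

## Signal chain

All steps are deterministic.

* **Pruning** — channels whose mean raw amplitude at either wavelength
  falls outside (2, 10) device units are flagged; recordings with < 300 s
  of data or > 50% bad channels are rejected outright (a distinct error,
  not per-channel pruning). The bounds are raw-amplitude bounds: the
  device unit is vendor-specific, so they are configurable. A
  source–detector distance filter (default 0–45 mm) implements the usual
  channel-geometry screen; all ~20 mm channels pass.
* **Optical density** — OD(t) = −log₁₀(I(t)/Ī) with Ī the channel's
  temporal mean. OD is therefore mean-relative; all downstream
  concentrations are *changes*, defined up to a constant.
* **Wavelet correction** — per series, a `db2` discrete wavelet
  decomposition (4 levels, symmetric padding); detail coefficients lying
  more than 0.8 interquartile ranges outside the level's quartiles are
  zeroed. Spikes concentrate in outlying detail coefficients; smooth
  hemodynamics pass nearly unchanged (< 5% RMS change on clean signal).
* **Motion detection + spline correction** — a 1 s moving-SD exceeding 5×
  the series' median moving-SD marks motion segments. Within each segment
  a smoothing spline (λ = (1−p)/p with p = 0.99) is fitted and
  subtracted; the segment is re-anchored to continue from the preceding
  sample and the remainder of the series is offset to meet the corrected
  segment's end. This removes both spike trajectories and sustained
  baseline steps while leaving unmasked samples untouched except for the
  level re-anchoring.
* **Band-pass** — 3rd-order Butterworth, 0.01–1 Hz, applied
  forward–backward (`filtfilt`) so epoch timing is not phase-shifted.
  Zero-phase IIR at this order attenuates the block-average peak of an
  event response by ~2%; recovery tests therefore compare pipeline output
  against identically filtered latent truth, while the optical round trip
  (OD → MBLL) is checked against raw truth.
* **MBLL** — per channel the 2×2 system
  ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·DPF(λ) is solved at every
  sample, with d = 20 mm, DPF = (5.1, 5.1) and extinction coefficients
  linearly interpolated from the packaged standard table
  (`data/extinction_coefficients.tsv`). The synthetic forward model uses
  the same table, distance and DPF, so forward + inverse is exact by
  construction (measured < 0.03% RMS).

## Epoching and the peak-window statistic

Onsets map to the nearest sample; all windows are half-open `[start, end)`,
so an 18-s block at 5 Hz is exactly 90 samples (15 baseline + 75
post-onset). An event is dropped when the gap between the previous kept
event's block end and its own baseline start is under 5 s — the reading
forced by the rule's purpose, preventing the delayed response from
bleeding into the next baseline. Blocks truncated by recording edges are
discarded, not errors. Baseline correction (subtract the 3-s baseline
mean per channel/chromophore) is idempotent.

Per participant × channel the response statistic is the mean over ±2.5 s
around the block-average peak (argmax for HbO, argmin for HbR) within the
activation window (default: the full 15-s post-onset block), clipped at
block edges so every participant stays estimable.

**Where the peak is located matters more than anything else in this
pipeline.** Three variants were considered:

* *per-participant peak* — argmax of each participant's own average. Max
  selection makes the statistic strictly positive in expectation under
  the null; in simulation every ROI and even randomized onsets come out
  "significant". Kept only as `peak_mode="participant"` for sensitivity
  analyses.
* *pooled group peak* — argmax of the grand average, shared by all
  participants. Better, but each participant contributes to the trace on
  which the maximum is taken, so the group mean at the selected time is
  still biased upward; simulated cluster-level type-I error was ~15% at
  a nominal 5%.
* *leave-one-out group peak (default)* — participant *i*'s window is
  centered on the peak of the grand average computed **without**
  participant *i*. A window position independent of the participant's own
  noise leaves their response exactly mean-zero under the null, so
  t-tests and sign-flip permutations keep nominal error rates (measured
  cluster type-I ≈ 5–7% over 200 null studies), while under a real
  effect all leave-one-out peaks coincide near the true peak and the
  statistic is essentially the pooled one.

Reported peak latencies always come from the full-sample grand average
(one latency per channel).

## Group inference

ROI values are per-participant means of available channel responses; a
participant lacking every channel of an ROI is omitted from that ROI only,
which is what makes degrees of freedom vary across ROIs. One-tailed
one-sample t-tests (HbO: increase; HbR: decrease), Cohen's d = x̄/s, post
hoc power from the noncentral t at α = 0.05, and Benjamini–Hochberg FDR
across units. BH is the default rather than a π₀-estimating q-value
procedure: with six p-values any π₀ smoother is unstable, and published
q-values produced that way are not reproducible by standard estimators. A
Storey-style mode with a *fixed, user-supplied* π₀ is available.

The published per-ROI table that serves as the package's worked example
reproduces exactly under these conventions (t to 3 decimals, p to 3, d to
2) with one quirk: its power column corresponds to evaluating one-tailed
noncentral-t power at the full sample size (n = 12) for every ROI, even
rows whose df = 10 implies n = 11. `reference.closure_table()` applies
that convention; the package's own tables use each ROI's actual n.

The cluster test thresholds channel t-values at t > 2.0, groups
supra-threshold channels by the configured adjacency, sums t-values into
cluster masses, and builds the null from the maximum mass under random
sign flips of each participant's whole response vector (preserving spatial
correlation). With n participants and 2ⁿ ≤ 4096 all sign patterns are
enumerated (exact; the plain proportion is the p-value, and the identity
pattern bounds p below by 2⁻ⁿ); otherwise 1000 sampled flips with the
add-one convention p = (1+#{null ≥ obs})/(1+n_perm), which is valid
regardless of sampling. The test is one-sided on positive masses,
matching the directional HbO hypothesis.

## Synthetic data

The generator emulates the study conditions rather than any particular
dataset:

* **Timeline** — alternating lognormal gaps (μ = 0.9, σ = 0.7; mean
  ≈ 3.1 s) and bouts; toy bouts μ = 1.4, σ = 0.6 (mean ≈ 4.9 s), other
  targets μ = 1.0 (mean ≈ 3.3 s), targets drawn toy-dominant (70%).
  These place mean looks inside the observed 1.8–5.7 s range, make toys
  the longest-attended target, and yield ~8–20 sustained toy events per
  20-minute session, comfortably above the 5-event gate.
* **Response** — for every bout longer than 8 s, a boxcar starting 5 s
  into the bout (the sustained-attention latency) convolved with a
  canonical double-gamma HRF (peak 5.5 s, undershoot 15 s, ratio 1/6),
  normalized per event so its peak equals the participant's amplitude,
  added to the three active channels; HbR = −HbO/3, the simplest model
  consistent with opposing chromophore traces. Group amplitude 0.3 µM
  with 0.1 µM between-participant SD — the scale of the published ROI
  means read as µM. With these timings the group block-average peak falls
  ~9–10 s after the +3 s shifted onset (orienting 5 s + hemodynamic
  delay), and moving the onset definition moves the measured latency by
  exactly the shift.
* **Noise and artifacts** (OD units) — low-pass-filtered drift
  (SD 1e-3), Mayer waves (5e-4 at 0.1 Hz) and respiration (3e-4 at
  0.4 Hz) with random phase and ±30% amplitude jitter per channel, white
  noise (3e-4), plus exponential spikes (0.5/min, 0.02) and sustained
  steps (0.2/min, 0.01) applied to both wavelengths together, as real
  optode motion is.
* **Optics** — latent concentrations are forward-projected through the
  same extinction table/DPF/distance as the inverse step and exponentiated
  onto a baseline intensity of 5.0 device units (the midpoint of the
  pruning bounds, so clean channels survive pruning).

What the generator does **not** emulate: photon-migration forward
modeling, cardiac pulsation (unresolvable at 5 Hz), caregiver-speech or
social confounds, heterogeneous channel quality, and real spatial
correlation of physiological noise across channels (noise is independent
per channel). Passing tests therefore demonstrate the *procedure's*
correctness and operating characteristics under a realistic signal
structure — not that any particular real dataset will show an effect.

## Simulation experiments and problem sizes

`natattn.experiments` packages the desk-scale studies used for
verification: cluster type-I error over 200 null studies (concentration-
domain generator path — the deterministic optics add nothing to null
behavior), recovery over 50 full raw-pipeline seeds (success = significant
cluster covering ≥ 2 truly active channels; measured 100%), the +0/+3
latency comparison, and the randomized-onset negative control (6 studies
× 100 shift seeds; ~95% of draws show no FDR-significant ROI, per-ROI
uncorrected false-positive rate ≈ 5%). The residual few percent of
"significant" random-onset draws are dominated by genuine leakage —
a ±15–30 s shifted window overlapping a neighboring event's response —
which is a property of dense naturalistic timelines, not a test error.

## Known limitations

* The channel adjacency and ROI membership shipped under `data/` are an
  illustrative 2×22-channel layout; real analyses must supply maps derived
  from their optode geometry and an infant atlas.
* Short-separation regression, global-signal removal and scalp-coupling
  indices are out of scope (the latter impossible at 5 Hz).
* Block averaging only; no GLM/deconvolution HRF estimation.
* One session per participant; multi-session concatenation is not
  implemented.
* The spline correction assumes motion segments are sparse; overlapping
  or very long segments degrade to mean-detrending.
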