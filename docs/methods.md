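# Methods

## Model and assumptions

The package infers stylet penetration ("probing") of a single aphid from the
motion of its tracked body centre point inside a circular arena.  The core
assumption is behavioural: an aphid whose centre point is on the leaf disc
and essentially motionless is penetrating the tissue, because walking,
searching, and grooming all move the body centroid measurably while probing
fixes the mouthparts to the substrate.  The assumption fails for sessile
non-probing behaviour (resting), which is why long observations can dilute
the signal and why durations derived this way overestimate feeding relative
to electrode-based (EPG) measurements of actual stylet activity.

Arena geometry is two concentric circles: the leaf disc (zone 1) of radius
`disc_radius` (default 3.0 mm) inside the arena wall (`wall_radius`,
default 3.25 mm — a 96-well microtitre well).  The outer `zone1_margin`
(default 0.75 mm) of the disc is excluded from zone 1 so subjects on the
wall or disc rim are not credited to the disc.  Only zone-1 behaviour feeds
the probe detector and (by default) the distance-moved variable.

## Kinematics

Acquisition tracks (default 25 frames s⁻¹) are down-sampled to the analysis
rate (5 samples s⁻¹) by taking every k-th frame; positional averaging over
the k frames is available via `average_positions` (whether the original
system averaged positions or speeds over its 5-frame window is not
documented; speed averaging is the default).  Instantaneous speed is the
backward finite difference between consecutive analysis samples; reported
speed is its centred 5-sample moving average, shrunk at the series
boundaries, with the first sample inheriting the first defined difference so
constant-velocity tracks report constant speed.  Undetected gaps of at most
`gap_max` (1 s) are linearly interpolated for kinematics only — samples stay
flagged undetected for QC; longer gaps leave speed undefined (NaN) and the
zone `UNDETECTED`, and such samples can never start a probe, always end one,
and hold the state of the moving/not-moving machine.

## Probe state machine

Thresholds (per species, `SpeciesProfile`):

| parameter | default | meaning |
|---|---|---|
| `v_probe_start` | 0.02 mm/s | stillness level opening a probe |
| `t_probe_start` | 10 s | dwell required to confirm a probe start |
| `v_probe_stop` | 0.3 (0.35) mm/s | excursion level ending a probe, *M. persicae* (*N. ribisnigri*) |
| `v_hysteresis` | 0.1 mm/s | level the excursion must stay above |
| `t_probe_stop` | 2 s | excursion dwell confirming the stop |
| `v_move_start` / `v_move_stop` | 0.3 / 0.02 mm/s | moving/not-moving thresholds (no dwell) |

A probe starts at the first sample where the subject is in zone 1 with speed
below `v_probe_start`, provided speed is defined and never exceeds
`v_probe_stop` during the following `t_probe_start` seconds.  The window
constrains **speed only**: zone membership is required at the start sample,
and a zone exit simply force-ends the (possibly very young) probe at the
exit sample.  This choice is deliberate — it reproduces the documented
disc-edge artifact, where a subject straddling the zone boundary yields a
train of very short probes, which the post-hoc filter then removes
(see below).  The alternative reading (the whole window must sit in zone 1)
would make probes shorter than 10 s structurally impossible and the 3-s
filter vacuous against the detector's own output.

A probe stops when speed exceeds `v_probe_stop` and does not fall below
`v_hysteresis` for `t_probe_stop` seconds; the stop is timestamped at the
excursion onset and the excursion itself is non-probing.  An excursion that
dips below the hysteresis level in time is ignored (short body movements
during probing — reproduction, honeydew excretion — must not end probes).

Corner rules, chosen where the behaviour is otherwise undefined and encoded
identically in the test oracle: threshold comparisons are strict
(at-threshold samples never trigger); a zone exit or detection loss during
an unconfirmed stop excursion ends the probe at the exit sample; an
excursion still unconfirmed when the data end leaves the probe running to
the observation end; an all-undetected series yields one non-probe interval
with a warning.  All intervals are half-open `[start, stop)` in seconds from
observation start, and probe + non-probe intervals tile the observation
exactly (a property the suite enforces).

**Zone-transition filter.**  Probes shorter than 3 s whose preceding
non-probe bout lasted at most 15 s are relabelled non-probing in a single
left-to-right pass over the original stream (durations and gaps are measured
on the unfiltered stream; a leading probe with no preceding gap is kept).
Both constants are configurable (`FilterParams`).

## Response variables

Probe categories, decided by full bout duration: short `< 180 s`, long
`≥ 1500 s`, sustained `> 2100 s`, other = not long.  The long boundary is
inclusive and the sustained boundary exclusive; assay tables print these
categories inconsistently (`>25` vs `≥25 min`), so the thresholds and their
openness are configurable (`ProbeCategories`).  Durations are reported in
minutes, distance in cm.  Mean long-probe duration and latency to the first
long probe are *absent* (`None`), not zero, when no long probe occurred.
Per-bin summaries (default 1-h bins) apportion a probe's time to bins pro
rata by overlap while its category is decided by its full duration, so
per-bin values sum to whole-observation totals.  QC excludes observations
whose fraction of detected analysis samples falls below 0.9 (the source
protocol dropped low-detection arenas without stating a numeric threshold;
0.9 is this package's default and is configurable).

## Validation against manual annotations

Overlap is open-interval intersection > 0 (touching endpoints do not match).
A manual probe is detected iff ≥ 1 automated probe overlaps it; multiplicity
≥ 2 marks it overrated (split), and one automated probe overlapping ≥ 2
manual probes marks those underrated (merged).  Offsets (automated − manual)
are computed per matched pair; with multiplicity ≥ 2 the automated probe
with the most similar duration is used, ties broken by earlier start.
Aggregate offsets carry t-based 95% confidence intervals (the CI method of
the original report is unstated; the suite checks t-CIs against a bootstrap).
Correlation reports choose Pearson, log-Pearson, or Spearman by Shapiro
normality checks at α = 0.05.

## Power simulation

Each plant line × variable is a normal distribution truncated to
`[lower_bound, upper_bound]` — zero or the category's minimum duration below,
the recording duration above.  Pools of 10⁴ accepted values are built by
rejection sampling (redrawing keeps the pool size exact; specs with < 1%
acceptance are refused as degenerate).  Detection rate: per iteration
(default 1000) and per variable, n replicates per line are subsampled
without replacement and compared by a two-sample Student's t-test (Welch via
`equal_var=False`); the iteration is significant if any variable's p-value
is below `alpha_per_test` (0.025 for two video variables — Bonferroni over
the family).  The Monte-Carlo standard error `sqrt(p(1-p)/iterations)` is
reported alongside.  Variables are simulated independently (no correlation
structure is published for them); `type1_rate` implements the null by
drawing 2n from a single shared pool per variable and splitting, which makes
the groups exchangeable by construction.  Shipped presets derive SDs from
printed means ± SEs as SE·√n with the per-variable n — they are labelled
derived, since the original simulation parameter table is not available.
Rescaling to shorter observations multiplies mean, SD and upper bound by the
duration ratio (`proportional`, default) or scales the SD by the square root
of the ratio (`sqrt_sd`, for totals built from roughly independent bouts);
the rescaling the original analysis used is not documented, so both are
explicit policies.

## Synthetic data generator

Schedules are sequences of bouts — walk (bounded random-walk at 0.8 mm/s
with heading diffusion, kept inside the zone-1 core), probe (fixed anchor +
isotropic Gaussian jitter, default SD 0.002 mm), confound spike (0.8-s
out-and-back excursion peaking at 0.8 mm/s, the "short movement during
probing"), and edge dwell (radial square-wave flicker of ±0.025 mm across
the zone-1 boundary, period 2.2 s in / 1.2 s out) — with kinds drawn from a
categorical mix and durations from exponential distributions (walk: 5 + 55 s
mean; probe: 30 + 570 s; edge: 20 + 40 s).  Ground truth merges adjacent
probe bouts and absorbs probe-flanked spikes; edge dwells are *not*
ground-truth probing (their true state is ambiguous by construction).  True
jitter statistics of probing aphids are unpublished; these values are
illustrative and chosen so that smoothed jitter speed sits safely below the
0.02 mm/s start threshold.

Frames are a backlit scene (background grey 200, disc 120, subject 30) with
an elliptical subject (semi-axes 0.85 × 0.5 mm, ≈ 1.7 mm body length) whose
orientation follows the motion heading — updated only for genuine
locomotion (> 0.01 mm/frame), since sub-pixel jitter must not spin the body.
Rendering is anti-aliased by approximate area coverage so sub-pixel
centroids are meaningful.  The tracker thresholds each pixel against its
zone's grey level (disc 75, surround 100 by default), labels 8-connected
components, and takes the largest component's binary centroid; size ties are
broken by darker mean grey, then top-left position.  Frames are streamed
(generator in, generator out), so hour-scale stacks never materialize in
memory.

**What passing tests do and do not show.**  The generator produces ideal
contrast, a rigid elliptical subject, no leaf texture, no lighting drift,
and no occlusion; recovering ground truth here demonstrates the internal
consistency of detector, filter, summaries, and tracker — not field accuracy
on real footage, where segmentation errors and behaviours outside the bout
vocabulary occur.  Boundary recovery is inherently lagged: finite-difference
speeds plus the 5-sample smoothing window delay detected starts by up to
~0.6 s and advance stops by ~0.2 s, so "exact" recovery means exact bout
correspondence and counts, with sub-second boundary tolerances (the same
early-stop bias the physical system shows, in miniature).

## Problem sizes

The test suite runs the state-machine oracle comparison on 10⁴ randomized
series of 60–140 analysis samples, and the full imaging loop on a 57-min
observation (two ≥ 25-min probes, ~86 000 rendered frames, streamed); the
power simulations use the full protocol (10⁴-draw pools, 1000 iterations).
These sizes are the package's chosen defaults for routine verification.

## Known limitations

- Sessile non-probing behaviour is indistinguishable from probing by
  design; derived "probing" durations are upper bounds on feeding.
- The detector cannot see sub-10-s probes (the start dwell), and manual /
  automated matching of very short events is correspondingly fragile.
- Power presets rest on SD = SE·√n reconstruction from printed summaries;
  with skewed or truncated underlying data this misstates dispersion, and
  detection rates near a decision boundary (≈ 80%) should be read with
  their Monte-Carlo SEs.
- The blob tracker assumes one subject and a static scene; it is a test
  harness for the pipeline, not a replacement for production tracking
  software.
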