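# Methods

This note documents the models implemented in `cohouse`, the defaults and
units of the parameters that matter, what the synthetic generator does and
does not emulate, and the numerical choices made where the underlying
procedure is open to interpretation.

## Behavioural scoring

Positions are animal centroids in cm, origin at the bottom-left cage
corner; times are seconds from session start; intervals are half-open
`[t_start, t_end)`. The nest is a circle (default radius 10 cm) and nest
entry/exit are scored as centroid crossings of that circle. With pose data
the field scores entry at the head crossing and exit at the rear crossing;
centroid trajectories cannot express that asymmetry, so both collapse to
the same circle — a documented simplification, not a claim about video
scoring.

A **chase** is a maximal interval in which the dam is within 10 cm of the
virgin, both move at ≥10 cm/s, and the dam lies behind the virgin's heading
(the dam→virgin displacement opposes the virgin's velocity). Runs separated
by ≤0.4 s merge; runs shorter than 0.6 s are dropped. These thresholds are
detector configuration (`ChaseParams`), not biology: real studies score
chases manually, and scored event logs can be ingested directly, bypassing
detection. A chase is a **shepherding** event iff the virgin's distance to
the nest center at the end is smaller than at the start, evaluated by
linear interpolation of the trajectory at the chase endpoints. Shepherding
rates are compared against 0.2 events/h — the dam→virgin chase rate
observed without pups — by a one-sample t test across cages; the
directional p is the halved two-sided p.

**Retrieval onset** is the first day a subject meets its rule: at least 2
of 10 successful trials (co-housed virgins; trials capped at 120 s) or at
least one success in any of four daily observation sessions (observer
cohorts). Subjects never meeting the rule are censored at their last
observed day. Distress-call bouts are classified by the medians of the
syllable inter-onset rate (4–8 Hz) and peak frequency (40–90 kHz).

## Spike-train statistics

Per behavioural episode the analysis rate spans the episode duration,
capped at 40 s for nest entries (long dwells mix in grooming, sleeping and
nest building). The baseline is an equal-duration window immediately before
onset for nest entries, and the fixed 10 s before onset for shepherding and
dam retrievals. The modulation index

    M = (r_behaviour − r_baseline) × 100 / (r_behaviour + r_baseline)

is bounded in [−100, 100], antisymmetric under exchanging the two rates,
and defined as 0 when both rates are 0.

Significance uses a **shift permutation**: all of a behaviour's intervals
are shifted by one common draw uniform in ±500 s (preserving inter-event
structure), wrapping circularly at the recording edges, and the across-
event mean of the per-event M is recomputed for 1000 shuffles. One-sided p
values use the add-one estimator p = (1 + #{M_null ≥ M_obs})/(N + 1); the
classical "greater than 950 of 1000 shuffles" criterion corresponds to
p ≤ 51/1001 ≈ 0.051 under this estimator. Whether the original procedure
drew one shift per event or per shuffle, and whether shifts wrapped, is not
specified anywhere we could pin down; one common wrapped shift per shuffle
is the stated choice here. Units flagged by both sides report the smaller
side.

For FDR, each unit's two-sided p is 2·min(p_act, p_sup) capped at 1
(activation and suppression are reported separately but corrected as one
test per unit), and Benjamini–Hochberg runs within each family — e.g. all
PVN units of one recording day — at accepted FDR q = 0.05. Significant
units are labelled by the direction of the smaller one-sided p.

PSTHs use 250-ms bins over −20…+40 s (−10…+20 s for shepherding). The z
reference is the mean/SD of the pre-onset bins of the same event-averaged
histogram (the reference distribution is not otherwise specified); ±3
clipping is applied only to the display accessor, raw z is retained. Pair
synchrony is the Pearson r of 10-ms spike-count vectors within each event,
Fisher z-transformed with |r| capped at 0.9999, averaged over events, and
back-transformed; zero-variance events are skipped and counted. Playback
responses normalize the 1-s call-window rate by the 1-s pre-call rate,
skipping calls with a silent baseline.

QC removes spikes coincident within 0.5 ms across ≥10 distinct channels
(electrical artifacts), then the later spike of any within-unit pair closer
than the refractory setting (default 2 ms from the accepted 2–3 ms range).
Photo-tagging requires ≥70 % of light pulses answered within ≤4 ms; both
thresholds are inclusive and the median first-spike latency is reported.

## Population statistics

The exact Fisher p is computed by hypergeometric enumeration with fixed
margins; the two-sided rule sums all tables whose probability is at most
that of the observed table, with a 1 + 10⁻⁷ relative tie tolerance (the
point-probability convention; conventions differ, so this one is isolated
in a single function). The "any units activated" test builds the 2×2 table
[[k, n−k], [0, n]] against an idealized zero-activation population of the
same size — the construction is a package decision kept behind
`fraction_activated_test` so alternates can be swapped.

The relative-risk CI solves the **Koopman asymptotic score** equation: the
endpoints are the two roots in ρ of the score statistic equalling the
χ²₁ 0.95 critical value, with the constrained MLE of p₁ under p₁ = ρ·p₂ in
closed form and bracketed Brent root-finding on a log scale (endpoint
residuals < 10⁻⁶; k₁ = 0 gives a 0 lower limit, k₂ = 0 an infinite upper
limit). The implementation's closed-form statistic is verified in the tests
against an independently derived profile-score statistic U²/I_eff and by
simulated coverage. Log-rank onset comparisons use the standard discrete-
day hypergeometric O−E formulation with right censoring (via lifelines),
cross-checked against a hand-worked table.

## Photometry

The raw signal is modelled as a 400-Hz sinusoidal excitation carrier
amplitude-modulated by the fluorescence envelope. Quadrature demodulation
followed by a zero-phase 4th-order Butterworth low-pass at 20 Hz recovers
the envelope; zero-phase filtering avoids latency bias when aligning
trials. ΔF/F for an interval uses F0 = median of the 1-s window immediately
before it (no baseline rule is prescribed by the field here; the median is
robust to transients leaking into the window) and is flagged undefined when
F0 ≤ 0. Daily call-response means can be re-indexed to each subject's
retrieval-onset day. Joint single-trial analysis correlates per-trial
population modulation (mean across units of M per trial) with per-trial
cortical ΔF/F by Pearson r.

## Synthetic generator

`synthio` emulates the study conditions, not the raw sensor data: no video
or audio is synthesized, trajectories are centroid-level (no pose), and
pup biology is not modelled. Defaults: 80 × 40 cm cage, nest at (15, 15) cm
with 10 cm radius; trajectories at 5 Hz as mean-reverting (OU) walks
(θ = 0.25 s⁻¹, σ = 2 cm·s^{-1/2}) clipped to the cage; chases ~3/h with
80 % nest-directed, 20–30 cm/s, scripted as straight runs with the dam 4 cm
behind the virgin; nest visits ~6/h with 10–40 s dwells; spontaneous dam
drop-and-retrieve episodes ~0.5/h (about once every two hours). Scripted
episodes are pasted over the free walk and the walk is bridged linearly to
their endpoints, so scripted geometry (e.g. d_start > d_end for
nest-directed chases) holds exactly and the detector can be scored against
construction-level truth.

Spike units are inhomogeneous Poisson: baseline rates log-uniform on
1–10 Hz (PVN baseline distributions are not reported anywhere usable;
this range is stated configuration, not a claim), multiplied by gain g
inside the assigned behaviour's events (default g = 3 activated, 1/g
suppressed; 30 % of units modulated, 25 % of those suppressed). Tagging
sessions deliver 5-ms pulses at 2 Hz; tagged units answer each pulse with
probability 0.9 at ~2 ms latency. Photometry envelopes are
F0 + Σ A·k(t−t_i) + drift + noise with a difference-of-exponentials kernel
(rise 0.2 s, decay 1.5 s, GCaMP6s-like; no kernel is prescribed, so the
constants live in the config). Learning cohorts draw a latent learning day
from a per-day hazard; sessions before it score 0/10 (naive virgins ignore
isolated pups), sessions from it on succeed on 2 + Binomial(8, 0.75)
trials, so both onset rules recover the latent day exactly and
never-learners are censored. Default cohort sizes and hazards reproduce
the four observation conditions (15, 19, 18 and 10 subjects with hazards
solved from the fractions 11/15, 12/19, 2/18 and 3/10 ever retrieving over
four sessions).

Because the generator's noise is exactly Poisson/Gaussian and episodes are
non-overlapping by construction, passing tests demonstrate statistical
correctness and calibration of the pipeline — not robustness to tracking
errors, overlapping behaviours, bursting or non-Poisson spike trains.

## Scales, determinism, degenerate inputs

All generators draw from `numpy` Generators seeded as `[seed, stream]`, so
identical configurations are byte-identical; the pipeline records the seed
in the bundle manifest. Calibration checks run at desk scale, chosen to
keep the whole suite in the low tens of seconds while leaving Monte-Carlo
error well below the decision margins: 500 null units × 1000 shuffles for
permutation calibration (KS at α = 0.01), 20 replicates of 40-unit mixed
populations for realized FDR, 80 units for gain-2 sensitivity, five 10-h
sessions for shepherding recovery, 2000 replicates for Koopman coverage,
and exhaustive Fisher-versus-enumeration agreement for all 2×2 tables with
N ≤ 40. Degenerate inputs are defined rather than left to chance: M(0,0)=0,
zero-baseline playback calls and zero-variance synchrony events are skipped
with counts, zero-variance correlations and empty event lists raise, and
both-zero Koopman inputs return an undefined-interval flag.
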