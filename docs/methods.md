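# Methods

This note documents the models, conventions and numerical choices behind
`larvaswim`: what the synthetic-data generator emulates (and what it does
not), how bouts are detected and measured, how fish are aggregated and
compared, and where the design was genuinely open.

## Synthetic cohorts

A cohort is a set of fish nested in clutches, two genotypes per clutch
(each clutch models one heterozygous incross, so mutant and wild-type
siblings share the clutch environment).  Every kinematic parameter has a
per-fish latent value

    latent = genotype mean + clutch offset + fish offset.

Offsets are Gaussian.  The per-parameter between-fish standard deviations
are calibrated from published group SEMs (SD = SEM·√n); 30% of the SD is
attributed to the clutch level and drawn once per clutch (shared by both
genotypes), the complementary share per fish.  Latents are floored at 5%
of the group mean; bout-rate latents are clipped to [0.12, 1.5] Hz
(higher spontaneous rates leave no room for glides).

Two deliberate choices keep cohort means honest:

* offsets are *normal*, not log-normal: a log-normal with median at the
  group mean would inflate the cohort mean by exp(σ²/2) (≈ 4% at the
  calibrated CVs), which is larger than the recovery tolerances;
* `CohortConfig.centering` controls finite-sample centring of the
  offsets: `"clutch"` (default) centres the clutch offsets, `"full"`
  additionally centres the fish offsets so a simulated cohort's latent
  mean equals the configured group mean *exactly* — used when the
  question is "does the pipeline recover the configured value", where
  cohort-level sampling noise is not part of the question — and `"none"`
  draws everything i.i.d., which is required for inference simulations
  (type-I error, power) where between-group sampling noise must be real.

Default group means reproduce published values for a neuropeptide
knockout line and wild-type siblings.  Genotype effects are injected for
the parameters that study found affected (forward-swim distance, speed,
bend amplitude, and duration through distance/speed); forward-swim
oscillation count and TBF are configured genotype-free, matching the
study's inference that they do not differ.  Escape parameters carry the
(tiny, non-significant) printed per-genotype means.

### Slow-swim sessions

Bout onsets follow a renewal process: glide = 0.15 s refractory +
Gamma(shape 2) with the mean set so that glide + mean bout duration =
1/bout-rate (the log-normal mean factor exp(σ²/2) of bout durations is
accounted for).  Each bout is a forward swim with probability p_forward.
Per-bout quantities are log-normal around the fish latent, anchored on
the **median** because fish are later summarised by per-bout medians:
duration (σ = 0.35, clipped to [0.08, 1.5] s and frame-quantised), speed
(σ = 0.30); distance = duration·speed, capped at 2 mm.  The published
distance, duration and speed means are not mutually consistent (means of
ratios do not multiply); duration and speed are the drawn anchors, which
reproduces the published distance and speed exactly at cohort level
while the implied mean duration is ~6% above the printed value.

The tail-angle waveform of a bout is a train of alternating-sign lobes:
zero at lobe boundaries, the signed bend amplitude at the lobe centre,
PCHIP-interpolated so peaks fall exactly on sampled frames and are never
overshot.  The bend-magnitude sequence decreases from the first (and
largest) bend; its *sample median* equals the drawn per-bout median bend
exactly: the bend count is even (2·n_osc, so that the analysis
convention n_osc = ceil(n_bends/2) returns the injected n_osc) and the
two middle magnitudes sit symmetrically at median ± 0.3°, which keeps
the measured median centred under additive sensor noise; magnitudes are
floored at 1.6°.  Forward max bends live in [5°, 22°] and turn first
bends in [28°, 90°], leaving the 25° classifier unambiguous on ground
truth.  n_osc = round(TBF·duration) with per-bout TBF log-normal
(σ = 0.10) around the fish latent.  During a bout the head advances at
constant speed along the heading; turns rotate the heading by 0.6 × the
first bend at bout end (the gain is a placeholder; ground truth records
the realised increment).  The fish steers back toward the well centre
whenever the head comes within 5.5 mm of the wall (body length 3.2 mm +
max bout travel 2 mm + slack), so the whole silhouette stays inside the
15-mm arena; wall thigmotaxis is deliberately not modelled.

Sensor noise: additive Gaussian on the tail angle (SD 0.5°) and on head
coordinates (SD 0.01 mm), both switchable off.

### Escape trials

A trial is 1 s at 650 Hz, stimulus at 200 ms.  With probability 0.9
(emulating the published ~90% selection rate) the fish responds after a
log-normal latency (mean-anchored, ≈ 5.4 ms, clipped below 30 ms): a
C-start whose first bend is the largest (normal around ≈ 100°, > 61°),
followed by an opposite counter bend (≈ 46°) and a geometrically
decaying tail-beat train; n_osc ≈ 8 and duration = n_osc/TBF with TBF
mean-anchored ≈ 37.5 Hz.  Escape draws are anchored on the **mean**
because escape fish are summarised by per-fish means over trials.  The
published escape duration and speed are again not consistent with the
published TBF and n_osc under pooling; TBF, n_osc, distance, latency and
the two bends are the primary anchors, so the simulated duration
(~0.22 s) and speed differ from the printed per-fish means.  The escape
path is straight along the heading (real escapes curve; path curvature
is irrelevant to the measured parameters here).

### What the generator does not emulate

Wall interactions, habituation across trials, 3-D posture, non-constant
within-bout speed, realistic bend-amplitude decay profiles (the sequence
is constructed to pin the median, not to look like a real decay), and
real tracking artefacts beyond additive Gaussian noise.  Passing tests
therefore show that the *analysis chain* is correct and calibrated on
signals with known structure — not that it is robust to every failure
mode of real video.

## Rendering and tracking

Frames are 8-bit grayscale: a bright head disk (radius 0.45 mm) plus a
tapering tail drawn along a constant-curvature arc of length 3.2 mm
whose total turn is −2 × tail angle, so the head→tip chord sits at
exactly the trace's tail angle from straight-behind.  Default scale
20 px/mm (tests use 30–40 px/mm); world coordinates are mm with y up,
image rows flipped.

The tracker performs background subtraction, a fixed threshold at 50% of
the frame's maximal contrast, connected-component filtering by area
(0.5–8 mm²; zero or multiple plausible components flag the frame), then
skeletonises the mask (cropped to the larva's bounding box) and prunes
the skeleton to its longest geodesic path.  The head end is the end with
the larger local mask width (distance transform), with temporal
continuity as a tie-breaker.  The path is refined to sub-pixel accuracy
by moving each of ~19 resampled points to the intensity centroid of the
background-subtracted image along the local perpendicular cross-section
— integer-pixel skeleton staircase noise persists across frames while
the fish rests, so no amount of temporal smoothing could remove it — and
resampled to 10 tail points.  The heading is the tangent at the head of
a one-parameter constant-curvature (chord-frame sagitta) fit over the
arc range 0.45–2.2 mm: the fit is exact for the rendered body model,
degrades smoothly to the chord for straight bodies, and avoids both the
failure of per-coordinate polynomial fits at ±100° bends and the
degeneracy of algebraic circle fits on collinear points.

Tail angle = signed angle between straight-behind (−heading) and the
head→tail-tip vector, positive toward the fish's left, (−180°, 180°].
On clean rendered sessions at 40 px/mm the round trip achieves ≈ 0.4°
RMSE, r > 0.99 against the rendered angle, and 0% flagged frames.

## Bout detection and kinematics

The tail angle is lightly smoothed (Savitzky–Golay, window 5, order 2)
for peak localisation; the detection envelope is the sliding RMS (50 ms)
of the **raw** angle (smoothing would push micro-bout lobes below
threshold).  Hysteresis: onset when the envelope holds ≥ 3° for ≥ 20 ms,
offset when it stays < 1.5° for ≥ 50 ms; intervals closer than 30 ms are
merged.  Onsets are refined to one frame before the first two
consecutive raw samples ≥ 1.5° (a single noise excursion never
qualifies).

Bends are alternating-sign extrema of the smoothed angle above a 1.5°
prominence floor, then the decaying tail of the bout is *tracked* past
the envelope's reach: while an opposite-sign extremum ≥ 0.85° appears
within ~1.8 beat spacings it is appended, and a trailing guard discards
a final "bend" smaller than 0.35 × its predecessor (post-bout noise
ripples inherit large prominences from the preceding deep lobe; genuine
final bends continue the decay at ratios ≈ 0.8–0.95).  The bout offset
is the return of the smoothed angle to ≤ 0.5° after the last bend.
Amplitudes are read from the raw trace (argmax over ±1 frame) when
≥ 6° and from the smoothed trace below: raw reads keep narrow large
lobes unbiased while smoothed reads keep the small-bend sample median
centred; the 6° crossover is where multiplicative smoothing attenuation
overtakes additive read noise.

Per bout: duration = (offset − onset)/rate over the half-open frame
interval; distance = head path length over the interval's displacement
steps, computed on Savitzky–Golay-smoothed coordinates (window 7, order
2 — raw path length of a noisy trajectory is biased upward ~40% at
forward-swim step sizes; wider windows trade noise for edge loss, and 7
minimises the net bias); the net start-to-end displacement is kept as a
secondary column.  speed = distance/duration; n_osc = ceil(n_bends/2);
TBF = n_osc/duration; median bend = median |bend|.  Sessions with > 20%
flagged frames are rejected; smaller flagged fractions are interpolated.

Accuracy limits at the default noise: duration, distance and TBF are
unbiased within ~2–3% per bout; bouts travelling < 0.25 mm are at the
positional noise floor and their distance is only median-unbiased;
per-bend amplitude accuracy is ~1.5° or 7%.  Cohort-level recovery of
all calibrated means is within ~1–2%.

## Classification, selection, aggregation

Forward iff max |bend| < 25° (25.0° exactly is a turn); escape selection
takes the first post-stimulus bout with latency < 30 ms and |first bend|
strictly > 60°, latency measured from the stimulus time to the onset
frame's timestamp (≤ 1.54 ms convention at 650 Hz); a bout overlapping
the stimulus marks the trial as contaminated.  QC keeps fish with ≥ 30
bouts per 5-min session ("fewer than 30" read strictly).  Slow-swim
parameters are summarised per fish and category by the median over all
QC-passing bouts; escape parameters by the mean over selected trials
(unselected trials contribute nothing, not zeros); fish with zero
selected trials drop out of the escape comparison only.

## Genotype comparison

Each parameter is fitted with `MixedLM`: response ~ genotype with a
random intercept per clutch (REML); the statistic is the 1-df Wald
chi-square of the genotype coefficient (for a single two-level factor
this equals the Type II test).  If the mixed fit degenerates (zero
clutch variance) or fails, the marginal OLS model — its exact limit — is
used, so a finite statistic is always returned.  The transform (none /
log / sqrt) minimises the |skewness| of within-genotype residuals; log
requires strictly positive data.  Within a family (escape: 8 parameters,
forward: 6, turn: 6) a shared Meff is computed from the QC-passing
fish × parameter matrix: Spearman correlation → eigenvalues → Vcorr
(sample variance, denominator k − 1 — the only choice for which perfect
correlation gives Meff = 1 exactly) → Meff, clipped to [1, k];
p_adj = min(1, p·Meff).  Bout rate is tested alone and unadjusted
(Meff ≡ 1).  Simulated under the null (shared clutch offsets, no
genotype effect) the raw p-values are KS-uniform and the family-wise
error at α = 0.05 stays at ~0.05.

Inference-level simulations (type-I error, power) run on per-fish
summaries built directly from the cohort latents
(`latents_to_summaries`): with ~270 bouts per fish the pipeline's
medians concentrate on the latents, so trace synthesis adds nothing but
cost there; trace-level fidelity is validated separately by the
recovery tests.

## Problem sizes

Tests use reduced sizes chosen to keep each check's statistical power
while running at desk scale: recovery at 12 fish × 2-min sessions (2 SEM
tolerances computed at that n), F1 on ~500 bouts, tracker round trip on
a 16-s clean stack, type-I calibration on 1,000 summary-level replicates
of 40-fish cohorts, and the forward-family power check at 500 fish per
group.  The acceptance script runs the full calibration-scale cohorts
(58/62 slow-swim fish, 84 × 10 escape trials) in ~30 s.

## Known limitations

The waveform and trajectory models are deliberately minimal (see the
generator section); the tracker assumes one animal on a dark background
with the rendered body proportions; escape trajectories are straight, so
render→track round trips are only exercised for slow-swim geometry; the
Meff values of the original study (7.230 / 4.003 / 4.518) depend on the
real data's correlation structure and are reproduced only in order of
magnitude (simulated families give ≈ 5–7.2 depending on the latent
correlations, within the theoretical bounds [1, k]).
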