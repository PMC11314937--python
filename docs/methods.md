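# Methods

## The measurement model

The package operates on the tabular output of an upstream semantic
segmenter watching a transparent duct between two rearing boxes: for
every frame, zero or more detections of (sex class, confidence, centroid
x/y in pixels). The in-memory container (`InfoMatrix`) is the
`n_frames × 4 × n_layers` information matrix: the k-th detection of a
frame occupies layer k, and absence is encoded as missing, never as a
magic number. Frame indexing is 0-based and contiguous; the x axis
points in the direction of travel from the origin box to the destination
box, so forward motion means increasing x. The frame period is
`dt = 1/fps` (default fps 5); pixel pitch 48.1 µm converts px/frame to
mm/s (`mm/s = px/frame × fps × pitch_mm`, so 50 px/frame ↦ 12.025 mm/s).

A *passage* is one animal traversing the duct; the counting problem is
to recover the number of completed forward passages, and their sexes,
from the stream. Five corrections address the five structured noise
sources; each is independently switchable so its contribution can be
measured (`ablation_table`).

## Criterion 1 — layer truncation

Layers beyond the second hold a negligible share of detections in a
well-designed duct (the reference regime puts it near 0.15%), and two
simultaneous trajectories are the most the sorting stage can
disambiguate. `truncate_layers` keeps layers 1–2 and reports the dropped
count. Disabling the criterion keeps only layer 1 — the uncorrected
variant whose undercount motivates the correction. Note that during a
(rare) triple occupancy the newest animal is invisible until a slot
frees; its passage may be shortened or, if the remainder is below the
cluster-size threshold, lost. This is the accepted cost of the two-layer
design.

## Criterion 2 — kinematic layer sorting

Layer identity is per-frame, not per-individual. Sorting imposes
trajectory continuity with gap-bridging finite differences: the velocity
at frame f is `(p(f) − p(f′)) / (t(f) − t(f′))` with f′ the last present
frame (so a run of missing frames is bridged, not broken), and the
acceleration is the analogous difference of velocities. A greedy
left-to-right pass decides per frame whether to exchange the two layer
slots, conditioning on the already-sorted past:

* **Two detections** — exchange iff *both* cross-assignment velocities
  are strictly smaller in magnitude than *both* straight velocities
  (the conjunctive rule); an inconclusive comparison falls back to the
  summed acceleration magnitudes; still tied → keep. Undefined terms
  (a track that just appeared, or whose history is older than
  `max_link_gap`) are excluded from the comparison; with no defined
  evidence the frame is left as emitted. A `summed` variant (compare
  summed velocity magnitudes) is provided in the configuration.
* **One detection** — the record may be moved to the other, empty slot.
  This is what keeps an individual on layer 2 for the remainder of its
  passage after its companion exits (the emission convention would
  otherwise fold it onto layer 1 and fuse two different animals into
  one cluster). Here raw velocity magnitudes are *not* comparable
  evidence: a staler track's gap-bridged velocity is diluted by its
  longer denominator, and magnitude ignores direction. The decision
  therefore scores each track by the deviation of the hypothesised
  velocity from the track's last observed velocity (an acceleration-
  consistency criterion), requires the receiving track to be at least
  as recent as the emitted slot's, and when the emitted slot's track is
  dead follows the live track only if the implied step is physically
  plausible (`plausible_step_px`, default 400 px — more than three
  times the 95th-percentile per-frame displacement).

Records move as whole 4-field units, so the per-frame multiset of
detections is conserved exactly; sorting is idempotent. Two numerical
guards matter in practice: `max_link_gap` (default 25 frames = 5 s)
expires stale histories so an old track cannot capture a fresh entrant,
and both guards are disabled (`None`) when comparing against the
exhaustive-search oracle in tests.

Properties verified in the suite: on streams whose two tracks stay
separated by more than the largest single-frame displacement, the sorted
layers reproduce the ground-truth identity partition within every
co-occupancy episode; the summed layer-trajectory speed never increases
on duct-geometry streams; and where the sorted assignment stays
layer-dense it matches the exhaustive swap-pattern optimum of summed
squared velocity in the large majority of random streams, never
exceeding twice its cost. The residual cases are streams where the raw
squared-speed optimum links a trailing detection across two different
individuals — cheaper in the metric, wrong in identity — which is why
identity recovery, not raw cost, is the primary assertion. (Extending
the exhaustive search to single-detection placements makes the metric
degenerate: splitting a trajectory across layers lengthens the bridged
gaps and *lowers* gap-normalised squared speed.)

## Clustering and Criteria 3–4

`segment_clusters` cuts each layer's trajectory into clusters: a
boundary falls at any missing run longer than `gap_tolerance_frames`
(default 0 — every absence splits) and additionally at any single-step
displacement above `jump_split_px` (default 400 px). The jump rule is
the differentiation-based part of the clustering: when one passage ends
at the duct exit and the next animal's detections continue on the same
layer without an intervening empty frame, the positional discontinuity —
far larger than any real per-frame move — marks the boundary. Every
present detection belongs to exactly one cluster.

Criterion 3 rejects clusters spanning fewer than `min_cluster_size`
frames (default 15). The threshold is anchored in the speed law: a
genuine passage shorter than 15 frames would need a speed above the 95th
percentile (≈120 px/frame, duct view 1920 px), so shorter clusters are
overwhelmingly noise fragments. The count is monotone non-increasing in
the threshold: small thresholds admit fragments (overcount), large ones
swallow real passages (undercount).

Criterion 4 rejects clusters whose net x-displacement
(`x_last − x_first`) is non-positive: the animal returned to the origin
box. Net displacement deliberately ignores internal back-and-forth
lingering. A `net_flow` mode (forward minus backward kept clusters) is
provided because discarding returns double-counts an animal that
crosses, returns, and crosses again; in that mode the passage total is
no longer the sum of the per-sex tallies, which are per-cluster.

Speed statistics pool per-step speeds (Euclidean distance over frame
gap) across clusters — a per-frame histogram, not per-passage means —
with the 95th percentile computed by linear interpolation of order
statistics. Standard errors on the pooled mean must be cluster-robust:
steps within one passage share that animal's base speed, so the
effective sample size is the number of passages, not of steps.

## Criterion 5 — sexing

The ovipositor points backward, so the segmenter systematically votes
male during the first frames of every passage; mid-track, occlusion
flips female votes to male far more often than a leg is mistaken for an
ovipositor (the reverse error). `assign_sex` discards the first
`discard_first` *detection* frames of a cluster (default 3, the typical
bias depth) and reduces the remaining votes under one of three rules:

* `female_override` (default): one remaining female vote attributes the
  passage to a female; only male votes → male; empty vote set →
  unresolved. Rationale: occlusion explains a male vote on a female,
  but almost nothing explains a female vote on a male.
* `majority`, `prob_weighted_majority`: vote (or confidence-weighted)
  majority, ties unresolved. These exist for the ablation study — under
  the override the entry-frame male votes are harmless and the benefit
  of discarding head frames only becomes visible under majority voting,
  which is how the discard-depth sweep locates its optimum at the bias
  depth.

Unresolved clusters count toward the passage total but not the sex
totals. Under the override the female count is monotone non-increasing
in `discard_first` (discarding can only remove female votes), and a
discard depth at least the bias depth recovers the exact sex of every
longer passage on streams whose only class noise is the entry bias. The
residual bias on fully noisy streams has a fixed direction — females
undercounted, males overcounted — because a female occluded for her
whole (post-discard) passage is indistinguishable from a male.

## The simulator

`simulate(SimConfig)` generates streams with complete ground truth
(identity, sex, entry/exit, per-frame positions, emitted/missed flags,
emitted layer). Defaults encode the reference farm-trial conditions:
1920 px duct view at 5 fps, arrival rate 0.0028 crossings/frame
(Poisson), female fraction 747/1281, entry male bias 3 frames.

**Speed law.** The published observable is the pooled per-frame speed
histogram (mean 50 px/frame, 95th percentile ≈ 120, "fairly Gaussian
with a slight skew toward high speeds"). The generator therefore (a)
models the pooled law as a skew-normal (shape 2, between-crossing sd 25
px/frame) truncated below 8 px/frame (slower than ≈2 mm/s is lingering,
not a passage) and recentred so the truncated mean is exactly
`speed_mean`; (b) draws each crossing's base speed *length-biased*
(weight ∝ speed), because slow animals occupy proportionally more
frames — without this the pooled mean comes out near 33 instead of 50;
and (c) adds within-crossing fluctuation (sd 30 px/frame, truncated at
1 px/frame and recentred per crossing so the step mean equals the base
speed), so that fast steps do not imply short transits. Centroid
measurement noise (2 px) and a small transverse random walk are added on
top.

**Noise rates the reference study does not quantify** are free
parameters with documented defaults, calibrated once so the reference
regime reproduces the study's qualitative outcome pattern (small total
error; female error negative near −8%; male error positive; second-layer
clusters an order of magnitude rarer than first-layer ones): miss
probability 0.0005/frame, layer shuffle 0.1/frame, occlusion flip
0.92/frame on post-entry female frames, spurious female vote
0.0005/frame on males, backward entrants 0.0025, mid-duct reversal
0.005. Entry bias is counted in *emitted* frames, matching how Criterion
5 counts discarded frames. Class confidences are Beta(20, 2).

**What the generator does not emulate.** Arrivals are independent
(Poisson): real crickets clump and avoid one another, and the reference
recording shows somewhat less co-occupancy than independence predicts at
the same rate. Entry frames are placed so every passage completes inside
the stream (no censoring at the recording edges). There is no
re-identification — each crossing is a fresh individual — and no
photometric model: confidences are independent of the occlusion state.
Passing tests on these streams therefore demonstrate the correctness of
the post-processing logic under the stated noise structures, not the
performance of any particular segmenter on real footage.

## Error accounting and ablation

`percent_error` reports `100 × (estimate − reference)/reference`,
positive = overestimation, with two rounding conventions (half-away and
truncate) because printed error tables circulate in both. The ablation
table re-runs the pipeline five times, one criterion disabled at a time
(disabled C1 = first layer only, C2 = no sorting, C3 = minimum size 1,
C4 = keep backward, C5 = vote on all frames), against reference counts
from ground truth or a manual tally.

Two ablation effects deserve honesty notes. Disabling the sorting does
not reliably inflate the *total* under presence-run clustering (merges
and fragments roughly balance); its measured, tested benefit is in the
combined count-plus-sex error, which sorting never worsens. And the
benefit of Criterion 5 is only visible under majority attribution; under
the female override the discard is neutral-to-slightly-costly, which is
why the default keeps both the override and the 3-frame discard but the
sweep that locates the optimum runs under majority voting.

## Problem sizes

Simulated experiments in the test suite and the acceptance script use
60,000–200,000-frame streams (≈150–550 crossings) — large enough for
stable error estimates while keeping the full suite around a minute.
The exhaustive sorting oracle enumerates swap patterns on ≤30-frame
streams with at most 12 two-detection frames (≤4096 patterns each).

## Known limitations

* Three simultaneous animals exceed the two-layer design; the newest
  animal is truncated and its passage may be lost (accepted, rare).
* The sorter is greedy; pathological co-occupancy with coincident
  positions can split or merge clusters. Separability (tracks further
  apart than one frame's travel) is the stated recovery condition.
* Exact noise-free recovery holds in the countable speed band (passages
  slower than `duct_length / min_cluster_size` per frame); faster
  passages are rejected by Criterion 3 *by design*, which is the
  documented, deliberate trade-off of the speed-anchored threshold.
* Sex recovery is information-limited: no post-processing can sex a
  female whose ovipositor is never visible; the pipeline's residual
  bias direction (females −, males +) is structural.
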