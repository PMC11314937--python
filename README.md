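# cricketcount

Sex-resolved passage counting for *Acheta domesticus* (house cricket)
from per-frame detection streams.

In cricket farming the male-to-female ratio drives both reproduction and
the nutritional profile of the product, but sexing a colony by hand is
slow and error-prone. A practical alternative is to let the colony
migrate between two rearing boxes through a transparent duct watched by
a camera, and to sex each animal from the one reliable visual cue — the
ovipositor, the posterior egg-laying organ only females carry. An
upstream segmentation model reduces each video frame to a small table of
detections: sex class (0 = male, 1 = female), class confidence, and the
centroid (x, y) in pixels. `cricketcount` is the post-processing half of
that measurement system: it turns the detection stream into a count of
duct passages split by sex.

The raw stream is noisy in structured ways, and the pipeline applies
five correction criteria in sequence:

1. **Layer truncation** — when several crickets share a frame the
   detections stack in "layers"; layers beyond the second hold a
   negligible share of detections and are dropped.
2. **Kinematic layer sorting** — layer identity is not individual
   identity; detections are re-assigned between the two layer slots by
   minimising the gap-bridged velocity
   `v(f) = (p(f) − p(f′)) / (t(f) − t(f′))` (and, where velocity is
   inconclusive, acceleration), so each individual keeps one continuous
   trajectory.
3. **Small-cluster rejection** — a contiguous trajectory run (a
   *cluster*, i.e. one candidate passage) shorter than 15 frames would
   imply a crossing speed above the 95th percentile of the observed
   speed distribution (≈120 px/frame against a mean of 50) and is
   discarded as noise.
4. **Direction rejection** — clusters whose net x-displacement points
   back toward the origin box are not passages.
5. **Initial-frame rejection** — the ovipositor points backward, so the
   first frames of every passage are systematically classified male;
   they are discarded before the per-frame votes are reduced to one sex
   per passage (by default with a *female override*: one credible
   female vote attributes the passage to a female, since male votes
   arise from mere occlusion).

Because the original multi-hour recording is not available, the package
includes a ground-truthed simulator that reproduces every statistical
structure the pipeline corrects for — sparse Poisson passages at 5 fps,
a right-skewed speed law (mean 50 px/frame, 95th percentile ≈ 120),
co-occupancy, backward travel and mid-duct turnarounds, detection
misses, per-frame layer shuffling, entry-frame male bias and random
ovipositor-occlusion flips — so every stage is testable against a known
answer.

## Worked example

Simulate a 60,000-frame stream (about 3.3 h at 5 fps), count it, and
quantify each criterion against the simulator's ground truth:

```console
$ cricketcount simulate --frames 60000 --seed 11 --out stream.csv --truth truth.json
simulated 151 crossings over 60000 frames (150 completed forward) -> stream.csv

$ cricketcount count --input stream.csv --report report.json
read 6021 detections over 60000 frames (3 layers)
clusters: 153 total, 2 small, 1 backward; 378 frames swapped, 16 detections beyond layer cut
{
  "total": 150,
  "females": 84,
  "males": 66,
  ...
}
```

The ground truth holds 150 completed forward passages (88 females, 62
males) plus one cricket that returned to the origin box. The pipeline
recovers the passage total exactly: 153 candidate clusters, of which 2
are noise fragments below the 15-frame threshold and 1 is the backward
traveller. The sex split lands at 84 females / 66 males — females
slightly under- and males over-counted, because a female whose
ovipositor stays occluded for her entire passage is indistinguishable
from a male. This residual bias direction (females negative, males
positive) is a structural property of ovipositor-based sexing.

```console
$ cricketcount ablate --input stream.csv --truth truth.json --out ablation.csv
criterion                         off: total%   female%     male%  residual total%
c1 layer selection                       -1.3      -6.8      +6.5             +0.0
c2 layer sorting                         +0.7      -4.5      +8.1             +0.0
c3 small cluster rejection               +0.0      -4.5      +6.5             +0.0
c4 negative velocity rejection           +0.7      -3.4      +6.5             +0.0
c5 initial frames rejection              +0.0      -4.5      +6.5             +0.0
```

Each row disables one criterion with the others left on: keeping only
the first layer loses the passages hidden behind a co-occupant (−1.3%),
while skipping the sorting or counting the backward traveller
overestimates (+0.7%). With everything on, the count error on this
stream is 0.0%.

The same workflow is available as a library:

```python
from cricketcount import PipelineConfig, run_pipeline, read_stream

matrix = read_stream("stream.csv")
result = run_pipeline(matrix, PipelineConfig())
print(result.total, result.females, result.males)
```

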