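# Methods

This note documents the models, conventions and numerical choices behind
`polypeval`, the points where the underlying evaluation protocol is
ambiguous and how the toolkit resolves them, and what the synthetic
fixtures do and do not establish about real colonoscopy data.

## Data model

A dataset is a frame manifest plus an instance table plus 8-bit PNG masks
(nonzero = polyp). Coordinates are 0-based, x rightward, y downward; boxes
are `(x, y, w, h)` over the half-open region `[x, x+w) × [y, y+h)`. Split
constraints are structural invariants enforced at construction: `data1` is
NBI; `data2`/`data4` are centre C6; `data3` is WLE from seen centres
C1–C5; sequence id and frame index come together and are jointly unique.

**Size taxonomy.** Boxes are rescaled to the 540×720 reference resolution
with independent per-axis factors (aspect is *not* preserved; the mapping
is the same resize applied to the frames themselves) and classified by
scaled **area** against the 100×100 and 200×200 landmarks: small below
100², large above 200², medium otherwise, with both boundaries assigned to
medium (closed middle interval). The landmark phrasing "<100×100 box" is
ambiguous between an area rule and a per-side rule; the area rule is the
default because sizes are reported in pixels (areas), and a `rule="side"`
switch provides the per-side reading (both sides < 100 → small, both
\> 200 → large). "Null" is a frame-level property — a frame with no
instances — not an instance category.

**Round composition** selects per-split quotas deterministically: frames
ordered by id, seeded sampling without replacement only when the quota is
strictly below availability, the generator keyed on (seed, split index) so
subsets depend only on manifest content, quotas and seed.

## Detection evaluation

Matching is greedy per frame: detections in descending confidence each
claim the unmatched ground-truth box of highest IoU when IoU ≥ threshold
(inclusive), one-to-one. Confidence ties break by larger best IoU, then
input order, making every run bit-for-bit reproducible. Frames without
ground truth contribute false positives only; frames without detections
contribute misses. The matching protocol itself is a toolkit convention
(the protocol source does not specify one); it is tested against an
independent replay of the confidence-ordered best-available assignment on
small random instances.

AP uses all-point interpolation over detections pooled across frames
(pooling per split, the unit at which results are tabulated):
`AP = Σ (r_{n+1} − r_n) p_interp(r_{n+1})` with recall measured from zero
and `p_interp(r) = max_{r'≥r} p(r')`. AP is averaged over the IoU grid
0.50:0.05:0.95; AR is the mean over thresholds of the final recall.

**Size strata.** A stratum restricts the ground truth to one size
category; a detection enters a stratum's curve only through the box it
matched. Unmatched detections (and detections matched in other strata)
count against the unstratified AP only — with no cross-stratum FP charge, a
stratum's precision is 1 along its curve and its AP is governed by recall.
A stratum with no ground truth is reported absent and excluded from
averages rather than scored 0.

## Segmentation evaluation

Area metrics come straight from the pixel confusion table. Degenerate
denominators: when ground truth and prediction are both empty the frame is
scored perfect (DSC = JC = p = r = F2 = 1, H_d = 0) — a correctly rejected
null frame; when exactly one is empty the overlap scores are 0 and H_d
takes a penalty equal to the image diagonal. These frames stay in split
means because the test data genuinely contains null frames.

The average Hausdorff distance uses mask **boundary** pixels by default
(foreground pixels with a background 8-neighbour; pixels outside the image
count as background), matching common practice for contour agreement — the
protocol says only "pixels", and `mode="all"` switches to all foreground
pixels. Nearest-neighbour distances are exact (k-d tree, Euclidean).
Normalisation divides by the maximum raw distance over the *whole
evaluated test set* (all splits pooled), with an all-zero guard; `1 − H_d`
is reported as the higher-is-better form.

Per-split aggregation is an unweighted per-frame mean ± sample sd
(ddof = 1; a single-frame split reports sd 0). Whether published per-split
tables average per frame or pool pixels is unstated; per-frame averaging
was chosen as the reading consistent with per-frame box plots.

## Generalisability deviation

Categories: detection `{mean, small, medium, large}` (AP family,
tolerance 0.1); segmentation `{DSC, F2, p, r, H_d}` (tolerance 0.05, with
the normalised H_d used as the [0, 1] category — whether the raw-normalised
or complemented form was intended is unstated, and the absolute difference
is the same either way; only the gating band placement differs). The
printed band condition in the protocol is tautological as written (every
number satisfies "≥ lower bound OR ≤ upper bound"), so the toolkit ships
both readings:

* **gated** (default): a category contributes its absolute difference only
  when the unseen score falls *outside* the tolerance band — the reading
  consistent with scoring the *stability* of a method;
* **literal**: plain mean absolute deviation (no gate).

Gated ≤ literal always, gated deviation is weakly decreasing in the
tolerance, and the overall `dev_g` — the unweighted mean of the three
per-pair deviations against reference split data3 — is mode-independent
given the per-pair values. Both modes are reported so either reading of
the protocol can be matched.

## Ranking

Criteria are ranked independently (rank 1 best, average ties). Inference
time can be banded (≤ 50 ms, 50–100 ms, > 100 ms; an exact edge value falls
in the lower band) before ranking so small timing differences do not
dominate. Mean ranks are optionally rounded **half away from zero** (the
procedure says only "rounded") and densely ranked; residual ties are broken
by a designated criterion (the segmentation score in the reference
procedure) or reported unresolved. Both rounded and unrounded tables are
emitted because the published segmentation leaderboard is consistent with
unrounded score ranks but rounded deviation ranks; the discrepancy is
surfaced rather than hidden. The published *detection* leaderboard ranks
are not reproducible from the printed columns under any variant of the
stated procedure, so the toolkit documents its procedure transparently
instead of matching them.

One caveat: "improving a value never worsens the final rank" holds in the
pairwise sense (a team never drops below a team it previously beat or
tied) but not for the dense rank *number*, which can shift when an
improvement splits a tie among other teams.

Elimination removes teams with reported time > 2000 ms or any task score
more than 10% below the baseline's worst-split score; explicit floors
(e.g. AP 0.10, DSC 0.50) can override the derived thresholds. The
Friedman test uses within-frame ranks (scipy, with tie correction; the
all-tied degenerate case is reported as statistic 0, p 1); the Nemenyi
post-hoc computes pairwise p-values from the studentized-range
distribution with infinite degrees of freedom,
`q = |R̄_i − R̄_j| / sqrt(k(k+1)/(12n))`, cross-checked in tests against
published critical-value tables.

## Synthetic fixtures

The generator emulates the *structure* of the benchmark, not its
appearance. Defaults are the benchmark's own composition: 3242 training
frames; test quotas 135/86/124/432 for data1–data4; null-frame probability
0.17 and size mixture (0.37, 0.40, 0.23), matching the published per-size
tallies; 540×720 frames. Polyps are star-shaped blobs — ellipses with a
low-order radial Fourier modulation `1 + Σ_{m=2..4} a_m cos(mθ + φ_m)`,
amplitudes bounded (Σ|a_m| ≤ 0.45 after noise) so masks stay simply
connected. Because the outline's half-extents are linear in the semi-axes,
one closed-form correction puts the tight bounding box on the sampled
target exactly (up to rasterisation); sampling bands sit a few pixels
clear of the 100²/200² landmarks so recorded categories (always recomputed
from the rendered box) match the requested mixture. Blob sizes are
sampled in native pixels against the reference-resolution bands, so an
infeasibly large polyp on a small frame raises an error; on non-default
frame sizes the effective category mixture follows the recomputed
categories. Sequences evolve by a Gaussian random walk of centre
(sd 8 px, reflecting boundaries) and log-scale (sd 0.03).

Predictions perturb the ground-truth blobs: independent misses, positional
jitter (sd 10 px), log-scale noise (sd 0.05), boundary-amplitude noise
(2 px), Poisson spurious blobs (rate 0.1/frame), and confidences
`base − penalty·(1 − IoU) + noise` clipped to [0, 1]. A per-split severity
multiplier scales every perturbation — the *only* mechanism of split-level
domain shift, sufficient to exercise the deviation score with a known
positive expected value. Random draws are made before severity scaling, so
equal seeds with different severities give coupled realisations, and the
identity perturbation reproduces the ground truth exactly. All randomness
flows from the two declared seeds; there is no hidden global state.

What passing tests on these fixtures show: the metric, deviation and
ranking machinery is arithmetically correct, deterministic, and recovers
injected split-level degradation. What they do not show: anything about
real tissue appearance, NBI spectra, specularity, motion blur, or how
actual models fail — no appearance is modelled at all.

## Problem sizes and tolerances

The test suite and the acceptance script run the simulation-based checks
at deliberately modest sizes — 4-split fixtures of 6–60 frames per split,
3 seeds for the injected-shift check, 1000 random instances for the AP
oracle bound — chosen so the full pipeline (generation, rendering, scoring,
aggregation) is exercised end to end in well under a minute per check
while leaving the expected effects (perfect limits exact; injected data4
shift ≈ 4–7× the no-shift deviation) far clear of sampling noise. Oracle
agreements are asserted at 1e-6 (AP) and 1e-9 (Hausdorff), both orders of
magnitude above float64 round-off as measured. Leaderboard-derived
arithmetic (deviation means, instance/round totals, rank order) is checked
exactly at the published precision.
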