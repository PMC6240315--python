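# Methods

This note records the models behind `nmlineage`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want written down.

## Scar clonal analysis

### Filter chain

The filter chain reproduces the four published processing stages in order,
on read-count tables (samples = dissected body structures):

1. *Fraction filter.* Scar fractions are computed per sample (counts over
   row total, the reserved `GFP_unscarred` column included).  A scar entry
   survives only if its fraction is **at least** 10× the minimum detected
   (nonzero) scar fraction — boundary inclusive, matching the wording of the
   rule.  The minimum is taken per fish over all of that fish's samples
   (configurable to per-sample or global): sequencing depth and scarring
   efficiency vary by fish, so a per-fish floor is the natural scope.  The
   rule is **one-shot by construction**: its threshold is 10× the smallest
   survivor, so re-applying it necessarily removes the new smallest
   survivor; the implementation and tests treat it as a single pass.  A
   matrix whose nonzero fractions are all equal loses everything and is
   flagged as pathological in the report.
2. *Fish QC.* A fish is kept iff its mean unscarred-GFP percentage across
   organs is strictly below 50 **and** it carries strictly more than 100
   distinct surviving scars.  Both inequalities are strict, as printed.
3. *Rare-scar filter.* Any scar detected (count > 0) in two or more fish of
   the cohort is removed everywhere, as is anything on a user-supplied
   blacklist (the generalization of excluding scars seen in unrelated
   dynamics experiments).  What remains are scars rare enough (creation
   probability ~1e-5) to have been created once, i.e. true clone markers.
4. *Binarization.* Presence/absence over surviving scars; `GFP_unscarred`
   is a QC quantity, not a clone marker, and is dropped here.

### IWSS dissimilarity

The published distance is named and described ("matches and mismatches in an
information-weighted manner for sparse samples") but no formula is printed.
The package's stand-in is an information-weighted Jaccard: with pseudocounted
presence frequency p_s = (k_s + α)/(n + 2α), presence weight w_s = −log₂ p_s
and absence weight v_s = −log₂(1 − p_s),

D(x,y) = Σ_mismatch w_s / (Σ_11 w_s + Σ_00 v_s + Σ_mismatch w_s).

α defaults to 0.5 (Jeffreys), keeping all weights finite and p strictly
inside (0,1).  Properties relied on downstream: D ∈ [0,1]; D(x,x)=0;
symmetry; adding an informative shared presence strictly decreases a
positive D.  IWSS is a dissimilarity, not a metric — triangle-inequality
violations are possible and only logged.  The definition lives in a single
function so an alternative weighting can replace it; comparisons with the
published organ distances are therefore qualitative ("IWSS-like"), which is
also why the package's recovery claims are made against simulated ground
truth rather than the published matrices.

### Heatmaps and trees

Heatmap ordering follows the published setting: rows of log₁₀(D + ε)
(ε = 1e-6, display/linkage only) agglomerated by average linkage on
euclidean distances (scipy).  Trees are canonical Saitou–Nei neighbor
joining — the published workflow is distance-tree based but does not name
the constructor, so NJ was chosen and the average-linkage dendrogram is
available as an alternative.  Ties in the Q criterion break toward the
smallest input index pair; negative branch lengths are clamped to zero with
a warning.  Bootstrap: scar columns (characters) resampled with replacement,
weights → distances → NJ recomputed per replicate, and each reference
internal edge supported by the number of replicates containing the same
unrooted bipartition (the unrooted analogue of clade-proportion scoring);
100 replicates by default.

## Scar simulator

The generator emulates the experimental design, not zebrafish cell biology:

* A synchronous binary division tree, 12 rounds (4096 leaves).  Real
  cleavage is ~10 divisions in the first 3 hpf followed by slower,
  asynchronous cycles; the simulator's rounds are *effective clonal
  generations*, and the hpf-based scarring windows map to rounds through a
  `divisions_per_hour` constant (default 1.6).  With that default the
  "protein" preset (scarring ends ≈3 hpf) covers rounds 0–4 — up to the
  round at which tissue progenitor pools are defined — and the "rna" preset
  (scarring to ≈10 hpf) covers every round.  This reproduces the mechanism
  behind the published contrast: scars made during tissue allocation are
  tissue-informative, scars made only before it are not, so the short window
  recovers organ groupings markedly less often.  The constant is an
  order-of-magnitude placeholder, exposed in the parameters.
* Eight independently scarred target copies per cell; each unscarred copy
  scars with probability 0.12 per division inside the window, identity drawn
  from a truncated power law (exponent 1.0, 30 000 identities) whose tail
  provides rare identities in the ~1e-5 regime.  Scars are irreversible and
  inherited — descendant scar sets are supersets of ancestral sets.
* Tissues draw from sets of progenitor subtrees defined at round 4
  (16 pools); overlapping sets encode shared progenitor pools.  The preset
  used throughout gives spinal cord and muscle overlapping pools, brain and
  skin one disjoint pool, intestine and liver another.
* Organ sampling: 300 leaves per organ (with replacement), two technical
  replicates, per-scar Bernoulli dropout (0.1), then multinomial read counts
  at depth 30 000; unscarred copies report as `GFP_unscarred`.

Defaults were calibrated so a synthetic RNA-Cas9 fish *resembles the
published fish*: 130–280 distinct scars after the 10× filter (the QC gate
demands >100) and 20–40% unscarred GFP (<50% required).  Not emulated:
sequence-level indel structure, PCR/lane bias, sequencing-error profiles
(which is why, unlike in the real data, the smallest detected fraction is a
genuine scar — protein-window fish consequently lose more scars to the 10×
rule than their real counterparts, and the end-to-end presets run the QC
gate only on RNA-like fish), spatial cell mixing during gastrulation, and
single-cell protocols.  Passing recovery tests therefore demonstrates that
the pipeline recovers planted clonal structure under realistic sparsity and
noise — not that the real organ distances are reproduced.

## Tracking analysis and simulator

A lineage forest holds one node per cell per timepoint (parent links,
positions in µm, reporter intensities); a division is a node with two
children; a track is a root plus all progeny.  In-silico photolabelling
selects the cells inside a sphere/box at a chosen timepoint (optionally
restricted to the viewer's side of a plane) and closes over descendants.

Fate classification of a terminal cell reads the reporter trace along its
whole track: sustained endoderm reporter (≥ k frames above threshold) →
excluded; sustained mesoderm reporter (≥ k *consecutive* frames) →
mesoderm; otherwise neural if the track survives to the end of the movie,
else unassigned.  k = 3 frames rejects single-frame tracking flicker — an
explicit replacement for by-eye scoring; thresholds are configuration, not
constants, because the original intensity criteria were visual.  Unassigned
tracks are excluded from denominators.  Terminal divisions (no further
division downstream) are classed from their daughters' fates; `incomplete`
if either daughter ends unclassifiable.

The track simulator draws a latent fate per starting cell (N / M / bi-fated
NM / endoderm), exponential division waiting times per fate class (defaults
give ~70% of tracks never dividing within the 60-frame window, the regime
the analysis operates in; the NM rate can be set to 0 to emulate the
quiescent tailbud population), and applies the NM rule: an NM cell's
division is terminal and yields one N and one M daughter.  Reporters step
from baseline 100 to plateau 1000 two frames after commitment, with Gaussian
noise (σ = 50); classification thresholds default to the midpoint.  Track
loss is per-frame censoring (0.002/frame).  A known, documented censoring
effect: a commitment within (delay + k) frames of the movie end cannot be
resolved by any scorer; such late divisions are the dominant source of
estimator error.  Recovery is scored against ground truth with a
Clopper–Pearson 95% interval on the bi-fated fraction.

The zone-based retrospective assignment (terminal position inside named
anatomical zones, mapped back to start positions) reports a k-nearest-
neighbour fate-sharing fraction (k = 5) as its mixing summary — an invented
segregation statistic, labelled as such in the output.

## Volume registration

* Downsampling to isotropic 1 µm voxels is block-mean pooling (integer
  factors), anti-aliased by construction and mean-conserving.
* Phase correlation uses conj(F(ref))·F(mov) normalized by max(|·|, floor)
  with floor = 1e-2 of the spectral maximum.  The floor matters: smooth
  objects (Gaussian-blob nuclei clusters) have essentially zero power at
  high frequencies, and exact whitening would hand those bins random phases
  that drown the correlation peak.  Bins below the floor keep their phase
  but are down-weighted, which preserves exactness for circularly shifted
  inputs (verified to ±8 voxels on 64³ volumes) and gives ±1-voxel accuracy
  at SNR 3.  The argmax is restricted to ±max_shift per axis (default a
  quarter of the extent — the loop assumes small inter-interval drift) after
  unfolding wrap-around; ties break toward the smallest-norm shift.
  Confidence = peak / sum of top-5 peaks; an optional Hann window is
  available for non-circular real data but is off by default because it
  biases estimates on compact synthetic objects by ~1 voxel.
* Shifts are integer voxels: the stage needs µm-scale corrections, and
  subpixel refinement would add no information to the feedback loop.
* The online loop estimates the shift of the current stack against the
  rolling reference every 5th timepoint, applies the negated shift as the
  stage correction (withheld, but logged, below a confidence floor), and
  replaces the reference with the current stack so gradual shape change does
  not accumulate into the estimate.  Corrections lag the drift by at most
  one interval; on constant integer drift they equal −interval·drift
  exactly.
* Offline registration chains consecutive pairwise shifts (prefix sums) and
  translates every frame back to frame 0; constant-boundary translation
  zero-fills and returns validity masks so downstream statistics can
  exclude padded voxels.
* The drifting-volume synthesizer renders Gaussian-blob objects on constant,
  random-walk or explicit per-frame drift paths at a 2.5 min cadence, in
  two boundary modes: `wrap` (frames are exact circular shifts — for exact
  estimator checks) and `crop` (a fixed field of view the object can leave —
  for closed-loop tests).  Objects are kept compact relative to the volume
  because content clipped at the boundary genuinely degrades any
  translation estimator; that limitation is inherent, not implementation.

## Problem sizes and determinism

The test-suite and acceptance-script problem sizes are the package's chosen
study conditions: 100 simulated fish for grouping recovery, 8×100 bootstrap
replicates for support comparison, 24 seeds per scarring window, 50 movies
of ~700 tracks (~200 terminal divisions each) for bi-fated recovery, and
64³ volumes for registration.  All randomness flows from explicit seeds;
the CLI expands its single `--seed` into per-stage streams with a
counter-based scheme (`SeedSequence(seed, spawn_key=(stage,))`) so adding a
stage does not perturb the others, and preset manifests (parameters, seed,
output hashes, no timestamps) are bit-identical across reruns.

## Known limitations

* The IWSS weighting is a stand-in for an unpublished definition; absolute
  distance values are not comparable to the published heatmaps.
* The scar simulator's division clock is coarse (synchronous effective
  generations) and contains no sequencing-error model, so the 10× filter is
  stressed differently than on real libraries (see above).
* Fate classification assumes reporter onset is a step plus delay; slow or
  graded onsets would blur the terminal-division classes near the movie end.
* Registration handles rigid integer translation only — no rotation,
  scaling or non-rigid deformation, matching the stage-feedback use case.
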