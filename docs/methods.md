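# Methods

## Scope and model

`swarmpath` simulates decentralized ("swarm") training of a weakly
supervised tile classifier across several cohorts, in one process, with
lockstep rounds standing in for networked synchronization. The simulation is
result-equivalent to a distributed deployment: parameter averaging is
associative and leader-independent, so the rotating merger election affects
only the audit log (the `SyncEvent` stream), never the model. Blockchain
coordination, containerization and identity management of production swarm
stacks are intentionally out of scope.

### Classifier

A four-layer fully connected network (512×256, 256×256, 256×128, 128×2;
ReLU between layers; softmax cross-entropy on tile logits), implemented
directly on numpy float64 arrays with hand-written backprop. Every tile of a
patient carries the patient's binary label; no tile-level cleaning is
attempted. Patient scores are the arithmetic mean of tile class-1
probabilities (majority-vote and top-k-mean rules exist behind a switch);
the mean is the default because tile evidence in this weak-label setting is
diffuse — a witness fraction of tiles carries signal and averaging
integrates it, whereas max-like rules are noise-brittle.

Class balance is restored per training table by random undersampling of the
majority tile class. Each swarm peer balances its own table (balancing is a
pre-training step of each training set); the merged model balances the
pooled table. Merge weights in the weighted schedule use post-balancing tile
counts — the count actually trained on.

### Swarm schedules

* **basic** — eᵢ = E (default 5 epochs), wᵢ = 1/P. Peers with fewer tiles
  finish earlier; at the merge where the i-th smallest cohort completes its
  final epoch the current *post-merge* global parameters are checkpointed
  (b-chkpt1, b-chkpt2), the peer deactivates, and the remaining weights are
  renormalized. The run ends when fewer than `min_active_peers` (2) remain.
  Post-merge content was chosen because the evaluated object in this
  protocol is the shared model, not any peer's local state.
* **weighted** — wᵢ = Nᵢ/ΣN and eᵢ = round(E·maxN/Nᵢ), minimum 1, so every
  peer's tile throughput is ≈ E·maxN and all peers stop at (nearly) the same
  round. Rounding can leave a small residual: peers that exhaust their
  iterations idle in the final partial rounds and their weight is withheld
  from those merges. The single terminal merge is w-chkpt.

Sync interval default S = 4 iterations. Iterations per epoch are
`ceil(N/batch)` with a short final batch, the standard loader convention.

### Determinism and the shuffle rule

A full training run is a pure function of (data, seed, hyperparameters).
Per-epoch shuffles are drawn from `SeedSequence(seed, epoch, fingerprint)`
where `fingerprint` hashes the trainer's own tile table. This makes two
exact oracles hold simultaneously: peers holding byte-identical tables
shuffle identically, so a degenerate swarm (identical data everywhere)
reproduces a single local run to float tolerance; peers holding different
tables shuffle independently. With S = 1, plain SGD, equal per-peer batch
sizes and batch-proportional merge weights, the weighted average of
per-peer steps is algebraically identical to one centralized SGD step on
the concatenated batch — the package's strongest correctness anchor, tested
to 1e-5 relative over 20 rounds and observed at ~1e-15.

### Hyperparameters

Batch 64, learning rate 0.2, plain SGD, E = 5 epochs. Plain SGD is the
default because the swarm-equivalence oracle above is exact for it (Adam is
available; its moment buffers live per peer and are not merged). The batch
size and learning rate were fixed once, by pilot runs on the synthetic
generator, so that all model types reach near-convergence within the five
base epochs: undertrained regimes are uninformative here, because parameter
averaging lags centralized SGD early in training and the early basic
checkpoint (taken when the smallest cohort finishes) would measure training
progress rather than protocol behavior. At full clinical scale the same
role is played by the sheer tile count per epoch.

## Synthetic data

Feature mode draws tile vectors in 512 dimensions: background tiles
N(0, I); signal tiles additionally shifted by `effect_size` (default 2.0)
along a fixed random unit direction **u**; all tiles of cohort *c* offset by
`site_shift` (default 4.0) along a cohort-specific unit direction **v**_c,
with {**v**_c} orthogonal to **u** and to each other. Positive patients
carry `round(witness_rate × tiles_per_patient)` signal tiles (defaults
0.5 × 32); labels exist only at patient level. Default cohort sizes
100/300/150 give smallest ≠ middle ≠ largest so the basic checkpoint
ordering is exercised; default prevalence is 0.3 per cohort — higher than
typical MSI/BRAF prevalence, a desk-scale concession that keeps minority
tile counts usable after undersampling at ~100-patient cohorts.

Because the site offsets are orthogonal to the signal, an oracle that knows
**u** is unaffected by them; finite-sample classifiers are not. A model
trained on one site encodes that site's offset in its ReLU pre-activations
and picks up arbitrary weight components along the other sites' offset
directions, so its scores shift differently per cohort on a multi-site test
pool and cross-cohort ranking degrades. Models trained across sites see the
offsets as label-uncorrelated variation and learn around them. This is the
mechanism by which "local < swarm ≈ merged" emerges, standing in for
staining/scanner/population shift. Test pools are drawn from the same
distributions (split-namespaced patient identities, shared directions) with
all three site offsets mixed.

The generator is a pure function of its config: per-patient RNG streams are
keyed by (seed, split, cohort, patient), so patient order cannot change any
bag and train/test splits share geometry without sharing patients.

Image mode renders the same bag structure as 64-px (default; configurable)
RGB tiles: hard-contoured isotropic blobs (signal), hard-edged oriented
stripes (background), plus a configurable fraction of constant-color blank
tiles per slide so the QC filter has genuine work. Sharp texture boundaries
are deliberate: the Canny criterion at the packaged thresholds must
separate textured from blank tiles by a wide margin, as real tissue does
from glass. What image mode does *not* emulate: stain chemistry, nuclear
morphology, magnification effects, scanner artifacts — conclusions about
real histology cannot be drawn from it; it exists to exercise the pipeline
mechanics end to end.

## Preprocessing choices

* Tessellation keeps only full tiles on the non-overlapping grid (grid
  floor); partial edge tiles are discarded.
* The QC score is the mean of the binary Canny edge map (edge = 255) of the
  luminance-converted tile (0.299/0.587/0.114). Tiles scoring **at or
  above** the threshold (default 4) are retained — "below threshold" is
  removed, so the boundary is kept. Canny hysteresis thresholds default to
  low 40 / high 100 on the 0–255 gradient scale (exposed in the API, since
  no canonical values exist for this filter), Gaussian σ = 1.
* Stain normalization is Macenko stain-vector normalization: optical
  densities are decomposed onto two robustly estimated stain axes
  (1st/99th-percentile angle extremes, OD floor β = 0.15), concentrations
  rescaled to the reference 99th percentiles, and the tile reconstructed in
  the packaged reference basis. Near-white tiles with too few stained
  pixels pass through unchanged with a warning flag. The method is
  pluggable and can be switched off.
* Per-patient sampling keeps min(n, available) tiles without replacement
  (default n = 150); patients with fewer tiles keep all of them, and
  patients with zero QC-passed tiles are excluded with a warning.

## Feature backbones

The desk-scale default is a handcrafted texture backbone: multi-scale
(1×/2×/4×) intensity and gradient-magnitude statistics plus
magnitude-weighted orientation histograms — which separate oriented stripe
from isotropic blob textures — projected to 512 dimensions by a fixed,
seeded Gaussian matrix. It needs no pretrained weights and is deterministic.
A fixed-random-projection backbone gives bit-reproducible featurization of
the raw image, and a CNN adapter seam exists behind the same contract for
users with torch and pretrained ResNet-18-class weights. Features are not
re-standardized after extraction by default. Whether a pretrained CNN was
tapped at the global-pool layer and with which weights is deliberately left
to the adapter's user; nothing downstream depends on the choice.

## Evaluation harness

Patient-level AUROC (Mann–Whitney; ties half-credited) over all test
patients, computed per replicate seed. Replicates default to 5 seeds;
summaries are mean ± sample s.d. (ddof = 1). Model comparisons use the
classical equal-variance two-sided unpaired t-test (Welch behind a flag;
with equal replicate counts the two nearly coincide), no multiple-testing
correction. If both replicate lists have (numerically) zero variance the
p-value is 1 for equal means and 0 otherwise, with a warning. Stratified
subsampling uses largest-remainder rounding of class quotas (ties toward
the larger class) so quotas always sum to n exactly. Train/test patient
overlap is rejected before any training starts. Grid results are cached by
content hash of (spec, seed) when a cache directory is supplied.

The sync-interval sweep trains the basic-schedule swarm to completion per
(interval, seed) on stratified 200-patient subsets and evaluates the final
checkpoint; "simple swarm model" is read as the basic schedule.

## Explainability

Heatmaps interpolate tile probabilities on the tile-grid lattice (not pixel
space — resolution-independent and faithful to tile-level predictions):
scored cells are anchored exactly, interior gaps filled by Delaunay-based
linear interpolation, cells outside the convex hull (and degenerate
collinear layouts, which fall back to 1-D interpolation) by nearest scored
value; rendering uses a univariate color map. Top-tile export ranks
patients by patient score toward the requested class, then tiles within
patients, with lexicographic (patient_id, x, y) tie-breaks so the selection
is total and order-independent. For examination, the replicate with median
AUROC (unique with 5 seeds) is the intended model.

## Problem sizes in the shipped experiments

The packaged experiments run on 1 CPU in minutes: the headline replicate
experiment uses the default generator (550 training patients across three
cohorts, 32 tiles each, 5 seeds, all seven model types ≈ 1.5 min); the
data-efficiency grid uses 450/600/500-patient cohorts subsampled to
400/200/100 with local and weighted-swarm models (5 seeds ≈ 2 min); the
sync sweep uses 200-patient subsets, intervals {1, 4, 16, 64}, 3 seeds
(≈ 1 min). These sizes are the package's reference conditions, not limits;
every size is a config value.

## Known limitations

* The numpy trainer is CPU-bound and desk-scale; it is not a performance
  path for real WSI cohorts.
* Synthetic site effects are a single additive offset per cohort; real
  inter-site variation is richer (nonlinear stain interactions, label-shift,
  scanner optics), so synthetic results bound what the protocol can do only
  qualitatively.
* Basic-SL checkpoint content (post-merge) and the weighted-schedule
  rounding rule are documented conventions for under-specified corners of
  the protocol; alternatives (pre-merge checkpoints, idle-free rounding)
  would change checkpoint provenance but not the protocol's equivalence
  properties.
* Pyramidal WSI decoding, magnification metadata and tissue segmentation
  are out of scope; the pipeline starts from RGB rasters or feature tables.
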