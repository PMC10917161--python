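# Methods

## The multi-scale network model

`netpyramid` analyzes one subject's resting-state BOLD data as a stack of
functional networks built at every level of a hierarchical parcellation.
The packaged gray-matter hierarchy has five scales — 84 gyrus-level
structures recombine into 58 gyri, 16 lobe-level regions, 6 cortex/nuclei/
thalamus divisions and finally 4 telencephalon/diencephalon nodes, left
and right separate throughout. Because coarser parcels are unions of finer
ones, any finest-scale labelling maps upward by table lookup, and a coarse
node's time course is exactly the voxel-count-weighted mean of its
children's time courses (an identity the tests exploit).

The pipeline assumes its input is *preprocessed* BOLD: motion-corrected,
nuisance-regressed, drift-free and band-pass filtered to 0.01–0.1 Hz. No
preprocessing is performed here, and `compute_alff` deliberately applies no
detrending.

Two packaging notes on the hierarchy table. The coarsest scale lists
left/right telencephalon and diencephalon; the table pairs the diencephalon
entries as L/R, matching the left/right symmetry of every other scale.
Amygdala and hippocampus are grouped with the limbic lobe (hence under
cerebral cortex at the next scale) rather than with the basal ganglia;
both conventions appear in anatomical ontologies, and the limbic placement
keeps the lobe-level scale exhaustive.

## Connectivity and binarization

Node series are unweighted means over member voxels; connectivity is the
sample Pearson correlation with the diagonal ("self-self connections")
zeroed. Binarization keeps the top `round(P·N(N−1)/2)` node pairs by
*signed* correlation — the Brain Connectivity Toolbox convention, under
which a strongly negative correlation is not an edge; an absolute-value
ranking is available behind `mode="absolute"`. Rounding is half-up so odd
pair counts are deterministic (15 pairs at the 6-node scale → 8 edges at
P = 0.5), and ties at the cutoff break by (row, column) order so repeated
runs agree bit-for-bit. When most correlations are negative the signed
ranking simply keeps the least negative pairs; with realistic connectivity
this regime does not arise.

## Graph metrics

All metrics operate on the 0/1 adjacency and are implemented directly
(breadth-first search and Brandes' accumulation); a graph library is used
only as an independent oracle in the test suite. Conventions for degenerate
cases follow the field's reference implementation so values are comparable:
`C_i = 0` and `E_i = 0` for degree < 2, disconnected pairs contribute 0 to
efficiency (1/∞), and no connectedness precondition is imposed — half-density
graphs at the coarsest scales are routinely disconnected and legitimately
yield zero clustering, mirroring what such tiny networks produce in
practice. Betweenness is normalized by `(N−1)(N−2)/2` by default so the
feature is comparable across scales with different node counts; the raw
count is available for oracle comparisons.

## ALFF

The amplitude of a DFT bin is `2|X_k|/n` (single-sided, DC excluded), the
convention under which a sinusoid of amplitude A at a bin frequency
contributes exactly A; ALFF is the sum over bins with `low ≤ k/(n·tr) ≤ high`,
endpoints inclusive. Maps are z-scored across all included units using the
sample standard deviation (n−1) — stated because it changes values at small
unit counts — then averaged within nodes at every scale.

## The synthetic cohort generator

The generator emulates what the analysis assumes about preprocessed data,
not raw fMRI physics. Every tree node at every scale carries an independent
latent signal synthesized in the frequency domain: equal-amplitude,
random-phase components on exactly the DFT bins inside the passband, scaled
to unit variance. Band limitation is therefore exact, which makes spectral
tests sharp. A voxel's signal is its parcel latent (weight 1) plus each
coarser ancestor's latent weighted by `module_coupling[s]`, plus white
noise, so the correlation between two voxels decreases as their lowest
common ancestor moves up the tree. The implied within-parcel correlation is
`(1 + Σw²) / (1 + Σw² + σ²)`, exposed as
`CohortDesign.within_parcel_correlation`.

Defaults are the acquisition conditions of the motivating study design:
TR = 2 s, 240 timepoints (an 8-minute scan), 0.01–0.1 Hz band, 21 patients
and 20 controls. Couplings default to a geometric decay `0.7^(s−1)`, giving
within-parcel voxel correlations near 0.65 and parcel-level correlations in
the 0.1–0.4 range typical of parcel-averaged resting-state data.

Group effects are multiplicative reductions applied to designated finest
parcels in patients:

- `coupling_reduction` shrinks the ancestor (shared) weights by
  `(1 − r)`, then rescales the voxel signal back to its original variance —
  so connectivity to the rest of the brain drops while band amplitude is
  unchanged;
- `alff_reduction` scales the whole pre-noise signal, lowering band
  amplitude (and, as a side effect of lower signal-to-noise, slightly
  lowering that node's correlations).

Each subject draws from an RNG stream derived from `(seed, subject_id)`,
so cohorts are bit-reproducible and independent of generation order.

What the generator does **not** emulate: hemodynamic response shape,
scanner noise spectra, motion or physiological artifacts, spatial
smoothness, registration error, or anatomically realistic voxel counts.
Passing tests demonstrate that the pipeline recovers the statistical
structure it models — not that it is robust to the artifacts real
preprocessing leaves behind.

## Group statistics

"Student's t-test" is read as the pooled-variance two-sample test (the
default meaning of the name); Welch's correction is available behind
`equal_var=False`. Nodes with zero pooled variance — constant metrics, as
at degenerate coarse scales — report t = 0, p = 1 with a warning rather
than failing. FDR is Benjamini–Hochberg applied per (metric, scale) family,
matching per-figure reporting practice; connectivity summaries (mean,
control-minus-patient difference, per-group SD) operate on the
unthresholded correlation matrices, since differences like 0.2 are only
meaningful pre-binarization.

## Classification

The SVM kernel and regularization are deliberately ordinary: linear kernel,
C = 1, features z-scored on training-fold statistics only — all recorded in
the report so runs are auditable. Folds are stratified (plain k-fold at
n ≈ 40 risks single-class training folds) and assigned on a canonical
subject ordering so the report depends only on the subject set and the
seed. Specificity, sensitivity and accuracy are computed from confusion
counts pooled across folds (stated in the report), with patient as the
positive class. Degenerate all-constant feature columns (e.g. all-zero
clustering at the coarsest scale) are carried through, not dropped; they
standardize to zero and contribute nothing to the decision function.

## Test-suite problem sizes and statistical checks

Cohort-level statistical properties are exercised on a compact 3-scale
hierarchy (16 parcels → 4 modules → 2 halves, 4 voxels per parcel,
couplings (0.75, 0.4), unit noise) — small enough that hundreds of cohorts
run at desk scale, with a clear within-module (≈0.37) versus
between-module (≈0.08) correlation contrast so that thresholded-graph
topology reflects structure rather than sampling noise. The injected
effect removes half the shared coupling of one whole module, a focal
subnetwork disconnection: within-effect-module pairs lose shared signal
from both endpoints, so the module visibly disintegrates at the finest
scale while coarse-scale networks, whose nodes average over it, barely
change. Scattering single effect nodes across modules produces much weaker
graph signatures — reduced correlations that still outrank the threshold
cutoff change no edges.

Calibration of the node-wise tests at the nominal 5% rate is checked on
the ALFF family, whose node values are continuous and near-Gaussian; the
thresholded-graph metrics are bounded, discrete-valued functionals on
which the two-sample t-test is mildly conservative, so they enter the
null-calibration check through the FDR bound (families almost never
reject) rather than the exact-rate band. Monte-Carlo bands use the
empirical standard deviation across independent cohorts.

Graph-metric correctness is established by exact equivalence with
independent implementations: exhaustively over all 4- and 5-node graphs at
3–10 edges against naive brute force (triple enumeration, Floyd–Warshall,
explicit shortest-path enumeration), exhaustively over all 6-node graphs
at 3–10 edges and a 2000-graph random sample at 7 nodes against networkx,
plus 500 random 10–20-node graphs. These sizes keep the full suite around
two minutes while covering every topology class the small-graph metrics
distinguish.

## Known limitations

- The hierarchy lookup table encodes parent edges reconstructed from
  standard anatomy; the source naming table lists nodes per scale without
  explicit edges, so individual placements (noted above) are conventions.
- Synthetic effect sizes are free parameters, not estimates of any
  disease's pathology; classification accuracies on synthetic cohorts say
  nothing about clinical discriminability.
- Only binary undirected graph analysis is supported — no weighted,
  directed, dynamic or partial-correlation variants.
- The NIfTI export lays voxels along one axis (units × 1 × 1); it
  round-trips time series and labels faithfully but carries no anatomical
  geometry.
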