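# Methods

## The analysis model

`surflight` implements surface-based multivariate pattern analysis (MVPA)
with *grid* searchlights on the spherical cortical registration space.  The
chain is:

1. **Template construction.**  The spherical space is a geodesic sphere:
   every edge of a regular icosahedron is divided into `n_div` equal parts,
   faces are triangulated, and all points are projected radially to the
   unit sphere, giving `10·n_div² + 2` vertices.  128 divisions reproduce
   the 163,842-vertex resolution of the standard registration sphere;
   40 divisions give the 16,002-vertex downsampled analysis template
   (about a tenfold reduction, still finer than typical fMRI resolution).
   Each high-resolution vertex is assigned to its nearest downsampled
   vertex (chord = angular distance; ties to the lowest index).

2. **Grid searchlights.**  For each downsampled vertex `p(α, β)` the sphere
   is rotated so that `p` lands on the origin `z(0, 0) = (1, 0, 0)`
   (`R = Ry(β)·Rz(−α)`), an `n1 × n1` grid of square angular cells
   (`cell_size` radians per side; defaults 1/35 rad and 11 cells) is laid
   out around the origin, and every high-resolution vertex falling in a
   cell is recorded:
   `i = ⌊a/cell + n1/2⌋`, `j = ⌊b/cell + n1/2⌋` on the rotated coordinates
   `(a, b)`, rows indexed by longitude.  Per trial, BOLD values are
   averaged within each cell to form an `n1 × n1` image; a circular mask of
   radius `n1/2` cell units (boundary inclusive) zeroes the corners.  On a
   100-unit registration sphere the default grid spans a disk of radius
   `100 · (1/35) · (11/2) ≈ 15.7`.

3. **Trial extraction.**  A trial's pattern is the single volume at index
   `round((onset + timepoint)/TR)` (numpy round-half-to-even).  Paradigm
   files are 4-column text (onset s, condition code, duration s, weight);
   code 0 is baseline and is excluded from decoding by default.

4. **Decoding.**  Per searchlight, a classifier is trained and tested under
   leave-one-run-out cross-validation; fold accuracies are averaged with
   equal weight per fold into the subject's per-vertex accuracy map.
   Chance is `1/k` for `k` (super)classes.  The default decoder is a
   linear-kernel SVM (C = 1, one-vs-one above two classes) on the
   flattened masked image; an alternative stream classifies the image with
   a small convolutional network.

5. **Group inference.**  A one-sample, one-tailed t-test of accuracies
   against chance per vertex; vertex-wise thresholding at
   `p < 10^(−vertexwise)` (default 3, i.e. p < 0.001); connected-component
   clustering on the downsampled mesh adjacency; and a sign-flip
   max-cluster permutation: per permutation every vertex's t value has its
   sign flipped with probability 1/2, the map is re-thresholded with the
   same one-tailed rule, and the largest cluster size recorded.  After
   `n_perm` (default 2,000) repetitions the maxima are sorted descending
   and clusters must be **strictly larger** than the
   `round(α·n_perm)`-th maximum (rank 20 at α = 0.01) to survive.

## Design choices where the procedure was open

- **Spherical convention.**  α = longitude (`atan2(y, x)`),
  β = latitude (`asin z`), origin at `(1, 0, 0)`.  The rotation uses zero
  roll about the final axis, fixing the in-plane orientation of the grid;
  any other roll would permute cell assignments near cell boundaries but
  leave the set of member vertices essentially unchanged.
- **Binning rule.**  Rotated spherical coordinates are used directly as
  grid axes with floor binning; at the origin the metric is locally
  Euclidean, so this realises "cell_size radians per cell" exactly at the
  grid centre.  Vertices outside the grid after rotation are discarded.
- **Empty cells** contribute 0, indistinguishable from masked cells —
  consistent with zeroing data outside the circle.
- **Vertex sharing in subdivision** is combinatorial (base vertices, then
  edge points keyed by the sorted edge, then face-interior points), not
  floating-point merging, so builds are bit-reproducible; a
  tolerance-merge oracle confirms the counts in the tests.
- **Searchlight member search** prefilters high-resolution vertices with a
  KD-tree ball query at the exact grid circumradius bound
  `arccos(cos²(n1·cell/2))`; the bound is conservative, so results equal
  the all-vertex computation (asserted by a brute-force oracle test).
- **Sign-flip semantics.**  The default flips the *per-vertex t values*
  themselves and re-applies the one-tailed positive threshold (a flipped
  noise vertex can only activate if its −t exceeds the threshold).  The
  conventional subject-level variant — flip each subject's
  (accuracy − chance) map and recompute t — is available as
  `mode="subject"`.
- **Zero-variance vertices** (all subjects identical, e.g. perfect
  decoding on noiseless data) give t = ±∞ and are handled by the
  thresholding rule rather than raised as errors.
- **Determinism contracts.**  The SVM stream sorts each training fold into
  a canonical content-based order before fitting, so accuracy maps are
  invariant to trial order within runs; per-vertex and per-subject
  computations are independent, so results are identical for any worker
  count.
- **CNN stream.**  The network is input `n1 × n1` → convolution (3 × 3
  kernel, 8 filters, same-padding so the `n1 × n1` size is preserved) →
  relu → 2 × 2 max-pool → dense layer with one unit per class → softmax.
  A literal `n1 × n1` kernel with padding `n1` would be degenerate;
  size-preserving padding is the only reading consistent with the
  following pool.  Training protocol (our choice, exposed as parameters):
  full-batch Adam, learning rate 0.01, 150 epochs, seeded He-style
  initialisation.  The network is implemented directly on numpy, trains on
  CPU at searchlight scale, and is bit-reproducible given its seed.

## Synthetic data generator

`SimConfig` emulates an event-related surface study: S subjects × R runs
of i.i.d. Gaussian vertex noise (sd `noise_sd`) on the high-resolution
sphere, with trials at fixed onsets (`iti` apart, conditions randomised per
run, balanced counts) and a condition-specific multivariate pattern added
only inside a geodesic patch (`patch_radius` radians around the downsampled
vertex `patch_center`) at exactly the volume the trial-extraction step
reads.  Patterns are drawn fresh per subject from
`N(0, (effect_size·noise_sd)²)` per patch vertex — fine-grained patterns do
not align across subjects, only decodability does.  With `noise_sd = 0`
the pattern sd is `effect_size` itself so noiseless data remain separable.

Deliberate non-realism: no hemodynamic convolution (the method reads a
single post-onset volume, so HRF shape is orthogonal to every computation
in scope), no autocorrelated noise, no motion or cortical geometry.
Passing tests therefore demonstrate the correctness of the geometry,
decoding and inference machinery and its statistical calibration under
i.i.d. noise — not robustness to physiological artefacts.

Default study size (also the test conditions): high_div 16 (2,562
vertices), low_div 4 (162), 8 subjects, 3 runs, 10 trials per condition
per run, 2 conditions, TR 1 s, timepoint 7 s, patch radius 0.3 rad,
effect size 1.5.  The patch radius was chosen to be commensurate with the
default searchlight span (grid half-diagonal ≈ 0.22 rad) so that a
realistic handful of searchlights are informative.  Full 128/40 resolution
is available through configuration.

## Problem sizes used in the validation suite

Oracle suites run on small template pairs (8/2 divisions, 642/42 vertices)
where exhaustive all-pairs scans are feasible; cluster detection is checked
against an independent sparse-graph component labelling on 1,000 random
maps over the 162-vertex sphere.  Parameter recovery runs 20 seeded
repetitions of the default synthetic study with 500 permutations at
FWE α = 0.05, plus 20 null (effect 0) repetitions whose surviving-cluster
rate is required to be consistent with α.  The full-scale layout structure
(16,002 records × 124 fields) is verified with the 40-division
downsampled template against a 32-division high-resolution sphere.

## Known limitations

- Index-level compatibility with externally produced registration spheres
  (vertex ordering of specific FreeSurfer files) is not claimed; an
  external sphere surface can be substituted via the reader, preserving
  that file's vertex order.
- The t-value sign-flip null (the default mode) conditions on the observed
  t magnitudes; with very strong, spatially compact effects the null
  maxima are dominated by random halves of the signal cluster itself,
  making the test conservative relative to the subject-level variant.
- Hemispheres are independent analyses; no cross-hemisphere searchlights.
- No geodesic-distance disk searchlights; only the grid searchlight.
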