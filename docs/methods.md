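# Methods

## The analysis

Connectome lesion-symptom mapping asks which white-matter connections, when
severed by a stroke lesion, drive a behavioural deficit. The pipeline
implemented here follows the SVR-CLSM design for spatial neglect:

1. **Normative connectome.** A whole-brain streamline tractogram from healthy
   template data is reduced to a symmetric ROI × ROI streamline-count matrix
   over a grey-matter parcellation. Because tracking terminates at the
   grey/white interface, each streamline endpoint is assigned by a radial
   search: a direct label hit wins; otherwise the nearest labeled voxel
   centre within 2 mm (Euclidean, anisotropy-aware; ties to the smallest
   label). Streamlines traversing 3 or more distinct ROIs (endpoints
   included) are discarded as tracking artefacts. Counts are raw — no
   inverse-length weighting and no ROI-volume scaling: count differences
   driven by ROI size are treated as a feature of the network, not a bias.
2. **Per-patient disconnectome.** For each patient, streamlines intersecting
   the binary lesion mask are removed, the connectome is rebuilt from the
   spared subset, and the disconnectome is the entrywise difference
   `normative − spared` — the number of streamlines each link loses to the
   lesion. Only direct disconnection is measured. Because endpoint assignment
   and the traversal filter are per-streamline, the spared matrix equals the
   normative count restricted to unlesioned streamlines; the cohort pipeline
   exploits this to precompute each streamline's link and voxel trace once
   (the suite asserts exact equality with the filter-then-rebuild reference).
3. **Feature assembly.** Canonical upper-triangle links altered in at least
   one patient form the feature matrix; links with both nodes in the left
   hemisphere are dropped (the tested family is the right intrahemispheric
   plus interhemispheric subnetwork; midline regions are retained).
4. **Behaviour.** Neglect severity is the Center of Cancellation: targets'
   horizontal positions are min–max normalised to [−1, 1] and the score is
   the mean position of detected targets minus the mean over all targets
   (0 for complete cancellation, positive for rightward bias). Letter and
   bells task scores are averaged into a compound; the binary classification
   uses strict cut-offs (letter > 0.083, bells > 0.081, either suffices).
   Zero-detection sheets are flagged missing, never silently zero.
5. **SVR-CLSM.** The compound CoC is regressed on the link features with
   ε-insensitive linear-kernel SVR (libsvm via scikit-learn). C is selected
   on a powers-of-two grid (2⁻³⁰…2³⁰ by default, 61 candidates) by repeated
   k-fold cross-validation maximising prediction accuracy (Pearson r of
   out-of-fold predictions vs. scores) plus weight-map reproducibility (mean
   pairwise r between training-fold weight vectors), equally weighted. Link
   significance comes from permutation: scores are shuffled, the model is
   refitted at the same C, and each link's back-projected primal weight
   w = Σ αᵢxᵢ is compared against its permutation distribution with the
   add-one estimator p = (1 + #{w_perm ≥ w_obs}) / (1 + B), one-tailed by
   default (the directed hypothesis is that more disconnection raises the
   CoC; two-sided is available). Significance applies Bonferroni over the
   retained links — the family actually tested, not all possible ROI pairs.
6. **Network report.** Significant links form an undirected graph; it is
   segmented into connected components (ordered by edge count), and nodes
   with degree strictly greater than 3 are reported as hubs. Edge tables
   carry β, p, hemisphere tags and an interhemispheric flag.

## Geometric exactness

Streamline–voxel queries (lesion intersection, traversal sets) are exact:
polylines are densified to half the smallest voxel dimension and the voxel
boundary-crossing points of each segment are inserted analytically, so the
set of visited voxels is enumerated without step-size tunnelling — a
one-voxel wall or a sub-voxel corner clip between vertices cannot be missed.
The test suite checks exact agreement against 4 µm brute-force rasterization
and exhaustive distance scans on randomized scenes. A vertex-only fast mode
exists but is never the default.

## The synthetic cohort

Real lesion-symptom cohorts are protected clinical data, so the package
ships a generator whose explicit contract is a cohort with *recoverable*
ground truth; every stage is exercised against it.

- **Anatomy.** ROIs are solid cubic blocks (3 voxels, 2 mm isotropic) on a
  lattice separated by background corridors (4-voxel gaps), one z-layer,
  right and left hemisphere slabs with the midline at x = 0. The default
  study cohort uses 12 right + 6 left ROIs.
- **Tractogram.** ~30 bundles (30–60 streamlines each) connect random
  right–right and interhemispheric ROI pairs. Each bundle descends from its
  start ROI into a gap plane (below or above, per bundle), runs as a
  straight chord to beneath the end ROI and ascends into it; corridor
  waypoints are canonical per bundle with 0.3 mm Gaussian wobble per
  streamline. With zero wobble the connectome reproduces the bundle
  specification exactly.
- **Lesions.** Each patient's lesion is multifocal: 2–4 ellipsoidal blobs
  (radii 2–4 mm) centred on mid-corridor points of randomly chosen bundles,
  clipped to right/midline territory (x ≥ 0), emulating an embolic-shower
  right-hemisphere stroke. Multifocality plus mid-corridor centring keeps
  link hits close to independent across bundles — a deliberately
  well-conditioned design. Lesion placement never consults the ground truth.
- **Ground truth.** Four right–right links are designated critical by an
  identifiability screen run after lesion placement: a link qualifies if
  disconnected in at least max(5, 5 % n) patients and is ranked by the share
  of its disconnection-fraction variance not explained by the other
  candidate links; the designated set is node-disjoint. Effect weights are
  variance-equalised (w ∝ 1/sd of the link's fraction, ratio cap 3:1) and
  sum to 1.2, so a patient whose entire critical set is destroyed saturates
  the CoC scale. Severity is the weighted sum of critical disconnection
  *fractions* (bundle-size invariant) plus Gaussian noise, clipped to
  [0, 1]; the statistics nevertheless consume raw disconnection counts.
  `noise_sd` defaults to the value giving generative R² = 0.5. A null mode
  severs the anatomy–behaviour link for type-I studies. Optionally the
  severity is expanded into synthetic cancellation sheets (detection
  probability falls left of a severity-dependent attentional border) so the
  behaviour module can be exercised from raw responses.
- **What it does not emulate.** No diffusion signal, no tracking errors
  beyond the wobble, no vascular-territory lesion shapes, no lesion-size
  confound (real lesion volume correlates with severity and with every
  feature at once), no measurement noise in lesion delineation, and feature
  correlations far milder than voxel-level clinical data. Passing tests
  demonstrate the statistical machinery recovers a known generative truth
  under favourable, controlled conditions — not that it would isolate single
  links in clinical data, where the authors themselves interpret whole
  networks.

## Numerical choices

- Pearson r is defined as 0 when either argument is constant (tiny-C models
  predict a constant; their accuracy is 0, not NaN).
- Radial-search ties resolve to the smallest label; CV fold splits are
  seeded shuffles; ties in the C objective resolve to the smallest C.
- libsvm iteration counts are bounded (`max_iter`, default 10⁶) because
  convergence at large C on raw-count Gram matrices is extremely slow; at
  the small C values the CV selects on such features (2⁻¹⁶ is typical,
  consistent with the small-C optimum reported for this analysis family)
  fits converge well within the bound.
- The add-one permutation estimator is used throughout; with B permutations
  the smallest attainable p is 1/(B+1), and `permutation_test` warns when
  the Bonferroni bar is unattainable at that floor.
- Cohort-scale experiments (acceptance suite and script) use 1,000
  permutations and a reduced C grid (2⁻²⁴…2⁰ step 4, 2 CV repeats); the
  problem sizes are n = 200 patients / ~30 links for recovery and n = 50
  patients for null cohorts. The type-I experiment fixes C = 2⁻¹⁶, the
  value the CV typically selects — permutation validity holds for any C
  fixed before testing.
- Per-stage seeds derive from the global seed through `SeedSequence` over
  the stage name, so stages are independently reproducible; all pipeline
  CSV/JSON artifacts are byte-identical across reruns (timings go to the
  log only; NIfTI is written uncompressed).

## Known limitations

- Fold assignment is a plain seeded shuffle (no stratification by severity).
- Bonferroni is the only multiple-comparison procedure (as in the source
  analysis); no FDR option.
- The hemisphere filter retains midline ROIs and drops only left–left
  links; whether the original feature set did exactly this is not
  determinable from the published description.
- Whether the original permutation test was one- or two-tailed is unstated;
  the default here is one-tailed positive, configurable.
- The generator's identifiability screen and variance-equalised weights make
  the planted effects unusually clean; they are design features of the
  validation cohort, not claims about clinical effect structure.
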