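# Methods

This note documents the models, conventions and numerical choices behind
`ringscape`, and what the synthetic benchmarks do and do not demonstrate.

## Data model and coordinate conventions

All volumes live on a `VolumeGrid`: an `(nx, ny, nz)` voxel lattice with a
4×4 voxel→world affine in millimetres.  Voxel indices are 0-based; the
affine maps voxel *centers* to world coordinates.  A world point is inside
a mask voxel when its nearest voxel center (rounding half up, per axis) is
true.  Streamlines are ordered polylines in world mm everywhere inside the
package; TrackVis TRK files are converted on read/write (via nibabel) so no
internal code ever sees TRK native voxel-offset coordinates.  TRK stores
float32, so round-trips are exact only to ~1e-4 mm at typical coordinate
magnitudes; the plain-text polyline dialect (one `x y z` per line, blank
line between streamlines) is kept for human-readable fixtures.

## Generative model of the synthetic subjects

Subject `s` is a 4D series

    Y_s(v, t) = Σ_n  I_sn · a_n · f_n(v) · c_nt  +  ε(v, t)

with `I_sn ~ Bernoulli(prevalence_n)` independent per subject, `f_n` the
network's binary footprint, `c_nt` i.i.d. standard-normal time courses,
amplitude `a_n > 0`, and `ε ~ N(0, noise_sd²)` i.i.d. over voxels and
timepoints.  With `a = noise_sd = 1` the per-voxel SNR (signal variance /
noise variance on footprint voxels) is 1, the regime used throughout the
benchmarks.  Time courses are deliberately white: the spatial logic of the
pipeline is independent of temporal structure (a property the tests verify
by permuting timepoints), so autocorrelated hemodynamics would only slow
the tests without exercising extra code.  The generator returns the exact
inclusion table, so recovery has a per-seed ground truth.  What passing
these tests does *not* show: robustness to motion, physiological noise,
registration error, spatially varying SNR, or overlapping networks — none
of which the generator emulates.

## Per-subject spatial ICA

`decompose_subject` centers each time volume over space, whitens the
voxels×time matrix to K dimensions and runs the fixed-point negentropy
iteration with the logcosh contrast and a seeded initial rotation
(scikit-learn's FastICA; `max_iter = 500`, `tol = 1e-5`).  Requirements
checked up front: K at most min(timepoints, in-mask voxels) and at most the
numerical rank of the series.  Each component map is z-scored over the
brain mask and its sign fixed so the map skewness is non-negative, making
"activation" positive and the downstream one-sided t-test meaningful.  K is
a configuration parameter (default 20; the phantom pipeline uses 10, the
recovery benchmark 8 — sized to the number of planted sources plus
headroom, so the whole 20-seed benchmark fits in a few CPU-minutes).

## Group classes, representativeness, FDR maps

Component maps from all subjects are agglomerated by average linkage on
`1 − r` (Pearson correlation over the brain mask; the similarity metric is
a package choice) and the tree is cut where linkage distance exceeds
`1 − cut_similarity` (default cut_similarity 0.25).  If a subject
contributes several components to one class, only the component most
similar to the class centroid counts as that subject's membership —
representativeness must mean "fraction of subjects in which the network is
present", not "fraction of maps".  Classes with `R ≥ min_R` (default 0.10)
are retained and ranked by decreasing R; ties break by larger thresholded
mask, then by class creation index, making ranks deterministic.

Group maps are voxelwise one-sample t statistics over member z-maps with a
one-sided alternative (mean > 0), thresholded by Benjamini–Hochberg at
level `q` (default 0.05) across in-brain voxels (statsmodels
implementation; the test suite checks it against a from-definition
enumeration oracle on all inputs up to 10 p-values).  Zero-variance voxels
— which arise in noiseless fixtures — are defined to have `p = 0` when the
mean is positive, `p = 0.5` at zero and `p = 1` when negative.

Cross-population matching is greedy one-to-one on decreasing mask Jaccard;
the per-pair similarity rate is reported as Jaccard in percent.  This
definition is a package choice — reasonable alternatives (Dice, overlap
fraction of the smaller mask) would change the absolute rates but not the
matched/control contrast the tests assert.

## Overlap matrices and Brodmann bookkeeping

The topographical-similarity unit is the raw number of shared voxels
between two binary masks; matrices are integer counts (a normalized per-row
variant exists but is not used by the benchmarks).  The extended-Brodmann
regrouping applies exactly five merges (20*=20+38, 41*=41+42,
28*=28+34+35+36, 32*=32+24+25, 23*=23+29+30+31) and is idempotent.  The
seven Brodmann-area families are BAF1 (10, 11), BAF2 (8, 9, 46), BAF3
(44, 45, 47), BAF4 (23, 32), BAF5 (41, 42, 21, 22, 37), BAF6 (2–6), BAF7
(17, 18, 19); on an already-regrouped atlas a required area is looked up
inside the starred region containing it, so BAF4 built from extended areas
includes the full posterior/anterior cingulate merges.

## Mixture clustering and its graph-based validation

Overlap profiles (rows) are standardized per column and clustered with a
**variational Bayesian Gaussian mixture** (diagonal covariances,
Dirichlet-process weight prior, up to `max_components` components,
`restarts` seeded initializations, `reg_covar = 1e-6`, `tol = 1e-8`).
Variational EM drives the weights of unsupported components to zero, so
the number of occupied components — the model order — is determined by the
data.  This was a genuinely open design point: the obvious alternative, a
maximum-likelihood EM scan over k with BIC selection, turned out to be
degenerate on exactly the structures these matrices have.  A hard variance
floor lets a component collapse onto a single standardized row and buy an
arbitrarily large likelihood spike, so BIC over-selects on tables with a
few large blocks, while any floor large enough to suppress the spikes
destroys the ability to give genuine singleton clusters (which the
published memberships contain) their own component.  No fixed floor
satisfies both regimes; the variational treatment regularizes component
variances through their prior instead and handles both, which is why it is
the shipped method.

The independent validation route builds a weighted graph over the same
rows: edge weight = cosine similarity of profiles (negatives clipped to
zero), edges strictly below the mean positive weight removed, all-zero
rows isolated.  Community detection greedily merges the pair of
communities with the largest positive modularity gain until no merge
helps, with weighted Newman modularity

    Q = Σ_c [ w_in,c / W − (s_c / 2W)² ]

(W total edge weight, w_in,c within-community weight, s_c community
strength).  On every graph in the test battery with ≤ 8 nodes the greedy
result attains the exhaustive-search optimum over all partitions.
Agreement between the mixture and the communities is summarized by a
confusion matrix after optimal one-to-one label matching
(maximum-trace assignment on the zero-padded square matrix) and by
accuracy = matched agreements / rows.

## Family assignment and intermediate RSNs

Family assignment consumes two or more clustering "views" (e.g. the
TBN-based functional clustering and the BA/BAF-based anatomical ones),
each carrying its overlap matrix and the subset of reference units flagged
sensorimotor.  A cluster is VSA when the majority of its members' total
overlap mass lies on sensory-flagged units, else PTF; labels are invariant
to cluster-id permutation.  An RSN is **intermediate** when its own
sensory-vs-association mass fractions differ by less than `margin`
(default 0.30; the balance criterion in the source analyses is
qualitative) in some view, *or* when two views place its cluster in
different families.  On the bundled membership tables this
concordance-of-assignment rule reproduces the published split exactly:
27 of 30 RSNs specialized, RSNs 1, 23 and 27 intermediate.

## Ring topology

Continuity is a connected-component count (6-connectivity by default,
26 by configuration; the choice of 6 is the conservative face-adjacency
reading).  Enclosure is defined by flood fill within a supplied domain
mask: the island is enclosed iff the connected component of
`domain \ ring` containing it never reaches a domain voxel on the grid
bounding-box faces.  With the phantom's flat-slab domain (full x–y extent,
z inset) this reproduces the 2D sheet intuition — an unbroken annulus
encloses its center; a one-voxel breach does not — without computing any
surface topology.  Hemispheric symmetry is the Dice overlap between a mask
and its mirror image about the mid-plane of a chosen axis.  A sector
ordering is reported as a cycle only if every consecutive pair (including
last–first) is voxel-adjacent and the cycle has length ≥ 3; the
adjacency-derived variant requires every sector to touch exactly two
others.

## The phantom parcellation

The toy cortex is a flat slab; the ring family is an annulus split into 6
angular sectors (pairwise adjacent in a single cycle), the association
family is a central island filling the annulus hole plus mirror-paired
scattered parcels outside the ring.  Everything is mirror-symmetric about
the x mid-plane by construction, so the planted symmetry Dice is exactly
1.0, the ring is one component, the island is enclosed, and the scattered
family has ≥ 2 components — giving the topology operators sharp expected
values rather than tendencies.  The layout is deterministic given its
geometry; the seed parameter exists for interface uniformity.

## Fixture overlap matrices and the bundled membership tables

`fixture_overlap_matrix` plants cluster structure as Poisson counts:
`high_mean` (default benchmarks use 500) on a cluster's column signature,
`low_mean` (10) elsewhere.  Clusters get disjoint contiguous column blocks
when possible.  The RSN×BAF table has 10 published clusters over only 7
reference columns, where disjoint blocks are impossible; its fixture
therefore pins an explicit column signature per cluster, chosen to respect
modality (sensory clusters draw on BAF5–7: visual {BAF7}, somatomotor
{BAF6}, the two bimodal somatomotor singletons {BAF6, BAF7} and
{BAF6, BAF5}, auditory {BAF5}; association clusters draw on BAF1–4) with
distinct signatures so all 10 clusters are identifiable.  The published
BAF table lists RSNs 18 and 20 in two clusters each; the tables are
shipped verbatim with the duplicates flagged, and the packaged resolution
assigns each to its singleton cluster.  Duplicate resolution is always
explicit — the loader never silently drops a row.

## Benchmark scales and expected outcomes

* Model-order recovery: 20 fixture seeds per table; the mixture selects 6
  clusters on the 30×18 table and 10 on the 30×7 table in ≥ 90% of seeds
  (observed 20/20 for both at the shipped settings).
* Group-ICA recovery: twenty populations of 50 subjects on a 12×12×6 grid,
  60 timepoints, K = 8, three disjoint networks at prevalence 0.6 / 0.3 /
  0.05, SNR 1.  The two common networks are always recovered and their
  estimated R tracks the *realized* inclusion fraction almost exactly, so
  the mean error against planted prevalence is binomial sampling noise
  (~0.05).  The rare network is rejected by the 10% rule in ~90% of seeds
  — precisely the seeds where its realized inclusion falls below 10%;
  rejection is a property of the rule, not of the estimator, and the tests
  assert exactly that conditional behavior.
* The problem sizes above were chosen once so the full suite runs in a few
  CPU-minutes; recovery quality is not sensitive to them in the regimes
  tested.

## Known limitations

* The ICA similarity metric, linkage cut, graph construction and matching
  rule are package choices where the source analyses leave the definitions
  unstated; each is a configuration knob.
* Ring topology is voxel-based on a slab phantom; no surface (mesh)
  topology is computed, and anatomical sector naming on real MNI-space data
  is out of scope.
* Tract filtering implements only endpoint-in-mask selection (`both` or
  `either` endpoints); everything upstream of streamlines — ODF
  reconstruction, seeding, smoothing — is out of scope.
* Real-data headline counts (hundreds of pre-threshold classes, 32 RSNs,
  ~60% cross-population similarity) depend on the original acquisitions and
  are not reproduced by the synthetic benchmarks.
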