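# Methods

## Problem setting

Thymomas are classified morphologically into five WHO subtypes — A, AB, B1,
B2 and B3 — that differ in tumor-cell shape (spindled in A, increasingly
atypical toward B3) and in how much lymphocytic infiltrate surrounds the
tumor cells (A and B3 are lymphocyte-poor; AB, B1 and B2 lymphocyte-rich).
Whole-slide images are far too large to classify directly and patch-level
annotation is expensive, so the package treats subtype classification as
weakly supervised multiple-instance learning (MIL): a slide is a *bag* of
patch feature vectors carrying a single slide-level label, while each
patch's own label — one of the C subtypes or the background class C+1
(non-tumoral tissue) — is unobserved.

## Model

### Attention-MIL bag classifier

Each slide X is tiled into N patches x_i, encoded to features
z_i = E(x_i) by a decoupled encoder, and aggregated per class with gated
attention: the instance score for class c is
w_c · (tanh(V z_i) ⊙ σ(U z_i)), softmax-normalised over the bag's
instances into weights a_i^c, giving the per-class bag representation

    F_c = Σ_i a_i^c z_i .

A per-class linear logit u_c · F_c + b_c and a softmax over classes give
the bag probabilities; the loss is categorical cross-entropy (optionally
class-weighted).  Attention weighting lets the classifier concentrate on
the informative (tumor-bearing) patches while ignoring background.

The attention-logit weights `w` and the class-logit weights `u` are both
initialised at zero: attention starts exactly uniform (the bag feature is
the instance mean) and the class logits start at zero, sharpening and
growing only as the loss demands.  Random initialisation of either causes
distinct failure modes at the small learning rates of the training
recipe — attention locks onto arbitrary instances, and the logits begin
as a random projection of the strong feature directions that early
training must first unlearn.  Only the gating networks (V, U) are
randomly initialised.  The gated branch width defaults to 32 — with
64-dimensional features and tens to a hundred-odd bags per classifier,
wider heads measurably overfit.

### Divide-and-conquer hierarchy

Direct five-way classification from slide labels alone is hard at these
cohort sizes.  The tree exploits known morphology: the root separates the
lymphocyte-poor pair {A, B3} from the lymphocyte-rich triple {AB, B1, B2};
one child then distinguishes A from B3 and the other AB/B1/B2.  Every node
carries its own attention-MIL classifier trained on the slides belonging
to its subsets, with the branch index as the node-local label and
inverse-frequency class weights against node-local imbalance (e.g. 21 A
vs 83 AB slides at the ternary node).

Stage outputs compose into a five-class prediction two ways:

* **hard** (default for reporting accuracy): follow the argmax branch at
  each node to a leaf;
* **soft**: each leaf's probability is the product of the branch
  probabilities along its path — a proper distribution, used for
  macro-AUC.

Soft-argmax is biased toward the binary subtree (the ternary branch's mass
splits three ways), which is why hard routing is the default decision
rule.

### Pseudo-label refinement of the encoder

Patches are initially unlabeled.  Each refinement round scores every
patch of a slide with the confidence

    s_n = a_n^{c} · p_n^{c} ,

the product of the patch's attention for the slide's class c (from the
current best MIL head) and its class-c score from the current best patch
classifier (taken as 1 in the bootstrap round, before any patch classifier
exists).  Per slide, the top-k patches are pseudo-labeled with the slide
class and the bottom-k with background; ties break by ascending patch id;
k defaults to max(1, ⌈0.1 N⌉) and shrinks to ⌊N/2⌋ with a warning if the
bag is small.  The auxiliary patch classifier — a softmax head whose
backbone weights are shared with the MIL encoder — is trained on these
labels, the bag features are re-extracted with the updated encoder, and a
fresh MIL head is trained.  Pseudo-labels are regenerated from scratch
every round so early mistakes are not frozen in.  The *current best*
bundle is the one with the highest validation bag accuracy so far (ties
keep the earlier round); the loop stops after one round without
improvement.  With a frozen (identity) encoder the loop has no lever and
degenerates, by construction, to plain MIL training.

In feature-bag mode the trainable encoder is an affine map initialised at
the identity; in image mode a fixed seeded three-layer random convolutional
feature extractor feeds it.  A full-scale deployment would substitute a
pretrained CNN backbone behind the same encoder contract.

### Auxiliary patch classifier for heatmaps

The interpretability heatmap colors every foreground tile by its predicted
patch category (C subtypes + background), so one slide can display several
subtype colors — unlike attention heatmaps, which can only shade the single
predicted class.  For this use the patch classifier is fit by
`fit_patch_classifier_from_bundle`: two bootstrap passes of
confidence-ranked pseudo-labels with a wider k = ⌈0.3 N⌉ for boundary
coverage, followed by a self-labeling refinement.  Before a patch
classifier exists, the patch score in s = a·p is bootstrapped from the
MIL head evaluated on each patch as a singleton bag (whose attention is
exactly 1, so the score reduces to the head's linear classifier on that
patch) — attention alone can be uninformative when the bag task is
solvable with near-uniform attention.  The self-labeling refinement runs
three nearest-centroid reassignment iterations in the raw feature space
(the maximum-likelihood rule when class-conditional features are
isotropic) and refits at a convergence-level step budget.  The
confidence-selected extremes alone give systematically offset boundaries
(they oversample class-typical patches); the centroid step restores
midpoint boundaries.  The reassignment runs in raw feature space because
the refined encoder is anisotropic and distorts Euclidean assignment.

`heatmap.minority_focus` extracts the slide's secondary focus: the largest
4-connected component of the second-most-frequent subtype color.  Isolated
single-tile speckle is expected even from a Bayes-optimal patch classifier
at realistic noise levels, so coherent-focus extraction, not per-tile
perfection, is the meaningful localisation statement.

## Training schedule

Adam throughout.  The MIL head trains with batch size 1 at learning rate
1e-4; the patch classifier with batch size 64 at 5e-5; both halve the
learning rate on a fixed epoch interval.  Those rates follow the original
fine-tuning recipe; because the desk-scale heads train from scratch rather
than from pretrained weights, the default horizon is doubled — decay every
20 epochs, 100 epochs, early-stop patience 20 on validation accuracy
(keeping the *latest* epoch among accuracy ties, i.e. the most converged
of the equally good snapshots).  `lr_decay_every=10, epochs=50` restores
the original schedule.  `fit_hierarchy` additionally scales each node's
epochs, decay interval and patience by (141 ÷ node training size) — 141
being the training-set size the defaults are calibrated for — so nodes
deeper in the tree and scaled-down cohorts, which see fewer slides per
epoch, receive a comparable optimisation budget in optimizer steps.  All
randomness
flows from injected seeded generators; runs are single-threaded and
bit-reproducible.

## Synthetic phantom

The generator emulates the statistical structure the method assumes,
without pretending to be histology:

* **Cohort layout**: 222 slides split 21/83/48/49/21 over A/AB/B1/B2/B3;
  stratified train/validation/test split of 141/42/39 by largest-remainder
  rounding.
* **Slides**: an 8×8 tile grid (64-px tiles at desk scale; 256 px mirrors
  full scale), ~85% of tiles are tissue; 60% of foreground tiles carry the
  slide's subtype signal, the rest are background-class (lymphocyte-rich
  stroma).  Every slide retains at least one patch of its own class (MIL
  positivity).
* **Features**: class signatures are orthogonal scaled basis vectors, so
  the distance between any two class means is exactly
  `signature_separation` (default 3.0); patch features add isotropic
  Gaussian noise (sd 1.0).  Separability is therefore one scalar.
* **Heterogeneity**: with probability 0.2 a slide hosts a contiguous
  rectangular block of a second subtype covering 5–15% of its patches,
  mimicking mixed-subtype slides; the slide keeps its majority label.
  (How mixed slides were labeled in practice is genuinely ambiguous;
  majority labeling is this package's convention.)
* **Cells**: per tile, a Poisson(8) number of elliptical nuclei that never
  cross tile borders.  Tumor-cell area and axis ratio are
  subtype-dependent (B3 nuclei largest, A spindled with the highest axis
  ratio), lymphocyte fraction is lowest in A and B3; background tiles are
  90% lymphocytes.  Image mode paints tissue and nuclei so the tiling,
  masking and morphology code paths run end to end.

What the phantom does **not** emulate: H&E texture and stain variation,
nucleus overlap and segmentation errors, spatial correlation of features
within a tumor region, magnification effects, or scanner artifacts.
Passing tests therefore demonstrate that the algorithms recover the
structure they assume, at the configured effect sizes — not clinical
performance on real slides.

## Cell-morphology statistics

Per nucleus: area (interior pixel count of the filled contour), major and
minor axis lengths (equivalent-ellipse convention, 4·√eigenvalues of the
second central moments of the filled region), elongation-ratio
"eccentricity" (major/minor — the long-to-short axis ratio, *not* conic
eccentricity), solidity (polygon area over convex-hull area), mean
absolute curvature (total turning angle per unit arc length of the
5-point-smoothed contour; 1/r on a circle), and mean intensity.  Per
slide, 12 summary features: {tumor, inflammatory} × {proportion, mean
area, mean eccentricity, mean solidity, mean curvature, mean intensity},
where *proportion* divides the slide's count of that cell type by the
cohort-wide grand total, so proportions sum to 1 over the cohort.

Groups are (subtype × cell type) vectors of per-slide values — ten groups
for five subtypes and two cell types; the five tumor groups are compared
with a tie-corrected Kruskal–Wallis test (df = groups − 1, chi-squared
upper tail) and Dunn's pairwise post hoc test with tie-corrected
pooled-rank standard errors; a positive Z means the first group ranks
higher.  The g(g−1)/2 p-values are Benjamini–Hochberg adjusted (step-up,
capped at 1) and star-graded (<0.05 *, <0.01 **, <0.001 ***, <0.0001 ****,
else ns; strict inequalities).  Dunn's statistic is computed on mean ranks
— the standard operationalisation of the "higher median" narrative; with
similar group shapes the two orderings coincide.

Segmentation audit metrics for an upstream nucleus segmenter: pixel Dice;
fast AJI (greedy best-IoU matching in ground-truth order, predictions
consumed once) and AJI+ (optimal one-to-one matching via the Hungarian
algorithm); DQ, SQ and PQ = DQ·SQ at IoU > 0.5; and per-type plus
micro-average detection F1 with centroids matched within 12 px.

## Numerical and design notes

* Attention softmax and class softmax are computed with max-subtraction;
  attention columns sum to 1 within 1e-6 by construction.
* Patch-class argmax ties resolve to the lower class index; pseudo-label
  ranking ties resolve to the ascending patch id.  Both are documented
  contracts, not accidents of the sort.
* The morphology rasteriser treats pixels as integer lattice points:
  a square spanning rows/cols 0..9 has area 100; moment-based axis lengths
  on an L×W block recover √((L²−1)/(W²−1)) — within 0.5% of L/W for the
  sizes involved.
* The `evaluate` metrics are computed from the one-vs-rest confusion
  counts (accuracy, macro precision/recall/F1) with scikit-learn used only
  for the ROC-AUC integration; classes absent from the truth are excluded
  from macro averages with a warning.
* Degenerate inputs: all-identical data gives a Kruskal–Wallis H of 0 and
  p = 1; an all-white image gives an empty tissue mask; an image smaller
  than one tile gives an empty tile set; collinear or self-intersecting
  contours are rejected.

## Problem sizes used by the test-suite and acceptance script

The seed-0 classification run uses the full default cohort (222 slides,
~54 patches each).  The five-seed refinement ablation and the heatmap
bundle run on a proportionally scaled cohort (8/16/10/10/8 slides) —
the assertions there concern the direction of the refinement effect and
patch-level localisation, not absolute cohort-scale accuracy.  Null-model
false-flag rates are estimated over 20–40 reduced cohorts (6 slides per
subtype, 4×4 grids) and asserted at the 5% level plus two binomial
standard errors of Monte-Carlo uncertainty.

## Known limitations

* The feature-space phantom bypasses the encoder problem entirely; image
  mode exercises the code path with a random (untrained) convolutional
  encoder, not a learned one.
* The linear trainable encoder cannot express the nonlinear feature
  corrections a fine-tuned CNN backbone would learn; refinement gains on
  the phantom are correspondingly modest and are asserted only as
  "not worse, usually better".
* Per-class gated attention normalises each class's attention over the
  bag, which discards instance counts; slides whose minority component is
  very distinctive can be routed by presence rather than majority.  The
  hierarchy's grouping mitigates this but does not remove it.
* Dunn + BH control the false discovery rate per feature family, not
  across the 12 features jointly.
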