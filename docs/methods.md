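# Methods

This note documents the models, conventions and numerical choices behind
`thallometry`, what the synthetic data generator does and does not
emulate, and the known limitations.

## Segmentation

Images are reduced to 8-bit grayscale with the BT.601 luminance weights
(0.299, 0.587, 0.114); the weights are a fixed documented constant, not
configurable.  The global threshold is Otsu's criterion — the level
maximizing between-class variance over the 256-bin histogram, found by
exhaustive search with a first-maximum tie-break — with a manual
override and a polarity flag (specimen darker or brighter than the
background; default darker, matching herbarium photographs).  Cleanup is
morphological opening then closing with disc-shaped structuring elements
(default radius 1 px each; radius 0 skips the step).  Discs were chosen
for isotropy on organic outlines.  Erosion treats the outside of the
frame as foreground and dilation as background, so specimens touching
the frame are not nibbled away.  Holes or speckle beyond the reach of
the structuring element are deliberately left: no connected-component
size filtering is applied.  The threshold actually used, its source
(otsu/manual), the polarity and both radii are recorded in the mask's
provenance and in the run log.

## Skeletonization

Thinning is the classical Zhang–Suen scheme: two alternating
subiterations, each simultaneously deleting every boundary pixel p with
2 ≤ B(p) ≤ 6 skeleton neighbours, exactly one 0→1 transition around its
8-neighbourhood, and the subiteration's two directional products zero,
until a full pass deletes nothing.  The image is padded by one
background pixel for the neighbourhood tests and cropped afterwards.
The scheme preserves 8-connected foreground components and 4-connected
holes for blob-like objects (verified exhaustively in the test battery);
it is known to erase isolated 2×2 squares, which cannot arise from the
structures this package measures.

**Feature classification.**  Terminals are skeleton pixels with exactly
one 8-neighbour.  Junction *candidates* have ≥ 3 raw 8-neighbours, but a
corner pixel on a smooth curve can reach 3 via a diagonal shortcut, so
the junction test is applied on the *reduced* adjacency: a diagonal link
is discounted when the two pixels share a 4-connected common neighbour
on the skeleton.  Thinning typically leaves 2–3 adjacent junction pixels
at one biological branching point; 8-connected clusters of junction
pixels are merged into a single junction whose representative is the
member pixel nearest the cluster centroid (lexicographic tie-break), so
one branching point yields one graph vertex and one junction disc.

**Spur pruning.**  A spur is the pixel path from a terminal up to (but
excluding) the first junction pixel.  Paths shorter than the threshold
are deleted and classification is re-run, iterating to a fixpoint.
Junction-to-junction and terminal-to-terminal paths are never deleted,
so pruning cannot disconnect the skeleton.  The default threshold is
adaptive: max(3 px, EDT at the parent junction), i.e. half the local
junction thickness — boundary roughness creates spurs on that scale.  A
fixed threshold can be given instead, and 0 disables pruning.  Pruning
precedes graph construction.

**Loops.**  Overlapping branches in the 2D projection create cycles.
The loop count is the cycle rank E − V + C of the traced region/edge
multigraph (equivalently of the reduced pixel graph with junction
clusters contracted); raw 8-adjacency is *not* used directly because it
manufactures 3-cycles at every diagonal corner.  Each basis cycle is
reported with its pixel coordinates.  Automatic loop removal is
deliberately not attempted — deciding which branch passes over which is
a biological judgement — so the package instead offers an explicit edit:
`break_loop` carves a one-pixel-wide, 4-connected background gap across
the branch, perpendicular to a user-supplied adjacent pixel pair, so
that re-skeletonization separates the branches.  Self-loop traces
shorter than 4 px are absorbed into their junction region rather than
counted: they are rasterization artifacts of thick junction areas, not
petal loops.

## Graph construction and traversal

The classified skeleton is decomposed into regions (junction clusters,
terminals) and maximal chains of degree-≤2 pixels between them; every
skeleton pixel belongs to exactly one region or one edge path, a
property asserted by the tests.  Vertices take the representative pixel
as coordinate but keep all member pixels.  The root is a terminal: the
caller's choice, or the lexicographically smallest (row, column)
terminal for determinism.  A component with no terminal (a closed ring)
cannot be rooted and is reported through the loop report instead.  Each
connected component gets its own rooted graph; per-image measurements
are pooled.

Depth-first traversal starts at the root and explores the edges at each
vertex ordered by the angle of the edge path's initial direction (then
edge id), giving a reproducible visit order and a parent→child
orientation on every edge.  An edge reaching an already-visited vertex
closes a cycle: it is visited once, flagged, and a warning refers to the
loop report.

## Measurements

All thicknesses are disc *diameters*: twice the Euclidean distance-map
value at the centre.  The distance map is the exact EDT of the
foreground with the image border counted as background.

* **da** — one disc per junction, centred at the representative pixel.
  At a junction the object is locally wider than its branches (the
  inter-branch wedges recede), so da modestly exceeds the nominal branch
  width; the synthetic ground truth models this analytically (below).
* **db** — walking each edge from its parent vertex, discs are placed
  greedily: the next centre is the first path pixel whose maximal disc
  (radius = EDT) no longer overlaps the previously placed disc (the
  parent's own disc to begin with).  The diameter is
  2·min(EDT, distance to the previous disc's boundary); with this
  placement rule the background term governs, and on a constant-width
  bar the discs recover the bar width with centres about one diameter
  apart.  A disc limited by the previous disc rather than the
  background would be flagged `boundary_limited`.  The walk stops on
  entering the far terminal's dc disc.
* **dc** — one disc per terminal, the root included.
* **bl** — both the interior pixel count of the edge path (vertex
  pixels excluded) and the Euclidean chord between the end vertices are
  reported.  The pixel count undercounts Euclidean length on diagonal
  runs (a diagonal step is one pixel but √2 long); the chord is the
  better estimator for straight branches, and recovery tests use it.
* **ba** — at each junction, for every pair of child edges under the
  DFS orientation, the angle between the two branch directions, in
  [0, 180]°.  A branch's direction follows its db disc centres: from
  the first to the second disc when the edge carries two or more —
  both lie beyond the junction's own disc, outside the transient where
  the medial axis bends into the junction (anchoring the vector at the
  junction pixel biased perfect-Y fixtures by tens of degrees) — else
  from the junction to the single disc centre, else to a probe pixel
  5 px along the path.  Only sibling–sibling angles are emitted, not
  parent–child: the biological quantity is the opening of the
  bifurcation.
* **bs** — distance from each tip to its nearest other tip, pooled
  across components of the image; both directions of a mutual pair are
  retained.  Tip positions are refined to sub-pixel precision before
  the search: thinning retracts a skeleton endpoint 1–2 px into the
  branch, so the tip is re-located by marching from the terminal along
  the branch's outward direction to the object's extreme end and
  stepping back one EDT radius.  Without this correction spacing is
  biased low by ≈ 2·retraction·cos(θ/2) for tips on arms θ apart.

The per-image summary statistic is the arithmetic mean per variable
(medians are also available).  A pixel scale (units per px, > 0)
multiplies all lengths; angles are never scaled; pixel values are
retained alongside scaled ones.

## Statistics

W and B are the within- and between-group sum-of-squares-and-cross-
products matrices.  MANOVA reports Λ = det(W)/det(W+B) with Rao's F
approximation.  CDA solves the generalized symmetric eigenproblem
B v = λ W v (numerically better behaved than forming W⁻¹B; the tests
cross-check against a brute-force eigen-solver on W⁻¹B to 1e-8) and
keeps the top f = min(g−1, p) functions.  Raw coefficients are scaled to
unit pooled within-group variance of the canonical scores, with the
largest-magnitude coefficient made positive for a deterministic sign;
standardized coefficients multiply by the pooled within-group standard
deviations.  Per function i the residual Λᵢ = Π_{j≥i} 1/(1+λⱼ) is
tested with Rao's F at the reduced dimensions.  Classification assigns
each specimen to the nearest group mean in canonical space (Euclidean
distance over all retained functions, equal priors), reported as a
resubstitution count matrix and trace/n rate.  Resubstitution is
optimistic: on pure noise with p = 6, g = 4, n = 140 it measures ≈ 37%
"accuracy" against the 25% chance level, which is why the chance-level
simulation in the acceptance suite evaluates a permuted-label fit on an
independent sample.

Pairwise comparisons after the one-way ANOVA use Tukey's HSD — the
standard all-pairs companion — with R-style significance codes
(*** 0.001, ** 0.01, * 0.05, . 0.1).  Pearson correlations carry
two-sided t-distribution p-values.  Shapiro–Wilk normality checks are
delegated to scipy and reported without judgement.

## Synthetic data

`generate_thallus` renders a recursive binary tree of tapered,
round-capped bars by sweeping discs along each centreline (0.25 px
steps), growing downward so the trunk base is the default root.  Widths
taper linearly across generations from the junction width through the
branch width to the terminal width; sibling branches open symmetrically
at the specified angle, branch length decays geometrically per
generation, optional Gaussian jitter perturbs each branch direction, and
`overlap=True` adds a bar between two tips to force a loop, recording a
cut location for `break_loop`.  Ground truth is computed from the vector
geometry, not the raster: branch lengths and sibling angles from the
actual (jittered) directions, tip spacing from cap-centre coordinates
(the trunk base counts as a tip, as the skeleton carries a terminal
there), and junction thickness from the closed-form inscribed disc where
three bars of half-width r meet — min over inter-ray wedges of
r/sin(gap/2), capped at r for reflex gaps.

The generator emulates the *geometry* the pipeline measures: tapering
widths (junction > branch > terminal), controlled lengths, angles and
tip spacing, boundary-level rasterization noise, and optional loops.  It
does not emulate photographic reality — uneven illumination, texture,
damaged or overlapping specimens, herbarium backgrounds — so passing
recovery tests demonstrates correctness of the measurement chain on
clean geometry, not robustness of segmentation on difficult images.
`generate_group_tables` draws per-specimen variables as independent
normals at stated group means/SDs (a correlation matrix is an option,
default off); the bundled `RICCARDIA_GROUPS` constant carries published
four-group summary statistics (n = 37/26/25/50).  Because the default
draws are independent while real thallus variables are strongly
correlated (r up to ≈ 0.96 between junction and branch thickness),
simulated tables separate *more* easily than real ones: simulated Wilks'
Λ ≈ 0.11 and resubstitution rates ≈ 80% should not be read as estimates
of the real-data values.

Recovery test batteries sweep one factor at a time — widths
{7, 11, 15, 21} px at length 80/angle 90°, lengths {40, 80} px at width
7, angles {60, 90, 120}° at width 7 — so each factor's tolerance
(±2 px thickness and spacing, ±5% length, ±5° angle, on fixture means)
is checked without interaction from the others; tapered fixtures
additionally assert the mean ordering da > db > dc.

## Numerical choices and degenerate inputs

* Otsu on a constant image, descriptives with a singleton group,
  correlation with a zero-variance column, MANOVA/CDA with singular W or
  n − g ≤ p, nonpositive pixel scales and background cut pixels all
  raise typed errors with actionable messages.
* An isolated skeleton pixel has no neighbours: it is neither terminal
  nor junction and yields no measurements.
* A junction with fewer than two child edges, or fewer than two tips in
  an image, produces a warning and no angle/spacing entries.
* Batch processing isolates failures per image; a corrupt file is
  logged and skipped.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); CSV/JSON output uses fixed float
  formatting, making reruns byte-identical.
* Problem sizes in the verification suite (64×64 thinning shapes, 40×40
  distance masks, depth-2/3 thalli, 200-replicate simulations at the
  published sample sizes) were chosen to exercise every code path at
  desk scale.

## Limitations

* One specimen per image is assumed; disconnected fragments are measured
  and pooled but there is no scene splitting.
* Thickness is a 2D projected width; no correction for tilt or for the
  unistratose wing along branch margins.
* The spur threshold, although adaptive, is a heuristic; very short real
  branchlets below half the junction thickness are removed with the
  spurs.
* Zhang–Suen skeletons bend smoothly into junctions, so the junction
  representative sits near the medial meeting point, which for very wide
  branches is displaced from the visual branch point by up to about one
  half-width.
* Whether the original measurement convention took branch angles between
  siblings or between parent and child is not determinable from the
  published material; this implementation measures siblings and
  documents it in the output metadata.
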