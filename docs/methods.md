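# Methods

## Model

A continuous-output SDM projection assigns each grid cell a suitability in
[0, 1]. `fprs` treats that surface as the membership function of a fuzzy set
F over the grid, so "range area" becomes fuzzy cardinality c(F) = Σ μ_ij
(unmasked cells only) and range comparison needs no presence/absence
threshold. Intersection and union are the Zadeh operators, cell-wise min and
max. These are chosen over product/probabilistic-sum because they preserve
the crisp-set limit: on binary maps O reduces to the classical Jaccard
overlap and I to the classical relative area change, which is the behaviour
the index endpoints ("0 = no overlap, 1 = complete congruence") rely on.

The five indices for a current/future pair (F_p, F_f) with a shared DEM:

* I = (c(F_f) − c(F_p)) / c(F_p). Defined only when c(F_p) > 0; I ≥ −1.
* O = c(min(F_p,F_f)) / c(max(F_p,F_f)). The prose notion "proportion of
  overlap with the current range" is ambiguous between this Jaccard form and
  c(∩)/c(F_p); only the Jaccard form attains 1 exactly at congruence, so it
  is the default and the other reading is exposed as
  `convention="current_normalized"`, with the convention recorded in every
  output row.
* (Dx, Dy, Dz) = C(F_f) − C(F_p), where C is the membership-weighted
  centroid over cell centers (X, Y in degrees) and DEM elevations (Z in m).
  Both periods use the *same* DEM; Dx is a plain longitude difference, with
  no cos-latitude correction, keeping the units contract in angular degrees.

Conventions fixed package-wide: square cells; row 0 at the south edge; cell
centers at (x0 + (i+0.5)·s, y0 + (j+0.5)·s); masked (NoData) cells enter no
sum. Cardinality uses compensated summation (`math.fsum`) so the lattice
identity c(min)+c(max) = c(a)+c(b) holds to 1e-9 relative even on
million-cell grids. An optional cos(latitude) area weighting exists on
`fuzzy_cardinality` but is off by default and unused by the index pipeline,
which deliberately follows raw-grid cell semantics.

## Ensemble consensus

Uncertainty from climate forcing and predictor choice is handled by a full
GCM × predictor-set design (5 × 5 = 25 members in the reference protocol),
collapsed per cell to the median. The even-count median averages the two
central order statistics; a cell masked in any member is masked in the
consensus (conservative, since a missing member leaves the cell's median
unsupported). No weighting or uncertainty bands — deliberately out of scope.

## Model evaluation

AUC is the rank-based Mann–Whitney statistic (ties ½), computed from
midranks; it is invariant under monotone transforms of the scores. κ and TSS
are evaluated on the 19 thresholds 0.05–0.95, generated as exact multiples
k/20 to avoid float drift, and their maxima reported. A score exactly at the
threshold counts as predicted present (≥), which keeps cells at the
threshold suitability inside the range. AUC here assumes a labelled
presence/absence table; pseudo-absence sampling is not this package's job.

## Group statistics

Species-level index values are aggregated to genus and (by pooling genera)
family level: mean, sample SD (n−1), n. The significance protocol is:
two-sided one-sample t vs 0 for I, Dx, Dy, Dz (α = 0.05; ** below 0.01),
skipping O because a bounded positive ratio trivially differs from zero;
one-way fixed-effects ANOVA across scenarios (α = 0.05); and, only when the
ANOVA is significant, Fisher's LSD pairwise t tests on the pooled
within-group mean square with N−k df at α = 0.10, summarised as a compact
letter display built by insert-and-absorb (letters are transitive-consistent
with every pairwise decision; ties in set construction are broken by
ascending group mean). Scenarios are really repeated measures on the same
species; the plain one-way ANOVA is kept as the faithful default and a
repeated-measures (species-blocked) variant is available via
`repeated_measures=True`, clearly a deviation when used. No multiple-testing
correction beyond the ANOVA gate.

## Synthetic fixtures

The generator emulates smooth unimodal MaxEnt-style suitability surfaces as
bivariate Gaussians μ(x,y) = peak·exp(−(x−cx)²/2σx² − (y−cy)²/2σy²)
evaluated at cell centers. Gaussians are used because cardinality
(peak·2πσxσy/cell²) and centroid (the center) are closed-form in the
continuum, giving analytic truth: translating by (dx, dy) and scaling σ by
√e yields expectations Dx = dx, Dy = dy, I = e − 1, and on a north slope of
s m/° the vertical displacement is s·dy. Truncation at the grid edge is the
only error source; a guard rejects surfaces losing > 0.1% of their mass, and
recovery tests run at the 5-arcminute analysis resolution (cell = 1/12°,
240 × 240 ≈ 5.8·10⁴ cells — large enough for sub-0.05° centroid recovery,
small enough that the full test suite runs in seconds). Default study
conditions: center (105° E, 35° N), σ = 1.5°, peak 0.9, a 20° × 20° grid,
and a 300 m/° north-slope DEM.

Evaluation samples draw scores from shifted symmetric Beta(3,3)
distributions: absences on [0, 1−s], presences on [s, 1], so class means
differ exactly by the separation s and supports become disjoint (AUC = 1)
for s > 0.5; s = 0 gives exchangeable classes (AUC → 0.5).

What the fixtures do *not* emulate: spatial autocorrelation of model
residuals, multimodal or anisotropically skewed niches, coastline masks, and
latitude-dependent cell areas. Passing recovery tests therefore demonstrates
correctness of the index computations, not SDM realism.

Growing-season aridity, part of the predictor protocol, is
ln(Σ PET / Σ precip) over months with mean temperature strictly above 0 °C
(months at exactly 0 °C excluded, per the strict inequality in its
definition); PET is an input, no PET model is implemented.

## Chart geometry

The future circle is drawn with *area* proportional to c(F_f)/c(F_p)
(radius = √ratio): a radius-proportional literal reading would contradict
representing I as an area difference, but it remains available as
`radius_mode="radius"`. The sector sweeps clockwise from 12 o'clock with
area fraction exactly O. Arrow lengths follow 1 + log₁₀(d/unit) with unit
1° horizontal and 100 m vertical — the two anchor points (1 unit at one
unit-distance, 2 units at ten) fix the transform; movements at or below a
tenth of a unit get length 0 and are omitted rather than drawn as dots,
since sub-unit behaviour is otherwise unconstrained. SVG output is
byte-deterministic (fixed hash salt, no date metadata).

## I/O and numerical edge cases

ESRI ASCII is the first-class raster dialect; GeoTIFF is read/written via
tifffile using ModelPixelScale/ModelTiepoint/GDAL_NODATA tags. No CRS
handling: geographic degrees are assumed and a warning logged, because the
degree/meter units contract depends on it. Degenerate inputs raise typed
errors rather than returning NaN: zero-cardinality ranges
(DegenerateRangeError), zero-variance t samples, single-class AUC samples,
misaligned grids (AlignmentError naming the first differing field; origins
and cell size compared within 1e-9°).

## Known limitations

Indices are in angular degrees, so east–west displacements at different
latitudes are not directly comparable in kilometers (by design — the units
contract); no reprojection or resampling (grids must arrive aligned); no
threshold-based binary indices; the statistics treat species as independent
replicates, ignoring phylogenetic and spatial non-independence.
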