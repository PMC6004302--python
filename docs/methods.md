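# Methods

`paleozone` implements the statistical workflow used to reconstruct the
hydroecological history of a contaminated lake from a sediment core of
Arcellinida (testate amoeba) assemblages: count screening, diversity and
stress indices, geochemical covariate screening, stratigraphically
constrained zonation, permutation inference, ordination, and age–depth
modelling.  This note records the models, the defaults and why they are
set as they are, and the package's known limitations.

## Data model and depth convention

A core sliced at 1 cm yields samples indexed 1…n from the sediment–water
interface down; sample *i* spans the interval (i−1, i] cm and its nominal
depth is *i*.  Assemblage tables are samples × taxa, either integer counts
with per-sample totals N_i or relative abundances whose rows must sum to
1 ± 0.05 (published tables round to 2 decimals; rows are renormalized to
exactly 1 after validation).  A taxon registry assigns every taxon a
functional group — *centropyxid* (stress-tolerant generalists),
*difflugiid* (contamination-sensitive), or *other* — plus a flag saying
whether it enters the stress ratio.  Geochemical concentrations are
stored in ppm (1% = 10⁴ ppm); cells written `<x` or `>x` keep the
detection limit x with a below/above flag, blanks are missing.
Loss-on-ignition (LOI) fractions partition dry mass into organics,
carbonates and minerogenics (closure enforced at ±0.02), with water
content carried separately.

## Count screening

Two screens precede multivariate work:

* **Sample screen.** A sample is retained when its total count T_i
  exceeds the probable error pe = 1.96·s/√T_i, where s is the standard
  deviation (ddof = 1) of the per-sample totals, and meets the minimum
  count (default 150 specimens — the conventional Arcellinida counting
  target).  The formula as printed in the source literature is
  dimensionally ambiguous (it names the fractional abundance inside the
  square root but compares the result to a total count); the default
  substitutes the sample total, the literal reading (sample's fractional
  share of all specimens) sits behind `interpretation="literal"`.
* **Taxon screen.** A taxon is retained when, in at least one sample, its
  binomial standard error S_X = 1.96·√(X(1−X)/N) is smaller than its
  fractional abundance X.  Retention is dataset-level: a taxon
  significant anywhere is kept everywhere.  Note the hard floor this
  implies: at N = 150 a taxon needs X ≳ 0.025 somewhere to qualify, so
  2-decimal published tables (where rare taxa print as 0.00–0.01) cannot
  attest rare-taxon significance — recomputations from rounded tables
  will legitimately retain fewer taxa than the original count data did.

## Indices

The Shannon Diversity Index, SDI = −Σ p_i ln p_i (nats), is computed on
renormalized proportions and banded by the convention used in lake
bio-monitoring: **stable** [2.5, 3.5], **in transition** [1.5, 2.5),
**stressed** < 1.5; the 2.5 boundary belongs to the stable band.

The difflugiid/centropyxid stress ratio is D/(D+C): D sums difflugiid
taxa flagged for the ratio, C sums centropyxids; values below 0.55 flag a
stressed, centropyxid-dominated assemblage.  *Cucurbitella tricuspis* is
excluded from D although it is difflugiid-lineage: it is a planktic
eutrophication indicator, not a benthic health signal, and a brute-force
comparison of candidate definitions against the published per-sample
ratio row shows the exclusion definition is the only one consistent with
it (e.g., it reproduces sample 7 = 0.20 exactly; including C. tricuspis
is several times worse in mean absolute deviation).  *Arcella vulgaris*
(group *other*) is excluded from both sums; at its near-zero abundance
the printed data cannot distinguish that choice from including it in C.
The registry flags make all of this overridable.

## Geochemical screening

Fixed order, each step audited: (1) drop any element with more than 25%
of its values missing or censored, substituting DL/2 for surviving
below-limit cells and the DL for above-limit cells (standard halved-limit
practice); (2) normalize each element by same-depth aluminum — a
stratigraphically immobile proxy for the detrital fraction — removing Al
itself from the covariate set; (3) reduce redundancy by a second-stage
resemblance comparison: per-element Euclidean distance matrices are
correlated pairwise (Spearman, off-diagonal entries), and within any pair
above ρ = 0.95 the element whose distance structure correlates more
weakly with the biotic resemblance is dropped (ties: more censored
entries lose, then the alphabetically later name).  The 0.95 threshold
and the tie-break are package choices — the original workflow names only
"highly correlated" — and are configurable.  Element:S and element:Mn
ratio series are provided to flag redox-driven remobilization; a zero
tracer leaves an undefined (NaN) entry rather than dropping the depth.

## Resemblance

Biotic resemblance is Bray–Curtis dissimilarity,
d_jk = Σ|x_jt − x_kt| / Σ(x_jt + x_kt), conventionally on square-root
transformed abundances — the transform tempers dominant taxa.  Because
skipping the transform silently is a classic mistake, `bray_curtis`
refuses untransformed input unless told `expect_transformed=False`.
Environmental profiles use Euclidean distance.  Similarity and
dissimilarity interconvert by s = 1 − d for bounded coefficients only.

**Transform sensitivity on rounded tables.**  With full-precision counts
the sqrt transform is benign, but on a 2-decimal published table it
amplifies quantization noise: √x has infinite slope at 0, so taxa
printed as 0.00 versus 0.01 (a rounding artifact) produce large spurious
contrasts.  On the packaged core this is measurable: the sqrt matrix
reproduces the published ANOSIM R (0.829 vs 0.832) but shifts one
zonation boundary by one sample and attenuates the RELATE correlation
with minerogenics (0.220 vs the published 0.317), whereas the
untransformed matrix reproduces the published zonation (zones 1–6 /
7–16 / 17–30, broken-stick k = 3) exactly.  The pipeline therefore
defaults to the sqrt matrix for ANOSIM/RELATE/NMDS (the stated original
choice) and the untransformed matrix for zonation, and records both
choices in every report.

## Zonation (CONISS + broken stick)

CONISS is agglomerative clustering in which only stratigraphically
adjacent clusters may merge; the fusion criterion is the incremental
increase in within-zone dispersion, computed from the pairwise
dissimilarities as Σ_{i<j∈c} d_ij/|c| — identical to Grimm's
within-cluster sum of squares when d is squared Euclidean, and the usual
generalization for Bray–Curtis input.  Ties merge the shallowest
eligible pair.  Dendrogram heights are reported as cumulative dispersion
(monotone, the "total sum of squares" axis of stratigraphic software).

Zone count: the dispersion reduction of the split into k zones is
compared with the broken-stick expectation Σ_{i=k}^{n}(1/i)/n; scanning
k = 2, 3, …, the chosen count is the largest k whose splits 2…k all beat
expectation, so structureless data yield k = 1.  (Reading "largest k
anywhere" would mis-select on noise, whose late tiny merges beat the
vanishing broken-stick tail.)  Cutting the tree yields contiguous zones
labelled 1 from the core bottom (deepest = oldest = zone 1).

## Inference

All tests are rank-based with average ties and seeded permutation nulls;
p = (1 + #{perm ≥ obs}) / (1 + n_perm) (add-one correction, so p > 0 and
the tests are slightly conservative).  Default n_perm = 999.

* **ANOSIM** (one-way): R = (r̄_between − r̄_within)/(M/2) over the
  M = n(n−1)/2 ranked dissimilarities; null by random relabeling.  R is
  invariant under monotone transforms of the dissimilarities.  An exact
  enumeration path exists for small n.
* **RELATE** (Mantel-type): Spearman ρ between the matched off-diagonal
  entries of two matrices, both converted to dissimilarity form first so
  positive ρ means agreement; null by jointly permuting rows/columns of
  one matrix.
* **Profile correlation**: Spearman ρ of two depth-aligned series with
  the analytic t-approximation p, plus an optional permutation p.

## Ordination (NMDS)

Kruskal-style NMDS: per iteration, disparities are fitted by
pool-adjacent-violators isotonic regression of configuration distances
on the dissimilarity order (ties handled by the primary/weak approach —
tied dissimilarities are pre-sorted by current distance, so no order is
enforced within a tie block), then the configuration is updated by the
Guttman majorization transform.  Fit is Kruskal stress-1,
√(Σ(d−d̂)²/Σd²).  Defaults: m = 2 axes, 50 starts (start 0 is classical
Torgerson scaling, the rest random), tol = 10⁻⁶, max 500 iterations.
The best configuration is centered and rotated to principal axes.  Taxon
scores, when requested, are abundance-weighted averages of sample
coordinates (taxa never observed get NaN).

## Chronology

Age–depth models interpolate linearly between dated tie points within
each continuous segment; extrapolation is refused.  An unconformity
splits the core into segments; querying below a hiatus with no dated
floor returns an explicit sentinel carrying the qualitative age (for the
packaged core, ">7,000 BP") instead of a number — fabricating numeric
ages across a depositional gap is exactly the error the sentinel
prevents.  Sedimentation rates are Δdepth/Δyear between tie points.  The
packaged model uses the 21 tie points above the 17 cm unconformity;
radiocarbon dates from the reworked upper sediments are shipped as
annotation only (they are stratigraphically jumbled) and never enter the
model.

## Synthetic cores

The generator draws the structure the analysis assumes, so recovery can
be scored against known truth: three zones (default layout 1–6 / 7–16 /
17–30) with per-zone Dirichlet base compositions; counts
Dirichlet-multinomial (precision c = 50 — realistic overdispersion;
totals uniform in [150, 300]); an arsenic-like contaminant a(d) =
baseline + two Gaussian peaks (defaults at 8 and 15 cm, mimicking a
double-peaked contamination/remobilization profile); a logistic coupling
logit(centropyxid share) = β₀ + β₁·z(a(d)) with β₀ = −1.5, β₁ = 1.2
(z standardized within-profile, so the coupling is scale-free);
compositional LOI with organics trading against minerogenics along z(a);
companion elements (Fe tracking the contaminant, quiet Al/S/Mn, an Hg
echo) with ~10% lognormal noise; and a tie-point age table with a hiatus
at the lower zone boundary.  Identical seeds reproduce bundles
byte-for-byte through serialization.

Under the default configuration a 50-replicate recovery study finds the
3-zone solution and both boundaries (±1 sample) in ≥ 90% of replicates
(the pilot run scored 1.0 on both).  What the generator does *not*
emulate: taphonomic loss, counting error beyond multinomial sampling,
depth-smearing/bioturbation, redox-driven element migration, or
correlated noise across elements — so passing recovery tests demonstrate
the statistical machinery, not robustness to those real-data effects.

## Numerical choices and edge cases

Relative-abundance rows tolerate ±0.05 before renormalization; LOI
closure ±0.02.  Relative-mode inputs without totals assume N_i = 150 for
error formulas (recorded in the output notes).  s in the probable error
uses ddof = 1, with s = 0 for a single sample.  All-zero samples are
errors for diversity, renormalization and Bray–Curtis.  CSV output uses
17 significant digits and reading uses round-trip float parsing, making
write→read bit-exact.  Permutation streams derive from
`numpy.random.default_rng(seed)` and are fully determined by
(seed, n_perm).

## Limitations

* Published tables rounded to 2 decimals limit what can be recomputed
  from them: rare-taxon significance is unattestable, sqrt-transformed
  resemblance is distorted (see above), and per-sample stress ratios can
  deviate by up to ~0.07 from values computed on the original counts.
* The redundancy-reduction settings of the original proprietary
  workflow are unpublished; this implementation follows the published
  description of second-stage resemblance analysis with its own stated
  defaults.
* Broken-stick zone selection on *univariate* profiles is weakly
  calibrated (noise yields k > 1 about half the time); the method is
  intended for multivariate assemblage dissimilarities, where the null
  behaves correctly.
* Radiocarbon calibration, ²¹⁰Pb activity modelling (CRS/CIC) and any
  geochemical process modelling are out of scope; tabulated ages are
  consumed as data.
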