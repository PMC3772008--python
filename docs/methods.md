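# Methods

This note documents the models and procedures implemented in `mnox`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Activity assay and tabulation

The LBB assay reads oxidized manganese as absorbance at 620 nm.
`fit_calibration` fits the KMnO4 standard series by ordinary least squares
(absorbance = slope · concentration + intercept) and reports R²; a
through-origin variant is available because Beer–Lambert behavior implies a
zero intercept, but the default keeps the intercept as a blank-offset check.
The stoichiometric conversion is fixed: 1 µM MnO2 ↔ 0.4 µM KMnO4, linear
through the origin.

Activity categories are half-open intervals closed on the left — high
[50, ∞), medium [10, 50), low [1, 10), none [0, 1) µM MnO2.  The interval
convention at 10 and 1 µM is a package decision (the upper boundary is
explicitly inclusive at 50, and the same closed-left rule is applied
downward for consistency); it is the only categorization ambiguity in the
assay and only matters for measurements landing exactly on a boundary.
Contingency tables keep raw ratios internally; percentages are rounded to
one decimal only for presentation.

## In-silico ARDRA

Digestion treats the amplicon as a linear, single-stranded stand-in for the
double-stranded product: every occurrence of the recognition site (scanned
left to right, overlapping occurrences included) is cut at the enzyme's
offset; zero-length fragments are dropped; `N` never matches; fragment
lengths always sum to the sequence length.  Methylation sensitivity,
partial digestion and overhang chemistry are out of scope.

Grouping is two-stage: partition by HaeIII pattern, then re-partition each
cell by Sau3AI pattern.  Pattern equality defaults to exact multiset
equality (tolerance 0); a "gel mode" preset (5% relative length tolerance,
50 bp detection floor) emulates agarose resolution.  Because a nonzero
tolerance is not transitive, tolerant grouping uses its single-linkage
(connected-component) closure, which is well defined and independent of
input order.  Representatives are the lexicographically smallest isolate id
per group — a deterministic stand-in for the survey's unstated choice of
which isolate to sequence.

## DGGE band calling and diversity

Band calling from a densitometric trace proceeds as: moving-average
smoothing (default 5 samples); baseline subtraction by morphological
opening (top-hat: rolling minimum then rolling maximum, default 51
samples); peak detection at prominence ≥ 2% of the maximum corrected
intensity; then the 1% rule — candidates whose peak height is ≤ 1% of the
summed candidate peak heights are discarded.  The top-hat baseline was
chosen over a plain rolling minimum because the opening removes monotone
background trends exactly and, for bands narrower than the window, leaves
peak heights proportional to the true band intensities; a bare rolling
minimum instead produces a cusp under each band that can split a peak top
in two.  The baseline window must exceed the band width (roughly
6σ in samples) for heights to stay proportional.

Band weights are P_i = n_i / N over the retained bands.  Whether P_i is
computed before or after the 1% filter is a genuine ambiguity; the package
filters first and renormalizes (so ΣP_i = 1), with a switch to keep
pre-filter weights.  The Shannon index uses the natural logarithm (the
reported magnitudes of many-band lanes, e.g. H ≈ 2.7, are consistent with
nats); the log base is a parameter.

Lane comparison matches bands across lanes greedily by closest migration
position within a tolerance (default 0.01 of the normalized lane length),
each band used at most once.  With c matched bands, P = n_A + n_B − c union
bands, and the default distance is D = Σ|A_i − B_i| / P, where a band
absent from a lane contributes probability zero.  The exact algebraic form
of the original study's similarity function is not recoverable from its
text; this form uses every quantity the text defines (A_i, B_i, absent = 0,
P) and is a declared reconstruction.  It is registered behind a strategy
name, with a presence/absence alternative (Dice, 1 − 2c/(n_A+n_B))
available without touching callers.  D is symmetric, zero for identical
lanes, and bounded by 1 when each lane's probabilities sum to 1.

## Ordination

Classical (Torgerson) MDS double-centers the squared distance matrix and
takes coordinates from the top-k non-negative eigenpairs; negative
eigenvalue mass (non-Euclidean input) is reported via the full eigenvalue
vector, and axes beyond the positive rank are zero with a warning.

Non-metric MDS minimizes Kruskal stress-1,
sqrt(Σ(d_ij − d̂_ij)² / Σ d_ij²), alternating isotonic regression of
configuration distances on the input dissimilarities (primary/averaging tie
handling, via scikit-learn's PAVA implementation) with a Guttman transform
update.  It is initialized from the classical solution (a tiny seeded
jitter is used only when that start is degenerate), keeps the best
configuration seen — so the reported stress history is non-increasing — and
stops when the relative stress improvement falls below 1e−6 (default) or
after 300 iterations.  Axis orientation and scale are arbitrary: only
relative point distances are interpretable, and scales are not comparable
across ordinations.  Both flavors are provided; non-metric is the default
for community fingerprints, where only the rank order of pattern
similarities is trusted.

## Distances, phylotypes, trees

Pairwise sequence distances use pairwise deletion: a site enters a
comparison only when both sequences have a plain A/C/G/T.  The p-distance
is the mismatch fraction over comparable sites; the K2P distance is
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) with P and Q the transition and
transversion fractions.  Saturated pairs (log argument ≤ 0) are flagged NaN
rather than silently clamped; downstream consumers refuse NaN entries by
name.

Phylotypes are complete-linkage clusters of the p-distance matrix cut so
that every within-cluster pair is strictly below the threshold (default
3%) — complete linkage is the only linkage for which the "< 3% within a
phylotype" guarantee holds pairwise; single and average linkage are
available as options.  The "< 3%" criterion is read as uncorrected
p-distance, the standard convention for OTU-style grouping; K2P is
available as an option.

Neighbor joining follows Saitou–Nei: join the pair minimizing
Q_ij = (n−2) d_ij − Σ_k d_ik − Σ_k d_jk, ties broken by the lowest index
pair for determinism; branch lengths by the standard formulas, the final
three lineages resolved in closed form around an unrooted central node.
Negative branch lengths are retained by default (they are information about
non-additivity), with a clamp-to-zero option.

Bootstrap supports resample alignment columns with replacement
(deterministic given the seed), rebuild the NJ tree per replicate, and
score each internal branch of the full-data tree by the percentage of
successful replicates containing the same leaf bipartition.  Replicates
whose resampled distance matrix has undefined entries are skipped and
excluded from the denominator; the used/skipped counts are attached to the
returned tree.  Trivial (leaf) bipartitions carry no support.  The default
replicate count is 1000; tests use 10–100 replicates, which is sufficient
for the binary well-separated/unresolved distinctions they assert.

Newick serialization writes branch lengths to 6 decimals and supports as
internal node labels; parsing round-trips topology, labels, lengths and
supports.

## Synthetic data

The generator is the package's only data source and is deterministic in
(specification, seed):

* **Trees** — Yule topologies (uniform random leaf splitting) with i.i.d.
  exponential branch lengths, mean 0.1 substitutions/site by default.
* **Alignments** — K2P evolution with the closed-form per-branch transition
  probabilities (rates normalized so a branch of length t yields t expected
  substitutions per site); root sequence uniform; default kappa 2, a
  typical transition/transversion rate ratio for 16S data.  Closed-form
  stepping is exact, so no rate-discretization error enters parameter
  recovery.
* **Gel lanes** — intensity(x) = baseline + Σ h_j exp(−(x−p_j)²/2σ²) +
  Gaussian noise, clipped at zero.  Defaults: σ = 0.006 of the lane,
  baseline 0.05, noise SD 0.01 (signal heights ≈ 1), 2000 samples.  The
  stratified-soil preset draws each horizon's bands from a shared pool of
  24 well-separated positions with richness 20/12/8 for A/B/C — an
  illustrative encoding of the qualitative surface-to-depth diversity
  decline, not a claim about any particular gel.
* **Activity tables** — per-category concentrations drawn uniformly within
  each category's interval, with the high category bounded at 240 µM (the
  top of the survey's reported activity range), so tabulation reproduces
  the requested counts exactly and re-categorization is the identity.

What the generator does **not** emulate: PCR and primer bias, GC-clamp
melting behavior, co-migration of distinct taxa to one band, lane-to-lane
migration distortion, silver-stain response nonlinearity, indels (simulated
alignments are gapless), and rate heterogeneity across sites.  Passing
tests therefore demonstrate the correctness of the computations on clean,
model-conformant data; they do not show robustness to these real-data
artifacts, which enter upstream of this pipeline's inputs.

## Numerical conventions and limitations

* Detection thresholds (2% prominence, 1% relative height), the matching
  tolerance (0.01), smoothing (5) and baseline (51) windows are all
  keyword-configurable; the defaults assume lanes sampled at ≥ 1000 points
  with bands a few percent of the lane wide.
* Band calling on lanes whose band width approaches the baseline window
  underestimates peak heights nonuniformly; choose the window ≥ 3× the
  band's 6σ footprint.
* Classical MDS on strongly non-Euclidean distance matrices reports the
  negative eigenvalue mass but still returns the best rank-k Euclidean
  approximation.
* Greedy band matching is not globally optimal for pathological band
  layouts (dense bands at just-over-tolerance spacings); with the default
  tolerance, well-separated synthetic bands match exactly.
* Distance-matrix construction is O(n²) in sequences and the bootstrap is
  O(replicates · n³); both are comfortable at survey scale (tens of taxa).
* CLI exit codes follow click conventions (0 success, 2 usage error,
  1 other failure).
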