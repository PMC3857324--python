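# Methods

## Problem and model

`dcenkit` detects *differentially co-expressed* genes between two groups of
individuals (e.g. responders X vs nonresponders Y), where each individual is
observed as a short expression time series of m ≥ 3 points.  The central
design commitment is that correlation is computed **within each individual's
own time series** and only then combined across individuals.  Heterogeneity
in the speed or onset of the underlying biological process between
individuals therefore cannot wash the signal out, whereas approaches that
first average individuals into one group profile mix misaligned responses.

For individual i and genes g, h, the Pearson correlation r_ghi over the m
time-ordered values is converted to a two-sided significance via

    t = r √((m − 2) / (1 − r²)) ~ t(m − 2)   under no correlation,

and to a signed edge weight

    w_ghi = sgn(r_ghi) (1 − p_ghi).

This "signed complementary significance" lies in [−1, 1], is monotone in |r|
at fixed m, and makes the prefilter p < 0.05 coincide with |w| > 0.95, the
same cut used to draw edges in the switching-neighborhood view.  The weight
function is a pluggable strategy (`weight_fn`); the raw correlation w = r is
available as an alternative.

A gene pair is retained (a_gh = 1) when it is significantly correlated
*with a consistent sign* in enough individuals of at least one group:

    T_G = max(ceil(frac · n_G), min(min_count, n_G), 1),

with defaults p_cut = 0.05, frac = 0.25, min_count = 2.  Positive and
negative counts are tallied separately so mixed-sign evidence does not
accumulate.  The floor of 1 ensures the degenerate setting frac = 0,
min_count = 0 reduces to "significant in at least one individual" rather
than retaining every pair unconditionally.

Weights are averaged per group (w̄_X, w̄_Y, arithmetic means over the
group's individuals) and each gene is scored over its retained
neighborhood:

    d_g = Σ_h a_gh |w̄_X(g,h) − w̄_Y(g,h)| / Σ_h a_gh (|w̄_X(g,h)| + |w̄_Y(g,h)|),

with d_g = 0 when the denominator is zero.  The numerator is the *changed*
neighborhood, the denominator the *total* neighborhood; 0 ≤ d_g ≤ 1 by the
per-edge triangle inequality, d_g = 0 exactly for equal neighborhoods, and
d_g = 1 exactly when for every retained neighbor the weaker averaged weight
is zero or of opposite sign to the stronger one.  This denominator is the
unique natural normalizer for which both boundary facts hold; a max-based
denominator would break the upper bound of 1.

### Significance

The permutation unit is the whole individual: group labels are reassigned
over individuals (group sizes preserved), keeping every time series intact —
shuffling samples would destroy the within-individual correlation structure
that is the method's core object.  Per permutation the mask, averages and
scores are recomputed (the per-individual networks are label-invariant and
computed once).  The null scores of *all genes* over all permutations are
pooled, because 100 permutations per gene cannot resolve p < 0.01, and

    p(g) = (1 + #{null ≥ d_g}) / (1 + n_perm · n_genes)

with an add-one correction so p > 0 always.  Pooling assumes genes are
roughly exchangeable under the null; genes with atypical neighborhood sizes
borrow the common null.  Defaults: 100 permutations, explicit seed required.

### Baselines

Three deliberately simple analogs of the classical strategies are provided
for comparison, each yielding per-group association matrices s_X, s_Y and a
soft-thresholded differential-connectivity ranking
score(g) = Σ_h | |s_X|^β − |s_Y|^β | with β = 6 by default:

* **average** — point-wise mean time profile per group (requires a common
  time grid), then Pearson correlation of mean profiles;
* **concat** — individuals' series concatenated end-to-end per group,
  optionally after per-individual gene-wise centering (without centering,
  between-individual baseline offsets dominate the pooled correlation);
* **indcorr** — within-individual correlations averaged per group (raw r,
  not significance weights).

These are strategy analogs, not re-implementations of any particular
package; β is exposed because no canonical value exists for this use.

## Synthetic cohorts

The generator emulates two-group time-course studies after a non-specific
variance filter.  Defaults: 300 genes, three 80-gene modules (trajectories:
sigmoid, pulse, down-up-down, each standardised to mean 0 / sd 1 on the
nominal window), 60 unstructured genes, 6 individuals per group, m = 8
points on a common nominal grid t ∈ [0,1], observation noise sd 0.3.

Heterogeneity has two layers:

* **Timing warp** — individual i evaluates trajectories at
  u = speed_i·t + offset_i with log-speed sd 0.3 and offset sd 0.15
  (speeds typically within ±35%, onsets within ±15% of the window).
* **Response amplitude** — gene g in individual i responds with amplitude
  exp(N(0, amplitude_sd)), default sd 0.6.  Scaling a series leaves its
  within-individual Pearson correlations untouched, so this layer is
  invisible to the per-individual networks; but it makes each gene's
  group-mean profile a differently weighted average of the individual
  curves, which is precisely what corrupts average-profile approaches on
  heterogeneous cohorts.

The amplitude layer exists because the timing warp alone cannot produce
that corruption: with gene-identical module responses and shared
per-individual warps, two same-module genes have *identical* group-mean
profiles up to loading and √n-attenuated noise, so their average-profile
correlation stays near 1 at any warp strength.  Amplitude heterogeneity is
also biologically grounded — cohorts routinely mix strong and weak
responders.

Planted ground truth: 20 *decoupled* genes follow their module in group X
but lose their temporal program in group Y (`decouple_mode="independent"`,
independent noise — the unambiguous zero-co-expression positive set); the
`"rewired"` mode instead moves them to the next module's trajectory.  An
optional *switch* gene follows module A in X and module B in Y.  Everything
is reproducible from a single seed.

What the generator does **not** emulate: probe-level artifacts,
count-based noise, autocorrelated measurement error, missing values, and
gene-specific response shapes within a module.  Passing tests therefore
demonstrate the method's behaviour under idealised module structure with
timing and amplitude heterogeneity, not performance on any particular
platform's data.

## Evaluation harnesses

*Reproducibility*: per repetition, 2n individuals per group are drawn
without replacement and split into two disjoint sub-cohorts of n, each is
ranked, and the relative top-k overlap |top-k ∩ top-k|/k recorded; disjoint
halves are used because overlapping draws would inflate reproducibility.
Individuals are redrawn independently each repetition.  *Enrichment*: the
mean of an external per-gene property over the top-k list is compared to
its null under 10000 random permutations of the property values over gene
labels, one-sided (greater), add-one corrected.

## Numerical choices and degenerate inputs

* Constant within-individual series: r := 0, p := 1, w := 0 (no NaN
  propagation); genes constant in the group-mean profile likewise get zero
  association in the average baseline.
* |r| = 1 maps to p = 0 (limit convention).
* All rankings break score ties lexicographically on gene id; duplicate
  probes tie-break to the lexicographically smallest probe id; "overall
  intensity" and "overall variance" use all samples pooled, population
  variance (denominator n).
* Group labels: any two distinct strings; the lexicographically smaller one
  plays the role of X.  The score is symmetric in the groups, so this only
  affects labeling of outputs.
* Missing values are a hard error; silent imputation would distort
  correlations.
* Time values are used only to order samples within an individual (Pearson
  correlation ignores spacing) and as the generator's nominal grid.

## Known limitations

* With small groups the consistency threshold bottoms out at two
  individuals, so a few percent of null gene pairs are retained by chance.
  Genes whose retained neighborhood consists only of such spurious edges
  form a background score pool around d ≈ 1/√2 ≈ 0.71 (the expected ratio
  E|a−b| / (E|a|+E|b|) for independent symmetric averaged weights), with a
  tail reaching d = 1 for genes with one or two retained edges.  At n = 6
  per group this caps top-list precision; with larger groups (T_G ≥ 4–5)
  the spurious pool is negligible.  Interpreting raw d rankings for small
  cohorts should lean on the permutation p-values and on neighborhood
  sizes, both exposed in the results object.
* The t-based correlation significance assumes exchangeable observations;
  strongly autocorrelated series inflate |r| at small m and hence |w|.
* The pooled permutation null trades per-gene resolution for depth; a
  per-gene null would need orders of magnitude more permutations.
* Module sizes used in the default tests and demonstrations (cohorts of
  300–2000 genes, 6 individuals per group, m = 8) are desk-scale choices;
  all of them are parameters of the public API.
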