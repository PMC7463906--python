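# Methods

This note documents the models, estimators and design choices behind
`genophen`, and what the synthetic study conditions do and do not show
about real data.

## Genetic distances and trees

Pairwise distances are closed-form estimators on aligned loci:
p-distance, JC69 (−¾ ln(1 − 4p/3)), K80 (separate transition P and
transversion Q proportions) and TN93 (purine and pyrimidine transitions
separated, empirical base frequencies). TN93 is the default recommendation
when composite-likelihood-style assumptions (unequal transition rates,
equal rates among sites and lineages) are wanted in a pairwise
estimator; K80 is the package default because it is the default of the
standard R tool for the same task. Gap/ambiguity handling defaults to
complete deletion (every column containing `-` or `N` dropped),
matching that tool; pairwise deletion is a flag. Saturation (a
non-positive logarithm argument) raises an error naming the offending
pair rather than returning NaN.

Neighbor joining follows Saitou & Nei with the canonical Q-criterion.
Ties break to the lowest (row, column) pair of the current step, making
the output deterministic. Negative branch lengths are kept, not
clamped: this preserves exactness on additive inputs (the path-length
matrix of the output reproduces the input to 1e−9, which the test suite
checks on 200 random tree-generated matrices). Bootstrap support
resamples alignment columns with replacement, rebuilds the tree per
replicate, and reports for each internal edge of the full-data tree the
percentage of successful replicates containing the same bipartition;
replicates whose distances fail are skipped, counted and logged.

## FTIR preprocessing

* **Quality test**: SNR = (max − min of the full spectrum) / RMS of the
  residuals after a linear detrend of the 2100–1900 cm⁻¹ window;
  pass requires SNR > 4000. This is a documented surrogate for the
  instrument vendor's proprietary quality test; a perfectly flat window
  yields the +inf sentinel (pass), a constant spectrum yields 0 (fail).
* **Rubberband baseline**: the lower convex hull of the spectrum
  (computed by a QhullError-tolerant convex-hull call; exactly
  collinear spectra fall back to the end-point segment), evaluated at
  64 equally spaced support abscissae and linearly interpolated back to
  the full axis. The 64-point grid mirrors the named instrument
  routine's parameter. A pure line corrects to zero exactly; a convex
  bowl corrects to zero up to chordal interpolation error of the
  support grid.
* **Vector normalization**: subtract the spectrum mean, scale to unit
  sum of squares. Batch preprocessing passes exactly-constant corrected
  spectra through centered (they carry no information to normalize).
* Atmospheric CO₂/H₂O compensation is replaced by an optional
  mask-intervals operation; the compensation algorithm itself is
  instrument-specific and the synthetic data need none.
* Window map: W1 = (3200, 2800], W2 = (1800, 1500], W3 = (1500, 1200],
  W4 = (1200, 900] cm⁻¹, half-open so adjacent windows tile the axis;
  fully configurable. Whole-spectrum preprocessing happens before
  window extraction.

## Metabolomics chain

IQR filter (zero-IQR metabolites always removed; then the lowest-IQR
metabolites until ⌊p·drop_fraction⌋ are gone, default fraction 0.1 —
an explicit knob in place of tool-version-dependent filter schedules),
per-sample median normalization, Pareto scaling (center, divide by
√SD; sample SD, ddof = 1). PLS-DA is PLS2 via NIPALS on the centered
one-hot class matrix; VIP for metabolite j is

VIP_j = √( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a ),

with SSY_a = (tᵀt)(qᵀq) the Y-variance explained by component a. The
mean of squared VIPs equals 1 by construction (the test suite asserts
it to 1e−9 on every fit), which is what gives the greater-than-one
selection rule its meaning. Component count defaults to 2; degenerate
deflation stops early with the achieved components, logged.
Hierarchical clustering uses Ward on Euclidean row distances
(ward.D2-consistent heights) or on 1 − Spearman correlation, with the
caveat that Ward formally assumes Euclidean geometry.

**Whole-profile LC-MS distances** are computed on strain-mean log2
profiles (after IQR filter and median normalization, log2-transformed
and per-sample centered). Euclidean distance on Pareto-scaled raw
intensities is dominated by the few highest-intensity metabolites —
in simulation that caps the fidelity of the metabolome distance matrix
to its generating structure at r ≈ 0.92 no matter how strong the
biological signal — whereas the log scale weights relative changes
evenly; heatmap practice in this field is log2-scale for the same
reason. The Pareto-scaled chain is still what feeds VIP selection and
clustering, where per-variable reweighting is the point.

## Distance correlation, PSW, trend classes

Matrix correlation is the Pearson r of the lower triangles of two
label-aligned distance matrices. The permutation p permutes rows and
columns of the second matrix jointly; when n! fits the permutation
budget the enumeration is exhaustive (all 24 relabelings for 4
strains), otherwise n_perm draws with the add-one correction. The
parametric t p-value is also reported for parity with generic
correlation tests but is anti-conservative for distances and should not
be preferred.

The descriptor scan treats each wavelength (or metabolite) separately:
replicate-averaged strain values x give strain distances |x_i − x_j|,
correlated with the marker's matrix. Constant descriptors are recorded
with r = 0 and kept in the denominator so PSW remains comparable across
conditions. PSW is the percentage of descriptors with r strictly above
0.75. A trajectory across doses is non-monotonous when its maximum
exceeds both end values (a plateau reaching a boundary is monotone);
monotone trajectories are high when the peak reaches 5% (midway between
the empirically observed low-response and high-response ranges) and low
otherwise. The region table reports, per marker × window × group
(control vs pooled stressed), the maximum scan r.

**Small-sample caveat**: with 4 strains there are only 6 distance
pairs, and a pure-noise descriptor clears the 0.75 filter about 5–7%
of the time regardless of the noise level (the statistic is
scale-free). PSW values from a 4-strain design therefore carry a noise
floor of a few points, and per-descriptor significance is not
interpretable without that context. The recoverability experiments in
the test suite use an 8-strain panel (28 pairs, false-positive rate
≈ 0.1%) so that planted fractions are read off cleanly; the default
4-strain scenario mirrors the real study design and its PSW tables
should be read with the noise floor in mind.

**Closure effect**: vector normalization couples wavelengths through
the per-sample norm, so a strain difference concentrated at a few
wavelengths leaks a small rank-one component into all of them. With a
realistic shared band structure dominating the norm the leak is ≤ ~6%
of the planted signal and ordinary noise drowns it; in noise-free
constructions it is visible, which is why constructed tests include
noise.

## Synthetic study conditions

The generator emulates the study design: 4 strains on a fixed rooted
tree (cerevisiae/paradoxus sisters; bayanus-like deep branch), 4
ethanol doses (0/8/12/16 % v/v), 3 replicates, 12 simulated loci named
and rate-scaled like the real panel (ribosomal slow, mitochondrial
fast) plus the ITS_LSU concatenation formed downstream, 89 annotated
metabolites, and viable counts whose default mortality profile follows
the published strain-specific tolerance pattern (sensitive
*S. bayanus*, tolerant *S. paradoxus*/*S. cerevisiae*/*S. pastorianus*).

* **Sequences** evolve site-independently under JC69 with per-locus
  rate multipliers and, by default, lognormal per-branch rate factors
  (σ = 0.7, mean 1). The branch-rate heterogeneity is what makes the
  thirteen markers genuinely different predictors: with a single shared
  tree and scalar rates all realized distance matrices are nearly
  collinear and the marker-ranking question degenerates.
* **Spectra** are a fixed shared band structure (OH/NH, CH stretches,
  amide I/II, fingerprint bands — the dominant norm contribution that
  keeps vector normalization anchored on shared biomass), a smooth
  random degree-≤3 polynomial baseline (convex-hull-removable), planted
  signals and i.i.d. Gaussian noise. A planted signal adds, at a fixed
  subset of wavelengths inside one window, amplitude[condition] times a
  per-strain score: the leading classical-MDS axis of the source
  locus' p-distance matrix, scaled to unit range, so |score_i −
  score_j| tracks genetic distance. The scan is univariate, hence the
  1-D score.
* **Feature tables** are log-normal (baseline log-intensity
  N(12, 0.8²)). Half the metabolites are affected: each responds to one
  axis of the source locus' full classical-MDS embedding, axes covered
  in a balanced way with fixed effect magnitude (0.5 log units at the
  unit-range embedding scale) and random sign, so between-strain
  log-profile distances reproduce the locus' distance matrix up to
  noise — the recoverable plant the analysis is meant to find. Shifts
  are amplified with dose (factor 1 + dose/max dose) and replicate
  noise is multiplicative lognormal with σ = 0.03 (≈ 3% CV, good
  technical LC-MS precision).
* **Viability** is Cv ~ Poisson(Ct·(1 − M/100)) with Ct = 10⁶ and M = 0
  at the control dose.

Determinism: every generator draws from its own substream of the
scenario seed, so any piece can be regenerated independently and a
fixed seed reproduces every file byte for byte.

What passing tests show — and what they do not: the planted-recovery
results demonstrate that the pipeline finds genotype–metabolome
structure when it exists and ranks the generating locus first (≥95% of
seeds under the default conditions), and that PSW reads planted
spectral fractions correctly on an adequately sized strain panel. Real
spectra have instrument drift, atmospheric residuals, scattering
artifacts and biology that is not a function of any single locus; none
of these are emulated, so passing tests validate the machinery, not the
biological claim.

## Problem sizes

The simulation-heavy checks run at sizes chosen to keep the full suite
in the tens of seconds on one core: loci of 400–2000 sites, bootstrap
with 20–200 replicates in tests (1000 in the pipeline default), 50–100
seeds for statistical recovery rates, 200 random additive matrices for
the NJ oracle. All sizes are configuration, not constants.

## Known limitations

* The composite-likelihood distance of the original tree figure is
  approximated by TN93; the two agree in assumptions but not
  numerically.
* The parametric p-value for matrix correlations is anti-conservative;
  permutation is the default and exhaustive only for small n.
* Ward-on-Spearman clustering is a heuristic (non-Euclidean input).
* Pathway enrichment, raw LC-MS feature extraction/annotation, genome
  marker extraction and alignment computation are out of scope; the
  pipeline starts at aligned FASTA and annotated feature tables.
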