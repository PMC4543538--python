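# Methods

## Scope

`tfactivity` implements the computational arm of a two-color microarray
time-course study design: per-sample quality control, channel-ratio
computation and LOWESS normalization, per-time differential-expression
calling, network-constrained inference of transcription-factor (TF)
activity profiles with uncertainty, and a cross-condition comparison of
those profiles. A synthetic-data module generates the study design end
to end, so every downstream stage can be validated against known ground
truth without external data.

## The generative / inference model

Each gene's log2 expression ratio (treated vs. untreated control) is
modelled as a weighted linear combination of the activity changes of the
TFs that regulate it:

    x[g,t,r] = m_g + Σ_f X[g,f] · b[g,f] · c[f,t] + ε,   ε ~ N(0, s²)

- `X[g,f]` — known binary connectivity (the wiring diagram); it is an
  input, never learned.
- `b[g,f]` — regulatory strength, nonzero only on network edges, sign
  free (activation/repression).
- `c[f,t]` — latent activity change of TF `f` at time `t`; the
  pre-treatment sample defines the reference, so true activities satisfy
  `c[f,0] = 0`.
- `m_g` — per-gene intercept (see *Baseline handling*).
- Replicates are repeated observations of the same gene/time mean
  (switchable to averaging).

The log-linear form trades transcription kinetics for tractability:
inference is linear-Gaussian in each factor conditional on the other.
There is deliberately no temporal smoothness prior linking adjacent time
points, no network-structure learning, and no nonlinear transfer
function.

### Variational EM

Posterior inference is mean-field variational Bayes over the bilinear
pair with zero-mean Gaussian priors (`b ~ N(0, τ_b)` per edge,
`c ~ N(0, τ_c)` per TF/time, `m ~ N(0, τ_m)` per gene) and a point
(EM-style) update of the noise variance `s²`:

- `q(c_t)`: one full Gaussian per time point over all TFs, closed form
  given the weight moments;
- `q(b_g)`: one full Gaussian per gene over its regulators, closed form
  given the activity moments;
- `q(m_g)`: scalar Gaussian;
- `s²`: expected residual mean square.

Every sweep is exact coordinate ascent on the evidence lower bound, so
the objective trace is non-decreasing; the trace is stored on the
results object and asserted in tests. Convergence is declared on a
relative ELBO change below `convergence_tolerance` (default 1e-6;
typical fits at bench scale converge in 500–1500 sweeps, well under
two seconds at 200 genes × 10 TFs).

Weights are initialized at the annotated interaction sign (±1) where
available, else at small seeded random values; activities start at
zero. Degenerate inputs: genes absent from the network (or with no
regulator) are dropped with a warning; an empty gene-network
intersection is an error; missing expression cells simply drop out of
the sufficient statistics; non-convergence returns a flagged result,
never an exception.

### Two gauges of the bilinear model

The likelihood is invariant under, per TF, (i) rescaling
`b → b/α, c → α·c` and (ii) joint negation `b → −b, c → −c`.

- *Scale* is fixed once after fitting by rescaling each TF column to
  unit root-mean-square weight (activities and their sds rescaled
  inversely). Doing this inside the sweep would break ELBO
  monotonicity, so it is an extraction-time convention.
- *Sign* cannot be fixed from expression data at all. It is resolved
  afterwards by majority vote of inferred weight signs against annotated
  edge signs (`sign_ambiguity_report`), and `flip()` negates a profile
  together with its weight column — a pure relabelling that leaves the
  fit unchanged, which is also why the comparison statistic uses the
  *absolute* Pearson correlation.

### Baseline handling

By default each gene's series is centred on its replicate-mean value at
the reference time *and* a per-gene intercept is estimated inside the
model. Centring alone leaves a residual offset — the sampling noise of
the reference-time mean plus any true baseline — that is constant in
time and correlated across all of a gene's observations. That offset is
the dominant model violation at this design size: without the
intercept it leaks into the activity profiles of silent TFs as smooth
spurious drift several times larger than their error bars, and the
downstream discard test then retains essentially everything. Both
behaviours are switchable (`center_baseline`, `intercept`).

### Error bars

The "error bars" used everywhere downstream are posterior standard
deviations of `c[f,t]`. The factorized posterior conditions each
activity on the weight moments and therefore understates marginal
uncertainty — in particular it cannot see the nearly flat directions of
the bilinear likelihood, along which a silent TF's profile is
constrained only by its prior. The reported sds therefore come from a
Laplace step at the variational solution: the joint curvature of the
negative log posterior over (weights, intercepts, activities) is
assembled, each gene's (weight, intercept) block is eliminated by a
Schur complement onto the activity block (exact Gaussian
marginalization), and marginal variances are read off the inverse of
the reduced matrix. Variances are clipped between the conditional
(mean-field) value and the prior variance for numerical safety. With
weights held fixed, the conditional posterior is exact and is used
directly — this is the configuration checked against brute-force
Bayesian linear regression in the tests.

With this construction, on data simulated with all activities zero,
100% of TF profiles in the packaged fixtures admit a constant within ±2
sds (the discard rule below), while responsive TFs at peak activity 2
and noise sd 0.2 are recovered with |Pearson| ≥ 0.8 in ≥ 80% of cases.

## Preprocessing

- **QC**: cDNA yield = A260 × 330 ng/µl × elution volume (default
  50 µl); specific activity = dye (pmol/µl) / cDNA (ng/µl) × 1000. A
  sample is suitable when yield > 825 ng *and* specific activity >
  8 pmol/µg, strict inequalities.
- **Ratios**: M = log2(experimental/control), oriented by the recorded
  dye of the experimental sample so dye-swap replicates agree in sign;
  A = ½·log2(Cy3·Cy5). Log base 2 because the fold-change cut-off is
  stated as 2-fold.
- **LOWESS**: one locally weighted regression of M on A per array
  (span 0.3, 3 robustness iterations — conventional for expression
  arrays), subtracted from M. "Global" is read as one fit per array
  across all features (no print-tip structure is modelled); a pooled
  all-array fit is not offered. Arrays with fewer than 20 features fall
  back to median-centering with a warning. Note that local-linear
  smoothing is not a projection: a second application can still move
  decile means by ~1e-2 (the smoother's own bias residue), which the
  tests bound explicitly.
- **Assembly**: gene × time × replicate tensor; missing cells stay
  missing (never imputed), duplicates are an error, genes missing in
  more than one replicate at a time point are flagged.

## Differential expression

Per (gene, time): replicate mean, signed fold change (2^m up, −2^(−m)
down), and a one-sample two-sided t-test of the replicate log2 ratios
against zero (each hybridization is already treated-vs-control, so the
one-sample form is the default; exact p from the t distribution with
n−1 df). A call requires |mean log2| ≥ log2(fold cut-off) (default
2-fold) *and* p < α (default 0.05); no multiplicity correction gates the
call, matching common practice for this design, but a Benjamini–Hochberg
column is emitted for transparency. Zero-variance policies: replicates
all equal to zero give p = 1; all equal and nonzero are perfectly
reproducible and flagged significant by policy with a sentinel p = 0;
fewer than two replicates is "untestable", never significant. Testing is
per time point (fold-change tables are per-time).

## Profile comparison

For each TF and condition, the profile is **discarded** when some
constant k fits within the error bars at every time:
max_t(m_t − z·σ_t) ≤ min_t(m_t + z·σ_t) — exact interval intersection,
no search. z defaults to 2 (≈95% band on 1-sd bars; z = 1 gives literal
±1 sd bars). A constant (including all-zero) profile is always
discarded.

Across two conditions: both discarded → unresponsive, no score; exactly
one retained → placeholder score **2** (a sentinel outside [0, 1],
excluded from any averaging); both retained → |Pearson r| between the
mean profiles. The reference time point, fixed at zero by convention in
both runs, is excluded from r by default (it inflates correlation);
`include_reference_time=True` restores it. The discard test always sees
the full profile. A retained profile with zero variance over the scored
points (possible only through the reference-time exclusion) gets an
undefined score and is reported as anomalous. Ranking partitions scores
at configurable thresholds (0.8 concordant / 0.3 discordant), ordering
within partitions by score then TF id.

## Synthetic data

The generator emulates the study design: 6 time points (0, 10, 20, 40,
60, 120 min), two biological × two dye-swap replicates per condition,
sparse signed networks, and two-channel intensities.

- **Network**: per-gene regulator count ~ Poisson(mean, default 2)
  clipped to [1, n_tfs]; regulators uniform without replacement; a
  fraction of edges (default 0.5) carries a random ±1 sign.
- **Activities**: exactly `round(frac_responsive · n_tfs)` TFs respond;
  each trajectory is a saturating rise `1 − exp(−t/τ)` or a transient
  pulse `(t/τ)·exp(1 − t/τ)` with τ ~ U(10, 60) min, scaled to peak
  magnitude `amplitude` (default 2 on the log2 scale) with random sign —
  smooth shapes typical of transient stress responses over 0–120 min,
  chosen so recovery is well-posed.
- **Weights**: magnitude U(0.5, 1.5); sign follows the annotation where
  present, else random.
- **Expression**: the model above with baseline sd 0.1 (small residual
  offsets of ratio data at the reference time) and noise sd 0.2 by
  default.
- **Two-color rendering**: per-gene abundance A ~ U(7, 14) log2 units
  with per-array jitter (sd 0.25); dye-scale ratio log2(Cy5/Cy3) =
  o·x + d(A) with o = ±1 per dye orientation and a logistic
  low-intensity inflation d(A) = amplitude · σ((9 − A)/1) — the bias
  sticks to the dyes, which is what dye-swapping cancels and LOWESS
  removes. Channels are floor-clipped at 1.0; knowing the amplitude the
  construction inverts exactly (`remove_known_bias`), which the
  conservation tests use.
- **Seeds**: every stage takes an explicit seed; a run seed derives
  per-stage seeds by fixed offsets, so a dataset is bit-reproducible.
- The control channel is a fixed pre-treatment reference (not a
  time-matched untreated culture); this is a stated config choice of the
  generator, not something the data model enforces.

What the generator does **not** emulate: spot-level image artefacts,
print-tip or spatial structure, correlated (non-Gaussian) noise,
cross-hybridization, or network misspecification (the inference network
is the generating network). Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical assumptions,
not robustness to violations real arrays may show.

## Problem sizes used in the tests

- Parameter-recovery and null-calibration fixtures: 10 TFs × 200 genes,
  6 × 4 design, noise sd 0.2, amplitude 2 — small enough for seconds-long
  fits while leaving ~40 target genes per TF.
- Normalization fixtures: 4000 genes × 40 TFs per array — LOWESS
  accuracy depends on the feature count (it absorbs the local mean of
  true signal, a 1/√(span·n) effect), so this stage is exercised at the
  genome-like scale the design emulates; at a few hundred features the
  decile-mean bands widen to ~0.12.
- Differential-expression calibration: 1000 genes × 6 times × 4
  replicates, null σ = 0.25.

## Known limitations

- The Laplace error bars are a second-order correction at a variational
  solution, not samples from the true posterior; strongly multimodal
  posteriors (e.g. several TFs with identical regulons) are summarized
  by one mode.
- TFs with identical target sets are unidentifiable up to rotation; the
  package reports them as fitted but their individual profiles should
  not be over-read.
- Correlation scores use posterior means only; score uncertainty is not
  propagated (matching the analysis this mirrors).
- The per-array LOWESS assumes most features are unchanged; arrays where
  a large fraction of genes respond in one direction will have part of
  that signal absorbed as "bias".
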