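# Methods

## Model and scope

The validator assumes predictions come from a linear mixed model
`y = Xb + Zu + Wp + e` with the validated random effect `u` carrying prior
covariance `G σg²` (pedigree numerator relationship matrix `A`, a genomic
matrix, or any user-supplied structure) and iid residuals.  The bundled
solver assembles Henderson's mixed model equations per trait and solves them
directly by sparse LU; multi-trait data are solved trait by trait with no
cross-trait covariances (a documented limitation — the validation statistics
themselves are trait-wise, so nothing downstream changes).  Fixed-effect
confounding is resolved deterministically by constraining the last level of
every fixed factor after the first to zero; the constrained levels are
reported in a warning.

Prediction error (co)variances are the focal block of the inverse
coefficient matrix times σe², obtained from the same LU factorisation by
solving for the focal unit vectors.  Reliabilities are
`rel_i = 1 − PEV_ii / (σg² (1 + F_i))` with `F` the inbreeding coefficient.

## Joint distribution and standard errors

Writing `K = G22 − Cp22` (covariance of û_p), `D = Cp22 − Cw22` (covariance
of û_w − û_p, which is uncorrelated with û_p) and `S = I − 11′/n`:

* **Bias** `mean(û_p − û_w)`: Var = `1′D1 / n²`.  Exact.
* **Reliability** `û_p′Sû_w / ((n−1) σ²_gi)`: Var =
  `[tr(SDSK) + 2 tr(SKSK)] / ((n−1)² σ⁴_gi)`.  Exact — the statistic is a
  bilinear form in a joint Gaussian, so its variance has a closed form with
  no asymptotic approximation.  Note the `(n−1)` matching the sample-moment
  denominator: the commonly printed `n` variant is only asymptotically
  equivalent and fails a 5% Monte-Carlo check already at n = 10.
* **Dispersion** `b = û_p′Sû_w / û_p′Sû_p = 1 + û_p′Sd / û_p′Sû_p` with
  `d ⊥ û_p`.  Conditionally on û_p the error is Gaussian, so

      Var(b) = E[ w′Dw / (w′w)² ],   w = S û_p ~ N(0, SKS).

  With `SKS = Q Λ Q′` and `d_i = (Q′DQ)_ii` this expectation is the
  one-dimensional integral

      Var(b) = ∫₀^∞ t · Π_k (1 + 2tλ_k)^{−1/2} · Σ_i d_i λ_i / (1 + 2tλ_i) dt,

  evaluated by adaptive quadrature after rescaling t by the mean eigenvalue.
  This is exact (machine-precision agreement with the isotropic chi-square
  closed form `d/(m−2)`, `m = n−1`, and sub-1% agreement with Monte-Carlo
  SDs at n ∈ {10, 25, 50}).  The popular first-order forms
  `tr(SDSK)/tr(SK)²` and `tr(SDSK)/(2tr(SKSK)+tr(SK)²)` underestimate the
  SD by 10–30% at n = 10 and are not used; they appear only as the
  asymptotic limit of the exact integral.  The degenerate case `D = 0`
  (whole and partial runs identical) correctly yields SE = 0, since then
  û_w = û_p almost surely and b ≡ 1.
* **Ratio of accuracies**: Fisher z interval,
  `tanh(atanh(ρ) ± z_{1−α/2}/√(n−3))`.
* **Predictivity**: the Fisher interval of the *raw* correlation
  `corr(y*, û_p) = h · predictivity`, with both bounds divided by h.  This
  reduces to the plain Fisher interval at h = 1 and inherits its coverage;
  a simulation test (n = 200, 1,000 replicates) confirms 92–98% empirical
  coverage.

### Approximated mode

When only per-individual reliabilities are available (no PEV store), the
exact forms are reduced under two assumptions: diagonal PEC blocks with
`PEV_i = (1 − rel_i) σg²`, and proportional whole/partial reliabilities
`rel_w ≈ c · rel_p` with `c = r̄_w / r̄_p`.  Writing `m₂ = var(rel_p) + r̄_p²`:

* bias: SE² = `σg² (r̄_w − r̄_p) / n`;
* dispersion: SE² = `(c − 1) m₂ / (2 m₂ + n r̄_p²)` (note `c = 1` gives 0,
  consistent with the degenerate exact case);
* reliability: SE² = `(1 + c) σg⁴ m₂ / (n σ⁴_gi)`.

The test suite enforces agreement with the exact mode within 15% when PEC
off-diagonals are small and reliabilities are proportional; outside those
conditions the approximation degrades gracefully but is not guaranteed.

### Bootstrap mode

Percentile bootstrap over focal individuals: paired rows (û_w, û_p, y*) are
resampled with replacement (the individual is the sampling unit, preserving
the within-pair dependence), 10,000 resamples by default, deterministic
given the seed.  The SE is the SD of the bootstrap statistics; the interval
is the [α/2, 1−α/2] percentile interval (robust to skew), widened if needed
to bracket the point estimate.  Degenerate resamples (zero variance of û_p)
are redrawn up to a capped number of rounds.  Note the bootstrap treats
focal individuals as exchangeable; with strongly related focal sets its SE
can differ from the exact one, which is the reason the exact mode exists.

### Monte-Carlo oracle

`mc_oracle` samples (û_w, û_p) jointly from
`MVN(0, [[G−Cw22, G−Cp22], [G−Cp22, G−Cp22]])` (eigendecomposition square
root; PSD asserted at −1e−8 relative tolerance) and recomputes every
statistic per draw.  It is the ground truth for every closed form above and
the agreement tests (5% at 10,000 draws for three random PSD structures at
n ∈ {10, 25, 50}) are part of the standard suite.

## Focal genetic variance σ²_gi

Three sources, selectable in the parameter file: the base genetic variance
from the variance components (default), the mean diagonal of the focal G22
block (accounts for inbreeding and relationships; requires a PEV store), or
a user value.  The default is the parameter-file variance because it needs
no extra inputs; with inbred focal sets the G22 source is preferable and the
reliability statistic shifts accordingly.

## Synthetic populations

The simulator emulates the structure of a classical dairy-style validation
dataset: a closed population with discrete generations, traits built as
overall mean + generation trend + sex effect + breeding value + residual,
and breeding values following the infinitesimal recursion with
Mendelian-sampling variance `σg²/2 · (1 − (F_s + F_d)/2)` so that the
simulated covariance is exactly `A σg²`.  Sexes alternate deterministically
within cohorts to remove a nuisance source of replicate variance.  Selection
is optional: none (the validation study design), phenotype truncation, or
EBV truncation via a BLUP solve of the accumulated data.

Defaults (chosen once): σg² = 0.3, σe² = 0.7 (h² = 0.3, a typical moderately
heritable production trait), mean 10, generation step 0.3, sex effect 0.4 —
the fixed-effect magnitudes are arbitrary since the statistics are invariant
to them; they exist so that a mis-specified fixed model is detectable in
tests.  The default scale, 5 generations × ~80 animals (~400 total, focal
cohort 80), keeps a full simulate–solve–validate cycle around 25 ms so the
500-replicate expectation studies run in seconds; `SimConfig.paper_scale()`
produces an 11-generation, ~4,600-animal population with a ~420-animal final
cohort for larger runs.

What the simulator does **not** emulate: marker-level genomes (genotypes for
the genomic-relationship builder are gene-dropped independent loci, no
LD/QTL architecture), overlapping generations, non-random mating designs,
heterogeneous residual variances, and maternal effects.  Passing tests
therefore certify the estimator and interval machinery under the stated
model, not robustness to structures outside it.

## Numerical choices

* Sample moments use the n−1 denominator throughout; all ratio statistics
  are denominator-invariant, and the reliability interval is written
  consistently with n−1.
* PSD assertions use an eigenvalue tolerance of −1e−8 relative to the
  largest eigenvalue (PEV blocks from numeric solvers carry noise);
  symmetry is enforced at 1e−8 relative.
* The MME solve is direct (sparse LU); the relative residual must be below
  1e−10 or the run aborts.  No iterative solver is provided — exact-CI mode
  needs inverse blocks anyway and the intended scale is ≤ a few thousand
  equations.
* Inbreeding comes from the Meuwissen–Luo tracing algorithm by default;
  the simulator and pipeline reuse the tabular-method diagonal (the two are
  cross-checked to 1e−12 in tests).
* Reliability and predictivity estimates outside [0, 1] are reported with a
  warning, never clamped — they are diagnostic of a mis-specified model or
  a wrong σ²_gi.
* Floats are written with 17 significant digits and parsed with round-trip
  precision, so every file dialect round-trips bit-exactly.

## Known limitations

Single-trait solver core (per-trait loops); no single-step or kernel
relationship matrices (the PEV store accepts any externally computed G22,
so such models can still be validated); no REML/Gibbs variance-component
estimation; the bundled engine emits PEV stores for the genetic effect only,
although the validator accepts any effect number for externally produced
files; bootstrap assumes exchangeable focal individuals.
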