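# Methods

## Model

The transverse relaxation rate of residue *n* in a disordered chain of
*N* residues is modelled as a product of multiplicative contributions from
all residues,

    R2(n) = Υ · ∏_{i=1..N} f(i; n),
    f(i; n) = 1 + (q(i) − 1) / (1 + b·s²),   s = |i − n|,

with 21 global parameters (one propensity q per amino acid, one distance
coefficient b) and one local scale Υ per protein. The self term i = n is
included and contributes exactly q(n). The product runs over the whole
chain with no distance cutoff: factors at large s are ≈ 1 and the full
product costs O(N²), negligible at disordered-protein lengths (tens to a
few hundred residues). The input sequence is used verbatim, expression
tags included — a long tag suppresses the terminal falloff exactly as
extra flanking residues should.

The Lorentzian attenuation defines a correlation length Lcorr = b^(−1/2),
the separation at which a neighbour's influence is halfway between its
contact value q and its asymptote 1. A Gaussian kernel
f = 1 + (q − 1)·exp(−b·s²) is available behind a `kernel` flag for
comparison; it decays much faster at long range and has no reference
parameterisation, so the Lorentzian is the default everywhere.

Assumptions worth stating plainly: the model is strictly local (it cannot
represent tertiary or inter-strand contacts), exchange contributions to R2
are not modelled, and temperature/field/viscosity effects are assumed to
rescale R2 uniformly along the sequence — which is what justifies mixing
datasets acquired under different conditions through the per-protein Υ.

### Residue handling

* Pro positions are always excluded from fitting and error metrics (no
  backbone amide proton), but Pro keeps a trainable q because it still
  influences its neighbours, and predicted values at Pro positions are
  emitted with a mask flag.
* Strict parsing rejects any letter outside the 20 standard amino acids.
  Permissive parsing resolves letters through an alias table (default:
  lowercase `c`, a methylated cysteine, treated as Ala). `X` is rejected
  in both modes — an unknown residue has no q and silently guessing one
  would corrupt the whole product.
* Indexing is 1-based and inclusive in every on-disk format and segment
  structure; arrays are 0-based internally.

### Helix boost

Stable long helices tumble more slowly than a ~6-residue correlation
length implies, so the base model underestimates their R2. Within helix
segments that survive a strict filter — per-residue helix propensity
pHlx ≥ 0.99 (secondary-structure predictors over-call helices in
disordered sequences; the high cutoff counters that) sustained over
≥ 12 consecutive residues — predicted values are multiplied by
1 + α·pHlx with amplitude α = 0.5. The boost uses each residue's own
pHlx, not a segment average, and applies exactly to the surviving
segment, not the broader predictor-called helix. Transient short helices
need no correction and get none.

## Statistics

Per-protein mean R̄2 and standard deviation σR2 are computed over scored
residues, with the population convention (divide by n). That choice makes
the null-model identity exact: the RMSE of the constant-mean predictor
equals σR2 to machine precision, so σR2 is the upper error bound any
sequence-aware predictor must beat. Scaled R2 (sR2 = R2/R̄2) removes
uniform external factors; msR2 pools sR2 values per amino-acid type over
residues (not over per-protein means).

The bundled benchmark table (45 training + 9 test proteins) stores both
the plain prediction RMSE and, where one was reported, the helix-boosted
RMSE; test-set means prefer the boosted value. Comparisons against its
printed numbers use a tolerance of one unit in the last printed decimal.

## Training

The objective is the **sum over proteins of the mean squared error** over
scored residues — each protein counts equally regardless of length.
Optimization is joint over {q (20), b, Υ (one per protein)} with
`scipy.optimize.least_squares` (trust-region reflective), residuals
weighted 1/√n_p per protein so the optimizer's sum of squares equals the
objective exactly. The Jacobian is analytic (the product differentiates
into per-residue log-derivative sums), which makes a full training run on
20 proteins take well under a second.

Numerical choices:

* Initialisation: q = 1 for every amino acid (the flat model), b = 0.04
  (Lcorr = 5, near where disordered-protein data put the optimum), Υ set
  to each protein's mean measured R2. The fit is smooth from this start
  and we observed no local-minimum issues on model-generated data.
* All parameters bounded below at 10⁻⁶ (the positivity floor).
* Tolerances 10⁻⁸ on cost change, step and gradient norm; at most 2000
  objective evaluations; exceeding the cap flags `converged_ = False`
  rather than raising. Training is deterministic given data and
  initialisation — there is no stochastic restart.
* Fitting a single protein is allowed but warned against: the parameters
  then merely reproduce that one profile and predict nothing.

For any protein outside the training fold, Υ is refit in closed form,
Υ = Σ(m·u)/Σ(u²) over scored positions (the least-squares scale for a
fixed profile shape), before computing held-out RMSE. The scale carries
experimental conditions, not sequence information, so refitting it leaks
nothing about the held-out profile shape.

### Cross-validation and baselines

* Leave-one-out: each protein in turn is held out, the model retrained on
  the rest, the held-out Υ refit, RMSE(−1) recorded. Jackknife parameter
  means are also reported to detect training-set bias.
* k-fold: k parameter sets from (k−1)/k splits, per-parameter mean ± sd,
  and Welch two-sample t-tests on per-fold q estimates for requested
  amino-acid pairs (Welch, because nothing guarantees equal fold
  variances).
* Null model: uniform R2 per protein; its RMSE is σR2 identically.
* One-residue model: per-residue msR2 learned from the training set,
  times a refit Υ. It is the Lcorr → 0 limit of the full model with q
  pinned at msR2.
* Correlation-length sweep: b pinned at Lcorr⁻² on a grid and everything
  else retrained. Lcorr = 0 is implemented as the exact self-factor-only
  model (prediction Υ·q(n)), not a huge finite b. Its freely-fitted
  per-residue factors can sit slightly below the msR2-pinned one-residue
  baseline, so tests compare the two at 5% relative tolerance rather
  than demanding equality.

## Synthetic data

The generator emulates the statistical shape of a typical disordered-
protein R2 compilation: by default 20 unrelated sequences of 80–150
residues, i.i.d. composition (uniform, or a disorder-biased preset
enriched in Gly/Ser/Glu/Pro/Lys — a documented package constant, not an
empirical claim), per-protein scales drawn uniformly from 0.8–2.0 s⁻¹,
and additive i.i.d. Gaussian noise of sd 0.3 s⁻¹ on R2, clipped below at
0.05 s⁻¹ so measurements stay positive. Additive Gaussian noise is the
model implied by a least-squares objective; the clip is a technical floor
that essentially never engages at default noise. The ground-truth q
constants follow the empirically observed ordering (aromatics, Arg, Ile,
Leu high; Gly and short-polar residues low) with values in the 0.86–1.30
range, and b = 3.164×10⁻² (Lcorr ≈ 5.6 residues).

What passing tests on this data do and do not show: recovery tests prove
the estimator finds the generating parameters when the model is correctly
specified and noise is additive — they validate the machinery, not the
model's adequacy for real proteins. Real R2 data contain structured
residuals the generator does not emulate (transient secondary structure,
rare tertiary contacts, exchange contributions, digitisation error), so
real-data errors are necessarily larger than the noise-floor errors seen
here.

Problem sizes in the test suite and acceptance script (20 proteins of
80–150 residues for recovery and leave-one-out; 10 proteins of 40–70
residues where many retrainings are needed, e.g. the t-test calibration
at 5 replicates × 3 folds) were chosen as the smallest datasets at which
the checks are statistically meaningful; every run completes in seconds.

## Design choices that were genuinely open

* Whether the helix boost uses per-residue or segment-average pHlx: per-
  residue is implemented (with the ≥ 0.99 filter the two differ by < 1%).
* Whether per-protein MSEs are weighted by residue count in the cost:
  they are not — sum of per-protein MSEs, equal protein weight.
* Whether held-out proteins reuse a training-derived scale: they cannot
  (no training scale exists for an unseen protein), so the closed-form
  refit above is used.
* σR2 convention (n vs n−1): population (n), to keep the null-model
  identity exact; at 2-decimal precision the benchmark table is
  consistent with either.

## Known limitations

* The model is blind to long-range order: β-sheet contacts, tertiary
  interactions and exchange broadening produce R2 peaks it cannot
  predict.
* The helix boost depends on an external secondary-structure predictor's
  scores; helices shorter than 12 surviving residues receive no
  correction even when they elevate R2 moderately.
* Published trained q values are not reproducible here without the
  original residue-level dataset; the training machinery is validated by
  synthetic-parameter recovery instead, and the bundled benchmark table
  supports only aggregate-level checks.
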