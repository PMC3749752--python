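# Methods

This note documents the models, conventions, and numerical choices behind
`avacrit`, in the order the pipeline applies them.

## Event detection and avalanche definition

Events are negative threshold crossings of a continuous multichannel signal.
The threshold is `mean + threshold_sd * SD`, with the SD computed per channel
over the full trace (no robust estimator); the default `threshold_sd = -2.5`
suits LFP-like data, `-3.0` MEG-like data.  One event is emitted per
contiguous sub-threshold excursion, timestamped at the excursion minimum;
equal minima resolve to the earliest sample.  A constant channel (zero SD)
is an error, not a silent skip.

Event times are assigned to half-open bins [kΔt, (k+1)Δt), 0-based, default
Δt = 2 ms (configurable; the method is stable over a wide Δt range).  An
avalanche is a maximal run of consecutive bins that each contain at least
one event anywhere in the channel group; its size s is the total number of
occupied (channel, bin) cells, so sizes sum exactly to the raster's
occupancy count.  The spatial pattern σ assigns +1 to channels with at
least one event in the avalanche and −1 otherwise.

Pattern distributions index the 2ⁿ states with channel 0 as the least
significant bit; index 0 is the quiescent state.  Empirical per-size
ensembles are built by extracting avalanches on the *full* channel group and
projecting each pattern onto a channel subset.  A projection may be entirely
inactive, which is what makes the quiescent probability p₀ positive and
monotonically non-increasing in subset size — the behavior the quiescent
diagnostics rely on.  (Whether p₀ should be measured per avalanche
projection or per time bin is a genuinely open reading; the projection
convention is adopted because it produces the size dependence the analysis
needs, and it is stated here as an interpretation.)

## Power-law fitting

Size distributions are fit with a discrete power law P(s) ∝ s^ε normalized
on the observed support [min s, max s] — no tail truncation, so the
finite-size cutoff is part of what the fit sees.  The exponent minimizes the
Kolmogorov–Smirnov distance between empirical and model CDFs.  D_KS(ε) is
only piecewise smooth and V-shaped at its optimum, where
parabolic-interpolation minimizers stall near √machine-epsilon, so the
implementation uses a coarse grid (160 points on [−8, −0.01]) followed by
golden-section refinement to an interval of 1e−12.  Self-fitting an exact
power-law pmf then returns the exponent to ~1e−6 and D_KS below 1e−10.

## Dichotomized-Gaussian model

Binary patterns are modeled by thresholding a latent Gaussian u ~ N(δ, Λ)
at zero (σⱼ = +1 iff uⱼ > 0).  The fit consumes per-unit rates and pairwise
covariances of the **0/1 indicators** — the ±1 coding used elsewhere differs
by a factor of 4, and explicit conversion helpers are provided rather than
guessing the caller's coding.  δⱼ = Φ⁻¹(rⱼ); each λⱼₖ solves
Σⱼₖ = Φ₂(δⱼ, δₖ; λ) − Φ(δⱼ)Φ(δₖ) by Brent root finding on
[−1+1e−9, 1−1e−9] (the left side is monotone in λ; a covariance outside the
Fréchet bounds is reported as infeasible, naming the pair).  An assembled Λ
that is not positive semidefinite — possible for empirical inputs — is
repaired by eigenvalue clipping and diagonal rescaling with a warning that
reports the maximum elementwise change.  Synthetic ring specifications are
never repaired: a non-PSD ring covariance raises, because a generator
should be valid by construction.

Pattern probabilities are Gaussian orthant integrals.  The generic path
maps each orthant to a lower-tail probability by sign-flipping and evaluates
scipy's Genz quasi-Monte-Carlo multivariate normal CDF at absolute tolerance
1e−6 (default), with a seeded generator per pattern so results are
bit-reproducible; the full vector is renormalized to sum to one and the
renormalization factor logged.  A homogeneous exchangeable model (constant
δ, constant non-negative off-diagonal λ) takes an exact fast path instead:
conditioning on the shared latent factor makes units independent, and a
201-node Gauss–Hermite quadrature gives every size-class probability
directly.  The two paths agree within the integration tolerance (tested).
Exact enumeration is capped at n = 20 (2²⁰ states); above the cap the
sampling path (`sample_dg`) is the intended estimator.

Subset models are exact Gaussian marginals (restrict δ and Λ), which is why
per-size families default to nested subsets (first n channels): whether the
original analysis refit each size or marginalized a single 20-unit fit is
not stated, and marginalization is adopted because it is exact under the DG.

## Temperature reweighting and observables

Energies use the natural-log convention Eᵢ = −ln pᵢ(1), fixing Z(1) ≡ 1.
All observables depend only on energy differences, so the unknown true
normalization is immaterial.  Reweighting pᵢ(T) ∝ pᵢ(1)^(1/T) is computed in
log space (log-sum-exp normalization) to survive small T; zero-probability
patterns are floored at 1e−300 with a warning, which is why DG-modeled
rather than directly-counted distributions are the recommended input.

Per-unit observables, with m the summed ±1 activity of a pattern and
expectations under p(T):

- susceptibility χ(T) = (⟨m²⟩ − ⟨m⟩²)/(nT) — the zero-field response of M
  to a weak external field, via the fluctuation identity; no field is ever
  applied explicitly;
- specific heat C(T) = (⟨E²⟩ − ⟨E⟩²)/(nT²);
- order parameter M(T) = (1/n) Σᵢ pᵢ mᵢ ∈ [−1, 1].

The default temperature grid is 0.5 to 2.5 in steps of 0.01 (the range is
the one the analysis is defined over; the step is a resolution choice).
For homogeneous independent units reweighting preserves independence with
per-unit rate r(T) = r^(1/T)/(r^(1/T) + (1−r)^(1/T)), which yields closed
forms for all three observables; enumeration matches them to 1e−10 and the
curves are exactly size-independent — the signature that independent
(surrogate) data carry no collective scale.

The size-distribution temperature scan reweights, aggregates pattern
probabilities by size excluding the quiescent state, and evaluates D_KS
against both the best-fit and a fixed −1.5 power law, reporting the
arg-min temperature for each.  The quiescent-perturbation operation
replaces p₀ and renormalizes the active states, leaving the conditional
size distribution (and hence any power-law fit of it) invariant.

## Finite-size scaling

Only the product νd is identifiable (the cortical dimensionality d is
unknown), so all powers of the linear size L = n^(1/d) are expressed through
n: abscissa x = n^(1/νd)(T − T_c)/T_c; ordinate scaled by n^(−γ/νd) for χ,
n^(−α/νd) for C, n^(+β/νd) for M.  Each quantity is collapsed separately,
yielding its own (T_c, νd, exponent), as in the original three-column
analysis.

Goodness of collapse is GC = MSD_after/MSD_before, where MSD is the mean
squared deviation of the curves from their point-wise across-size mean.
Scaling destroys the shared T grid, so both MSDs are evaluated on a fixed
200-point grid spanning the intersection of the abscissa ranges, with
linear interpolation — the minimal completion of a point-wise average that
scaling otherwise leaves undefined.  Identical input curves make
MSD_before = 0 and are rejected as degenerate; an empty overlap interval is
an error.

Two guards make the raw GC objective well-posed, both adopted after the
unguarded objective was found to have spurious optima:

- **Ordinate-factor canonicalization.**  The factors n^(∓exponent/νd) are
  divided by their geometric mean across sizes.  Collapse quality depends
  only on the *relative* factors; without the canonicalization, driving the
  exponent to ±∞ scales every ordinate to zero and GC to a meaningless
  zero.  With it, the planted-family recovery and the GC = 1 identity
  transform are unchanged.
- **T_c window constraint.**  Candidate T_c values are restricted to the
  measured temperature window.  A T_c outside the sweep leaves data on only
  one side of the putative transition, and the shared abscissa interval
  then contains only flat curve tails, which collapse spuriously.

The optimizer is Nelder–Mead (tolerance 1e−8 on GC, up to 2000 iterations)
from a full grid of starts — T_c ∈ {0.8, 1.0, 1.2, 1.5}, νd ∈ {0.5, 1.0,
1.5}, exponent ∈ {0.5, 1.0, 1.5} for χ/C and {−0.1, 0, 0.1} for M — with
every local optimum kept in the trace and the global best returned.

On noise-free planted families (five sizes, n = 6–20, a smooth bump master
curve) all three parameters are recovered within 5% with GC < 1e−3, and
within 10% under 1% multiplicative noise.

## Synthetic generators as study conditions

- **Ring DG model.**  n units on a ring (wrap-around distance, adjacent
  units at distance 1); latent covariance λᵢⱼ = λ_max exp(−½(rᵢⱼ/ω)²),
  rate r per unit.  ω = ∞ is an explicit flag, not a large float, and
  yields the exchangeable model in which every equal-size pattern is
  equally probable — the model's critical limit.  ω → 0 gives independence.
  The validation study uses λ_max = 0.5 and r = 0.2, chosen once so that
  the implied binary pattern correlations fall inside the 0.2–0.6 Pearson
  range reported for cortical avalanche data; each system size n = 6–10 is
  built as its own n-ring (at ω = ∞ this coincides exactly with nested
  marginalization of a larger ring).
- **Branching process.**  Each avalanche starts with one active unit on a
  random channel; per bin, every active unit attempts binomial thinning
  over the currently inactive channels at per-channel probability
  σ/n_available, and parents' draws merge.  The offspring law is not fixed
  by the underlying theory — the binomial-over-available-channels choice is
  this package's (documented, swappable); it respects the finite-channel
  cap that produces the system-size cutoff of the size distribution.  At
  branching ratio 1 the fitted size exponent reproduces −1.5 within ±0.1.
- **Surrogates.**  Independent Bernoulli rasters at matched rates
  (destroying all cross-channel correlation) and per-channel time shuffles
  (conserving per-channel counts exactly).
- **Exact power-law sampler** on {1..s_max} for fitter fixtures.

All generators take explicit seeds; no global random state is used
anywhere.

What the generators do *not* emulate: continuous LFP/MEG waveforms with
realistic spectra (detection is exercised on constructed deflections and
noise), volume conduction or sensor mixing, non-stationarity, and
higher-order interaction structure beyond what thresholded Gaussians carry.
Passing tests therefore validate the machinery and its calibration on
models with known ground truth, not the neurophysiological claims
themselves, which require real recordings.

## Known limitations

- Exact DG enumeration is practical to n ≈ 12 and capped at 20; larger
  systems need the sampling path.
- The FSS sensitivity at n = 6–10 has a finite-size floor: collapse
  residuals GC ~ 0.01 remain even for the exactly-critical exchangeable
  family, so ring models with ω ≳ 8 (covariance decay wider than the
  largest ring distance, 5) are inside the method's resolution and cannot
  be reliably ordered against the ω = ∞ limit — consistent with the
  original observation that deviations from criticality are detectable for
  ω below about 7–8 at these sizes.  Larger n sharpens the ordering.
- The correlation-decay fit is a log-log least-squares line, appropriate
  for a normalized correlation function but not a maximum-likelihood
  power-law fit.
- Exponent error bars are not produced; variability should be assessed
  across channel sub-groups, as in the segment-stability and
  cross-validation utilities.
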