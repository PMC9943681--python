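# Methods

This note documents the modelling and numerical choices behind the
package, the places where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Protection-kinetics model

RNase A behaves as a kinetically perfect enzyme: digestion of the
accessible pool of transcript *i* follows dR/dt = −k·R·A with *A* the RNase
concentration (assumed constant during the reaction). Integrating at fixed
digestion time *t* and allowing a pool of size *r* that never enters the
reaction (shielded by membranes, or intrinsically inert) gives the
remaining fraction

    f(A) = (1 − P₀)·exp(−k′A) + P₀,   P₀ = r / (R₀ + r),   k′ = k·c·t

with R₀ the accessible pool and c the conversion from μg/ml of enzyme to
molarity. P₀ = 0 collapses to a pure exponential (Model 2); P₀ = 1 to the
constant f = 1 (Model 3, the implicit null of both fits). The measurable
f is a spike-in-normalised count ratio with f(0) ≡ 1 by construction, so
values above 1 are legitimate noise and are never clipped.

## Profile reconstruction

Counts are normalised per library by the spike-in and then per replicate by
that replicate's untreated (A = 0) sample. Library-size factors cancel
exactly (a property test verifies invariance under arbitrary rescaling of
any library column). Replicates are pooled as points into one profile per
(transcript, condition), each replicate contributing its own f(0) = 1
anchor. Filtering precedes normalisation: repetitive-gene entries are
summed under compound ids, user-blacklisted cross-mapping features are
dropped (unknown ids warn rather than fail, since blacklists outlive
annotation versions), and a ≥ 30-read cutoff is enforced in *every*
untreated library of both conditions — the strictest reading, chosen
because a noisy anchor corrupts the entire profile; the boundary is
inclusive.

## Fitting

Model 1 is fitted by bounded nonlinear least squares (scipy's trust-region
reflective variant of damped Gauss-Newton) under 0 ≤ P₀ ≤ 1, k′ ≥ 0, with
relative tolerance 1e-9 and at most 500 iterations. The initial P₀ is the
lowest observed f. The initial k′ inverts the model at the first clearly
decayed point; a small deterministic multistart over k′ scales plus a final
machine-precision polish guard global optimality — the contract, enforced
by test against an exhaustive grid-search oracle, is that the reported
optimum is the SS minimiser, not any particular optimizer trajectory.
Model 2 is fitted unconstrained (one parameter); a negative optimum on
noisy flat data is clamped to k′ = 0 and flagged. R² is 1 − SS_res/SS_tot
about the observed mean and may be negative for flat profiles, where the
mean outperforms the decay model.

### Parameter dependency and model selection

The two parameters of Model 1 become inestimable when a profile barely
decays over the gradient. The dependency diagnostic is
1 − 1/(C_ii·(C⁻¹)_ii) with C the Jacobian-based covariance at the
solution — the squared correlation ρ² between the two estimates, which is
how the curve-fitting software used for the original analyses defines it.
(The absolute correlation |ρ| was considered and rejected: on the
experimental concentration grid |ρ| exceeds 0.33 even for arbitrarily fast
digestion, so a 0.3 threshold on |ρ| would reject every well-behaved
profile.) Model 1 is replaced by Model 2 when the fit fails to converge or
the dependency exceeds 0.3.

Two degenerate regimes get explicit conventions. When a parameter sits on
its box bound only one parameter is free: dependency 0. When digestion
completes before the first non-zero concentration (k′·A_min > 10) the
profile is a two-level step: if the step height (1 − P₀) is significant
against residual noise (t > 2), P₀ is pinned directly by the plateau and
dependency is 0; an insignificant step is a flat profile in disguise and
reports dependency 1, routing it to Model 2 — the behaviour observed for
fully protected organellar transcripts, whose intact-organelle profiles
stay flat.

### Confidence intervals

95% intervals are profile-likelihood (F-comparison) bounds: parameter
values where the SS profiled over the other parameter reaches
SS_min·(1 + F(1, n−p)/(n−p)), found by bisection and clipped to the box
constraints (clipping is flagged). Zero-residual fits give degenerate point
intervals. This is a standard stand-in for the proprietary "model
comparison" interval of the original software.

Known limitation, measured: each replicate's profile is anchored on its own
noisy untreated count, which scales the whole replicate coherently. This
shared-within-replicate error is invisible to iid profile likelihood, so
the intervals undercover in count-noise simulations (~72-80% instead of
95% at sequencing depth 1000; every miss is a near-miss of a
correctly-shaped interval, and the same code achieves nominal coverage
under independent noise). Users needing calibrated uncertainty at low
depth should fit replicates separately and compare, or deepen the
untreated libraries.

### Rate conversion

k = k′/(c·t) with c = 1e-3/MW mol·L⁻¹ per μg/ml. Defaults: MW 13,700 g/mol
(bovine RNase A) and t = 600 s, both configurable because neither constant
is fixed by the assay itself. At k′ = 1 per μg/ml this gives
k ≈ 2.28 × 10⁴ M⁻¹ s⁻¹; well-digested substrates sit near 10⁶ M⁻¹ s⁻¹.

## Classification

With thresholds τ_low = 0.1 (the published contaminant boundary) and
τ_high = 0.2 (no boundary for "high P₀" is published; 0.2 is this
package's choice, configurable and echoed in every output):
contaminant if both P₀ < τ_low; resident if coloc P₀ ≥ τ_high, mock
P₀ < τ_low and (by default) the coloc lower confidence bound clears τ_low;
RNase-resistant if coloc P₀ ≥ τ_high and mock P₀ ≥ τ_low; otherwise
ambiguous. A dedicated flat-coloc rule covers profiles so flat that P₀ was
unidentifiable (Model-2 fallback with mean f > 0.8 and k′ ≈ 0): paired
with a cleanly decaying mock profile they are called resident — nothing
was digested while membranes were intact, so the plateau is real even
though the two-parameter fit could not place it.

## Synthetic data

The generator emulates what the sequencing assay measures. Expected
feature counts are depth · L · (R₀·e^(−k′A) + r)/(R₀ + r) per library,
with L a lognormal library-size factor (unit mean, CV 0.2) and the
spike-in expectation tracking the same L. Counts are drawn
negative-binomial in the NB1 parameterisation, var = μ(1 + d) with d = 0.1
by default (Poisson at d = 0): a gradient of libraries prepared from one
organelle suspension varies technically, not with the gene-level
biological dispersion of independent cultures, whose depth-independent CV
floor would swamp the anchor measurement the normalisation rests on.
Default concentrations are the experimental gradient 0, 0.1, 0.2, 0.6,
1.2, 2.0, 2.6, 3.2, 4.0, 6.0 μg/ml, t = 600 s, two replicates, depth 1000,
spike-in depth 1e5. Mock data share each feature's k′ (lysis is assumed
not to change intrinsic reactivity); membrane-protected features have
their r zeroed in mock, intrinsically resistant ones keep it in both
conditions. Rates are drawn log-uniformly between 10⁵ M⁻¹ s⁻¹ (the lower
edge of the robust regime) and 2.3 × 10⁶ M⁻¹ s⁻¹ (the benchmark rate on a
good RNase A substrate).

What the generator does not model: positional coverage, RNase A's
pyrimidine preference, partial cleavage and re-ligation artifacts,
transcript-length effects on capture, or correlated digestion between
transcripts sharing an RNP. A green recovery test therefore establishes
that the inference is correct for the stated kinetics-plus-count-noise
world, not that the wet assay is unbiased.

### Identifiability map

For each (P₀, k) cell the grid simulates single-transcript experiments,
refits, and scores the median |P₀_hat − P₀|; cells below 0.1 are "robust"
(the strict threshold is compared at 1e-9 resolution so that boundary
cases — a flat fit at P₀ = 1 against truth 0.9 scores exactly 0.1 — do not
flip on optimizer epsilon). At the defaults the map is robust everywhere
for k ≥ 10⁵ M⁻¹ s⁻¹ and nowhere for k ≤ 10⁴: slow digestion leaves the
plateau entangled with the rate and the selection rule degrades such
profiles to Model 2, whose P₀ is 0 by construction. For a truly undigested
transcript (P₀ = 1) the grid accordingly reports error ≈ 1 — the plateau
is unidentifiable when nothing decays, which is the honest reading; the
classification layer recovers such transcripts through the flat-coloc rule
instead.

## Numerical conventions

ε = 1e-12 guards logs and divisions; concentration values are taken as
given in the sample sheet (no pre/post-mixing dilution arithmetic);
within-tolerance concordance uses |Δ| ≤ tol (boundary inclusive); binomial
proportion intervals default to Wilson, with Clopper–Pearson available,
since the software used for the published intervals does not state its
method and Wilson reproduces the printed example interval.
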