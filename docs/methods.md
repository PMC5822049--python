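# Methods

This note documents the models implemented in `shapereadout`, the
numerical choices behind them, what the synthetic-data generators emulate,
and the known limitations.

## Shape tables and window conventions

A shape table assigns one structural value to every DNA k-mer. Base-pair
parameters (MGW in Å, ProT in degrees) use pentamers centered on a base
pair (window offsets −2..+2); step parameters (Roll, HelT, degrees) are
recentered onto tetramers centered on a base-pair step (base offsets
−1..+2). Raw step tables carry two values per pentamer (the steps between
positions 2–3 and 3–4); recentering marginalizes each over the
non-overlapping terminal base, averages the two aligned tetramer tables,
and reverse-complement (RC) symmetrizes last, which guarantees
value(t) = value(revcomp(t)) exactly. Because the two strands are
physically equivalent, RC symmetry is enforced throughout; table
permutation operates on RC equivalence classes {s, revcomp(s)} (palindromic
k-mers form singleton classes), which preserves both symmetry and the
class-value multiset exactly.

## Sequence-to-shape regression

Tables are compressed into linear models φ̂(s) = X(s)·γ with indicator
features: intercept; mononucleotide δ_{c,sᵢ}; adjacent dinucleotide
δ_{cd,sᵢ:ᵢ₊₁}; optionally all position pairs. Indicator designs are
deliberately redundant, so coefficients are identified only up to gauge;
we fit the minimum-norm least-squares solution via SVD, discarding
singular directions whose squared singular value falls below 1e−9 times
the largest (the exact-zero redundancy eigenvalues are well separated
from signal, so the cutoff is uncritical). Predictions are
gauge-invariant. For display, mono coefficients are centered per position
and dinucleotide blocks doubly centered; this affects logos only, never
predictions.

Degrees of freedom are counted as eigenvalues of XᵀP_RC X above the same
relative cutoff, where P_RC = (I + R)/2 projects onto RC-symmetric value
vectors (R the revcomp permutation). The counts match the closed forms
⌈(3k+1)/2⌉ (mono) and 4⌊3k/2⌋−2 (mono+di) for k = 2..6; the adjacent-
dinucleotide-only design spans the mono+di space and has the same count.

Reported R² is leave-one-out cross-validated by default: each RC pair is
held out together (it shares one value), the model refit, and the pair
predicted. The fast path uses the block leave-out identity on the hat
matrix U Uᵀ (thin SVD basis); it is verified against explicit refits in
the test suite. In-sample R² is available separately.

## Binding models and partition sums

The mechanism-agnostic model scores a k-mer footprint as
−ΔΔG/RT = β⁽⁰⁾ + Σᵢ β⁽¹⁾ᵢ,ₛᵢ + Σᵢ β⁽²⁾ᵢ,ₛᵢ:ᵢ₊₁ (larger = stronger). The
shape-readout model replaces dinucleotide terms with sensitivity
coefficients β⁽ᵠ⁾ᵢ (−ΔΔG/RT per unit shape) multiplying the model-
predicted shape of the window centered at i. Sensitivities at the first
two and last two base positions (first and last step for step-centered
features) are structurally zero: their windows would extend beyond the
footprint, creating sequence preferences outside the mechanism-agnostic
model's support. Substituting the linear sequence-to-shape model yields
the exact sequence-only representation: γ⁽⁰⁾ accrues to the intercept,
γ⁽¹⁾ rows to the scoring matrix at offsets −2..+2, γ⁽²⁾ rows to steps
−2..+1 (step-centered features: base offsets −1..+2 and step offsets
−1..+1, mirroring the tetramer window convention). Scores agree on every
k-mer to machine precision.

Partition sums σ(β) = Σₛ exp(score(s)) over all 4ᵏ k-mers are computed by
a left-to-right transfer recursion carrying per-base partial sums through
the mono and adjacent-dinucleotide weights, entirely in log space
(footprints near 20 bp with |β| of a few RT would otherwise overflow).
The gradient of log σ comes from forward–backward accumulation and equals
the marginal base and dinucleotide probabilities under p(s) ∝ exp(score);
both are validated against brute-force enumeration (relative 1e−10 for
k ≤ 6) and central finite differences (1e−6).

## Shape projection

Projection decomposes a mechanism-agnostic model into base readout plus
shape sensitivities by minimizing, over the shape-readout parameters
(applied through the linear map to their sequence-only representation),
one of two losses:

* affinity: σ(2β_agn) + σ(2β_seq) − 2σ(β_agn + β_seq), the summed squared
  affinity error over all footprints, evaluated via three partition sums
  (internally rescaled by exp(−log σ(2β_agn)) for overflow safety — a
  fixed positive factor that leaves optima unchanged);
* KL: the Kullback–Leibler divergence between the Boltzmann sequence
  distributions, (β_agn − β_seq)·∇σ(β_agn)/σ(β_agn) − ln σ(β_agn) +
  ln σ(β_seq). This loss is convex in β_seq and invariant to intercepts,
  so the intercept is fixed at zero (gauge) under KL.

Because two-thirds of shape variance is itself mono-explainable, base and
shape readout are nearly collinear and the unpenalized problem is poorly
conditioned: solutions wander along near-null directions while score-level
predictions stay fixed. Stage 1 therefore minimizes the bare loss from a
zero start (L-BFGS, objective tolerance 1e−12, gradient tolerance 1e−9)
to obtain the reference loss V_ref and reference block norms; stage 2
minimizes V/V_ref + λ_shape Σ_φ ‖β⁽ᵠ⁾‖_p/‖β⁽ᵠ⁾,ref‖_p +
λ_mono ‖β⁽¹⁾‖_p/(‖β⁽¹⁾,ref‖_p/4), warm-started from stage 1. Penalty
norms are p-th-power sums Σ|x|ᵖ, so p = 2 is smooth (L-BFGS); p = 1 is
reformulated with auxiliary bound variables t ≥ |β| and solved with SLSQP.
All four shape features are fitted jointly by default, each carrying its
own normalized penalty term; single-feature mode is available. The /4 on
the mono reference norm is implemented as stated in the objective above
and can be disabled (`mono_ref_quarter=False`). Blocks whose reference
norm falls below 1e−8 per parameter have their penalty dropped with a
warning. Defaults: λ_shape = λ_mono = 1. No automatic λ selection is
performed; a λ grid can be scanned by calling `project` repeatedly.

## Desk-scale SELEX inference

The SELEX model: round-0 probe frequencies p_{i,0} = w_i/Z₀ with
log w_i the sum of k_bias-mer coefficients over the variable region
(flanks are constant and absorbed by normalization); round-1 frequencies
p_{i,1} ∝ p_{i,0}·κ_i with κ_i = exp(β_NS) + Σ_v exp(view score), views
running over all footprint offsets and both strands within
flank + variable region + flank. Counts are multinomial in both rounds.

This implementation is deliberately desk-scale: the probe space is
enumerated exactly (variable region L ≤ 12), which makes all partition
sums exact and testable. Fitting aggregates views by their context k-mer
(the footprint, extended ±2 bp when shape predictors are used, so edge
pentamers draw context from neighboring probe or flank bases), reducing
per-iteration cost to O(4^context width); minus-strand views reuse the
plus-strand context through the RC index permutation. With shape
predictors, views are restricted to placements with 2 bp of context on
both sides. A transfer-matrix evaluator for Z₀ and Σ w_i κ_i over
flankless probes cross-checks the enumeration.

Both fits are maximum likelihood with analytic gradients (L-BFGS,
relative tolerance 1e−12). The bias model is gauge-fixed to zero-sum
coefficients. The binding fit starts at zero plus a small seed-controlled
perturbation: the likelihood is invariant under strand swap, so the
exactly-zero start is a stationary point of that symmetry and would trap
the optimizer on the RC-symmetric manifold; consequently the fitted
orientation is arbitrary (and reported as found). β_NS starts at −10.
Reported matrices are gauge-fixed per position; shape predictors are
centered to zero mean over all k-mers to decorrelate them from the
intercept. Optional RC symmetry is imposed by averaging parameters with
their reverse-complement image inside the objective.

Performance is quantified by sliding a 10-bp window across probes,
tabulating held-out-read counts, keeping 10-mers with count ≥ 100, and
correlating log observed with log expected counts (expected = held-out
total × Σᵢ p_{i,1} × window incidence). Held-out reads are a binomial
50% thinning of round-1 counts with a fixed seed. Differences between
correlations use the Fisher r-to-z two-tailed test; the effective n is an
explicit argument because the appropriate value (reads vs retained
10-mers) is a modeling choice.

## Energy-binned sampling and probe alignment

To show what shape preferences a scoring matrix encodes, sequences are
binned by W(s) = Σⱼ w_{j,sⱼ} (shifted so the best sequence scores 0; 10
uniform bins over [W_min, 0]) and each bin's mean shape profile computed.
Extreme bins are unreachable by uniform sampling, so Metropolis–Hastings
chains target p(s) ∝ exp(β_T W(s)) on a grid of 13 uniformly spaced
inverse temperatures spanning (ln 4ᵏ / −W_min)·[−2, 2] — scaled so the
Boltzmann tilt is comparable to the sequence entropy — with single-base-
substitution proposals (defaults: 10⁵ steps, 10³ burn-in, thinning 10).
Within each (bin, temperature) cell, rejection sampling with acceptance
probability proportional to exp(−β_T W(s)), normalized by the cell
maximum, restores the uniform-within-bin distribution before pooling
across temperatures; uniformity is verified against enumeration at small
k. Bins never reached are flagged empty rather than raising.

High-affinity probe alignment: m-mers passing count (≥ 100) and relative-
affinity (≥ 0.1) filters are oriented to the top m-mer (strand maximizing
base matches, no shift), a base-frequency matrix built from them, and
each probe containing a retained m-mer assigned the offset and strand
maximizing the frequency-matrix log-score. The relative-affinity table is
a simple round-1/round-0 frequency ratio normalized to the top m-mer — a
deliberate simplification of model-based affinity estimators.

## Complexity-matched nulls and significance

Permuting a table destroys what makes shape tables special — their
variance is concentrated in low-order, center-localized sequence
features — so permutation nulls are too easy to beat. The matched null
draws mono and dinucleotide coefficients from U(0,1), RC-symmetrizes the
implied component tables, and rescales per-position blocks (scales tied
between mirror positions, constrained nonnegative) to minimize
D = Σᵢⱼ (C_ij(ref) − C_ij(candidate))², where C_ij is the expected
conditional variance after fixing the bases at positions i and j
(computed by exact enumeration; the mean offsets of the U(0,1) draws are
pure gauge and do not affect C). Because the candidate is linear in the
scales, every C_ij is a quadratic form αᵀM_ij α with precomputable M_ij,
making the optimization (L-BFGS with bounds, analytic gradient) essentially
free; a failed draw is retried up to 5 times. The typical relative
matching error ‖C − C_ref‖/‖C_ref‖ is below 1% (median), with occasional
hard draws near 20%.

Null bands rerun the projection, with identical configuration, once per
matched table set (N = 200 by default in tests; larger ensembles by
argument). Empirical per-position significance uses the add-one two-sided
p-value p_i = (1 + #{n: |β_null,n,i| ≥ |β_obs,i|})/(N+1) on the absolute
coefficient, with Benjamini–Hochberg correction across interior positions
within each feature separately (features are not pooled). These
definitional choices — add-one two-sided p, per-feature BH, |β| as the
statistic — are this package's; calibration is assessed by simulation in
the acceptance suite. Against an exchangeable null (reference tables
redrawn from the same generative process) the empirical p-values are
uniform; against the complexity-matched null they are mildly
anti-conservative, because the U(0,1) coefficient draws have lighter
tails than Gaussian-structured reference tables — an intrinsic limit of
the matched-null approximation worth keeping in mind when interpreting
borderline q-values.

A note on units when comparing null schemes: sensitivity coefficients are
per unit shape, and a permuted table's fitted mono+di model is nearly
flat, which mechanically inflates its per-unit-shape coefficients. Band
comparisons between null schemes are therefore made in free-energy units
(coefficient × SD of the fitted shape predictions).

## Synthetic study conditions

The table generator mixes an RC-symmetric random mono component, a
dinucleotide component orthogonalized against the mono design span, and
Gaussian noise, standardized so the three variance fractions are
controlled exactly up to the noise draw; defaults (0.65, 0.30, 0.05)
emulate the real pentamer tables, where mononucleotides explain roughly
two-thirds of the variance and adjacent dinucleotides nearly all of the
rest. Noise is added per k-mer before the final symmetrization, which
halves its variance on non-palindromic k-mers; the noise scale is
pre-compensated by √2. Planted binding models combine a per-position
zero-mean Gaussian scoring matrix (scale 0.5 RT) with unit-scale planted
sensitivities at interior positions; their mechanism-agnostic
counterparts are exact by construction. SELEX fixtures default to
L = 10, 4-bp flanks, 2×10⁵ reads per round, and a dimer bias of scale
0.15 — sizes at which multinomial sampling noise, not model error,
limits recovery (scoring matrices are recovered within ±0.1 RT per
gauge-fixed cell). A single global seed fans out to per-component seeds
through tagged numpy SeedSequences, so adding a fixture never perturbs
existing ones.

What the synthetic data do **not** emulate: sequencing error,
platform-specific adapter artifacts, PBM spatial bias, multiple selection
rounds, cooperative or multi-mode binding, and any higher-than-
dinucleotide structure in the shape tables themselves. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not robustness to those real-data complications.

## Problem sizes and other choices

Simulations in the test suite run at deliberately modest sizes chosen as
the smallest that make each statistical assertion stable: 20 seeds for
recovery medians, N = 200 null tables × 100 global-null models for FDR
calibration, 10 seeds for held-out model comparisons, probe spaces of
4⁸–4¹⁰. Degenerate inputs are handled explicitly: constant tables have
zero conditional variance everywhere and matched nulls collapse to
near-constants; an all-zero scoring matrix yields a single occupied
energy bin; empty alignment filters warn and return empty results;
single-probe SELEX data raise.

## Known limitations

* The desk-scale SELEX path enumerates the probe space; it is exact but
  limited to L ≤ 12 and is not a streaming large-L implementation.
* Strand orientation of fitted binding models is not identifiable from
  the data; comparisons must consider both orientations.
* The p = 1 projection path relies on a general constrained optimizer
  (SLSQP) and is slower and less numerically crisp than p = 2.
* Empirical p-values are bounded below by 1/(N+1); position-level
  conclusions at small N are correspondingly coarse.
* Electrostatic-potential or other extended k-mer tables are readable
  (the format is generic) but receive no special treatment.
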