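# Methods

## The reduction problem

A linear chain of monomolecular reactions

    S_1  <->  S_2  <->  ...  <->  S_{n-1}  <->  S_n

(with forward rates c_i for S_i → S_{i+1} and backward rates c_{i,r} for
S_{i+1} → S_i, optionally decorated with bypass reactions S_j → S_i for
|i−j| > 1, degradation of intermediates, synthesis of intermediates, and
bimolecular reactions feeding the chain ends) is simulated exactly by the
SSA, but every hop of every molecule is an event.  When only a subset of
species matters — the *species of interest* (SOIs) — the chain between SOIs
can be removed exactly.  Because the reactions are monomolecular, molecules
inside the block are independent random walkers, and the block is fully
characterised by the first-passage behaviour of one walker:

* **first return**: a walker that leaves SOI `S` (entering the block at its
  neighbour) comes back to `S` before reaching any other SOI;
* **first arrival**: the walker reaches another SOI `T` without revisiting
  its origin;
* **loss**: the walker is killed inside the block (degradation), possibly
  emitting products outside the chain (e.g. the dissociation C_i → T + M in
  the proofreading model; pure degradation is the empty-product case).

Each outgoing reaction of an SOI with rate `c` into the block is replaced by
consuming delayed reactions, one per possible fate, with rates `c`
multiplied by the fate probabilities (so the total outgoing propensity of
the SOI is unchanged — this is exact, not an approximation) and delays
distributed as the *conditional* passage times.  Reactions entirely between
retained species are carried over unchanged.  The abridged model is then
simulated with the rejection-method delay SSA (DSSA), whose SOI marginals
are distributionally identical to the full model's.

## Closed-form passage laws

Let K̃ be the (m×m) column generator of the block (intermediates only):
off-diagonal K̃[i,j] is the rate of S_j → S_i inside the block, the diagonal
is minus the total exit rate of each intermediate (including flow to the
boundary SOIs, degradation, and bypasses leaving the block).  All first-
passage laws follow from the Laplace transform of the absorption flux.  For
a walker injected at block state `a` and an absorption target fed by
channels (c, b) — exit rate c out of block state `b` — the unconditional
passage-time density transforms to

    f̂(s) = N(s) / det(sI − K̃),      N(s) = Σ_channels c (−1)^{a+b} M_{a,b}(s),

with M_{a,b}(s) the minor of (sI − K̃) deleting row a and column b.  From
this single identity the package derives everything:

* **probabilities** p = f̂(0), evaluated in practice as
  p = Σ c · [(−K̃)^{-1}]_{b,a} by one LU solve (exact to machine precision);
* **conditional CDF for simple eigenvalues** λ_k of K̃:

      F(t) = 1 + (1/p) Σ_k  N(λ_k) / (λ_k Π_{j≠k}(λ_k − λ_j)) e^{λ_k t};

* **tridiagonal full-span arrival** (no bypasses): the minor M_{1,m} is the
  constant product of the one-step rates, so the conditional arrival law is
  the convolution of exponentials with rates |λ_k| — the same in both
  directions, which is why the two first-arrival distributions of any
  bi-directional chain coincide even when the rates are biased.  The two
  first-return laws use the corner minors M_{1,1}(s) and M_{m,m}(s) and are
  *not* direction-symmetric in general;
* **bypasses** put entries outside the tridiagonal band: minors become
  genuine determinants (evaluated directly; the tridiagonal three-term
  continuant recurrence is used, and cross-tested, for the corner minors of
  banded blocks) and eigenvalues may form complex-conjugate pairs.  The
  residue expansion is unchanged; conjugate terms combine to damped
  cosines, and evaluated CDF values are real to < 1e−9;
* **degradation** only adds to the diagonal of K̃ and contributes extra
  absorption channels.  The *expressions* above are untouched; the
  eigenvalues and therefore the numerical laws do change (a killed walker
  population is time-tilted), and the event probabilities pick up a
  degradation mass p_deg = 1 − p_r − p_a;
* **synthesis of an intermediate** ∅ → S_i becomes one delayed synthesis
  per reachable SOI, weighted by the arrival probabilities from S_i, with
  the first-arrival-from-S_i delays; the killed fraction emits nothing;
* **initial molecules on intermediates** are translated into a *delay
  history*: per molecule, a fate is drawn from the first-passage
  probabilities of its species and a completion time from the matching
  conditional law; the drawn updates seed the DSSA queue.

### Representation fallbacks

The closed forms assume simple eigenvalues.  The engine picks, in order:

1. **stage convolution** (hypoexponential) whenever the block is
   uni-directional and the outcome is a single channel down the chain —
   valid for arbitrary rate multiplicity (the relevant case in practice:
   equal-rate cascades such as the proofreading chain, eigenvalue
   −(k_p+k_-1) with multiplicity N).  Repeated stage rates are evaluated
   through the phase-type matrix exponential rather than partial fractions;
2. **residue form** when the eigenvalues are simple (relative gap
   ≥ 1e−8 × spectral radius);
3. **tabulated numeric CDF** otherwise (e.g. the mixture-type dissociation
   delay of the proofreading model), from the matrix exponential of the
   absorbing-augmented block generator, flagged via `fallback_reason` —
   never a silently wrong closed form.

Bi-directional tridiagonal blocks with positive rates are similar to
symmetric Jacobi matrices, so their spectra are automatically real and
simple; the fallbacks only trigger for partially uni-directional chains.

### Numerical choices

* Numeric tabulations use a geometric grid of 512 points from
  t_min = 0.01/max|λ| to t_max = ln(1/ε)/min|Re λ| with ε = 1e−9 of
  transient mass (t_max doubles until verified), monotone interpolation in
  between.
* Quantiles solve the monotone CDF by bracketed Brent iteration to ~1e−15;
  bulk sampling inverts an 8192-point tabulation of the CDF (the
  stage-convolution form is instead sampled exactly as a sum of
  exponential draws).  `quantile(1.0)` raises — the support is unbounded.
* Eigenvalue simplicity tolerance: relative gap below 1e−8 × spectral
  radius counts as non-simple (residues become numerically unstable near
  degeneracy).
* DSSA tie-break: a queued completion at exactly the tentative firing time
  wins (ties have probability zero; a fixed rule keeps runs reproducible).
  Pending completions beyond the horizon are dropped from the reported
  state — molecules in transit are invisible to SOI marginals.
* One seeded generator per run drives history construction first, then the
  firing-time/selection/delay draws of the main loop.
* Probability-zero branches (p < 1e−12) are dropped from abridged models.

## Simulators

`ssa_direct` and `dssa_rejection` are readable event-recording reference
implementations.  Ensemble statistics run through numba-compiled kernels of
the identical algorithms (`delaylump._kernels`) that record state on a fixed
observation grid; delayed reactions carry their sampler into the kernel as
either stage rates (sampled exactly) or a 4097-point inverse-CDF table
(linear interpolation on the uniform probability grid, truncated at
1 − 1e−7).  Reference and kernel paths are compared distributionally in the
test suite.  The propensity table supports mass action (unimolecular,
bimolecular, identical-pair, zero-order) plus one declared non-mass-action
law, the Hill-repressed PFK propensity of the glycolysis model.

## Worked systems and what the fixtures emulate

* **Bypass chain** — 10 species S0..S9, fully bi-directional, one forward
  (S2 → S6) and one backward (S7 → S3) bypass, SOIs {S0, S9}, 200 molecules
  started on S9.  The shipped rates (forward 1.5, backward 1.0, bypasses
  0.5/0.4) are synthetic, documented defaults in the order-one regime; every
  check on this system is rate-agnostic.  Both the two-SOI abridgement
  (two first-return loops + two first-arrival links) and the single-SOI
  abridgement (one loop whose return law also counts walks touching the far
  end — measurably different from the two-SOI loop law) are exercised.
* **Glycolysis** — a minimal autocatalytic scheme: PFK invests q = 2 ATP
  (species Y) per firing with the ATP-inhibited propensity
  V/(1 + (Y/(φV))^h), feeding X1 → X2 → X3 → X4 at rates g_i = 2, the final
  step returning 2q ATP; demand removes ATP at γY.  Defaults V = 500,
  φ = 0.5, q = 2, h = 5, γ = 2, Y(0) = 100, horizon 40.  φV = 250 acts as
  the ATP homeostasis set-point; with the two-unit pathway lag the system
  sustains large glycolytic oscillations, which makes the exactness test
  demanding.  Intermediate degradations (rates h_i = 1) and a basal ATP
  synthesis (g_y = 0.5) are carried as parameters of the extended variant
  but excluded from the minimal scheme, whose abridgement is exactly one
  delayed reaction (qY → 2qY with the four-stage Exp(g) convolution delay,
  mean 2.0) plus the non-delayed demand.
* **Kinetic proofreading** — T + M bind at k_1 = 1 into C0; complexes
  mature C_i → C_{i+1} at k_p = 5 against dissociation C_i → T + M at
  k_-1 = 0.25, N = 6 steps, T(0) = M(0) = 200.  The completion probability
  from C0 is p = (k_p/(k_p+k_-1))^6 ≈ 0.74622 and the conditional
  completion delay the 6-stage convolution of Exp(5.25) (mean 8/7).  The
  abridgement retains C0 (keeping both delay laws atom-free at zero):
  binding and the first-step dissociation are carried over; two delayed
  reactions out of C0 produce C6 (rate k_p·(k_p/(k_p+k_-1))^5 = (k_p+k_-1)p,
  5-stage delay) or regenerate T + M (the complementary rate, with the
  tabulated conditional dissociation delay).

The synthetic generator (`random_chain`) emulates well-mixed mass-action
chains with time-homogeneous rates in [0.5, 5]; it does not emulate
time-varying rates, spatial structure, or general bimolecular coupling, so
passing tests certify the reduction machinery, not the fit of any fixture
to a particular measured pathway.

## Validation design

Every closed form is triangulated twice: against the matrix-exponential
tabulation (sup-norm below 1e−8, in practice ~1e−13, over ≥ 50 seeded
chains, n = 3..12, with and without bypasses and degradations) and against
10^5-walker first-passage samples (KS at α = 0.01; event frequencies inside
99% binomial bands, degradation included).  Exactness of the reduction is
asserted by comparing 1000-run SSA ensembles of the full models with
1000-run DSSA ensembles of the abridged models (glycolysis: 2000 runs) at
20 checkpoints — |z| < 3 on SOI means, terminal chi-square p > 0.01 with
bins merged to expected counts ≥ 5.  Null calibration shows same-model
comparisons at these sizes occasionally exceed |z| = 3 by chance, so every
stochastic assertion retries once with a fresh documented seed; a second
failure is a real failure.  Ensemble sizes and walker counts are the
package's validation defaults, chosen to keep the whole suite desk-scale
(a few minutes on one CPU).

## Limitations

* Bypass reactions *consuming* an SOI are rejected (the abridgement would
  need two extra delayed reactions whose laws this package does not
  implement); bypasses *producing* an SOI are handled by the multi-channel
  residue machinery.
* Non-simple spectra outside the uni-directional case fall back to numeric
  tabulation; no symbolic treatment of defective eigenvalue structures.
* One chain block per model: composing several lumped blocks is done by
  abridging manually block by block.
* The deterministic delay-differential-equation analogue of the reduction
  is out of scope, as are tau-leaping variants and wall-clock benchmarking.
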