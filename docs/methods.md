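# Methods

This note records the model, the estimation and interrogation procedures,
the free constants and their defaults, what the synthetic data do and do not
emulate, and the numerical choices a maintainer would need to know.

## Model formulation

A reaction network is an ordered species list and an ordered list of
irreversible mass-action reactions; reversible reactions are split into
independent forward/reverse steps before any computation.  The dynamics are

    dx/dt = S · r(x, k),    r_j(x, k) = k_j · Π_{s ∈ reactants(j)} x_s^σ_sj

with the reactant stoichiometric coefficient used literally as the kinetic
exponent, including coefficients > 1.  Zeroth-order sources return the bare
rate constant; empty product lists are sinks.  Compartments are carried as
labels but treated as unit volume — no volume factor enters any rate.  The
Jacobian ∂(S·r)/∂x and parameter-derivative matrix ∂(S·r)/∂k are assembled
analytically from the same flat reactant-triple structure that evaluates the
rates; both are verified against central finite differences in the tests.

The SBML reader accepts a deliberate Level-2 subset: species with initial
amounts, reactions with reactant/product references, a reversible flag and a
kinetic law reducible to a single rate constant (or a kf/kr pair).  Events,
rules, function definitions, constraints, initial assignments and modifiers
raise explicit errors rather than being skipped: the model class is pure
mass action, and silently approximating a foreign rate law would corrupt
every downstream derivative.  A plain-text format (`R1: A + 2*B -> C ;
k=0.1`, `<->` with `kf=, kr=`, bare `A = 1.0` lines for initial amounts)
supports desk-scale authoring; both formats round-trip.

## Simulation protocols

Integration uses LSODA (stiff-capable, analytical Jacobian supplied) at
rtol 1e-6 / atol 1e-9.  Hormone-stimulation experiments are two-phase: relax
to the pre-stimulus steady state, add the stimulus amount to the stimulus
species (no clamping — ligand consumption is part of the model), record the
response over a 100-minute horizon.  Time is in minutes throughout.

Steady states are detected by integrating successive windows of length Δt
and accepting the first state whose distance to the previous window
endpoint falls below ε.  ε = 0.001 in every run; Δt defaults to 1.0 min and
is a config key, since only detection granularity (not the criterion)
depends on it.  The norm is Euclidean by default, max-norm selectable.  The
declared state tracks the true fixed point to roughly ε amplified by the
slowest relaxing mode, which is why code that needs tighter agreement (the
linear-chain oracle test) widens Δt rather than shrinking ε.

Tiny negative excursions are an LSODA artifact near zero; trajectories are
clipped at 0 on output, and only excursions beyond 1e-4 of the trajectory
scale are treated as integrator failure.

Knockdowns remove every reaction in which the target participates (as
reactant or product) and zero its initial condition — node removal from the
stoichiometric matrix, not mere concentration zeroing, so synthesis routes
cannot regenerate the species.  Inhibitor conditions multiply selected rate
constants (usually by 0); both are declared per condition in the run config.

## Objective scoring

Within each training dataset, measurement and simulated readout are min-max
scaled independently and compared by summed squared error at the measured
points (simulation linearly interpolated).  Scaling is per-objective, over
that objective's time points or condition bars, making the error invariant
to positive affine transforms of either series — appropriate for relative
band intensities.  Exactly constant series map to all zeros (flat basal
controls are legitimate data); series whose range is below 1e-9 of their
magnitude are treated the same, otherwise solver-level noise would be
normalised up to a full-range shape.  A readout may sum several species
(one blot band can pool complexes); the mapping lives in the objective
file.  Simulations are cached per unique condition within an evaluation, and
steady-state searches warm-start from the previous evaluation's solution —
results for identical call sequences are bit-reproducible, while calls with
different histories agree within the steady-state tolerance.

## Ensemble estimation (POETs)

Fitness is the Fonseca–Fleming Pareto rank: the number of archived error
vectors that dominate the candidate (rank 0 = nondominated), ranked against
the archive only.  Acceptance probability is exp(−rank/T), hence always 1
at rank 0.  The temperature is discretised into 10 quanta descending
geometrically from T0 to T_final = 0.1; the epoch counter (and quantum
index) advances after every `epoch_size` archive additions, and the archive
is exactly re-ranked at each epoch and at the end of the run.  T0 defaults
to 10× the initial candidate's largest objective error.  Candidate moves
multiply every parameter by an independent Uniform[1−m, 1+m] factor,
m = 0.25 by default; initial conditions are perturbed alongside rate
constants unless frozen by flag.  Every `pattern_search_interval` accepted
steps (default 10) a coordinate-polling pattern search (multiply/divide by a
step factor, accept improvements, shrink on failure) refines the current
point on one randomly selected objective; it can only reduce that
objective's error.  All schedule constants are config keys and are logged
with the archive.

Two structural notes.  First, the uniform multiplicative move has a negative
log-mean (E[ln(1+u)] < 0 for u ~ U[−m, m]), so a long weakly-constrained
walk drifts parameters downward; data constraints and the pattern search
tether it, and the sub-ensemble selection (below) restores coverage of the
generating parameters.  Second, with ~20 objectives dominance is rare, so
most accepted members are rank 0 — the rank-0 set is a broad population,
not an elite, which is why selection weighs error alongside diversity.

Leave-three-out cross-validation partitions the 24 objectives into 8
disjoint folds (21 train / 3 validation); each fold runs an independent
POETs instance and validation errors are computed post hoc.  Sub-ensemble
selection starts from the rank-0 entry nearest the origin in error space
and greedily adds, from random candidate draws, the entry minimising the
sum of (i) its mean signed Pearson correlation with the already-selected
members, computed on log10 rate constants because the constants span
decades, and (ii) its error-vector norm scaled by the pool median.  Signed
(not absolute) correlation is used: anticorrelated members are maximally
diverse.  The achieved mean pairwise correlation is reported.  A
random-parameter control draws rate constants log-uniformly within ±1
decade of nominal (initial conditions optionally randomised the same way)
and provides the baseline against which training errors are judged.

## Sensitivity analysis and fragility ranking

For each ensemble member the augmented system ds_j/dt = J·s_j + B_j is
integrated over the response phase with s_j(0) = 0 (sensitivities of the
post-stimulus response; the steady state's own parameter dependence is not
propagated).  Coefficients are scaled to dimensionless log-sensitivities
(k_j / max(x_i, δ)) · ∂x_i/∂k_j with δ = 1e-6 guarding zero concentrations,
then trapezoid-averaged over a window and divided by its length.  Member
matrices are stacked into an array (parameters × members·species) and
decomposed by SVD; an index is marked in a singular vector when its
coefficient magnitude exceeds a threshold, and its score is the fraction of
the leading k vectors in which it is marked.  Left vectors score parameters
(reactions), right vectors score species, aggregated over member blocks.
k defaults to the number of singular values capturing 95% of spectral
energy; the threshold defaults to 0.001.  On the 29-species toy network
unit-norm singular vectors have typical coefficients ~0.2, so toy-scale
analyses and tests use threshold 0.1 to discriminate — both are config
keys.  Per-member rankings give a mean and one standard error per species;
the pooled-array score is reported alongside.  Whether a published "rank"
axis is this raw fraction or a further normalisation is ambiguous; the
fraction is exported.

## Robustness screening

The robustness coefficient of a perturbation is the trapezoid integral of a
marker species over the protocol window in the perturbed run divided by the
nominal run; the marker defaults to the assembled-80S proxy and the window
to the full 0–100 min horizon.  The screen evaluates every (member, target,
condition) cell; a target may be a tuple knocked down together (both
nucleotide states of Rheb, both PI3K forms).  Effects are classified from
the member-median m: increase (m > 1+δ), none (|m−1| ≤ δ), moderate
decrease (c_sev < m < 1−δ), severe decrease (m ≤ c_sev, boundary closed).
δ = 0.1 and c_sev = 0.25 are config keys printed in every report header; the
median is used because documented ensemble subpopulations behave
qualitatively differently and would distort a mean.  Sub-population reports
expose raw counts at fixed cutoffs (direction, two-fold change) rather than
hardcoding a significance threshold, and a convergence report recomputes
categories over nested member subsets (50/100/200/all) and flags flips.

## The synthetic study system

The toy network (29 species, 33 reactions) preserves the pathway's control
structure: ligand–receptor activation, IRS-1 adaptor, PI3K with a small
basal activation rate, PIP2→PIP3 opposed by PTEN, Akt, TSC inhibition,
Rheb-GDP/GTP cycling whose loading consumes an explicit finite GTP pool,
mTORC1/mTORC2, S6K1, 4E-BP1 phosphorylation releasing eIF4E with a slow
mTORC1-independent release leak, GTP-consuming 80S assembly, and removable
S6K1→IRS-1 feedback.  Inhibitor analogues zero the target activation rates
(wortmannin: PI3K activation; rapamycin: mTORC1 catalysis) instead of
introducing drug species.  The truth rate constants were hand-tuned once to
place the system in the regime of interest — basal initiation restrained by
PTEN, induced initiation through PI3K, minute-scale relaxation — and are
frozen; tests never regenerate them.  A strong-Rheb variant (10× Rheb–GTP
association, reduced GTP supply) realises the GTP-limited regime in which a
Rheb knockdown paradoxically *raises* initiation by releasing the
nucleotide pool.

Training data are 16 eight-point time courses and 8 condition-comparison
bar sets over six conditions (±insulin, both inhibitors, feedback off),
sampled from the truth model and multiplied by lognormal noise
(mean 1, default CV 0.1, standing in for blot quantitation error).  Each
objective was designed to be informative — readouts pinned at zero under
their own condition, or exactly conserved species sums, carry no shape
information after min-max scaling and were excluded when the plan was
frozen.  What the generator does *not* emulate: cell-line heterogeneity
across datasets, digitisation artifacts, correlated (gel-wide) measurement
error, and absolute concentration scales.  Passing recovery tests therefore
show the estimation machinery works on data of this structure, not that the
biological parameters of any real cell line are identifiable.

The end-to-end recovery harness runs, at desk scale, 2 of the 8
cross-validation folds with 600 POETs iterations each (epoch size 50,
steady-state budget 300 windows), starting from the truth parameters under
a 30% multiplicative jitter — the analogue of starting from an initial
best-fit set.  It reports truth coverage by the sub-ensemble's [5, 95]
percentile intervals, fold-aware training-vs-random error comparisons (an
objective's training error comes only from members of folds that trained
it), held-out validation errors, and the knockdown switch table.  These
problem sizes are the package's default desk-scale configuration; all are
parameters of the harness.

## Known limitations

- First-order, local sensitivities only; no adjoint or global (Sobol)
  methods.
- The archive grows without pruning; very long runs re-rank lazily per
  epoch, so instantaneous ranks between epochs can be stale.
- The Fonseca–Fleming variant ranks candidates against the archive only,
  not against the current generation.
- Knockdowns are complete; no partial or dose–response knockdowns, no
  double-knockdown combinatorics.
- The SBML subset is intentionally narrow (pure mass action); full-standard
  documents with rate laws outside the subset are rejected, not coerced.
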