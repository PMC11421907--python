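# Methods

## Model

`rangesse` models the joint evolution of a clade's phylogeny and geographic
ranges as a continuous-time Markov process. The state of a lineage is the
non-empty set of areas it occupies, capped at `M` areas
(`sum_{k=1..M} C(N,k)` states over `N` areas; states are ordered by range
size, then ascending bit pattern, so indices are stable across runs and in
all serialized output). Five rates act:

* **Anagenetic** (along branches): dispersal adds one area at total rate
  `d * |S|` into each unoccupied area (each occupied area is an independent
  colonization source at the uniform per-pair rate `d`, the DEC convention);
  extirpation removes one area at per-area rate `e`, and only from ranges of
  two or more areas — a single-area lineage cannot be removed anagenetically.
* **Cladogenetic** (at nodes): in-situ speciation at `lambda_is` *per event*
  (a single-area parent duplicates itself; under DEC a widespread parent of
  `k` areas additionally buds each member area as a single-area daughter, so
  its total in-situ rate is `k * lambda_is`), and vicariance at `lambda_vic`
  *per unordered bipartition* of the range into two non-empty complementary
  daughter ranges. DEC restricts vicariance to bipartitions with a
  single-area side; DIVA allows all bipartitions and drops the widespread
  in-situ (subset-sympatry) events. No per-state normalization of
  cladogenetic rates is applied: the two conventions are then literally two
  arrangements of the same four parameters, and their likelihoods are
  directly comparable. (The alternative convention — dividing `lambda_vic`
  equally among a parent's bipartitions — is equally self-consistent; the
  choice made here is recorded in all pipeline output metadata.)
* **Lineage extinction** `mu`: an instantaneous loss of the lineage across
  its entire range, regardless of range size. `mu` is a fixed input,
  deliberately not estimated — tree-only estimates of extinction are
  notoriously near zero and in conflict with the fossil record, so the
  protocol explores fixed levels instead (below).

Assumptions worth stating: rates are uniform across areas and through time
(no time-stratified connectivity, no per-area speciation/extinction, no
founder-event "jump" dispersal at nodes); the tree is binary, rooted and
time-calibrated; sampling of extant tips is uniform with fraction `rho`
(default 1).

Consequence of the model structure, useful as intuition and exploited by the
tests: the per-state probability of leaving no sampled descendants, `E_i`,
does **not** converge to a common value on long branches — widespread states
carry more cladogenetic events, survive more often, and so have strictly
smaller `E` limits than single-area states.

## Likelihood

Standard SSE pruning: tips are initialized `D_i = rho * [i = observed]`,
`E_i = 1 - rho`; the coupled E/D system is integrated backwards in time
along every branch; daughters combine bilinearly over the cladogenetic table
at nodes (unordered events summed over both daughter assignments, the
symmetric case counted once, matching the single `lambda E_l E_r` term in
the E equation); at the root, states are averaged with data-proportional
weights `w_i = D_i / sum_j D_j` by default (uniform weights available), and
the likelihood optionally conditions on survival of both crown lineages by
dividing by `sum_i w_i (1 - E_i)^2`. Both root choices are conventions, not
facts about the data; the pipeline records them in its run metadata. With
one area the whole machinery reduces exactly to the closed-form constant-rate
birth–death likelihood, which is both a unit test and the basis of the
`BD_mu` calibration.

### Numerics

Two engines share the equations:

* **checkpoint** (default): since `E(t)` does not depend on the data, it is
  solved once per parameter set on `[0, root age]` (LSODA, rtol 1e-8 / atol
  1e-10, dense output). Given `E(t)`, the D system is *linear* with
  time-varying coefficients, so branches are propagated through a global
  time grid whose cells each carry a 4th-order commutator-free Magnus
  propagator (two Gauss nodes, two matrix exponentials per cell). All
  branches crossing a cell advance with one matrix–matrix product, which is
  what makes 63-state, 100-tip likelihoods cost tens of milliseconds. Cell
  width defaults to `min(T/60, 0.2 / max total rate)`; the scheme is exact
  whenever `E` is constant (e.g. `mu = 0` at complete sampling). Per-branch
  rescaling of `D` with accumulated log factors prevents underflow on deep
  trees; the factors cancel exactly in reconstruction.
* **ode**: classic per-branch adaptive LSODA on the joint (E, D) system,
  kept as an internal reference. The engines agree to ~1e-6 log units at
  moderate rates and ~1e-4 at extreme extinction (`mu` several times the
  speciation rate), which bounds the default engine's accuracy envelope.

During maximum-likelihood fitting the integration grid is **frozen per fit**
(cell width from the a-priori scale `mu_fixed + 6 * lambda_heuristic`): a
parameter-dependent grid makes the objective piecewise-constant at the
1e-6 level and defeats finite-difference gradients. Optimization is
L-BFGS-B on the four log-rates, bounds `[1e-6, 1e2]` events/Myr, `ftol`
1e-8 and finite-difference step 1e-6 (matched to the engine's precision),
one heuristic start (a Yule-style rate estimate) plus seeded log-normal
perturbations (5 starts by default). Degenerate inputs — zero-height trees,
missing tip ranges, non-binary nodes, negative branch lengths — raise typed
errors before any integration; trees deviating from ultrametric by more than
0.1% of their height warn but run, since empirical chronograms carry
rounding noise.

## Scenario protocol

`run_scenarios` fits a standard birth–death model (crown age given,
conditioned on survival), names its speciation-rate estimate `BD_mu`, and
fits all eight cells `{0, BD_mu/10, BD_mu, 10*BD_mu} x {DEC, DIVA}` — the
premise being that extinction has plausibly been nearly as frequent as
speciation, with the low/high levels bracketing it. Per level the
higher-likelihood model is marked selected, ties broken toward DEC (recorded
as a tie). A fitted total speciation rate below the assumed `mu` raises a
warning flag, not an error. AIC is emitted for reference only — both models
have four free parameters.

## Reconstruction

Marginal ancestral ranges are *defined* by the clamp oracle: the probability
of state `i` at node `v` is the likelihood recomputed with `v` restricted to
`i`, renormalized over states, **with the root weights and the conditioning
factor frozen at their unclamped values**. Freezing makes the likelihood
linear in any single node's D vector, which has two consequences: the
clamped likelihoods sum exactly to the unclamped likelihood, and all
marginals can be computed in one root-to-tips adjoint pass (transposed cell
propagators, bilinear node adjoints) instead of `nodes x states` re-runs.
The brute-force clamped recomputation stays available
(`compute_loglik(..., clamp=...)`) and is the oracle the pass is tested
against.

A calibration point that matters for interpretation: the root weighting is a
convention, not a prior, and the posterior it induces at deep nodes is only
calibrated against a generative truth when the weighting *matches* how the
clade actually started. With data-proportional weights, deep-node marginals
skew toward widespread ranges (widespread states carry higher total
speciation, hence higher data likelihood), and in simulations started from a
single-area stem ancestor the modal root state is then usually a widespread
superset of the truth. The recovery studies therefore use crown-started
simulations (the crown split at a known time, both crown lineages
conditioned to survive — the likelihood's own conditioning) analysed with
the generating singleton prior as explicit root weights; under that matched
design the crown posterior is calibrated (mean probability on the truth
0.76 vs the posterior's self-expected 0.74 over 50 replicates) and the
modal state recovers the truth in ~84% of clades. `SimConfig.crown_start`
exists for exactly this purpose.

The clade origin summary thresholds the root's per-area presence
probabilities (sum of state probabilities over ranges containing the area)
at 0.5 by default; when no area passes, the single most probable root state
is reported instead. The full root distribution is always emitted — the
threshold is a display convention, not an inference.

Richness through time evaluates, on a uniform grid from the root age to the
present (100 slices by default), each surviving branch's conditional state
distribution at the slice time — the slice times are inserted into the
integration grid, equivalent to exact degree-2 node insertion, with no
interpolation between node marginals — and sums per-area presence
probabilities over contemporaneous branches. Expected richness therefore
counts *reconstructed* (sampled-survivor) lineages only; extinct lineages
shape the result through the E terms, not the tally. At `t = 0` the profile
equals the observed per-area tip counts identically; at the root-age slice
the single crown ancestor is represented by the root marginal.

## Forward simulator

The simulator realizes the same generative process with per-lineage
competing exponential clocks over the same event tables (exact Gillespie;
hazards recomputed after every event, no tau-leaping) — a requirement, since
it doubles as the likelihood's independent oracle: conditioned 2-tip outcome
frequencies over 1e5 replicates must match normalized pruning likelihoods
within Monte-Carlo error. Stop rules: a fixed time horizon, a cap on extant
lineages (the horizon is then the moment a cladogenesis event would exceed
the cap; the event is not applied — this conditions the final interval on
ending at a speciation attempt, an effect that is negligible here because
the expected extra window is one inter-event time across the whole clade),
or both. Conditioning on a minimum number of survivors (default 2) is by
rejection with the retry count reported, since silent conditioning would
bias the calibration checks. The root state defaults to a uniform draw over
single-area states: a widespread ancestor should be a finding, never an
assumption. Pruning removes extinct leaves and suppresses the resulting
degree-2 nodes with branch lengths merged, preserving extant divergence
times exactly; the recorded "crown state" truth is the simulator state at
the earliest node with sampled descendants on both sides, which is the
quantity a reconstruction on the pruned tree can be compared against.

### What the synthetic data do and do not emulate

The packaged presets mirror the empirical setting the method targets:
`iaa7_small` uses the seven Indo-Australian areas, `M = 3`, intermediate
lineage extinction (`mu = 0.1`/Myr against `lambda_is = 0.25`), ~60 extant
tips over ~10 Myr, and produces tip ranges dominated by one or two areas, as
in the region's real clades; `two_area_geosse` is the classic three-state
system; `single_area_bd` collapses to plain birth–death. The generator
shares the model's assumptions — uniform rates across areas and time,
complete sampling, no fossils — so passing recovery tests demonstrate
internal consistency and estimator behaviour *under the model*, not
robustness to rate heterogeneity, area asymmetries, incomplete sampling or
model misspecification in real data.

## Study sizes and open choices

Recovery studies use 30 simulated four-area clades of 100–200 tips at
(`lambda_is=0.25, lambda_vic=0.05, d=0.05, e=0.02, mu=0.1`)/Myr with `mu`
fixed at truth (median relative error targets: 30% for `lambda_is` and `d`;
`e` is weakly identified at these sizes and routinely collapses to its
bound), and 50 clades of 150 tips at
(`lambda_is=0.3, lambda_vic=0.05, d=0.03, e=0.01, mu=0.05`) for crown-state
recovery; `lambda_vic` in the latter set is this package's choice, made once.
The structural scenario-grid checks run on the three-state fixture, where an
8-cell grid costs a minute rather than ten. The acceptance script reports
the same quantities at moderately reduced replicate counts, as measured
values rather than pass/fail assertions.

## Known limitations

* Rates are homogeneous in time and across areas; no time-stratified
  palaeogeography, no jump dispersal, no per-area extinction.
* `mu` is not estimable from the tree within this framework by design;
  conclusions are conditional on the assumed extinction level.
* Extirpation (`e`) is near-unidentifiable at realistic clade sizes when
  ranges are narrow; treat its point estimates with caution.
* `lambda_is` carries a modest (~8% at 100–200 tips) downward finite-sample
  bias: the likelihood marginalizes over latent range sizes, the total
  in-situ rate of a k-area lineage is `k * lambda_is`, and reconstructed
  widespread occupancy runs slightly high, trading off against `lambda_is`.
  A single-area control (plain birth–death, `mu` pinned) shows no bias, so
  this is a property of the multi-area model, not of the optimizer or
  integrator. Median relative errors stay near 10%.
* Deep-node marginals under data-proportional root weighting lean toward
  widespread ranges (see the calibration note above); report the full root
  distribution, not just the mode.
* Marginal (not joint) reconstruction: per-node distributions are each
  optimal marginally and need not assemble into a coherent single history.
* The checkpoint engine's accuracy degrades to ~1e-4 log units when `mu`
  exceeds the speciation rate severalfold; the `ode` engine is available
  where tighter control is needed.
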