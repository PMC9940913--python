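# Methods

## The model

A compositional restricted Boltzmann machine (cRBM) is a maximum-entropy
model of binary neural population activity. `N` visible units `v_i ∈ {0,1}`
(one per recorded neuron) are coupled to `M` real-valued hidden units
`h_μ` through a weight matrix `w` on a bipartite graph — no direct
neuron–neuron or hidden–hidden couplings. The joint energy is

    E(v, h) = − Σ_i g_i v_i + Σ_μ U_μ(h_μ) − Σ_{i,μ} w_{i,μ} v_i h_μ

with the double-rectified-linear (dReLU) hidden potential

    U(h) = ½ γ₊ h₊² + θ₊ h₊ + ½ γ₋ h₋² + θ₋ h₋ ,  h₊ = max(h,0), h₋ = min(h,0).

Depending on its four parameters, U is quadratic (the model then reduces
exactly to a pairwise Hopfield model with couplings
`J_ij = Σ_μ w_iμ w_jμ / γ_μ`), ReLU-like, or a double well, in which case
the hidden unit's activity is bimodal — an assembly that switches between
a silent and an active mode.

Because the graph is bipartite both conditionals factorise:
`p(h_μ | v)` is a two-branch truncated-Gaussian distribution driven by
the input `I_μ = w_μᵀ v`, and `p(v_i | h)` is a Bernoulli with logit
`g_i + w_iᵀ h`. Marginalising the hidden layer gives the closed form
`log P(v) ∝ gᵀv + Σ_μ Γ_μ(I_μ(v))` where `Γ(I)` is the cumulant
generating function of the dReLU potential. `Γ′(I)` and `Γ″(I)` are the
conditional mean and variance of the hidden unit; `Γ′` is the
deterministic "hidden trace" used whenever latent activity is computed
from data.

### Numerical realisation of Γ

`Γ` is the log of the sum of two truncated-Gaussian normalisers.  All
evaluations go through `scipy.special.log_ndtr` / `erfcx` / `ndtri_exp`,
which switch to asymptotically exact tail expressions internally, so Γ,
Γ′, Γ″ and the exact conditional sampler are finite for any finite
input (validated against adaptive quadrature to a relative 1e−8, and to
±1e6 inputs for finiteness). The mixture variance is assembled in the
cancellation-free form `p₊v₊ + p₋v₋ + p₊p₋(μ₊−μ₋)²`, which keeps
`Γ″ > 0` identically. Sampling picks the branch by its probability mass
and inverts the truncated-Gaussian CDF in log space — exact arbitrarily
deep in the tails, with no rejection step.

### Gauge freedoms

Two reparameterisations leave `P(v)` untouched and are used
deliberately:

* **Sign swap** (`h_μ → −h_μ`): negate the unit's weight column and
  exchange the branches with negated offsets, `(γ₊,θ₊) ← (γ₋,−θ₋)`.
  Note the offset negation: with both linear terms of `U` written with a
  plus sign, a plain parameter exchange is *not* an invariance.  Applied
  after training to all units with predominantly negative weights, so
  assemblies activate positively.
* **Unit rescaling** (`h_μ → h_μ/s`): `w → sw`, `γ± → s²γ±`, `θ± → sθ±`.
  Used by the hidden-unit normalisation below.

## Training

Parameters are fit by maximum likelihood with persistent contrastive
divergence (PCD). The gradient of the mean log-likelihood for every
parameter is a difference of sufficient statistics, e.g.
`∂L/∂w_iμ = ⟨v_i h_μ⟩_data − ⟨v_i h_μ⟩_model`, plus the L1 subgradient
`−λ sign(w)` on the weights. Data-side hidden statistics are conditional
expectations given the observed frames (Rao-Blackwellised — no sampling
noise on that side; the split is a design choice, made for stability).
Model-side statistics come from persistent fantasy chains advanced 15
alternating Gibbs steps per update. Updates use RMSprop (β₁ = 0,
β₂ = 0.999, ε = 1e−6) with a learning rate constant at first and then
geometrically annealed to 1e−5. Analytic gradients agree with central
finite differences of the exactly enumerated log-likelihood to a
relative 1e−5 on small systems.

Default hyperparameters follow the full-scale reference protocol
(100 chains, batch 100, λ = 0.02, initial rate 5e−3), except the number
of updates, which defaults to a desk-scale 20,000 (the full-scale
protocol uses 200,000 and is a one-line override).

### Sparsity warm-up

One scheduling element is added to that protocol: the L1 coefficient
ramps linearly from 0 to its nominal value over the first quarter of
training (configurable). The reason is structural: under RMSprop the
per-parameter step size is `≈ lr` whenever one gradient term dominates,
so with the full penalty active from the start and near-zero initial
weights, `w = 0` is an absorbing state — the correlation-driven gradient
(quadratic in the small weights) can never outgrow the constant penalty,
and training provably collapses to the zero-weight model. With the
warm-up the assemblies break symmetry first and are sparsified
afterwards; the final penalty is unchanged.

### Hidden-unit normalisation

Each update, every hidden unit is driven towards `Var(h_μ) = 1`,
`⟨h_μ⟩ ≈ 0` (estimated on the current batch with an EMA, β = 0.99): the
variance correction is the exact rescaling gauge above (no effect on the
modelled distribution), the mean correction is a damped offset shift
(damping 0.05) which does move within the model family and is therefore
gentle. This keeps units comparably scaled, prevents individual units
from dominating, and makes λ act uniformly across units. Units with
degenerate variance estimates are left untouched and logged.

### Divergence handling

If any gradient goes non-finite, or the weight spread exceeds a bound
(default std > 1.0), the run restarts from scratch with a halved initial
learning rate, at most 3 times, then fails loudly with a diagnostic
snapshot. A separate post-hoc screen (`convergence_check`) flags models
whose weight spread falls outside (0.01, 0.1) — the band used to select
converged full-scale models; desk-scale models with a few hundred
neurons legitimately sit above it.

## Evaluation

The likelihood is intractable at scale, so goodness of fit is measured
by comparing moment statistics — `⟨v_i⟩`, `⟨h_μ⟩`, `⟨v_i h_μ⟩` and the
mean-corrected `⟨v_i v_j⟩`, `⟨h_μ h_ν⟩` — between train data, withheld
test data and model-generated samples.

* **Splitting**: the recording is cut into 10 chronological segments;
  all C(10,3) = 120 choices of 3 test segments are ranked by
  train-vs-test RMSE over `[⟨v⟩; centered ⟨vv⟩]` and the split at the
  10th-percentile rank is used (near-best without overfitting the
  selection).
* **Model statistics protocol**: 300 chains started on random training
  frames, burn-in of 100 effective configurations, 50 saves per chain,
  20 Gibbs steps apart (all configurable). A burn-in "effective
  configuration" is read as one save interval (20 raw steps); the knob
  `burn_in_raw_steps` overrides that reading.
* **Sparsity correction**: the model-side `⟨v_i h_μ⟩` is offset by
  `λ sign(w_iμ)` (the penalty shifts the stationarity condition);
  entries with `w_iμ` exactly 0 are masked.
* **nRMSE**: `1 − (RMSE(model,test) − RMSE_shuf)/(RMSE(train,test) −
  RMSE_shuf)`; 0 = as good as the train/test gap, 1 = chance, negative
  values legal. The chance reference permutes the model statistics with
  one seeded permutation (permuting both sides with independent
  permutations is identical, since RMSE is invariant under any joint
  permutation).
* **Reconstruction**: per neuron, the Bernoulli log-likelihood of the
  deterministic round trip `v → Γ′(I(v)) → σ(g + Wh)`, normalised so
  the constant-rate (independent) model scores 0 and perfection scores 1.
  Probabilities are floored at 1e−7 only when the observed symbol would
  otherwise get probability below it, so the perfect-reconstruction
  identity `LLH = 0` is exact. The GLM baseline is an L2-penalised
  logistic regression per neuron (penalty quoted as λ_GLM, scikit-learn
  `C = 1/λ_GLM`, reference value 1000); it includes an intercept so that
  it nests the independent model the normalisation is anchored to.
* **Latent diagnostics**: the participation ratio
  `PR(x) = (Σx²)²/Σx⁴` (in [1, n]; the `PR/n` variant is used wherever a
  "PR × count" quantity is formed, which makes the two printed
  conventions of the ratio consistent). The compositional statistic is
  `m(t) = (PR/M)(h₊(t))·M` with `h₊ = max(h − h_inactive, 0)`; the
  inactive peak of each unit is the lower mean of a 2-component Gaussian
  mixture (10 restarts, fixed seed), the transition point the midpoint
  of the two means, with a unimodality flag when components merge. Time
  constants are median two-state oscillation periods (one negative +
  one positive run for hidden traces; one inter-spike + one spike
  interval for neurons). Hidden units are ordered by Ward clustering of
  `1 − r` on their trace correlations.

## Connectivity

The functional coupling between neurons i and j in the context of
configuration v is the in-silico perturbation statistic

    J_ij(v) = Δ_j [log-odds of v_i = 1 | rest of v]

(symmetric; zero for an independent model; equal to the Ising coupling
for a pairwise model, independent of v). Averaging over data frames
gives the exact estimator (cost `O(N²MT)`, guarded); the second-order
expansion `J_ij = Σ_μ w_iμ w_jμ ⟨Γ″_μ⟩_data` is the fast estimator,
exact in the quadratic limit (both verified identical there to 1e−8).
The neuron diagonal is fixed at 0.

Region aggregation takes the mean of `|J_ij|` over region-pair blocks
(within-region blocks exclude the i = j pairs from numerator and
denominator), drops regions with fewer than 5 neurons, and specimens
are combined with weights `T_F (N_r + N_r′)/2`. Covariance and Pearson
correlation matrices (diagonals zeroed) serve as baselines under the
same aggregation.

The structural estimator converts single-neuron morphology into a
region matrix: directed strength r→r′ = mean neurite length inside r′
of neurons with soma in r, divided by the volume of r′; symmetrised by
averaging the two directions. If one direction is undefined (region
without somata) the defined one is used; if both, the pair is masked.
The legacy variant `Σ_n (ℓ_n(r)+ℓ_n(r′)) / (N(V_r+V_r′))` also credits
pass-through neurites and has no defined diagonal. Regional occupancy
of an assembly is `L·|w_μ|` (absolute weights — membership regardless
of sign; the signed alternative would cancel inhibitory-like members),
with the effective region count `(PR/R)·R` and a thresholded count at
`|w| ≥ 0.15`. Matrix comparisons vectorise the strict upper triangle
under a shared mask, optionally log10-transform functional values for
Pearson, and exclude exactly-zero structural entries.

## Synthetic data

The generator emulates the regime the model targets: sparse binary
activity whose correlations arise from partially overlapping assemblies
with bimodal latent dynamics. A planted cRBM is built with
index-contiguous assemblies (optionally permuted), member weight 0.9
(±10% jitter), background weights 0.01, and per-unit double wells
(γ = 4, minima near ±1) whose silent well is deepened by a bias of 0.5
to counteract the mean excitatory drive of the members. This places the
dynamics in a deliberately sub-critical regime: the
assembly-to-itself feedback gain stays below 1, so an active assembly
elevates its members' firing ~10× (≈0.15 vs ≈0.015 per frame) rather
than saturating, and assemblies are active ~10% of frames with fast
on/off switching. A global offset of the visible fields is calibrated
by short Gibbs runs until the sampled mean activity enters the target
band (0.03–0.07, aiming at 0.05); the calibration takes small clipped
logit steps because the collective dynamics is hysteretic. The default
benchmark is N = 200 neurons, 10 assemblies of 20 neurons with 10%
overlap, T = 20,000 frames.

Planted anatomy assigns each assembly's members round-robin to
`regions_per_assembly` consecutive regions (an `alignment` knob
interpolates to fully random assignment) and draws neurite lengths so
soma-resident neurons project into the other regions of their assembly;
the ground-truth structural matrix is by construction the direct
estimator applied to that morphology.

What the generator does *not* emulate: calcium indicator dynamics and
deconvolution noise (the pipeline starts at binarised spikes),
anatomical spatial structure beyond region labels, non-stationarity,
and behavioural covariates. Passing the recovery benchmark therefore
demonstrates correctness of the estimation machinery under the model's
own assumptions, not robustness to real-recording artefacts.

### Benchmark training protocol

The benchmark fit uses `crbm.synthetic.benchmark_training_config`:
M = 15 hidden units, λ = 0.005 ramped over the first half of training,
annealing from 2e−3 after 50% of 20,000 updates, batch 200, 200 chains.
M and λ are the two quantities the method itself selects per dataset by
cross-validation; at this problem size the full-scale values (M = 200,
λ = 0.02, tuned on a ~41,000-neuron recording) are not transferable —
λ = 0.02 prunes entire hidden units here. The modest unit surplus
(15 units for 10 planted assemblies) mirrors full-scale practice, where
M safely exceeds the expected assembly count so that unit attrition
during sparsification cannot leave an assembly unrepresented. Recovery
is scored by sign-invariant cosine similarity between planted and
learned weight columns under optimal one-to-one assignment.

## Problem sizes used by the test suite

Exact-enumeration oracles run at N ≤ 10, M ≤ 3 (2^N states); sampler
z-tests use 10⁶ Gibbs samples with autocorrelation-inflated standard
errors; the recovery benchmark runs the full N = 200 / T = 20,000 /
20,000-update fit once (minutes on one core) and shares the fitted
model across the dependent checks.

## Known limitations

* Likelihood values are only available by enumeration (N ≤ 20); there
  is deliberately no annealed-importance-sampling estimator.
* PCD convergence is not guaranteed; the divergence-restart policy and
  the weight-spread screen mitigate but do not remove this (full-scale
  practice trains several replicas and screens them).
* The GLM baseline is O(N) logistic regressions and is meant for
  subsets of neurons at realistic N.
* `hu_normalization`'s mean correction is heuristic (damped θ shift);
  only its observable target (Var ≈ 1, mean ≈ 0) is contractual.
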