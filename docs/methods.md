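# Methods

`eitune` implements a multiscale brain-modeling pipeline in three layers:
a whole-brain dynamic mean-field network whose long-range excitation and
feedforward inhibition are tunable per connection, an online learning rule
that fits the network's simulated functional connectivity (FC) to an
arbitrary target FC, and a four-population frontoparietal circuit for
decision-making (DM) and working memory (WM) that can be driven either by
synthetic noise or by the large-scale model's synaptic currents.

## Large-scale model

Each node holds a reduced Wong–Wang excitatory/inhibitory pair.  Input
currents (nA):

    I_E_i = W_E*I_0 + w_plus*J_NMDA*S_E_i
            + J_NMDA * Σ_j w_LRE_ij C_ij S_E_j − J_i S_I_i
    I_I_i = W_I*I_0 + J_NMDA*S_E_i
            + J_NMDA * Σ_j w_FFI_ij C_ij S_E_j − S_I_i

with the sigmoidal transfer r(I) = (aI−b)/(1−exp(−d(aI−b))) per
population and gating dynamics

    dS_E/dt = −S_E/τ_E + (1−S_E) γ_E r_E + σ ν(t)
    dS_I/dt = −S_I/τ_I + γ_I r_I + σ ν(t).

C is the structural connectome (nonnegative, zero diagonal).  The two
per-connection multipliers are the model's central degrees of freedom:
`w_LRE` scales excitatory→excitatory coupling (long-range excitation,
LRE), `w_FFI` scales excitatory→inhibitory coupling (feedforward
inhibition, FFI).  Their quotient is the connection's E/I-ratio; the
untuned baseline is w_LRE=1, w_FFI=0.

Constants default to the canonical dynamic mean-field values
(W_E=1, W_I=0.7, I_0=0.382 nA, w_plus=1.4, J_NMDA=0.15 nA, a_E=310,
b_E=125, d_E=0.16, a_I=615, b_I=177, d_I=0.087, τ_E=100 ms, τ_I=10 ms,
γ_E=0.641e−3, γ_I=1e−3, σ=0.01 nA); everything is overridable.

Numerics: Euler–Maruyama at dt = 1 ms with one independent standard
normal per population per step scaled σ√dt; gating clipped to [0, 1]
(the S_I equation has no intrinsic upper bound); initial gating
0.1 ± 0.01 seeded jitter.  The transfer quotient is evaluated with
`expm1`, which keeps it accurate through the removable singularity at
aI = b (value 1/d).  The hot loops are numba-jitted; one jit call
integrates one TR (720 ms), after which plasticity and tuning hooks run
in Python.  Identical seeds give bitwise-identical trajectories.

## Hemodynamics

Excitatory gating drives a Friston-type Balloon–Windkessel model per node
(vasodilatory signal, inflow, venous volume, deoxyhemoglobin; κ=0.65 s⁻¹,
γ_h=0.41 s⁻¹, τ_h=0.98 s, α=0.32, ρ=0.34, V0=0.02, k1=7ρ, k2=2,
k3=2ρ−0.2), integrated with explicit Euler at the neural dt — the
hemodynamic time scales are three orders slower, and halving dt moves the
BOLD signal by well under 0.1 % (tested against a high-accuracy RK
integration).  BOLD is read out every TR = 720 ms.

## Feedback inhibition control (FIC)

The local inhibitory weight J_i follows an inhibitory-plasticity rule
once per TR:

    ΔJ_i = η_FIC (pre_i · post_i − ρ0 · pre_i),   η_FIC = 0.001, ρ0 = 4 Hz

where pre/post are the inhibitory and excitatory rates averaged over the
preceding TR window (the rule itself does not name the estimator; the
window mean is the natural choice at the 720 ms update cadence).  J is
clamped below at 0.001 nA and initialized at 1 nA.  The homeostat settles
each excitatory population's long-term rate into 4 ± 0.5 Hz across
E/I-ratios spanning 0.01–100; the equilibrium sits slightly below 4 Hz
because rate–rate covariance enters the product term.  FIC is the
precondition for everything downstream: without it the FC-versus-E/I-ratio
relation of the two-node model is non-monotonic and unfittable.

## E/I tuning

Per TR, with ρ_sim the Pearson FC over a trailing window of simulated
BOLD samples:

    diff       = ρ_trg_ij − ρ_sim_ij
    w_LRE_ij  += η_EI · diff · rmse_i ;  w_FFI_ij −= η_EI · diff · rmse_i

rmse_i is the RMS deviation between rows i of target and windowed FC
(diagonal excluded — it is constant 1), an annealing-like factor that
shrinks steps for well-fitting rows and makes the (i,j)/(j,i) steps
asymmetric.  Updates are synchronous from one FC snapshot and applied
only where C_ij > 0 (the multipliers act through C).  The staged schedule
halves η_EI and doubles the window per stage, from η_EI = 0.1 and
150 TRs; stages default to 20 min of biological time (a paper-faithful
10 h/stage variant is provided as `TuningSchedule.paper_faithful()`).
Fit quality is always reported from a tuning-free validation run with a
fresh seed.

Two stabilizations beyond the bare rule, both needed at desk scale:

- a tuning-free burn-in of one start-window (150 TRs) precedes stage 0.
  The first window otherwise contains the hemodynamic onset transient,
  which reads as near-global positive correlation and triggers a spurious
  network-wide w_FFI surge before any honest FC feedback exists;
- weights are clamped to [0, w_max] with w_max = 10.  FC saturates in the
  multipliers, so when a target entry is outside a connection's
  expressible range the persistent error would ratchet the weight upward
  without bound (the zero-clamp breaks the rule's sum-preservation and
  lets the other matrix grow freely); runaway values distort the whole
  row's dynamics and can stall the fit even though the target is
  reachable.  The cap does not bind in healthy fits (observed maxima
  4–9).

Variants: `E_only` applies the same rule to w_LRE with w_FFI frozen at 0;
`global_scalar` grid-searches one coupling factor G rescaling C.  On
ground-truth benchmarks the fit quality orders EI ≥ E-only ≥ global
scalar.

## Measurement lengths

FC estimates carry sampling noise with an effective sample size well
below the TR count (BOLD autocorrelation spans several TRs).  At 30
nodes, a 30-min measurement reproduces even a model's own FC only to
r ≈ 0.5–0.6; the agreement ceiling is set by estimation length, not by
the fit.  Target FCs and validation runs therefore default to 3 h of
biological time, which puts the self-agreement ceiling near r = 0.98.
Fitted 30-node models reach validation r ≈ 0.97–0.98 against
ground-truth targets under the 6 × 20 min schedule; repeated refits from
different seeds produce visibly different weight matrices (coefficient of
variation ≈ 0.2) whose simulated FCs nevertheless agree pairwise to
r > 0.99 under shared validation noise — the procedure reproduces
dynamics, not parameters.

## Synthetic data

The generator stands in for tractography connectomes and empirical FC.

- Connectomes: a random spanning tree guarantees connectedness, extra
  edges fill to the requested density (default 0.12 at 30 nodes),
  weights are log-normal (σ_w = 0.5).  The matrix is row-normalized by
  symmetric Sinkhorn balancing and then scaled so the maximum row sum is
  exactly 1.  Balancing equalizes every node's total coupling — the
  standard input normalization for connectomes — and is what gives each
  connection enough leverage for FC structure to rise above the
  estimation noise floor at desk scale; plain global scaling leaves
  hub-diluted graphs whose FC spread (≈0.06 s.d.) is unresolvable.
- Ground-truth targets: per-connection E/I-ratios are drawn log-normal
  with median 6 and σ = 2, symmetrized, and split as w_LRE + w_FFI = 1;
  the model is simulated with FIC until rates converge and its FC over
  3 h becomes the target.  The resulting targets have empirical-like
  statistics (mean FC ≈ 0.06, s.d. ≈ 0.12, entries −0.4 … 0.8) and lie
  close to the untuned model's FC — the regime in which the η = 0.1
  schedule is stable.  Zero-mean targets (median ratio 1) sit far from
  the untuned state and provoke a global relaxation oscillation of the
  learning loop through the 150-TR feedback delay.
- Cohorts: K models whose generating median E/I-ratios are spread
  log-uniformly (heterogeneity parameter h), giving mean target FCs that
  increase across the cohort.

What the generator does not emulate: tractography biases, distance
dependence, hemispheric structure, measurement noise in empirical FC, or
subject-level covariates.  Passing tests therefore show that the
algorithms behave as designed on networks with realistic coupling and FC
statistics — not that they reproduce any particular empirical dataset.

## Decision circuit

Four reduced NMDA populations (A/B selective pools in PPC and PFC) with
r(I) as above (a=270 Hz/nA, b=108 Hz, c=0.154 s), τ=60 ms, γ=0.641,
integrated at dt = 0.5 ms.  Input noise is an Ornstein–Uhlenbeck process
(τ_AMPA = 2 ms, σ_noise = 0.02 nA, Euler–Maruyama); within-area noise
correlation is built by mixing a shared white-noise drive with weight
√corr.  Evidence enters the PPC pools as I_e(1 ± c′/100) with
I_e = 0.0118 nA and c′ = 6.4 %; a decision registers when a PFC pool
crosses 40 Hz (tie at one step: higher rate wins; exact tie: none), and
time-to-threshold is the integration time.

The coupling matrix is not published in reachable form; the defaults were
chosen by construction and then frozen: within-area self-excitation
0.35 nA and cross-inhibition −0.11 nA, inter-areal same-selectivity
coupling 0.09 nA (PPC→PFC) and 0.04 nA (PFC→PPC), background current
I0 = 0.323 nA.  At this operating point the evidence alone is near the
decision bifurcation: the circuit is bistable (persistent activity
≈ 40 Hz), noiseless symmetric trials never decide, and noisy trials
integrate for ~1–1.5 s.  This slow, fluctuation-driven regime is what
produces the characteristic phenomenology: accuracy and integration time
both grow as the input mean falls; PPC noise correlation improves
accuracy while integration time follows an inverted U with its maximum
at correlation ≈ 0.5 (common input cancels differential noise — slower,
better decisions — but at high correlation shared excursions through the
expansive transfer accelerate threshold crossing); PFC noise correlation
has no relevant effect.  Decision experiments at low input means use a
longer trial window (8 s) than the 3 s default, because slow trials that
hit the cap would otherwise be scored as errors and mechanically invert
the accuracy ordering.

Working memory: a 250 ms boxcar to one PPC pool at t = 0.5 s, a
distractor of the same amplitude to the rival pool 1.5 s later; memory is
"present" when the target pool's mean rate over a 500 ms window exceeds
20 Hz and the rival's by 10 Hz (the criterion is a design choice; no
numeric rule is published).  Outcomes classify as no-induction /
disrupted / robust.  The net recurrent strength J_S (self minus cross,
default 0.46 nA) shifts self and cross couplings symmetrically.  Both the
induction and the disruption threshold in stimulus amplitude rise when
the background input mean falls.

## Multiscale coupling

A fitted model's regional drive — I_E without the constant external term,
i.e. local recurrence plus long-range input minus local inhibition — is
captured per integration step, averaged per model, and the cohort's
10th–90th percentile band of these means is mapped affinely onto
[−0.006, 0.001] nA (no clipping outside the band).  Both pools of the
corresponding circuit module receive the same normalized drive by
zero-order hold at the circuit dt, each with its own independent OU
realization; evidence currents are added as in the isolated circuit.

Known desk-scale limitation: a region's drive fluctuates with the node's
own gating noise (s.d. ≈ 0.025 nA, independent of network size), which
exceeds the across-model spread of mean drives (≈ 0.007 nA).  After range
normalization the injected signal is therefore dominated by slow
common-mode excursions rather than by between-model mean differences.
The integration-time limb of the speed–accuracy trade-off survives this
(binned DM time increases with cohort mean FC), but the accuracy limb
does not resolve: decisions cluster inside high-drive excursions, which
biases accuracy the opposite way.  At cohort sizes of hundreds of models
with empirical FC diversity the mean spread grows and this limitation
recedes; it is a property of the desk-scale cohort, not of the coupling
equations.

## Problem sizes

Defaults throughout are desk scale, chosen so the full test suite and the
acceptance script run on one CPU: 30-node networks for fitting (10–24 for
cohort and refit studies), 6 × 20 min tuning stages, 3 h FC measurements,
500–1000 circuit trials per condition.  The paper-faithful stage length
(10 h) and larger parcellations (379 supported) are available through the
same interfaces.
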