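# Methods

## Model family

Radiation produces DNA double-strand breaks of two kinds: simple breaks
whose clean ends need only Ku70/80 and the XRCC4/Ligase IV/XLF ligation
complex (XL), and complex breaks whose chemically modified ends must first
be processed by DNA-PKcs/Artemis. Repair is described by mass-action
reaction networks over dimensionless number concentrations, with four
variants:

- **SF1** — synapsis formation before end processing. Simple branch:
  `∅ →(b_S·u) S0 →(k_a1) S1`, `S1 + S1 →(k_LK) S2 →(k_d1) S3 →(k_d2) RS`.
  Complex branch: `∅ →(b_C·u) C0 →(k_a1) C1`, `C1 + C1 →(k_LD) C2
  →(k_EP) C3 →(k_a1) C4 →(k_pD) C5 →(k_d2) RC`.
- **SF2** — end processing precedes synapsis: `C1 →(k_EP) C1p`,
  `C1p + C1p →(k_LD) C3`; the paired-unprocessed stage C2 disappears.
- **SF3** — processing and synapsis merged: `C1 + C1 →(k_EPL) C3`.
  The SF3 species list simply drops C2.
- **BF** — break filling: the break is one unit filled by sequentially
  recruited proteins (`S0 → SKu → S2 → S3 → RS`; `C0 → CKu → C2 → C3 →
  C4 → C5 → RC`), with the recruitment rates refined into `k_a1` (Ku),
  `k_a2` (DNA-PKcs) and `k_a3` (XL). Every reaction is first order, so
  the system is linear and has a matrix-exponential solution — this is
  the closed form used as an integration oracle in the tests.

`RS`/`RC` are bookkeeping pools of repaired simple/complex material: they
receive mass and never feed back, existing so that conservation can be
asserted along every trajectory.

Assumptions inherited by every variant: repair proteins are abundant and
of constant concentration (recruitment steps are pseudo-first-order with
the protein concentration absorbed into the rate); Ku and DNA-PKcs leave a
complex-repair intermediate together (one `k_pD` step); only a single
category of complex DSB is modelled; DSBs arise only from the direct dose
forcing (the initial state is zero and production is `b·u(t)` with `u`
the right-open irradiation-window indicator, `u(T_R) = 0`).

Conventions the source material leaves open, fixed here:

- Second-order self-reactions `X + X → Y` carry flux `k·X²` and consume
  two X per event (no 1/2 factor; the factor is absorbable into
  `k_LK`/`k_LD`).
- `b_S`, `b_C` count *ends* produced per minute — one break contributes
  two — because the SF species are ends. The BF species are breaks, so in
  the default `breaks_mode="ends"` the BF production flux is `b/2`;
  `breaks_mode="breaks"` uses `b` directly.
- ATM inhibition modifies `k_pD` in every variant, additionally `k_EPL`
  in SF3 and `k_EP` in BF. Inhibited members default to their control
  values when unset.

## Observables

Each DSB end carries one tagged molecule (Ku80-EGFP on every protein-bound
end; DNA-PKcs-YFP only on complex-pathway intermediates), so single-end
species weigh 1 and synapses weigh 2 in the observables; species past the
release of the tagged protein (S3, C5, repaired pools) weigh 0. For SF1:
`K = S1 + 2 S2 + C1 + 2(C2 + C3 + C4)`, `D = C1 + 2(C2 + C3 + C4)`.
Measured fluorescence is normalized to its maximum, so the model curves
are divided by their maximum over the dense simulation grid (not over the
sparse sample times: a peak falling between samples still defines 1.0).
Two structural consequences double as test oracles: the observables are
exactly invariant to the XL release rate `k_d2` (its reactions sit
strictly downstream of every counted species), and the simple and complex
branches are mutually uncoupled.

## Dose forcing and integration

The indicator `u(t)` is 1 on right-open windows `[T_even, T_odd)`; acute
exposure is `[0, T_R)` with `T_R = 0.5` min by default (a ~30 s laser
pulse). Integration splits at window boundaries so the solver never steps
across the discontinuity, and freezes `u` at its in-segment value. LSODA
with analytic Jacobian, `rtol = 1e-8`, `atol = 1e-10` by default; solver
round-off below zero is clipped only when evaluating observables, never
fed back into the state. The default output grid has 0.02 min resolution
over the first 5 min (the recruitment peak) and ~240 points beyond; data
times are unioned into the grid so interpolating the model onto them is
exact at the nodes.

## Error function and fitting

Per channel the misfit is the discrete L2 norm
`E_ch = sqrt(Σ_i (ŷ(t_i) − y_i)²)` (a sum-of-squares variant is
selectable); the total is `E = E_K + E_D + E_K^i + E_D^i`, control curves
simulated with control rates and inhibited curves with the `_i` rates,
all other parameters shared. Channels with unequal point counts are not
reweighted (a weights option exists, default 1). Data times are stored on
the model clock: experimental time zero is recorded immediately after
irradiation, so file readers shift declared post-irradiation clocks by
`+T_R`.

Minimisation runs on log-parameters (positivity by construction) with an
Armijo backtracking line search, so the accepted-step error sequence is
non-increasing by construction. The default search direction applies
limited-memory BFGS curvature correction (memory 12): the landscape is
badly ill-conditioned — rates spanning `0.0025–30` min⁻¹ — and plain
steepest descent (`method="gd"`, kept as an option with a
Barzilai–Borwein trial step) needs several times more iterations for the
same accuracy. Stopping: relative error change `< 1e-8`, gradient norm
`< 1e-8`, error below `1e-8` (the root-sum-square metric is a cone at a
perfect fit, so below solver resolution the gradient direction is noise),
or an iteration cap, in which case the best-so-far point is returned with
`converged=False`. Multi-start support draws log-uniform starts within
one decade of the given start from a seeded generator; fits are
reproducible bit-for-bit given (seed, start, options).

Gradients come from central finite differences with relative step `1e-3`
per log-parameter (smaller steps amplify ODE-solver noise on E into the
gradient and stall the line search well above the attainable floor;
truncation error at `1e-3` is ~1e-6 relative), or from the adjoint system: `λ' = −J(x,t)ᵀ λ`
integrated backward with jumps `c_i · w_ch` at each observation time and
a Danskin correction at the grid argmax of the raw observable (the
normalizing maximum depends on the parameters through its location), then
`dE/dp = ∫ λᵀ ∂f/∂p dt` accumulated per rate constant. Both routes
differentiate the same discrete objective and agree to ~1e-7 relative in
the tests; the control and inhibited rates are treated as independent
coordinates (inhibited members are materialized before differentiating).

## Identifiability: the normalization gauge

Max-normalized observables are *exactly* invariant under
`(b_S, b_C, k_LK, k_LD/k_EPL) → (α b_S, α b_C, k_LK/α, k_LD/α)`: every
species scales by α, second-order fluxes scale by α, first-order rates
are untouched, and the normalization divides α back out. The absolute
damage-production scale is therefore not identifiable from normalized
intensities — only the ratio `b_S : b_C` and the products of `b` with the
second-order rates are. Parameter-recovery experiments consequently hold
`b_S` fixed at its known value (in a real experiment the dose is
measured, and dose determines DSB yield), which breaks the gauge and
makes the second-order rates recoverable. One-at-a-time sensitivity scans
cannot see this four-parameter null direction, which is why a parameter
can classify "sensitive" yet be unrecoverable without the gauge fixed.

## Sensitivity analysis

One-at-a-time scans perturb each rate on the symmetric relative grid
`Δp/p ∈ {−0.4 … 0.4}` (step 0.1) with all others fixed and record
`ΔE/E(p*)`. A parameter is *robust* when ±30% perturbation moves the
error by less than 5%, *sensitive* otherwise; both thresholds are
configurable. Relative (not absolute) error change is reported and
labelled. Perturbations driving a rate non-positive are skipped and
flagged. The scan is order-independent and, at a fit output, `ΔE ≥ 0`
holds in a neighbourhood of the reference.

## Synthetic data generator

The generator stands in for published live-cell recruitment/loss curves
that exist only as figures. It simulates a chosen variant under known
`p_true` for both conditions, samples the normalized observables on
confocal-like grids — 13 points over 0–120 min (Ku80-EGFP) and 15 over
0–180 min (DNA-PKcs-YFP), experimental clock, dense near the peak — and
adds independent additive Gaussian noise (σ = 0.05 on normalized
intensity), truncated below 0 and above the 1.2 intensity ceiling. One
substream per quadrant is spawned from a single seed, so bundles are
byte-reproducible. A channel whose raw signal is identically zero (e.g.
`b_C = 0` leaves no DNA-PKcs recruitment) raises a zero-signal error.

The reynolds-like preset (all rates in min⁻¹): `b_S = 30`, `b_C = 15`
(ends; simple:complex 2:1), `k_a1 = 30` (τ = 2 s — Ku accumulates at
laser damage on a seconds scale, and the rise must be saturated at the
first post-exposure sample for the observables to be insensitive to
recruitment, as they are in this regime), `k_LK = 0.5` vs `k_LD = 0.02`
(complex synapsis 25× slower), `k_d1 = 0.15` (fast-phase τ ≈ 7 min),
`k_d2 = 0.05` (invisible to both channels), `k_EP = 0.3`,
`k_pD = 0.015` (slow-phase τ ≈ 67 min), `k_pD_i = 0.0025` (= k_pD/6:
strong DNA-PKcs retention under ATM inhibition, still resolvable within
the 180 min window), `k_EPL = 0.02`, `k_EPL_i = 0.008`, `k_a2 = 2`,
`k_a3 = 1.5` (BF refinements). These values reproduce the qualitative
curve shapes: peak < 1 min after the 0.5 min exposure, biphasic Ku loss,
convex log-decay, retarded DNA-PKcs loss under inhibition.

What the generator does **not** emulate: photobleaching, focus drift and
background subtraction; per-cell heterogeneity (the model is the
deterministic mean); correlated noise along a trace; any spatial
structure (chromatin compartments, end diffusion distances). Passing
recovery tests on these bundles therefore demonstrates the pipeline's
correctness under its own assumptions, not that real fluorescence data
satisfy them.

## Numerical and design notes

- Second-order kinetics decay algebraically (`X(t) ~ 1/(2kt)`), so
  "complete repair" checks use a benchmark parameter set with synapsis
  rates of 5 min⁻¹; at the preset's `k_LD = 0.02` the residual end
  fraction at 10⁴ min is ~1e-5 by this intrinsic tail, not by solver
  error.
- The SF1→SF3 merging limit (`k_EP → ∞` collapses pairing+processing to
  one reaction with `k_EPL = k_LD`) is verified at `k_EP = 10³·k_LD`
  with sup-norm observable agreement below 2%.
- Model comparison refits every variant from matched multi-start points
  (the same seeded perturbation factors per parameter name across
  variants, 8 starts by default) and ranks by fitted error; ties within
  1e-6 rank the variant with fewer free parameters first; a failed
  variant keeps its row with error NaN.
- The shipped SF-vs-BF discrimination benchmark
  (`model_comparison_preset`) varies only the DNA-PK release rate between
  control and inhibited conditions. A condition-dependent merged
  processing/synapsis rate is a feature only SF3 can express; leaving it
  in would hand every other variant an irreducible inhibited-channel
  misfit and turn the ranking into a test of per-variant flexibility
  rather than of rejoining order. On this benchmark the break-filling fit
  floors at E ≈ 1.9e-2 — with the largest residual in the DNA-PKcs
  control channel, whose slower-than-exponential late decay a linear
  chain cannot produce — while the two-step SF variants, started with
  their nuisance processing rate in the merging-limit regime
  (k_EP = 20 ≫ k_LD), reach E ≈ 5e-4 within a few dozen iterations.
- Problem sizes in the shipped tests and acceptance script — single
  bundles, 20 random draws for the linear-model oracle, one recovery fit
  with an iteration cap of 250, comparison fits capped at 25–40
  iterations — are chosen to exercise every claim at desk scale.

## Known limitations

- The gradient iteration is local; the error function is not convex and
  multi-start mitigates but does not remove the risk of local minima.
- Absolute rates tied to the normalization gauge (above) require external
  dose information.
- The BF topology with distinct `SKu`/`CKu` intermediates is one of
  several first-order chains consistent with the verbal description; it
  was chosen so that `k_a1`, `k_a2`, `k_a3` are all identifiable.
- No statistical noise model or likelihood: the error function is
  deterministic, so no confidence intervals on parameters are produced.
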