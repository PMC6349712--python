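# Methods

`ecginverse` reconstructs cardiac activation and repolarization maps from
body-surface potential recordings by identifying the parameters of an
action-potential ansatz distributed over a triangulated heart surface.
This note records the model, the numerical choices, and what the synthetic
validation does and does not establish.

## The action-potential ansatz

Each heart-surface node carries a transmembrane-voltage waveform taken from
the two-variable Mitchell–Schaeffer ionic model,

    v' = h v²(1−v)/τ_in − v/τ_out,
    h' = (1−h)/τ_open   if v < v_gate,
    h' = −h/τ_close     if v ≥ v_gate,

integrated from (v, h) = (0.15, 1) so that `v` traces a single action
potential; (0, 1) is the resting state. The voltage and gate are
dimensionless and bounded in [0, 1]. The node waveform is the shifted,
rescaled solution

    Vm(x_i, t) = A · v(t − τ_i),   v(s) ≡ 0 for s < 0,

parameterized per node by the activation time τ_i and by the two
repolarization constants τ_out,i (repolarization speed, default 6 ms) and
τ_close,i (plateau duration, default 150 ms). The upstroke constants
τ_in = 0.3 ms, τ_open = 120 ms and the threshold v_gate = 0.13 shape parts
of the waveform that the body-surface data constrain only weakly; they are
configurable but never optimized. The single global amplitude A absorbs
the intra-/extracellular conductivity ratio of the underlying bidomain
reduction, so all potentials carry arbitrary units. A distributed
amplitude is deliberately not offered: with one amplitude per node the
least-squares problem loses identifiability (amplitude trades off against
the transfer-matrix column norms) and the optimization is known to wander
or converge to mixed-sign amplitudes.

At the exact threshold v = v_gate the model's strict inequalities leave h'
undefined; the closed branch (v ≥ v_gate) is used.

## Forward model

Transmembrane voltages map to extracellular potentials through the
homogeneous-and-isotropic bidomain reduction

    φ_e(x_i, t) = (1/N_H) Σ_k Vm(x_k, t) − Vm(x_i, t),

an unweighted mean over all vertices of all surfaces present (no area
weighting — the discrete form is taken as the model, not as a quadrature of
the continuous one). Each column of φ_e sums to zero by construction.
Electrode potentials follow from the infinite-medium kernel

    φ_T(y_j, t) = Σ_i φ_e(x_i, t) / (4π‖x_i − y_j‖),

with distances in mm. A bounded, inhomogeneous torso is out of scope; the
synthetic electrodes are placed far enough (torso radius 100 mm vs heart
semi-axes ≤ 60 mm) that the kernel is well-conditioned.

## Numerical integration and sensitivities

The ionic model is integrated with fixed-step RK4, default step 0.05 ms.
The model is only mildly stiff at the ~1 ms upstroke; the fixed step keeps
every quantity deterministic and reproducible. At 0.05 ms the voltage
agrees with a 0.001 ms reference to < 1e-7 absolute; steps above 0.5 ms
trigger a warning.

Parameter gradients need ∂v/∂τ_out and ∂v/∂τ_close, which are
co-integrated as forward sensitivity ODEs. The gating switch is the one
subtle point: the crossing time t_s of v through v_gate itself depends on
the parameters, so the true sensitivity of h jumps at the crossing by
[h'(t_s⁻) − h'(t_s⁺)] · dt_s/dp with dt_s/dp = −s_v(t_s)/v'(t_s).
Integration steps that straddle a crossing are therefore split at the
(linearly interpolated) crossing time: the first sub-step runs in the old
regime, the jump is applied, the remainder runs in the new regime. The
same splitting is used in the plain forward kernel so that cost and
gradient evaluations see identical trajectories. Without the jump the
post-repolarization sensitivities are wrong by O(10%); with it they match
central finite differences of re-integrated templates to better than 0.1%
at every probed time, including well after the switch.

The onset of the ansatz is a genuine discontinuity (v jumps 0 → 0.15 at
t = τ). Template evaluation uses linear interpolation on the integration
grid with v ≡ 0 for t < τ, so ∂Vm/∂τ across the onset is the interpolant's
one-step slope — a finite, grid-dependent subgradient. This is an accepted
approximation; gradient checks avoid placing samples exactly on onsets.

Within one forward evaluation, nodes sharing a (τ_out, τ_close) pair
(rounded to 1e-6 ms) share one template: the unique pairs are integrated
together as an ensemble in a compiled kernel. A uniform initial field thus
costs one ODE solve, a fully distributed field N_H solves.

## The inverse problem

The unknown vector P = (A, τ_out[·], τ_close[·], τ[·]) ∈ ℝ^{1+3N_H}
minimizes the mean-centered least squares misfit

    J(P) = ½ Σ_k Σ_j [(φ_T(y_j,t_k) − φ̄_T(t_k)) − (φ*(y_j,t_k) − φ̄*(t_k))]²,

where the bars are per-time means over electrodes. Centering removes the
reference-potential freedom of both recordings (J is invariant to adding
any c(t) to all electrodes of the target) and doubles as noise reduction in
the spirit of referencing against Wilson's central terminal.

The gradient is assembled analytically: the residual is back-propagated
through the (symmetric) electrode-centering projector I − 𝟙𝟙ᵀ/N_T, the
transfer transpose, the (symmetric) node-centering map 𝟙𝟙ᵀ/N_H − I, and
contracted with the per-node ansatz partials (∂Vm/∂A = v, ∂Vm/∂τ = −A v',
∂Vm/∂τ_out = A s_out, ∂Vm/∂τ_close = A s_close). Verified against central
finite differences: cosine similarity > 0.999 and componentwise error
< 1% on seeded random cases.

Updates use RMSprop with γ = 0.9 and ε = 1e-7:

    κ ← γκ + (1−γ) ∇J ⊙ ∇J,
    P ← P − η ∇J ⊘ (κ^½ + ε).

The learning rate η is chosen anew each iteration by evaluating the
tentative update on a fixed grid of 15 log-spaced values spanning
[1e-5, 1e2] and keeping the η with the lowest resulting J (ties to the
smaller η; the best candidate is taken even if every candidate raises J,
matching plain RMSprop's unconditional step). The grid is a declared
convention: it is deterministic, testable, and costs exactly 15 forward
evaluations per iteration.

After every update τ_out and τ_close are clipped to lower bounds of 0.5
and 10 ms respectively — RMSprop's sign-like steps can otherwise push a
weakly constrained time constant through zero, where the ODE is invalid.
No upper bounds and no spatial regularization of any field are imposed;
the waveform parameterization itself is the regularizer.

Initialization is uniform: A = 10, τ_out = 6 ms, τ_close = 150 ms, τ ≡ τ0
(default 60 ms, configurable). A uniform field makes the spatial mean equal
every node value, so the initial torso potentials are identically zero.
The loop stops when the relative change of J stays below 1e-6 for 10
consecutive iterations, or at `max_iterations` (default 500).

## Synthetic validation data

No recorded or simulated reference data ship with the package; the
`protocols` module generates ground truth at desk scale:

- **Activation**: geodesic spread on the mesh edge graph from one or more
  pacing sites at constant conduction velocity (default 0.6 mm/ms, in the
  physiological range for ventricular myocardium). This is the standard
  eikonal-style surrogate for a reaction–diffusion front; it reproduces
  front-like τ maps but no wavefront curvature or anisotropy effects.
- **Repolarization fields**: τ_close and τ_out as base value plus an
  endo–epi offset, an apex–base gradient (normalized apex height), and
  vertex-wise Gaussian noise smoothed by 3 rounds of 1-ring averaging,
  clipped to τ_out ∈ [2, 20] ms, τ_close ∈ [50, 300] ms.
- **Recordings**: the package's own forward projection, optionally with
  i.i.d. Gaussian noise at a requested SNR (10·log10 of power ratio), and
  optionally with *model mismatch* to break the inverse crime: either the
  generating mesh is a 4× midpoint-subdivided copy of the inversion mesh,
  or the generating template uses perturbed fixed constants
  (τ_in = 0.35 ms, v_gate = 0.15).
- **Reference repolarization times**: time of the steepest positive slope
  of the clean φ_e after a 50 ms post-activation guard window — the same
  extraction applied to reconstructions, keeping both on one footing.

Synthetic geometry is a half-ellipsoid ventricle (default semi-axes
30×30×60 mm) open at the base, with near-uniform vertex density: per-ring
segment counts scale with ring circumference and adjacent rings are
triangulated by angular merge. Uniform density matters for the inverse
problem — early versions that crowded ~12 vertices into the apex produced
clusters of mutually indistinguishable nodes whose activation order the
optimizer could permute freely. An optional nested shell inset by the wall
thickness models the endocardium, joined to the epicardial rim along the
base so both surfaces form one connected propagation graph. Electrodes sit
in staggered near-uniform rings on a surrounding cylinder.

Because generator and solver share the forward model in the default
(noiseless, no-mismatch) configuration, recovery there is an *inverse
crime*: it validates the optimization machinery, not the method's
robustness. The noise and mismatch modes exist precisely so tests do not
rely on the crime alone. None of the synthetic data reproduce volumetric
conduction, anisotropy, torso inhomogeneity, or real electrogram
morphology; quantitative scores on these benchmarks say nothing about
clinical data.

## Reference benchmark

The packaged benchmark (`benchmarks.make_benchmark_case`) is a 100-vertex
epicardium-only ventricle with 64 cylinder electrodes, one pacing site at
the apex (onset 5 ms), conduction velocity 0.6 mm/ms, an apex–base
τ_close gradient of 20 ms with 5 ms smoothed noise, recorded over 0–460 ms
at 1 ms. These sizes keep a full 300-iteration solve (≈ 4800 forward
evaluations) in the minutes range on one core while leaving the problem
genuinely distributed (301 unknowns from 29 440 data values).

A 300-iteration run on this benchmark (the demo command prints these
numbers) reaches an activation-map correlation near 0.88 with the cost
reduced by roughly 92%, and localizes the pacing site to within one mesh
edge. The run does not reach the global (zero-misfit) optimum: the
activation correlation rises quickly in the early iterations and then the
greedy descent keeps lowering J while partially *degrading* the map —
late-activating basal nodes whose τ must travel ~50 ms from the uniform
initialization get compensated by small amplitude and τ_close adjustments,
and the iteration settles into a local minimum where the learning-rate
search finds no improving candidate on its whole grid. This mirrors the
behavior of waveform-parameterized ECGI on realistic validation data,
where cost reductions of 74–90% and activation correlations between 0.4
and 0.9 are the norm: the far-field forward operator makes individual
nodes only weakly distinguishable, and the waveform parameterization gives
the cost genuine non-convexity in τ. Users who care about the activation
map more than the misfit should monitor the map against held-out
information or stop early; the packaged solver deliberately reports the
final iterate, not a best-so-far one.

## Evaluation conventions

- CC: Pearson correlation; undefined (NaN, with a warning) under zero
  variance.
- RE: global relative L2 error ‖rec − ref‖₂/‖ref‖₂. (A mean-absolute or
  max-based definition would be equally defensible; L2 is declared here
  and used consistently.)
- BSPM metrics: per-time CC across electrodes and per-time RMSE, with
  mean ± sd over time.
- APD90: from the upward v_gate crossing (the model's natural activation
  marker) to the first fall below 10% of the peak, both crossings linearly
  interpolated.
- Endo–epi delays: τ(epi) − τ(nearest-endo partner by Euclidean distance,
  ties to the lowest vertex index); box-plot summary with
  linear-interpolation quartiles.
- Pacing-site localization: graph-Dijkstra geodesic distance between true
  and earliest-activation vertices. Edge-graph geodesics overestimate
  exact polyhedral ones by at most the mesh-resolution anisotropy, which
  is below the vertex spacing of every mesh used here. An optional filter
  can exclude isolated early vertices (1-ring mean AT more than 30 ms
  later than the vertex); it is off by default.

## Known limitations

- The infinite-medium kernel ignores torso boundedness and inhomogeneity;
  amplitudes are only meaningful relative to one another.
- The learning-rate grid search costs 15 forward solves per iteration;
  RMSprop with line search still stalls in flat directions — components
  with little influence on the recording (e.g. basal nodes far from
  electrodes) converge last and dominate the residual map error.
- Sensitivities assume at most one gate crossing per integration step,
  valid for all parameter ranges exercised here.
- The repolarization-time extraction needs the recording to extend past
  the latest repolarization; otherwise nodes report NaN.
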