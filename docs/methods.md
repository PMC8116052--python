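# Methods

## The model

Receptor–antigen recognition lives on a one-dimensional antigenic
coordinate ("shape space").  A receptor whose cognate antigen sits at
the origin binds an antigen at distance `d` with affinity

    E_{α,θ}(d) = e_max · (α / α_max) · exp[−(α·d)^θ],

where the specificity `α ∈ [0, α_max]` is the inverse of the
receptor's cross-reactive range and `θ ≥ 0` shapes the profile (flat
at θ=0, double-sided exponential at θ=1, Gaussian at θ=2, approaching
a top-hat beyond).  The prefactor `α/α_max` builds in the
affinity–cross-reactivity tradeoff: narrower receptors bind their
cognate target more strongly, peaking at `e_max` for `α = α_max`.
The kernel is written in the literature up to a proportionality
constant; we fix the constant by the normalization convention that a
conserved antigen met at maximal specificity and deliberation with no
deliberation cost has rescaled net utility 1 (up to the `e^{-β_max}`
recognition deficit).  One dimension suffices because every quantity
in the pipeline depends on antigenic *distances* only.

Upon re-infection, a stored memory receptor at distance `d` from the
antigen either recognizes it during the deliberation window
(probability `P_mem = 1 − exp(−E(d)·β)`) or the window elapses and a
novel naive response is mounted.  `β`, the *deliberation factor*, is
the pathogen load accumulated over the deliberation time `τ` and also
plays the role of inverse temperature in the equivalent
maximum-entropy decision rule `Q_a ∝ exp(β·U_a)`; equating the two
descriptions yields `β(U_mem − U_naive) = log(e^{Eβ} − 1)`, which the
package implements as a verified consistency layer while the pipeline
itself always uses the kinetic form.  In terms of cellular kinetics
the deliberation time is `τ = τ0 + t_half·log2(b)` (head start plus
the doublings needed to offset the recruitment-size ratio `b`), about
1.5–5 days for reported B-cell parameters.

Utilities per encounter: the naive response pays the proliferation
cost of deliberating, `U_naive = −e_max·Ω̂(β̂)` with `Ω̂` zero, linear
(`Ω̂₀·β̂`) or quadratic (`Ω̂₀·β̂²`) in the scaled deliberation
`β̂ = β/β_max`; a memory response adds the binding affinity on top,
`U_mem = U_naive + E(d)`.  The expected binding profile of the round
is the `(P_mem, P_naive)`-weighted mixture of the memory-centered and
freshly-centered normalized profiles, and its Kullback–Leibler
divergence from the fresh profile, in units of `β`, is the
dissipation

    K_diss = (1/β) · KL( P_mem·profile_mem + P_naive·profile_new ‖ profile_new ).

Net utility per encounter is `U_net = ⟨U⟩ − K_diss` with
`⟨U⟩ = P_mem·U_mem + P_naive·U_naive`.  `K_diss` vanishes at `d = 0`,
rises within roughly one cross-reactive range of the memory, and
falls back to zero at large `d` where the recognition weight
collapses — the low-dissipation ends are the "equilibrium memory" and
"equilibrium naive" regimes, the dissipative middle the
"non-equilibrium memory" regime.

## Pathogen drift and the lifetime simulation

Pathogen evolution is diffusive in shape space: after `k` infection
rounds the expected squared distance from the reference antigen is
`⟨d_k²⟩ = k·δ²`, with `δ` the antigenic divergence per round.  The
generator draws round-`k` distances from `Normal(δ√k, 0.05·δ√k)`,
truncated at zero; the 5% relative width models how one trajectory
samples the multidimensional neighbourhood of the reference antigen.
The scaled divergence `δ̂ = δ·α_max` measures drift in units of the
minimal cross-reactive range.  A `linear` drift law (mean `δ·k`,
ballistic rather than diffusive) is available behind a config switch;
the diffusive law is the default because it is the one the regime
structure of the results requires — under ballistic drift memory
becomes worthless beyond `δ̂ ≈ 0.35` and the cross-reactive regime
never forms.

A lifetime is `L` encounters with one evolving lineage.  The primary
infection seeds memory (all of it, in the mixture case) and
contributes only its deliberation cost; encounters `1..L−1` are scored
re-infections.  By default memory remains anchored to the primary
antigen for the whole lifetime — recognition at round `i` uses the
distance from the primary — matching the simulation design the
results reproduce.  The alternative `reset` convention (a realized
naive response re-centers memory and restarts the drift clock) is
implemented and tested but makes maximally specific memory strictly
dominant at every divergence, because refreshing restores full
affinity at a cost that does not depend on specificity; it therefore
cannot produce the cross-reactive regime.  The optimizer's objective
is the lifetime *sum* of net utilities, including the primary's
β-dependent cost; this matters only for short lifetimes (at `L = 2`
it shifts the optimal deliberation from ≈0.55 to ≈0.45) but is the
form the total-utility argmax prescribes.

## Optimization

*Single strategies.*  `(α̂*, β̂*)` is found by exhaustive search on a
uniform 50×50 grid over `[0,1]²` (a desk-scaled version of the
full 500-increment sweep), with common random numbers: every grid cell experiences
identical antigenic trajectories and decision draws, so cell-to-cell
comparisons are paired and the argmax is stable at 120–200 ensemble
lifetimes where independent sampling would need orders of magnitude
more.  Ties are broken toward the cheaper strategy (smallest β, then
smallest α); exact ties occur only along the zero-utility boundary
(β̂ = 0 or α̂ = 0), which is also where the memory-shutdown optimum
lands for fast-evolving pathogens under high cost.  For lifetime
scans the ensemble count per `L` is scaled to keep the total number
of simulated encounters roughly constant (12 000, capped at 4 000
ensembles), since short lifetimes average over fewer encounters.

*Mixtures.*  A repertoire of `n_m = 20` specificities with fixed
effective deliberation `β̃ = n_m·β = 0.2·β_max` is optimized by
stochastic gradient ascent (step `ε = 0.1`): each step draws a fresh
set of 50 antigen lineages with divergences uniform on `δ̂ ∈ (0, 1.6)`
followed for 40 rounds, evaluates the objective at the current vector
and at 30 Gaussian perturbations under shared draws, and fits the
gradient by least squares.  The antigen panel is drawn once per
restart and held fixed across steps — only the drift trajectories are
redrawn — so the objective is a fixed function estimated under fresh
noise, not a moving target.  The probe SD is `0.10·α_max`: with 30
probes in 20 dimensions the regression has only ~10 effective degrees
of freedom, and at half that width the estimator noise dominates the
drift, leaving the iteration a bounded random walk that never leaves
its uniform initialization.  We run 2 000 steps per restart and pool
24 restarts, which at this probe width reproduces the component
structure of reference runs at 3 000 steps with 100 probes (the
full-scale budget also uses 1 000 antigens and 200 restarts).  Pooled
histograms use bin width 0.05 over `α̂`, excluding non-functional
(`α = 0`) components; `histogram_modes` reports local maxima of the
lightly smoothed histogram ([1,2,1]/4 kernel, boundary bins included)
above the uniform-density level, and `dominant_modes` the k
highest-mass peaks — the right summary for a distribution claimed to
be k-modal.  Because memory is anchored,
the mixture objective is deterministic given the distance draws;
responder selection (probability `E_i / ΣE_j`) enters the utility as
its expectation `ΣE_i²/ΣE_j` and the dissipation as the
selection-weighted single-responder KL.  Dissipation is not uniquely
defined for coexisting memories; this selection-weighted
generalization is ours, reduces exactly to the single-memory form at
`n_m = 1`, and is isolated in one function.  Usage curves report, per
specificity bin, the probability that a produced receptor responds at
least once during a test lifetime (5 000 test pathogens at full
scale, 500 here).

## Numerics

The dissipation KL depends, once positions are measured in units of
`1/α`, only on the scaled distance `a = α·d`, the profile shape `θ`,
and the memory weight `w = P_mem`.  One global table per `θ` is
therefore precomputed on a 512×2048 grid in `(a, v)` with
`v = log w/(1−w) = log(e^{βE}−1)`; the log-odds coordinate is
essential because the KL varies on the scale `w ~ e^{−a^θ}`, which a
linear `w` grid cannot resolve.  Catmull–Rom bicubic interpolation
reproduces direct profile computation to ~1e-7 (θ=2; ~1e-5 for the
kinked θ=1 profiles), far below every decision the optimizers make;
the stochastic mixture kernel uses a bilinear variant (~1e-4) whose
error is orders of magnitude below its Monte-Carlo noise.  Outside
the tabulated window (`a > 8` or `w < 4e-18`) the small-weight
asymptote `f ≈ w·(KL(P‖Q) + log w)` (clipped to `[0, KL(P‖Q)]`) is
used, where contributions are negligible.  Profile grids for the
direct path span 8 cross-reactive ranges beyond the profile centers
with 801 points; KL sums of smooth profiles converge essentially to
machine precision at that spacing, and halving the step changes
K_diss by far less than 1e-4 nats.  Negative drift draws are redrawn
in the scalar generator and clipped in the compiled sweeps — at the
default 5% relative width the distinction is a >20σ event.  `0^0 = 1`
in the kernel exponent so θ=0 yields exactly flat profiles, for which
dissipation is identically zero.  All randomness flows from a single
root seed through named `SeedSequence` substreams; fixed seeds make
every stage bit-reproducible.

## What the generator does and does not emulate

The synthetic pathogen is a drift *distance* process only: no
within-host dynamics, no multi-epitope antigens, no explicit
high-dimensional antigenic coordinates, and one lineage per lifetime
with no cross-pathogen interference.  Memory has no intrinsic decay,
and mixed memory+naive co-responses are excluded by construction.
Passing tests therefore demonstrate the internal consistency of the
decision-theoretic model and the reproducibility of its optimal
strategies — not that real immune repertoires realize these optima;
the model's contact with data is qualitative (bimodal IgM/IgG-like
specificity mixtures, reduced memory usage against fast-evolving
pathogens).

## Known limitations

Desk-scale budgets leave Monte-Carlo noise of order one grid step in
reported argmax locations.  In the mixture ensemble the specific mode
at `α̂ ≈ 1` is sharp and stable, but the cross-reactive component is
a broad plateau over roughly `α̂ ∈ [0.2, 0.7]` whose peak position
moves by ±0.2 across seeds at 20–24 restarts; localizing it sharply
appears to require ensemble sizes closer to the full 200-restart
budget.  The specific-memory regime boundary lands at
`δ̂ ≈ 0.10–0.15` here, and the optimal specificity declines with
divergence faster than the narrative `δ̂ ≤ 20%` boundary suggests — a
systematic feature of this reconstruction, not seed noise (removing
dissipation entirely shifts the scan by at most one to two grid
steps).  The lifetime scan's specificity minimum `c*` is reported
from the scanned grid of `L` values and is only as resolved as that
grid; within `L ≤ 60` the optimal specificity declines monotonically,
so no interior minimum is observed at the scanned divergence.
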