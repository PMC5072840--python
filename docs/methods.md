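# Methods

This note documents the models, numerical choices and limitations behind
`grfkit`, in the order the pipeline uses them.

## Protein proxy

Active TF protein is modelled by `dp/dt = ν·m − λ·p`.  Because every GRF
responds to ratios `p/K` with `K` fitted on an arbitrary scale, the ratio
`ν/λ` only sets the (irrelevant) absolute protein scale and is fixed to 1,
leaving `dp/dt = λ(m − p)` with the single parameter λ (units 1/min;
effective half-life `τ½ = ln2/λ`).  λ is bounded in fitting to half-lives
of 1–120 min, bracketing the biologically plausible 5–50 min range.

**Integration.**  The sampled mRNA series is interpolated by a not-a-knot
cubic spline (no physical boundary information favours any other end
condition).  On each spline segment the convolution integral
`∫ e^{λτ} m(τ) dτ` is evaluated in closed form via the recurrence
`I_k = (h^k − k·I_{k−1})/λ`, so the only approximation in the filter is
the spline itself; a generic ODE integration of the same spline agrees to
better than 1e−6 relative.

**Warm-up.**  Initial conditions are obtained by extending the measured
series backward periodically by whole copies of itself and integrating
from far enough back that the start transient has decayed below 1e−6
(the smallest multiple of the series span with `exp(−λ·T_w) ≤ 1e−6`).
This is deterministic and exact for signals that are periodic over the
measurement window.  For oscillations incommensurate with the window
(e.g. a 60-min rhythm in a 205-min window) the wrapped history is out of
phase with the true history, which biases the proxy over roughly the
first `3/λ` minutes of the window.  This artifact is shared by every
candidate fit of the same target, so model *selection* is unaffected; it
does, however, put a floor (~0.1) on absolute scores of ODE-generated
benchmark data at early time points.

## GRF forms

Hill building blocks: `h(p; K, n) = pⁿ/(Kⁿ + pⁿ)` (activation) and
`r = 1 − h` (repression), evaluated as logistic functions of
`n·(ln p − ln K)` so large `n` cannot overflow.  One-input forms: ACT,
REP (4 shape parameters `b, α, K, n`).  Two-input forms (6 shape
parameters): AND `h₁h₂`, OR `h₁+h₂`, ANDNOT `h₁r₂`, NOTAND `r₁h₂`,
ORNOT `h₁+r₂`, NOTOR `r₁+h₂`, NOR `r₁r₂`, NAND `r₁+r₂`,
XOR `h₁r₂+r₁h₂`, EQ `h₁h₂+r₁r₂`, each wrapped as `s = b + α·[bracket]`.
The additive brackets (OR family, NAND, and the composite form below)
deliberately reach 2 when both branches saturate: α is a *per-branch*
amplitude and no renormalization is applied, so the maximal fold change
of an additive form is `b + 2α`.  With per-input protein rates included,
a two-input fit has 8 free parameters.

The composite four-input form (SUM_OF_ANDS), used for a gene repressed by
two factors and additively activated by an external cyclin input plus its
own product, is `s = b + α[r₁r₂ + h₃h₄]`.

The sensitivity `n` is restricted to [1, 8]: `n < 1` is non-sigmoidal and
`n > 8` is indistinguishable from a step at 42-point sampling.

## Thermodynamic promoter model

For promoters whose architecture is known, a statistical-mechanics
ensemble replaces the phenomenological logic: every admissible set of
occupied binding sites is a state with Boltzmann weight
`∏ affinity·concentration × ∏ pairwise cooperativities`, subject to
mutual-exclusion groups (overlapping sites) and recruitment constraints
(a cofactor site can only be occupied when a platform site is).  Each
state carries a polymerase fold-activation `F` (1 for the empty
promoter) and the synthesis rate is `s = basal + scale·(⟨F⟩ − 1)` with
`⟨F⟩` the weight-averaged `F`.  This convention makes the empty promoter
transcribe at exactly `basal` and reduces a single activating site to a
Hill function with `n = 1`.

The bundled three-input G2/M architecture (a Kip2-like promoter) has four
sites — a constant Mcm1 platform, an overlapping Fkh2 and Fkh1 pair, and
a recruited Ndd1 coactivator — and exactly 12 free parameters:
3 affinities, 2 recruitment cooperativities, 2 proximal-pair
interactions, 3 polymerase attractions (one per activating configuration
class), basal and scale.  The breakdown is one plausible allocation
consistent with the printed parameter count; it is a design choice of
this package, not an established fact about any particular promoter.

## Score and global fitting

`S = ⟨(s_d − s_m)²⟩/⟨(s_d − ⟨s_d⟩)²⟩` over all grid points: 0 for a
perfect fit, 1 for the constant time-average model, invariant under
common affine rescaling of data and model.  Because the constant model is
inside every form's parameter space (α → 0), a converged fit never scores
meaningfully above 1.

Optimization is simulated annealing in transformed coordinates (log for
`b, α, K, λ`; linear for `n`): geometric cooling (factor 0.85 by
default), 100 single-coordinate Gaussian moves per temperature,
per-temperature step-size adaptation toward 44% acceptance, initial
temperature calibrated so ~80% of probe moves are accepted, floor at
1e−5 of the initial temperature, 5 independent restarts with the best
kept, followed by a derivative-free Nelder–Mead polish.  These
hyperparameters are this package's choices — the annealing variant used
in the original analyses is not specified anywhere we could follow — and
were sized so that the documented recovery experiments run inside a CI
budget.  `fast_config()` (2 restarts, shorter chains) is the documented
scale-down used for batch network fitting, where λ is pinned and only
4–6 shape parameters remain.

Bounds: `K` within a factor 10 outside the observed input range; `b, α`
in `[1e−6, 10]·max(s_d)`; λ as above.  Ties between forms (within 1e−12
in score) resolve to fewer parameters, then fixed menu order — parsimony
first.

Replicates are never pooled: each replicate is fitted independently.

## Consensus half-lives

Per suitable target (periodic, score < 0.5 with the TF as input, fitted
regulatory sign matching the literature), a Metropolis chain samples all
fit parameters with stationary density `∝ exp(−S/T_mc)`.  The score is a
goodness measure, not a likelihood; `T_mc` is an explicit sharpness knob
set to 0.05, the order of the score difference separating competing
fits.  Marginals over λ are histogrammed on a shared grid of 100
log-spaced bins spanning half-lives 1–120 min and multiplied bin-wise;
the consensus λ is the center of the product's highest bin.  Empty bins
are genuine zeros — an all-zero product raises an error, surfacing
mutually inconsistent targets rather than smoothing them away.  Chains
run 20 000 steps with 25% burn-in; proposal scales adapt during burn-in
only, keeping the post-burn-in kernel fixed and the histogram exactly
reproducible per seed.

## Network inference

Candidate nodes are the periodic genes that, within the allowed
interaction table, both regulate and are regulated by another member
(iterated pruning to the fixed point).  Homologous, synchronously
expressed factors can be merged into one node by configuration.  Per
node, every allowed input set of size 1 or 2 is pre-fitted and only the
best-scoring form per input set is kept.  A network chooses one
candidate per node; its score is the arithmetic mean of node scores, so
ranking is exact without refitting.  Only strongly connected networks
(externals excluded) are admitted; enumeration is lazy best-first over
the per-node sorted menus, yielding networks in ascending score order
with deterministic lexicographic tie-breaks.

Periodicity flags are an upstream input.  The bundled
`periodicity_score` (fraction of spectral power near the target period)
is a labelled stand-in, not the established ranking method for DTA data.

## Network dynamics

`dm_i/dt = s_i(p_j, …) − δ_i m_i`, `dp_i/dt = λ_i(m_i − p_i)`, with
constant mRNA decay rates δ initialized from steady-state consistency
(`δ_i = ⟨s_i⟩/⟨m_i⟩`) and refined in the global refit.  Integration uses
LSODA with the analytic Jacobian (assembled from the GRF gradients) at
relative tolerance 1e−8, split at external-input switch times so the
policy discontinuity never sits inside an integrator step.  External
drivers are measured series turned into protein signals; after the
series ends the drive either drops to zero, holds its time average
(default), or holds its last value.  Knockouts clamp both mRNA and
protein of the named genes to zero — in the two-stage model protein
cannot outlive its transcript, and clamping both lets indirect effects
propagate cleanly.

The global refit adjusts all GRF shape parameters (and δ) jointly by
finite-difference gradient descent with a backtracking line search on the
summed per-gene variance-normalized mRNA residuals, starting from the
single-node fits; the objective is monotone by construction and the
starting model is returned if no descent step succeeds.  λ stays at its
consensus value during refit.

Oscillation diagnostics use the unbiased autocorrelation (each lag
normalized by its overlap count, truncated at half the window): the
dominant period is the first local maximum, and a trajectory is
classified sustained vs damped by the envelope of successive
autocorrelation maxima (median peak-to-peak ratio within 5% of 1 counts
as sustained).

## Synthetic data generator

The generator emulates the structure of synchronized-population DTA
measurements: 42 time points at 5-min spacing (0–205 min), two
replicates, oscillations near a 60-min period driven either externally
(cyclin-like sinusoidal driver) or by ring feedback.  On top of the
noiseless truth it applies, in order:

1. **Desynchronization damping** — each series' deviation from its time
   mean shrinks by `exp(−γ_sync·t)`, a first-order surrogate for phase
   diffusion in a desynchronizing population; it affects inputs and
   outputs alike, which is exactly the property that makes the nonlinear
   inference tolerant of it.
2. **Measurement noise** — i.i.d. multiplicative log-normal factors
   `exp(σZ)`, σ = 0.05 by default, reflecting expression-array error
   scaling.

Truth networks are integrated with the package's own ODE machinery from
a long washed-out transient (per-node staggered initial conditions —
a perfectly symmetric state can sit on an unstable fixed point of a ring
indefinitely), and the clean synthesis rate is the truth GRF evaluated
on the truth protein trajectories at the grid points, so the
self-consistency `s_clean = GRF(p_clean)` holds exactly.

Fixture notes:

- `ring_oscillator_5` uses stage half-lives of ~2–2.5 min, faster than
  the biological protein range: a five-stage free-running relaxation
  ring needs short delays to reach a ~60-min period (it lands at
  ~64 min).  The driven fixtures keep λ inside the 5–50 min range
  because their rhythm comes from the driver, as in the real system.
- In `two_input_and`/`two_input_xor`, thresholds sit at the realized
  protein mid-levels and the two drivers are phase-shifted (anti-phase
  for AND; 0.8 rad for XOR) so the data visit enough of the input plane
  to discriminate the logic.
- `driven_oscillator_10` is a forward-activation ring with four backward
  repressions and one externally driven node — the dominant motif
  structure of transcriptional cell-cycle modules.

**What a green test does and does not establish.**  The generator's
damping is exponential in time, not a mechanistic population-dispersion
model; its noise is uncorrelated across time points, unlike array
artifacts; mRNA sampling is exact at grid points rather than arising
from labeling kinetics; and real regulatory networks contain
post-transcriptional layers the model class excludes by construction.
Recovery results on this stated world therefore validate the inference
machinery, not the biological completeness of the model class.

## Degenerate inputs and errors

Constant observed series make the score undefined (zero variance) and
raise a dedicated degenerate-input error, as does min–max rescaling of a
constant test series.  Time-series files with non-numeric cells are
rejected with the gene and time named; missing time points are rejected
rather than imputed.  Disjoint λ posteriors raise rather than smooth.

## Known limitations

- Three-input general logic is out of scope (combinatorial data
  requirements); the composite form and the thermodynamic model are the
  two supported routes past two inputs.
- Scores of ODE-generated data carry an early-window floor from the
  warm-up mismatch discussed above.
- The MCMC pseudo-posterior has no probabilistic calibration; consensus
  modes are point estimates whose spread depends on `T_mc`.
- The ODE model cannot express checkpoint coupling or
  post-transcriptional activation, so knockout predictions for genes
  regulated at those layers are expected to fail.
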