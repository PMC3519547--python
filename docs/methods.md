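# Methods

## Model and assumptions

The remodeling of a single head-group class (diacyl PE in the canonical
setting) is modeled as a continuous-time linear mass-action system on the
set of observed molecular species. Three assumptions make the model small
enough to identify from a single pulse-chase time course:

1. **sn-position independence** — the sn1 and sn2 chains remodel
   independently, so every reaction changes exactly one chain and the
   reaction graph only connects species differing at one position;
2. **time-invariant rates** — each reaction is first-order with a constant
   rate over the chase;
3. **constant acyl-donor pools** — reacylation draws on donor pools large
   enough that their depletion is negligible, so rates do not depend on the
   system state beyond the source species concentration.

Under these assumptions the concentration vector obeys x′(t) = A(θ)x(t)
with one parameter per directed edge: species i gains θ_e·x_source for each
incoming edge e and loses θ_e·x_i for each outgoing edge. Columns of A sum
to zero, so total label is conserved — head-group degradation and de novo
synthesis of labeled material are outside the model.

The model is deliberately agnostic about concentration units (arbitrary
MS-intensity units are fine); fit errors scale with the square of the unit,
rates do not. Ether-linked species and cross-class head-group fluxes are
out of scope.

## Network inference

Working on replicate means per (species, time), the reduced reaction
network is inferred by a correlation analysis:

- **Sources.** At each time index h, a species is a candidate source if its
  replicate values decrease significantly toward h+1 under a one-sided
  Welch t-test at level α (default 0.3, constant across time points; a
  per-time-point schedule is accepted). Exact replicates (zero spread at
  both times) are decided by strict mean decrease, since the t statistic is
  undefined there; time points with a single replicate fall back to a
  relative mean-decrease margin (5%, logged).
- **Candidates.** Targets are observed species sharing exactly one chain
  with the source. Unobserved species never enter the network.
- **Score.** The edge score is the negated Pearson correlation of the two
  mean series over an evidence window, clipped to [−1, 1], with a sign
  guard forcing the score non-positive when the target never increases
  inside the window (a species that never accumulates cannot be the
  product). Zero-variance series score 0.
- **Acceptance.** An edge is accepted when its score exceeds
  `corr_threshold` (default 0.5), or — second-order rule — when the target
  does increase somewhere in the window and some neighbor w of the target
  anticorrelates above threshold with both the source and the target
  (source → target → w with a transient target). The accumulation condition
  matters: without it, two sources draining into a shared sink get linked.
- **Window shrinking.** Scanning starts on the full remaining range
  (h, H); if nothing is accepted the window end retracts one point at a
  time down to `min_window` (default 3 — a two-point correlation is
  degenerate). Sources flagged in the last intervals have their window
  start clamped back so the window always spans `min_window` points.
- **Multi-target diagnostic.** A source assigned several targets is
  re-scored against the sum of its targets' series. A failing combined
  score is logged; optional `prune_multitarget` reduces such a source to
  its best single edge, but the default keeps all individually accepted
  edges — pruning destabilized rate estimates across threshold settings.

All passing targets at the productive window are accepted (the observed
edge-count-versus-threshold behavior of the method requires multi-edge
sources), and edges found at several time points are merged keeping the
best score. Before fitting, the network is closed under reversal
(`bidirectionalize`, reverse edges entering with score 0): one-way networks
bias kinetic estimates because back-reactions are real.

The default `corr_threshold = 0.5` was calibrated on synthetic data by
counting recovered true edges and false edges over five scenarios at
thresholds 0.3–0.6: recovery is flat over 0.3–0.5 (zero false positives
throughout) and degrades at 0.6.

## Rate fitting by spline collocation

Each trajectory is expanded on clamped cubic B-splines with uniform
interior knots over the observed time range: 5 basis functions for the
initial smoothing ("shooting"), then 21 for the working representation,
with 49 evenly spaced collocation points. The objective is

    E_total(θ, β) = E_obs(β) + λ · E_ode(θ, β)

where E_obs sums squared deviations of the spline curves from the replicate
means over (species, observation time) and E_ode sums squared residuals
x̂′ − A(θ)x̂ over (species, collocation point). E_total is exactly
quadratic in θ at fixed β and in β at fixed θ, so the fit alternates two
linear least-squares solves via SVD (`numpy.linalg.lstsq`); rank-deficient
designs yield minimal-norm solutions and are flagged. Iteration stops when
the relative change of E_total drops below `tol` (default 1e-6) or at
`max_iter` (default 1000); because the trace can oscillate, the reported
solution is the best iterate seen, and the trailing-window minimum is used
when the budget is exhausted.

Numerical choices:

- **λ default 1.0.** Rate estimates on noiseless chain data agree to better
  than 0.1% across λ ∈ {0.1, 1, 10} in non-negative mode.
- **Non-negativity.** The default θ-solve is unconstrained; `nonneg=True`
  switches to NNLS. At λ ≫ 1 the unconstrained alternation can converge to
  a sign-indefinite stationary point with a far higher error than the true
  optimum (observed at λ = 10 on noiseless data), and on multi-edge
  networks the constraint noticeably improves rate recovery; the
  non-negative mode is recommended whenever rates are meant to be physical,
  and is used by the control and robustness protocols.
- **Fitting target.** Replicate means per (species, time); per-replicate
  fitting is not implemented because replicate counts may differ per time
  point and the mean ± SEM is the quantity the experiments report.
- **Initialization.** A 5-basis least-squares smooth of the means,
  refitted onto the 21-basis span at the collocation points. No constraint
  links the spline to x ≥ 0; near-zero data may produce infinitesimally
  negative spline values.
- **Verification.** `verify_by_integration` integrates the fitted system
  with adaptive Runge–Kutta (reporting step 0.01 h, rtol 1e-8) and reports
  the deviation from the collocation trajectory; on fitted synthetic data
  the two agree to within 2% of the trajectory scale.

## Deacylation/reacylation decomposition

Writing d_i for the deacylation rate of chain i and a_j for the reacylation
rate of chain j at one sn position, and assuming the lyso intermediate pool
is at steady state (lyso species are scarce relative to diacyl species),
the effective conversion rate is k_{i→j} = d_i·a_j / Σ_l a_l. Absolute d
and a are unidentifiable from k alone — only ratios survive, which is why
the module returns relative rates against a reference chain.

Relative rates are arithmetic means of pairwise ratios over all shared
rows/columns (a geometric-mean mode is available); with a rank-1 input
table the round trip is exact by construction. Entries marked missing are
excluded, never zeroed. Tables may contain several rows for the same
initial chain (independent experiments); ratio operations average over all
row pairs. Rows whose reacylation preference orderings conflict — as the
22:6 row does against the 14:1 row at sn2 in the packaged table — are
surfaced by `reacylation_consistency` as a diagnostic of sn-position
cross-talk, not corrected.

## Synthetic data

The simulator emulates the statistical structure of a cyclodextrin
pulse-chase: precursor-loaded initial state, sampling at {0, 1, 2, 4, 8,
24} h, 3 replicates, multiplicative lognormal noise with CV 0.10
(mean-preserving), optional detection floor censoring to zero. Trajectories
are propagated with the matrix exponential, which is exact for a linear
system, keeping the simulator independent of the Runge–Kutta route used for
verification. Ground truth (noiseless trajectory, true network, true rates)
is returned alongside the data.

Canonical scenarios:

- `single_path_spec` — 3-species chain 18:3-18:3 → 18:1-18:3 → 18:1-18:1
  (rates 0.25, 0.05 /h), the smallest end-to-end recovery exercise;
- `control_path_spec` — 5-species chain with rates 0.3/0.15/0.08/0.05 /h so
  flux reaches every species within the chase; used by the negative
  controls;
- `grid_remodeling_spec` — full 3×2 chain grid (6 species, 18 reactions)
  with rank-1 rates spanning ~0.003–0.3 /h, mirroring the two-orders-of-
  magnitude spread of measured primary rates; used by the threshold
  robustness protocol.

What the simulator does **not** emulate: positional-isomer ambiguity of MS
spectra, missing species, heteroscedastic detector noise, head-group
interconversion, donor-pool depletion. Tests passing on these data
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to every artifact of real spectra.

## Negative controls

- **Label permutation.** Species labels of the data are permuted uniformly
  (identity allowed) and each permuted dataset is refit against the system
  inferred from the *unpermuted* data; the real fit error is compared with
  the null mean and standard deviation. One structural caveat, documented
  because it bounds the achievable separation: a permutation that realizes
  a graph automorphism of the fitted network yields *exactly* the real
  error, since rates are refit and the problem is isomorphic. Chain
  networks are reversal-symmetric and isolated species are mutually
  interchangeable, so on small panels the null distribution has an
  irreducible floor at the real error and a wide spread; the 5-species
  control chain with non-negative fits gives a population separation of
  about 2 null standard deviations (exhaustive enumeration of all 120
  permutations), and a 20-permutation sample fluctuates around that value.
  Larger panels with asymmetric networks would separate more sharply in
  the mean but also admit more flexible refits; specificity claims should
  always be read against the panel size.
- **Parameter perturbation.** The major-flux reactions (default: the
  precursor's conversions to 18:1 at either position) are deleted — both
  directions, so the bidirectional closure cannot silently restore them —
  and replaced by randomly drawn single-position reactions among observed
  species; the refit error is compared with the unperturbed fit. On grid
  data the perturbed error exceeds the real error for every draw.

## Known limitations

- Sources are only detectable while their concentration falls; a terminal
  species that rises monotonically can never seed an outgoing edge, so
  slow conversions out of late-accumulating species are invisible to the
  correlation step (they can still be fit if the edge enters the network
  through bidirectionalization of the reverse direction).
- With ~6 time points, evidence windows near the end of the chase span only
  3 points; 3-point correlations are coarse, which is why the acceptance
  threshold, not the window length, carries the specificity burden.
- Unconstrained fits may return small negative rates that absorb noise;
  they are flagged, and the non-negative mode avoids them at slightly
  higher fit error.
- The decomposition's absolute d and a scales are unidentifiable without
  lyso-pool measurements; only relative rates are reported.
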