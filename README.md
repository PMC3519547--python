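# lipidremodel

Inference of phospholipid acyl-chain remodeling networks and kinetics from
pulse-chase lipidomic time courses.

## The problem

Glycerophospholipids carry two acyl chains, at the sn1 and sn2 positions of
the glycerol backbone. Cells continuously remodel these chains through the
Lands cycle: a phospholipase removes one chain (deacylation), leaving a
transient lyso-lipid, and an acyltransferase attaches a new one
(reacylation). In a pulse-chase experiment a labeled precursor species —
say PE 18:3-18:3 — is loaded into cells and its conversion into other
species is followed by mass spectrometry over ~24 h. The question is which
conversion reactions actually carry flux, at what first-order rates, and
what those rates say about the chain preferences of the deacylating and
reacylating enzymes at each sn position.

`lipidremodel` answers this in two steps plus a decomposition:

1. **Network inference.** Under the assumption that the two sn positions
   remodel independently, any single reaction changes exactly one chain, so
   candidate reactions connect species differing at one position. Species
   whose concentration falls significantly between consecutive time points
   (one-sided Welch t-test on replicates) are treated as sources; a
   candidate edge source → target is accepted when the two mean
   concentration series are inversely correlated (negated Pearson
   correlation above a threshold) over an evidence window, which shrinks
   from the full remaining time range until evidence is found. A
   second-order rule rescues targets that are themselves drained onward.
2. **Rate fitting by B-spline collocation.** The bidirectional network
   compiles to a linear mass-action system x′(t) = A(θ)x(t), one rate per
   directed edge. Each trajectory is represented on a cubic B-spline basis
   (21 basis functions, 49 collocation points) and the objective
   E_total = E_obs + λ·E_ode couples the distance to the observed replicate
   means with the squared ODE residual at the collocation points. E_total
   is quadratic in θ at fixed spline coefficients β and vice versa, so the
   fit alternates two linear least-squares solves (SVD-based; optional
   non-negativity on rates). A Runge–Kutta integration of the fitted system
   cross-checks the collocation solution.
3. **Deacylation/reacylation decomposition.** With the lyso pool at steady
   state, the effective conversion rate from chain i to chain j at one
   position is rank-1: k_{i→j} = d_i·a_j / Σ_l a_l. Ratios within a column
   therefore give relative deacylation rates d_i/d_i′ and ratios within a
   row give relative reacylation rates a_j/a_j′, averaged over all shared
   rows/columns of a rate table.

A pulse-chase simulator (exact matrix-exponential kinetics, lognormal
replicate noise) generates data with known ground truth, so the entire
pipeline is testable without any experimental download. Negative controls
(species-label permutation, major-parameter perturbation) quantify fit
specificity.

## Worked example

```python
import lipidremodel as lr

# simulate a noisy chase through 18:3-18:3 -> 18:1-18:3 -> 18:1-18:1
tc, truth = lr.simulate_pulse_chase(lr.single_path_spec(noise_cv=0.10, seed=42))

net = lr.infer_network(tc, lr.InferenceConfig())
for e in net.edges:
    print(f"{e.source} -> {e.target}  ({e.position}, score {e.score:.2f})")

sys = lr.build_ode(lr.bidirectionalize(net))
fit = lr.fit_dynamics(tc, sys)
for e, th in zip(sys.edges, fit.theta):
    print(f"{e.source} -> {e.target}: {th:+.4f} /h")
```

prints

```
18:1-18:3 -> 18:1-18:1  (sn2, score 0.81)
18:3-18:3 -> 18:1-18:3  (sn1, score 0.98)
18:1-18:3 -> 18:1-18:1: +0.0448 /h
18:3-18:3 -> 18:1-18:3: +0.2356 /h
18:1-18:1 -> 18:1-18:3: -0.0030 /h
18:1-18:3 -> 18:3-18:3: -0.0044 /h
```

The true conversion path is recovered exactly; the fitted forward rates
(0.236 and 0.045 /h against true values 0.25 and 0.05 /h) are within the
expected tolerance for 10% replicate noise, and the reverse reactions,
which carry no true flux, fit near zero.

The rate-table decomposition works directly on a published table. With the
packaged BHK21 table:

```python
from lipidremodel import load_reference_rate_tables, pairwise_rate_ratio, relative_deacylation
from lipidremodel.lipid_model import AcylChain

sn1 = load_reference_rate_tables()["sn1"]
pairwise_rate_ratio(sn1, AcylChain.parse("14:0"),
                    AcylChain.parse("18:1"), AcylChain.parse("18:0"), ndigits=2)
# 5.36  — 14:0 converts to 18:1 5.36x faster than to 18:0 at sn1
relative_deacylation(sn1, AcylChain.parse("14:0")).ratios
# {14:0: 1, 14:1: 6.58, 18:3: 2.99, 18:0: 0.77, 18:1: 0.20}
#   -> sn1 deacylation order 14:1 > 18:3 > 14:0 > 18:0 > 18:1:
#      unsaturated chains are removed faster from sn1 than saturated ones
```

A command-line surface wraps the same stages:

```sh
lipidremodel simulate --noise-cv 0.1 --seed 42 --out tc.tsv --truth truth.json
lipidremodel infer-network --input tc.tsv --alpha 0.3 --corr-threshold 0.5 --out edges.tsv
lipidremodel fit --input tc.tsv --network edges.tsv --lambda 1.0 --out fit.json
lipidremodel decompose --rates src/lipidremodel/data/remodeling_rates_bhk21.tsv \
    --ref-deacyl 14:0 --ref-reacyl 18:1 --out relrates.json
lipidremodel permute --input tc.tsv --network edges.tsv --n 100 --seed 17 --out control.json
lipidremodel run --input tc.tsv --out-dir run/
```

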