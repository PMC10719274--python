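# impnet

Tools for studying how impulsivity relates to the topology of weighted
white-matter brain networks. The package covers the full analysis chain:

1. **Delay discounting (behavior).** Each subject's discount rate *k* is
   estimated from intertemporal choices (smaller-immediate vs.
   larger-delayed reward) under the hyperbolic value model
   *SV* = *A* / (1 + *kD*), with the probability of choosing the delayed
   option modeled as logistic(β·ΔSV) and (*k*, β) fitted by maximum
   likelihood. Subjects who chose the same option on every trial are
   excluded. BIS-11 questionnaires (30 items) are scored into attentional,
   motor and non-planning impulsiveness subscales.
2. **Connectome construction (network).** A symmetric weighted network over
   atlas regions (90-region AAL cerebrum by default) is built from
   tractography summaries: *W*ᵢⱼ = FN × FA / v̄ᵢⱼ, where FN is the
   streamline count, FA the mean fractional anisotropy, and v̄ᵢⱼ the average
   volume of the two regions.
3. **Topology metrics (metrics).** Weighted clustering coefficient *Cp*,
   characteristic path length *Lp* (distances *d* = 1/*W*), global and
   local efficiency, degree and betweenness centrality, and hub detection
   (> 1 SD above the nodal mean). *Cp* and *Lp* are normalized against the
   means of 100 degree-matched rewired null networks:
   γ = *Cp*/*Cp*ʳᵃⁿᵈ, λ = *Lp*/*Lp*ʳᵃⁿᵈ, σ = γ/λ; σ > 1 indicates
   small-world architecture.
4. **Association analysis (stats).** Spearman rank correlation between
   behavioral scores and each topological measure, computed on residuals
   after regressing out age, sex and education years; *p* < 0.05 for global
   measures and *p* < 1/*n*_nodes (= 0.011 for 90 nodes) for nodal measures.
5. **Synthetic cohorts (synthetic).** A generator producing complete
   cohorts — choice data on the 120-trial task grid, BIS-11 items,
   covariates, small-world connectomes — with known ground truth and
   optionally a planted monotone association between log *k* and
   small-worldness, so every stage is testable end to end.

## Worked example

```python
from impnet.synthetic import simulate_choices, simulate_connectome, NetworkParams, TaskDesign
from impnet.behavior import ChoiceDataset, fit_discounting
from impnet.metrics import global_metrics

trials = simulate_choices(k=0.0164, beta=0.005, design=TaskDesign(), seed=11, subject_id="demo")
fit = fit_discounting(ChoiceDataset("demo", trials))
print(f"k = {fit.k:.4f}   log10 k = {fit.log10_k:.3f}   beta = {fit.beta:.4f}")

net = simulate_connectome(NetworkParams(n_nodes=90, mean_degree=8, rewiring_prob=0.1), seed=11)
gm = global_metrics(net, n_nulls=100, seed=11)
print(f"Cp = {gm.Cp:.3f}  Lp = {gm.Lp:.3f}  gamma = {gm.gamma:.3f}  "
      f"lambda = {gm.lambda_:.3f}  sigma = {gm.sigma:.3f}")
```

prints

```
k = 0.0159   log10 k = -1.799   beta = 0.1959
Cp = 0.084  Lp = 2.578  gamma = 6.829  lambda = 1.308  sigma = 5.220
```

The simulated subject's discount rate (true *k* = 0.0164, a typical
young-adult value meaning a 180-day delay roughly quarters a reward's
subjective value) is recovered as 0.0159; β is only weakly identified when
choices are nearly deterministic, which does not affect *k*. The 90-node
network with 10% rewiring shows the expected small-world signature: heavily
elevated clustering relative to degree-matched nulls (γ ≈ 6.8) at modestly
longer paths (λ ≈ 1.3), hence σ ≈ 5.2 > 1.

The same stages are available from the shell:

```
impnet simulate --out cohort/ --seed 1 --n-subjects 65
impnet fit-dd cohort/choices.csv --out fits.csv
impnet run --config run.yaml --out results/ --seed 1
```

`impnet run` executes the whole pipeline (fits → exclusion log → topology
reports → cohort table → association battery → manifest) from a YAML config.

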