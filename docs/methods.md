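# Methods

## Behavioral model

Choices between a fixed immediate reward and a larger-delayed reward are
modeled with hyperbolic discounting, SV = A/(1 + kD), where A is the reward
amount, D the delay in days and k (> 0, per day) the subject's discount
rate. The probability of choosing the delayed option is
logistic(β·(SV_del − SV_imm)) with a free sensitivity slope β ≥ 0 and no
intercept: on this design an intercept is not identified separately from k,
and the choice probability is by construction a function of the subjective
value difference alone.

(k, β) are estimated by maximizing the Bernoulli log-likelihood, written in
the numerically stable softplus form with an analytic gradient, over
(log10 k, log10 β). Because the surface can be multimodal for extreme
preference patterns, the optimizer screens a log-spaced 8 × 4 start grid
(k from 1e-4 to 1, β from 1e-4 to 0.1) by likelihood and polishes the four
best basins with bounded L-BFGS-B. Box bounds are k ∈ [1e-6, 10] per day and
β ∈ [1e-6, 1e3]; a solution at a bound is flagged (`at_bound`) rather than
discarded, since nearly-deterministic responders legitimately push β toward
its upper bound while k remains well identified. Estimates are reported as
log10 k (the dominant convention in the discounting literature; monotone
transforms do not affect the downstream rank correlations).

Subjects who chose the same option on all trials are excluded before
fitting ("always-delayed" / "always-immediate"): their likelihood is
maximized on the boundary and carries no information about k.

BIS-11 scoring follows the published 30-item key: reverse-keyed items are
reflected (5 − response), then summed into attentional (8 items), motor
(11) and non-planning (11) subscales plus the total (range 30–120). The key
ships as `data/bis11_key.yaml` and can be replaced by a user file.

## Network construction

Edge weights combine streamline count FN and mean fractional anisotropy FA,
normalized by the arithmetic mean of the two regions' volumes:
W_ij = FN·FA / ((v_i + v_j)/2). The volume normalization compensates for
larger regions attracting more streamlines. No density thresholding or
binarization is applied — each subject contributes a single weighted
network. Disconnected nodes are retained; the metrics handle them
explicitly. The packaged AAL-90 node table fixes the region order (left and
right hemispheres interleaved); its volume column holds synthetic nominal
values because region volumes are subject-specific in native space and are
normally supplied with the data.

## Topology metrics

- **Distances.** d_ij = 1/W_ij for present edges, infinite otherwise.
  Reciprocal weight is the standard connectome convention: stronger
  connections transfer information faster.
- **Clustering Cp.** Geometric-mean (Onnela-type) triangle intensity on
  weights rescaled by the network maximum; per-node values lie in [0, 1]
  and reduce to binary clustering for unit weights (a K-neighbor ring
  lattice gives exactly 3(K−2)/(4(K−1))). Nodes with fewer than two
  neighbors score 0.
- **Path length Lp.** Mean shortest-path distance (Dijkstra) over reachable
  ordered pairs; the count of unreachable ordered pairs is reported
  alongside instead of folding a sentinel into the mean. The
  harmonic-mean alternative is exactly what global efficiency captures, so
  both are exposed as separate quantities.
- **Efficiency.** E_glob = mean of 1/d over ordered pairs (1/∞ = 0);
  nodal E_loc(i) = E_glob of the subgraph induced on i's neighbors with
  original weights, 0 for nodes with < 2 neighbors; global E_loc is the
  nodal mean.
- **Centrality.** Degree centrality defaults to strength (weight row sums)
  with a binary mode switch; betweenness uses Brandes' algorithm on the
  reciprocal-weight distances with fractional sharing among equal-length
  paths and endpoints excluded. Raw pair counts are kept — the subsequent
  mean-normalization cancels any constant factor. Both nodal vectors are
  normalized by their network mean, and hubs are nodes exceeding the mean
  by more than one sample (n−1) standard deviation.
- **Null model.** Each of the (default) 100 surrogates randomizes the
  binary topology by degree-preserving double-edge swaps (10 successful
  swaps per edge) and then reassigns the original weight multiset to the
  rewired edges at random. This preserves n, the edge count, the exact
  degree sequence and the weight distribution while destroying clustering
  structure. When no legal swap exists (complete graphs) the surrogate
  keeps the source topology and a warning is emitted. γ = Cp/Cp_rand,
  λ = Lp/Lp_rand, σ = γ/λ, with the null values averaged over the
  ensemble. All randomization is reproducible from an integer seed.

Correctness of the path-based metrics is established against naive
references (Floyd–Warshall triple loop; exhaustive simple-path enumeration
for betweenness) on random graphs of up to 8 nodes, at 1e-10 tolerance.

## Association analysis

Both the behavioral score and the topological measure are residualized by
OLS on [intercept, age, sex, education years]; Spearman's rho is then
computed on the residuals (ranks taken after residualization, average ranks
for ties). Two-sided p-values use the t approximation with n − 2 degrees of
freedom; an exact permutation option exists for small samples. The battery
tests every behavioral × metric pair, applying p < 0.05 to global measures
and p < 1/n_nodes to nodal measures, with no further multiple-testing
correction — the two fixed thresholds are the analysis contract. Because
every pair shares one covariate design, the battery residualizes all
columns in a single projection; this is algebraically identical to per-pair
residualization. The top decile of |rho| among nodal pairs is flagged for
reporting.

## Synthetic cohorts

The generator emulates the study conditions end to end:

- **Task grid:** 120 trials; immediate reward fixed at 10,000; delayed
  reward uniform on 11,000–48,000 in steps of 1,000; delay uniform on
  2–180 days. The exact trial list of the original task is not published,
  so trials are drawn uniformly from the grid.
- **Population:** log10 k ~ Normal(−1.9, 0.45), straddling the typical
  young-adult mean rate of about 0.016/day; β = 0.005 (sharp but stochastic
  choices); age ~ Normal(22.06, 2.77), education ~ Normal(15.05, 1.30),
  sex Bernoulli(0.43), mutually independent and independent of behavior so
  that residualization is exercised without confounding.
- **BIS items:** a latent trait (correlated 0.3 with standardized log k,
  echoing the commonly reported modest DD–questionnaire association) is
  mapped onto each item's 1–4 scale with Gaussian noise (sd 0.6) and
  rounding; reverse-keyed items are stored reflected.
- **Connectomes:** Watts–Strogatz ring-lattice topology (90 nodes, mean
  degree 8, rewiring 0.1 by default; Erdős–Rényi and pure lattice variants
  available) realized as tractography-style edge records — FN log-normal,
  FA ~ Normal(0.45, 0.08) clipped to [0.05, 0.95] — so cohorts exercise the
  same W = FN·FA/volume construction as real inputs.
- **Planted effect:** the subject-level rewiring probability is a noisy
  monotone function of log k (higher k → more rewiring → lower σ), mapped
  rank-wise onto [0.05, 0.6]. Rewiring directly manipulates small-worldness
  without changing degree or density. The coupling strength is
  target/0.95, where 0.95 is the attenuation |rho(knob, realized σ)|
  measured once by pilot simulation at the scaled cohort conditions
  (6 replicate cohorts, n = 65, 45 nodes, 20 nulls: 0.958 ± 0.011) and
  frozen. Requested |rho| above the attenuation bound raises an error
  stating the attainable maximum.

What the generator does **not** emulate: real anatomical geometry,
hemispheric symmetry, distance-dependent connection probability, the
log-normal strength hierarchy of real connectomes, questionnaire
item-level factor structure, or any confounding between covariates and
brain/behavior variables. Passing end-to-end tests therefore demonstrates
that the pipeline recovers known monotone brain–behavior associations at
realistic sample sizes and noise levels — not that it reproduces any
specific empirical cohort's values.

## Problem sizes and determinism

Default analyses use 100 nulls per network. The end-to-end recovery study
runs 50 cohorts of 65 subjects with 45-node networks and 20 nulls — scales
chosen so the whole validation runs comfortably on a single CPU while
keeping the power of the planted-effect test above the 80% design point.
All randomness descends from a single integer seed through
`numpy.random.SeedSequence` spawning, split per stage and per subject, so
identical configurations reproduce byte-identical outputs regardless of
execution order.

## Known limitations

- β and k trade off weakly on near-separable data; β is reported but only k
  (as log10 k) feeds the association stage.
- Whether the original GRETNA-based analysis used strength or binary degree
  on weighted matrices is not documented; both modes are implemented and
  the choice is a config key (`degree_mode`).
- Lp averages over reachable pairs only; heavily fragmented networks push
  interpretation toward E_glob, which is reported alongside.
- The hub rule uses the sample (n−1) standard deviation; with 90 nodes the
  distinction from the population form is negligible but it is fixed here
  for determinism.
- The planted-effect calibration constant is specific to the σ channel and
  the default rewiring range; planting through other metrics would require
  a fresh pilot.
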