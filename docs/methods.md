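# Methods

## Network model and statistics

The regulatory network is a directed bipartite graph (miRNA → target).
Duplicate edges collapse; a node id may appear in only one partition.
Global statistics follow the conventions of desktop network-analysis tools
and are computed on the undirected simple projection:

- avg. neighbors = mean distinct-neighbor count; density = 2E/(N(N−1));
- diameter, radius and characteristic path length are taken **within the
  largest connected component** — on a multi-component graph they are
  undefined globally, and a finite published value on a 28-component
  network implies some such convention. The choice is recorded in
  `NetworkStats.conventions`;
- local clustering of degree-<2 nodes counts as 0 and enters the mean;
- heterogeneity = √var(k)/mean(k) with population variance;
- centralization = (N/(N−2))·(k_max/(N−1) − density).

The out-degree filter (default bounds 1–56, inclusive) acts on the
*directed* graph: miRNAs outside the band are dropped with their edges,
and orphaned targets are removed.

`anneal_order` ranks node prominence by a seeded Metropolis schedule
(geometric cooling T ← 0.95·T, 100·N transposition proposals) maximizing
Σ position·w with w = degree·(1 + local clustering), followed by a
deterministic stable adjacent-swap polish. The weight is a product of
degree and a clustering term offset by one: on a bipartite graph every
local clustering coefficient is zero, so a bare product would make all
weights vanish and the ordering meaningless; the offset keeps degree as
the dominant signal while still boosting clustered nodes in general
graphs. Equal-energy proposals are rejected, so all-tied inputs keep
their order.

## Hub scoring

Eleven node scores (plus BottleNeck) on the undirected projection:

| method | definition |
|---|---|
| MCC | Σ over maximal cliques C ∋ v, \|C\| ≥ 2, of (\|C\|−1)! |
| MNC | nodes in the largest component of the N(v)-induced subgraph |
| DMNC | edges/nodes^ε of that component, ε = 1.7 (plugin default) |
| EPC | mean component size containing v over seeded percolation draws (each edge kept with p = ½; 1000 draws by default) |
| Radiality | Σ_u (diam(C_v) + 1 − d(v,u)) / (N−1) within v's component |
| Degree / Closeness / Betweenness | standard; closeness is the within-component form (n_reach−1)/Σd, betweenness unnormalized |
| EdgeBetweenness | node score = Σ of incident-edge betweenness |
| ClusteringCoefficient | local clustering, ranked higher-is-better (plugin behavior, even though hubs tend to score low) |
| Stress | # shortest paths through v (Brandes-style accumulation) |
| BottleNeck | # of BFS shortest-path trees (smallest-id predecessor) in which > \|T\|/4 of the tree's nodes route through v |

All are deterministic except EPC, which is seeded. Ranks use min-tie;
top-k ties break by node id so every list is reproducible. Hubs are the
nodes occurring most often across the per-method top-10 lists.

Over-representation uses the one-sided hypergeometric tail
P(X ≥ k) with Benjamini–Hochberg step-up applied across exactly the terms
with nonzero query overlap (matching common over-representation tools);
enrichment-map edges carry Jaccard |A∩B|/|A∪B| or overlap
|A∩B|/min(|A|,|B|) weights with a 0.25 default cutoff.

## GSEA

Signal-to-noise ranking (μ₁−μ₂)/(σ₁+σ₂) with each σ floored at
max(0.2·|μ|, 0.2) to guard constant genes; ties break by gene id. The
running sum increments |metric|^p (normalized over hits) at set members
and decrements 1/(N−|S|) at misses; ES is the signed maximum deviation and
the leading edge is the set members at or before (positive ES) / at or
after (negative ES) the extremum. Default weight p = 1, the standard tool
default; with p = 0 the statistic reduces to the classical
Kolmogorov–Smirnov running sum, which is what the brute-force oracle in
the tests recomputes.

Permutation significance: p = (1 + #{perm ES at least as extreme, same
sign}) / (1 + #{perm ES of the same sign}), NES = ES / mean |same-sign
perm ES|. Conditioning the denominator on the sign is what keeps the null
p-value uniform — dividing by all permutations would systematically halve
null p-values; the calibration test (200 replicate null generations,
Kolmogorov–Smirnov at 0.01) verifies this. Phenotype permutation is used
when both classes have ≥ 7 samples, gene-label permutation otherwise
(standard small-sample guidance; with 3 samples per class only 20 distinct
label shuffles exist).

## Seed matching

Site patterns come from the mature miRNA's seed (positions 2–8): 7mer-m8 =
reverse complement of 2–8; 8mer = 7mer-m8 + A; 7mer-A1 = reverse
complement of 2–7 + A; 6mer = reverse complement of 2–7. Matching is an
exact-string KMP automaton (prefix function exposed and oracle-tested
against the quadratic scan), case-insensitive, U ≡ T. Overlapping hits
resolve by precedence 8mer > 7mer-m8 > 7mer-A1 > 6mer, then leftmost
start, with accepted sites consuming their window — each window is typed
once, deterministically. Coordinates are 1-based inclusive ("Position
768-774" style); 6mers are reported only on request since canonical target
tables list 7–8mer sites.

`simple_context_score` is an explicitly simplified, fixed-weight surrogate
(type weights −0.31/−0.16/−0.10/−0.03; AU weight −0.06 on (AU−0.5);
3′-pairing −0.03·run/4; distance +0.05·min(d,1500)/1500). It reproduces
the canonical type-strength ordering (more negative = stronger) and
nothing more; its numeric values are **not** comparable to trained
context++ scores, whose regression coefficients are proprietary to the
upstream predictor and out of scope.

## Circuit model

Five dynamic species — two ring repressors, LacR, miR-520c-3p, GFP — and
one external input (IPTG). Wiring: repressor1 ⊣ repressor2 ⊣ LacR ⊣
repressor1 (the ring), and active LacR represses the single promoter
transcribing miR-520c-3p and GFP together (polycistronic, so reporter and
payload co-switch). IPTG–LacR binding is treated as instantaneous
equilibrium sequestration, free LacR = LacR_total/(1 + (IPTG/K_I)^h),
rather than an explicit binding ODE — it matches the qualitative
"inducer binds the repressor" picture with two parameters instead of four.

Per-gene dynamics d[x]/dt = α₀ + α·Kdⁿ/(Kdⁿ + [R_free]ⁿ) − δ·[x], with
dimensionless concentrations and nominal repressilator-style rates
α = 50, α₀ = 0.05, n = 2, δ = 1, K_I = 1, h = 2. Dissociation constants
are per-promoter: **ring operators Kd = 100, output operator Kd = 1**.
The separation matters: with the ring fixed point near 42 the output
promoter (Kd = 1) is repressed ~1800-fold in the OFF state (steady GFP ≈
0.08 = α₀/δ·(1+leak), far below the OFF threshold 0.1·α/δ = 5) and fully
active in the ON state (steady GFP ≈ 50 > 0.5·α/δ). A single intermediate
Kd for every operator leaves the output only partially repressed
(steady ≈ 0.3·α/δ) and, if the ring coupling is made strong, turns the
ring into an oscillator — both of which contradict the clean two-state
switching the design targets. The weakly-coupled ring keeps LacR high and
near-constant in total, so the switching signal lives entirely in its
*active* (IPTG-free) form — which is also why trajectories report free
LacR as the LacR readout.

Integration is LSODA (stiff-capable) at rtol 1e−8 / atol 1e−10 on a
uniform grid (default 100 points over t ∈ [0, 100]); outputs are clipped
at zero. Case analysis: `off_case1` (IPTG = 0) labels OFF when steady GFP
< 0.1·α/δ, `on_case2` (IPTG = 100·K_I) labels ON when steady GFP >
0.5·α/δ; anything between returns an explicit "indeterminate" rather than
a silent label.

### Boolean stage

Binarization thresholds at the per-species midrange (min+max)/2; when
several runs are compared (the two induction cases) the thresholds are
shared across runs so that states are comparable. Near-constant species
(range < 1e−9·max) binarize to their rounded level clipped to {0, 1}.

Best-fit inference searches all input sets of size ≤ 3 per variable,
scores each candidate truth table by transition mismatches (majority vote
per observed input state; transitions counted within runs only), and
breaks ties by fewer inputs, then lexicographically smallest input index
set, then fewest 1-entries; unobserved input rows map to 0. Updating is
synchronous (the common default for qualitative circuit models).
Attractors are enumerated exhaustively over all 2ⁿ states per frozen
input condition (capacity-guarded at 2²⁰), with basin sizes that must
partition the state space; an independent plain state-space loop verifies
the enumeration in the tests up to n = 10.

With the default sampling grid (Δt ≈ 1 at δ = 1) every switching species
crosses its threshold within one sample, so the fitted rules are the
intuitive ones — ring genes constant-on, LacR = NOT IPTG, miR = GFP =
IPTG — and the system has exactly two attractors across the two input
conditions: OFF (LacR active, outputs silent) and ON (outputs high).

## Dynamic network inference

Lag-1 linear model per target gene i: x[t+1,i] = Mu_i + Σ_j
Gamma_ij·B_ij·x[t,j] + ε, ε ~ N(0, 1/Lambda_i), self-links excluded, data
standardized per gene. Priors: Gamma_ij ~ Bernoulli(ρ) with ρ = 1/G; slab
B_ij ~ N(0, 2) (appropriate on standardized series); Lambda_i ~
Gamma(2, rate 0.01); Mu_i ~ N(0, 10). The Gibbs sweep integrates B_ij out
of each inclusion update (conditional Bayes factor with Occam factor
√(v₀/v) and data term exp(m²v/2)), then draws B_ij from its Gaussian full
conditional when included; Mu and Lambda are conjugate. A ridge jitter of
1e−8 on the X'X scalars guards exactly collinear deterministic series.

Defaults: 2 chains × 20,000 iterations, 50% burn-in, chains differing
only by seed stream (spawned from one `SeedSequence`). Convergence is the
largest absolute pairwise difference of per-chain link probabilities,
declared at < 0.05. Two deliberate conventions:

- a **zero-variance target** carries no likelihood; its Gamma row is drawn
  from the prior (so its link probabilities equal ρ exactly) with a
  warning, rather than letting the precision diverge and the Occam factor
  drive the probabilities to zero;
- on **noise-free circuit series** the two ring repressors are nearly
  collinear regressors, so links that trade off between them can settle
  into different posterior modes per chain and the whole-matrix
  convergence diagnostic stays high. The regulatory links of interest —
  the LacR row — agree across chains to < 0.001, and the acceptance
  script checks agreement on the reported link itself before pooling.

On the 100-point OFF-to-ON switch series the sampler assigns posterior
probability 1.0 to LacR → miR-520c-3p and LacR → GFP in every chain; on
20 seeded 3-gene linear systems (coefficient 0.9, noise 0.1) the true
edge reaches P ≥ 0.95 at rank 1, and independent-noise nulls keep all
off-diagonal probabilities below 0.5.

## Synthetic data: what it does and does not emulate

The generators reproduce the *printed summary scale* of the study inputs,
not their biology: the bipartite generator matches node/edge counts with a
rank^(−skew) heavy-tailed target draw (the published degree sequence is
unknown; note the published "avg. neighbors 3.354" is not even consistent
with 2·1278/804 = 3.179, so no generator setting is asked to reproduce
it); UTR backgrounds are uniform A/C/G/U with rejection sampling
guaranteeing no spurious canonical site (which makes truth tables exact
but removes the composition bias of real 3′UTRs); expression is i.i.d.
Gaussian with a mean-shift effect (no correlation structure, no
count-distribution effects of real RNA-seq); miRNA/gene labels are
opaque. Passing tests therefore demonstrate correctness of the methods
under controlled conditions, not performance on real NSCLC data.

Problem sizes used by the test-suite and acceptance runs — 200 small
graphs for oracle equivalence, 1000 pattern/text pairs, 200 null
replicates at 99 permutations, 20 recovery systems at 2×4,000 iterations,
one switch series at 2×20,000 iterations — were chosen so the full
validation chain stays a desk-scale computation.

## Known limitations

- The eleven-method battery runs comfortably at the 804-node scale but the
  exact stress/betweenness accumulations are O(N·E); very large networks
  would need sampling variants.
- The Boolean stage's conclusions depend on the sampling grid: grids much
  finer than the gene response time create multi-sample transients whose
  majority-vote rules can differ from the asymptotic logic.
- The inference model is linear with lag 1; it recovers the effective
  switch logic of the circuit, not its Hill-type nonlinearity, and
  collinear regressors split posterior mass (reported per chain rather
  than hidden by pooling).
- Seed scanning is exact-complementarity only: no wobble pairing, no
  thermodynamic duplex model, no conservation signal.
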