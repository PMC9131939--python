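# mirhub

A systems-biology toolkit for studying down-regulated hub miRNAs in
non-small cell lung cancer (NSCLC) and for designing an inducible synthetic
circuit that re-expresses one of them, miR-520c-3p.

Deregulated miRNAs are a recurring theme in NSCLC: when a tumor-suppressive
miRNA such as miR-520c-3p is lost, its targets in the PI3K/AKT/mTOR axis
are de-repressed. `mirhub` implements the computational chain used to find
and exploit such a miRNA:

1. **Network hub ranking** — build the directed bipartite miRNA→target
   network, compute its global statistics (density, diameter,
   heterogeneity, centralization, ...), filter by out-degree, and score
   every node with eleven centrality methods (MCC, DMNC, MNC, EPC,
   Radiality, Degree, Closeness, Betweenness, EdgeBetweenness,
   ClusteringCoefficient, Stress). Hubs are called by frequency of
   occurrence across the per-method top-10 lists.
2. **Enrichment** — one-sided hypergeometric over-representation with
   Benjamini–Hochberg control, enrichment-map graphs weighted by
   Jaccard/overlap coefficients, and gene-set enrichment analysis (GSEA):
   signal-to-noise ranking, the weighted running-sum enrichment score
   ES = max deviation of Σ(hit increments) − Σ(miss decrements), leading-edge
   extraction and permutation significance over GCT/CLS/GMT inputs.
3. **Seed-site scanning** — canonical 8mer / 7mer-m8 / 7mer-A1 / 6mer site
   patterns derived from the mature miRNA's seed (nucleotides 2–8), scanned
   with a Knuth–Morris–Pratt automaton, plus a simplified fixed-weight
   context score (site type, local AU content, 3′-supplementary pairing,
   UTR-end distance).
4. **Synthetic circuit** — a repressilator ring coupled to a Lac-operon
   toggle: active LacR represses the promoter that transcribes miR-520c-3p
   and GFP together; IPTG sequesters LacR and flips the circuit ON. Each
   gene follows d[x]/dt = α₀ + α·Kdⁿ/(Kdⁿ + [R]ⁿ) − δ·[x]. The model is
   validated three ways: deterministic ODE simulation with ON/OFF case
   analysis, best-fit Boolean network inference with exhaustive synchronous
   attractor enumeration, and spike-and-slab Gibbs variable selection
   (a first-order dynamic Bayesian network with two MCMC chains) that
   recovers the regulatory links as posterior inclusion probabilities.

Because the original 91-miRNA network and sequencing data are not publicly
deposited, the `syndata` module generates every pipeline input with known
ground truth at the published scale (804 nodes / 1278 edges, heavy-tailed
target degrees; UTRs with implanted seed sites; two-class expression with a
known enriched set; circuit time series).

## Worked example

The headline result is the circuit's bistability and the inferred
LacR → miR-520c-3p link:

```python
from mirhub import circuit, netinfer

model = circuit.build_default_circuit()

# ON/OFF case analysis
off, label = circuit.run_case(model, "off_case1")   # IPTG = 0
print(label, round(off.metadata["steady_gfp"], 4))  # OFF 0.0778
on, label = circuit.run_case(model, "on_case2")     # IPTG = 100*K_I
print(label, round(on.metadata["steady_gfp"], 4))   # ON 50.0491

# qualitative validation: binarize -> best-fit Boolean net -> attractors
for lvl, attrs in circuit.two_condition_attractors(model).items():
    for a in attrs:
        print(lvl, dict(zip(circuit.SPECIES, a.states[0])), a.basin)
# 0 {'repressor1': 1, 'repressor2': 1, 'lacR': 1, 'mir520c': 0, 'gfp': 0} 32
# 1 {'repressor1': 1, 'repressor2': 1, 'lacR': 0, 'mir520c': 1, 'gfp': 1} 32

# quantitative validation: Gibbs variable selection on the switch series
traj = circuit.simulate_switch(model)               # 100 points, OFF -> ON
post = netinfer.gibbs_infer(traj.data[list(circuit.SPECIES)],
                            n_iter=20000, n_chains=2, seed=1)
print(post.link_probability("lacR", "mir520c"))     # 1.0
```

The two attractors are the OFF state (LacR active, miR-520c-3p and GFP
silent) and the ON state (both output genes high), each draining the whole
32-state space under its input condition — the circuit is bistable across
induction levels. The posterior link probability of 1.0 says the sampler is
certain that LacR regulates miR-520c-3p, recovering the designed wiring
from the time series alone.

Every stage is also reachable from the shell, e.g.

```bash
mirhub syndata network --seed 1 --out-dir out     # 804-node / 1278-edge network
mirhub netcore stats out/network.tsv
mirhub hubrank hubs out/network.tsv
mirhub circuit attractors
mirhub run --config pipeline.yaml                 # full staged pipeline + manifest
```

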