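# seedwalk

Seed-expanding community detection for undirected networks via
personalized random walks, together with planted-partition benchmark
generators (GN and LFR-style) and the evaluation machinery (NMI,
best-match F1, strong/weak community classification) needed to validate
it offline.

The detection pipeline:

1. **Seeding** — find local maximal degree nodes (degree ≥ every
   neighbor's) and build dense seed communities from the triangles
   around them; triples sharing a hub pair are consolidated into one
   dense seed, and still-unseeded regions are re-seeded recursively.
2. **Expansion** — for each candidate node, the probability of
   belonging to each community is computed from `q` restart walks over
   a structural-similarity transition matrix (one walk per "the node
   belongs to community k" hypothesis, restart vector uniform over that
   community), combined through a total-probability model with a
   similarity-based prior. Communities absorb their best-scoring
   adjacent nodes; in the default *overlapping* mode several seeds
   planted in the same dense region grow into near-identical
   communities.
3. **Refinement** — leftover low-degree nodes join the community they
   are tightest to, communities whose overlap coefficient reaches
   ξ = 0.5 are merged, residual multi-membership is resolved by
   tightness, and a total disjoint partition is returned.

Default parameters: teleport probability α = 0.15, seed size Z = 3,
merge threshold ξ = 0.5, Jaccard similarity over closed neighborhoods.

## Library use

```python
from seedwalk import GNSpec, generate_gn, nmi, run_rwa

net, truth = generate_gn(GNSpec(p_in=0.9, rng_seed=1))
found = run_rwa(net)
print(nmi(truth, found))
```

## Command line

```bash
seedwalk generate gn --p-in 0.9 --seed 1 --prefix mynet
seedwalk detect mynet.edgelist --out found.tsv --report run.json
seedwalk evaluate mynet.truth.tsv found.tsv --graph mynet.edgelist
seedwalk benchmark lfr --mu 0.2 --reps 30 --seed 1 --out results.csv
```

Graphs are read as whitespace edge lists (`#` comments allowed) or GML;
memberships as `label<TAB>community_id` files.

## Known limitations

- On GN benchmarks the pipeline recovers the planted partition
  essentially perfectly for P_in ≥ 0.7, but collapses to too few
  communities for P_in ≤ 0.6 (heavily ambiguous regime): candidate
  seed triangles there straddle planted blocks and the overlapping
  expansion then bleeds across block boundaries.
- The LFR-style generator truncates the degree distribution at the
  feasibility bound `(Maxc − 1) / (1 − μ)` so every node's internal
  degree can fit inside a community, and random stub matching drops a
  few percent of stubs, so the realized mean degree runs slightly
  (~5%) below the target.
- Sparse-matrix scalability is out of scope; the implementation is
  dense and intended for networks of up to a few thousand nodes.
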