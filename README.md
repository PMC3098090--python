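# phyloplace

Maximum-likelihood and Bayesian phylogenetic placement of query sequences
onto a fixed reference tree.

Metagenomic and amplicon surveys produce large numbers of short reads that
carry too little signal for joint tree inference. Phylogenetic placement
sidesteps this: a reference tree (topology **and** branch lengths fixed) and
a reference alignment are taken as given, and each query read — already
aligned to the reference columns — is attached independently to the edge
where it fits best. Because the reference is fixed, all information it
contributes can be precomputed in two tree traversals, after which every
query is scored by three-taxon-tree computations; run time and memory are
linear in the number of reference taxa, query count, and read length.

## The model

Attaching a query to edge ℓᵢ (length Aᵢ) introduces two new branch-length
parameters: the attachment position *a* ∈ [0, Aᵢ] along the edge, and the
pendant branch length *b* ≥ 0 leading to the query. With the phylogenetic
likelihood ℒ(D | T, ℓᵢ, a, b) under GTR+Γ (nucleotides) or LG/WAG+Γ
(amino acids), the package reports per edge:

- **ML score** ℒ_ML(ℓᵢ) = max over (a, b) of ℒ, and the **likelihood weight
  ratio** LWR(ℓᵢ) = ℒ_ML(ℓᵢ) / Σⱼ ℒ_ML(ℓⱼ);
- **Bayes marginal** ℒ_Bayes(ℓᵢ) = Aᵢ⁻¹ ∬ ℒ(D | T, ℓᵢ, a, b) P(b) da db by
  direct 2-D quadrature (no MCMC is needed on a fixed tree), with an
  exponential or uniform prior P on the pendant length, and the **posterior
  probability** as the marginals normalized over edges;
- **EDPL**, the expected distance between placement locations:
  Σᵢⱼ pᵢ pⱼ dᵢⱼ / L, where pᵢ are the placement probabilities, dᵢⱼ the tree
  distance between the optimal attachment points and L the total tree
  length. EDPL separates local ambiguity among neighboring edges (small
  EDPL) from genuine positional uncertainty spread across the tree.

Search is two-stage ("baseball"): cached center-of-edge vectors give every
edge a quick midpoint score (the *batting order*), and edges are then fully
optimized in that order until the configured number of *strikes* (full
evaluations falling more than the *strike box* D below the first edge's
score) or *pitches* (total full evaluations) is reached. A *fantasy
baseball* mode replays recorded searches to tune D and the strike count for
a sample of reads. Highly similar queries share work through *friend*
links: identical reads copy placements, similar reads reuse optimized
branch lengths as warm starts — exact accelerations, not approximations.

Model parameters are inputs (flat key-value model file, with best-effort
importers for PHYML/RAxML statistics files); the package never estimates
substitution-model parameters or topology.

## Worked example

```python
from phyloplace import simeval
from phyloplace.placement import Placer, BaseballParams

# synthetic bundle: random 8-taxon tree, 300 columns evolved under GTR+Γ4
tree, aln, model, model_text = simeval.make_fixture(8, 300, seed=42)
placer = Placer(tree, aln, model)

# a 120-column fragment of taxon t003's row, gapped to reference coordinates
row = aln.rows["t003"]
read = placer.make_read("frag1", "-" * 60 + row[60:180] + "-" * 120)
qp = placer.place(read, BaseballParams(), posterior=True)
for c in qp.candidates[:3]:
    print(f"edge {c.edge:2d}  logL {c.log_like:9.2f}  LWR {c.lwr:.3f}  "
          f"posterior {c.posterior:.3f}  a {c.attach_a:.3f}  b {c.pendant_b:.3f}")
print(f"EDPL = {qp.edpl:.4f}")
```

prints

```
edge  5  logL   -745.15  LWR 0.997  posterior 0.999  a 0.000  b 0.000
edge  4  logL   -751.74  LWR 0.001  posterior 0.000  a 0.000  b 0.000
edge  6  logL   -751.74  LWR 0.001  posterior 0.000  a 0.245  b 0.000
EDPL = 0.0002
```

Edge 5 is t003's own pendant edge: the fragment goes home with likelihood
weight 0.997 and posterior 0.999, attaching at the edge's distal end with a
zero-length pendant branch. The near-zero EDPL says the alternatives are
immediate neighbors, so the position is certain, not just the edge.

The same run is available from the shell:

```
phyloplace makefixture --taxa 8 --columns 300 --seed 42 --out-prefix ref
phyloplace place --tree ref.nwk --ref-aln ref.fasta --model ref.model.txt \
    --reads reads.fasta --out run.place.json --posterior
phyloplace placeviz run.place.json --xml          # phyloXML, width+color
phyloplace placeutil filter run.place.json --metric lwr --bound 0.9 --out hi.place.json
phyloplace simeval --tree ref.nwk --aln ref.fasta --model ref.model.txt \
    --reads-per-taxon 10 --seed 1 --report report.tsv
```

Placement files are structured JSON in the style of the community `jplace`
format (edge-numbered tree, a `fields` schema, one row per candidate), and
carry a digest of the canonicalized tree + model so shards from different
references refuse to merge.

## Validation

`simeval.run_simulation` implements a leave-one-out study: each taxon in
turn is removed from the alignment, its pendant branch pruned (the two
branches at its attachment node merged) and branch lengths re-estimated on
the fixed topology; read fragments of normally distributed length and
uniformly distributed position are simulated from the held-out sequence and
placed back. Accuracy is the topological error — the number of internal
nodes between the placed edge and the pruned edge (0 = correct, 1 = sister)
— reported in tables binned by the top candidate's LWR and by its
posterior probability.

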