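# prince-net

Disease-gene prioritization and disease-associated protein complex inference
by global network propagation (the PRINCE approach), with the random-walk and
direct-neighbor-correlation baselines, a cross-validation harness, and
coherency statistics for evaluating inferred complexes.

## Who this is for

Computational biologists who have (i) a confidence-weighted protein–protein
interaction network, (ii) a phenotype-similarity matrix over diseases and
(iii) a table of known gene–disease associations, and who want to rank
candidate causal genes for a query disease — over the whole network or inside
a linkage interval — and to extract the densely interacting protein modules
that carry the disease signal. A synthetic-data module generates all inputs
with planted ground truth, so the entire pipeline runs and is tested without
any external download.

## The model

Known causal genes of diseases phenotypically similar to the query seed a
prior vector `Y`: each associated protein gets
`Y[p] = L(max_d S[q,d])`, where `S[q,d]` is the phenotype similarity of the
query `q` to the protein's most similar associated disease and
`L(x) = 1/(1 + exp(c·x + d))` (with `c < 0`) maps similarity to confidence,
squashing the uninformative low-similarity range to ~0.

The prioritization function `F` diffuses this prior over the network:

```
F = α W' F + (1 − α) Y,      W' = D^(−1/2) W D^(−1/2)
```

where `W` is the weighted adjacency, `D` the diagonal matrix of weighted
degrees and `α ∈ (0,1)` trades smoothness over the network against fidelity
to the prior. Because the spectrum of `W'` lies in `[−1, 1]`, the system has
a unique solution, reachable either exactly (sparse LU) or by the fixed-point
iteration `F_t = αW'F_{t−1} + (1−α)Y`, which converges geometrically.

Complexes are then grown greedily from the top-scoring proteins (adding the
highest-scoring neighbor while its score exceeds a threshold β, up to 20
proteins), refined by removing members whenever that raises a log-likelihood
ratio contrasting a clique-like complex model (pairwise interaction
probability γ) against a degree-proportional random background, and filtered
by size (≥ 4) and mutual overlap. Inferred collections are evaluated by
functional (minimal hypergeometric enrichment), expression (mean pairwise
Pearson) and conservation (mean pairwise phylogenetic-profile Jaccard)
coherency, each against an empirical null of random same-size protein sets
with Benjamini–Hochberg correction.

## Worked example

```
$ prince simulate --preset easy --seed 5 -o study/
wrote synthetic bundle (easy, seed=5) to study/

$ prince prioritize --network study/network.tsv --similarity study/similarity.tsv \
    --associations study/associations.tsv --disease D000 -o scores.tsv
wrote 2000 ranked candidates to scores.tsv

$ grep -v '^#' scores.tsv | head -4
rank    protein score   prior   source_disease
1       P0002   0.39422693699765365     0.9786636006016628      D002
2       P0005   0.3787006708313384      0.9786636006016628      D002
3       P0004   0.3710514425169993      0.872685423211817       D001
```

The top-ranked proteins are the planted causal genes of disease `D000`'s
phenotype family: the `prior` column shows the logistic confidence of each
protein's source disease (e.g. `L(0.88) ≈ 0.98` for a gene of the highly
similar sibling disease `D002`), and `score` is the converged propagation
value.
Cross-validation and complex inference follow the same pattern:

```
$ prince evaluate --network study/network.tsv --similarity study/similarity.tsv \
    --associations study/associations.tsv --genome-order study/genome_order.txt \
    --methods prince,rwr,cipher-dn --seed 5 -o eval/
$ prince complexes --network study/network.tsv --similarity study/similarity.tsv \
    --associations study/associations.tsv --disease D000 --beta 0.05 -o cx.gmt
inferred 1 complex(es); wrote cx.gmt
$ prince coherency --complexes cx.gmt --annotations study/annotations.gmt \
    --expression study/expression.tsv --profiles study/profiles.tsv \
    --n-null 1000 --seed 2 -o coherency.tsv
functional: 100.0% coherent (q<0.05)
expression: 100.0% coherent (q<0.05)
conservation: 100.0% coherent (q<0.05)
```

Here the single inferred complex is exactly the planted 6-protein module the
disease family's causal genes were drawn from, and all three coherency
measures call it significant.

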