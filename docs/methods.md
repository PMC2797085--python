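# Methods

## Prioritization model

Given a weighted protein interaction network `G = (V, E, w)` with
`w(u,v) ∈ (0,1]` interpreted as interaction reliability, a query disease `q`,
a disease–disease phenotype-similarity matrix `S` with values in `[0,1]`, and
a set of known gene–disease associations, the prioritization function
`F : V → R≥0` is the unique solution of

    F = α W' F + (1 − α) Y,        W' = D^(−1/2) W D^(−1/2),

where `D` is the diagonal matrix of weighted degrees and `Y` the prior
vector. `F` minimizes a quadratic objective combining a smoothness penalty
over the normalized network with a fit-to-prior penalty; `α` weighs the two.
Normalizing each edge by the geometric mean of its endpoint degrees makes
`W'` similar to the row-stochastic matrix `D^(−1)W`, so its eigenvalues lie
in `[−1, 1]` and `I − αW'` is invertible for every `α < 1`. Ranking is over
proteins *not* already known to be associated with the query; the known genes
are the input evidence, not candidates.

Assumptions worth stating: the network is undirected, has no isolated
proteins (these are dropped at load time since `D^(−1/2)` would be
undefined), and edge weights are comparable across the network; phenotype
similarity is informative only in its upper range; a protein associated with
several diseases inherits evidence from the single disease most similar to
the query (argmax, lexicographic ties).

### Prior construction

`Y[p] = L(max_d S[q,d])` over `p`'s associated diseases `d`, with the
logistic confidence `L(x) = 1/(1 + exp(c·x + d))`, `c < 0`. Defaults
`c = −15`, `d = ln 9999` give `L(0) = 10⁻⁴` and `L(0.3) ≈ 0.009`, i.e. the
similarity range empirically found uninformative contributes essentially
nothing, while `L` rises steeply through the informative range above ~0.5.
Both parameters are exposed (`--logistic-c/--logistic-d`); `c` is the one
worth cross-validating per data set.

### Solvers

`propagate_exact` factorizes `I − αW'` (sparse LU) and solves for
`(1−α)Y`; the cross-validation harness reuses one factorization across all
trials. `propagate_iterative` runs `F_t = αW'F_{t−1} + (1−α)Y` from
`F₀ = Y` until the max-abs change drops below `tol` (default `10⁻⁶`,
`max_iter = 1000`); the residual contracts at least geometrically with ratio
`α`. `α = 0` is admitted as the closed prior-only limit (`F = Y`). Default
`α = 0.9`: results are insensitive to `α` anywhere above ~0.5, and a high
value lets the network term do the work the model intends. Rankings
stabilize after roughly ten sweeps; a fixed `--iterations` override exists
for that regime.

### Baselines

*Random walk with restart*: steady state of
`p_t = (1−r)·WD^(−1)·p_{t−1} + r·p₀` with `p₀ = Y/ΣY`; reported vector sums
to 1; `r = 1` returns `p₀`. Default `r = 0.5`.

*Direct-neighbor correlation (CIPHER-DN)*: a candidate's score is the Pearson
correlation, over all diseases with known genes, between the query's
phenotype-similarity profile and the candidate's closeness profile, where
closeness to a disease is the sum over its known genes of 1 (the candidate
itself) or the edge confidence (direct neighbor) or 0. Candidates with a
constant closeness profile have undefined correlation and are ranked last
(−∞); fewer than two diseases with genes is an error.

## Cross-validation protocol

Each trial hides one (disease, protein) association *plus every other
association of that protein* — otherwise a protein shared by several very
similar diseases would make its trial trivially easy — then rebuilds the
prior, reruns the scorer and records the hidden protein's rank among the
candidates. Candidates are an artificial linkage interval: a window of
`size` genes (default 100) centered on the protein in a genome ordering,
extended at list boundaries so the interval keeps exactly `size` members.
Ranks are pessimistic competition ranks with lexicographic tie-breaks, so
ties never flatter a method. k-fold variants partition the (seed-shuffled)
association list and hide a whole fold per trial; `folds = n` reduces
exactly to leave-one-out. Recall at threshold `k` is the fraction of trials
whose hidden gene ranked in the top `k`; with one hidden association per
trial precision coincides with recall and both are reported.

## Complex inference

Seeds are the 100 top-scoring proteins (insensitive across 50–150),
processed in descending score order; seeds below the membership threshold
`β`, or already absorbed into a previously grown complex for the same
disease, are skipped. Growth repeatedly adds the neighbor of the current set
with the highest propagation score while that score exceeds `β`, up to 20
proteins (about twice the mean size of curated complexes). If the disease
has only a linkage interval, complexes containing no interval member are
discarded.

The log-likelihood-ratio score contrasts a complex model — every member pair
interacts with probability `γ = 0.9`, independently — with a background in
which an edge between `u` and `v` arises with probability
`p(u,v) = d(u)d(v) / (2·Σ_e w(e))` (weighted degrees, clamped to
`[10⁻⁶, 1−10⁻⁶]`). Edge reliabilities enter as noisy observations: an
observed pair with reliability `r` contributes
`log[(γr + (1−γ)(1−r)) / (pr + (1−p)(1−r))]`, an unobserved pair
`log[(1−γ)/(1−p)]`. This mixture form is the simplest scheme consistent with
the qualitative requirements (reliability-weighted evidence, degree-aware
null, finite terms); it is isolated behind `complex_score` so variants can be
swapped. Refinement repeatedly removes the member whose removal most
increases the score while the induced interaction subgraph stays connected;
it is monotone in score and idempotent. Filtering drops complexes under 4
proteins and greedily suppresses candidates overlapping a higher-scoring kept
complex by `|A∩B|/min(|A|,|B|) ≥ 0.8` (the conventional overlap cutoff in
the complex-detection literature; exposed as config).

`β` is scale-bound to the score distribution of the data set, so rather than
fixing it globally the package ships `tune_beta_to_size`, which picks the `β`
whose inferred collection's mean complex size best matches a reference mean
(the same mean-size criterion used to calibrate against curated complex
collections). The classical operating points for the real OMIM-scale data
are 0.1 (query disease with a known gene) and 0.015 (locus-only).

## Coherency evaluation

Per complex and measure: functional — the minimal hypergeometric upper-tail
probability over annotation terms (annotations must be pre-propagated up the
term hierarchy; `propagate_annotations` does this given a parent table);
expression — mean pairwise Pearson correlation of member expression
profiles, pairs with zero variance excluded; conservation — mean pairwise
Jaccard of binary phylogenetic profiles, an all-absent pair counting 0. Each
raw statistic is compared with the same statistic on `n_null` random protein
sets of the same size drawn from the proteins carrying the relevant data
type, giving the add-one empirical p-value `(1 + x)/(1 + n_null)` (never
exactly zero; `n_null` defaults to 10,000 and is reduced in tests).
Per-measure p-values are Benjamini–Hochberg corrected across the collection
and a complex counts as coherent at `q < 0.05`.

The report also carries the percent of complexes with *raw* empirical
`p < 0.05`: under a complete null that rate calibrates to the nominal 5%,
whereas the BH-corrected rate is necessarily far smaller (step-up correction
under a global null rejects almost nothing), so the raw rate is the right
quantity for calibration checks and the corrected rate the right one for
reporting discoveries.

## Synthetic study conditions

The generators plant known structure so recovery is measurable:

* **Network** — planted-partition: dense modules (within-module edge
  probability `p_in`, Beta(8,2) confidences) over either a uniform
  Erdős–Rényi background or a Chung–Lu background with power-law expected
  degrees (exponent 2.5), Beta(2,4) confidences; real interactome maps are
  hub-dominated, so the benchmark presets use the Chung–Lu background (mean
  background degree 8). Disconnected components are stitched with
  weight-0.1 chain edges so no protein is isolated.
* **Disease world** — families of 3 diseases; intra-family similarity
  drawn from U(0.7, 0.9) (the informative zone), inter-family from
  U(0, 0.3) (the uninformative zone); each family's causal genes (2 per
  disease, disjoint) are drawn from one planted module.
* **Genome ordering** — a random permutation constrained so same-module
  genes sit at least one interval-width apart. At real-genome density
  (~20k genes) two functionally related disease genes essentially never
  share a 100-gene window; a uniform shuffle of a 2,000-gene synthetic
  genome would inflate that co-location rate by an order of magnitude, so
  the constraint restores the realistic rate. The spacing auto-caps at the
  feasible density and relaxes (with a warning) if placement fails.
* **Coherency tables** — planted-coherent modules share an annotation term,
  an expression profile driven by a common latent factor
  (`x = √(1−noise)·factor + √noise·ε`), and a binary phylogenetic template
  with per-bit flip probability `noise`; everything else is random
  background (profiles Bernoulli(0.5) over 18 genomes, expression i.i.d.
  standard normal over 20 conditions).

Presets: `easy` (the planted-recovery benchmark: 2,000 proteins, 12 modules
of 6 with `p_in = 1` — the family's causal genes form a clique, the textbook
scenario for propagation — 8 disease families, noise 0.1), `hard` (modules
of 12 at `p_in = 0.5`, weaker similarity contrast, noise 0.3), `null`
(identity similarity, random associations, no coherent modules — the
calibration condition). Everything regenerates bit-identically from (seed,
parameters).

What the synthetic conditions do *not* emulate: literature-driven
ascertainment bias in association tables, the heavy-tailed and blockwise
structure of real phenotype-similarity matrices, correlated measurement
error between interaction confidence and gene popularity, and annotation
incompleteness that correlates with network degree. Passing the planted
benchmarks therefore demonstrates correctness of the machinery and the
expected qualitative behavior (propagation ≥ both baselines, calibrated
nulls), not the absolute accuracy attainable on real OMIM-scale data.

## Numerical choices and edge cases

* Edge de-duplication keeps the maximum weight (best evidence wins);
  self-loops dropped with a warning; IDs are opaque case-sensitive strings.
* Similarity matrices must be exactly symmetric with unit diagonal.
* Ties anywhere (argmax source disease, growth neighbor, rank, filter
  order) break lexicographically for determinism.
* All-zero priors short-circuit to all-zero scores (and are flagged in CV
  with rank = |candidates|).
* Dense/sparse solve choice is irrelevant to results: iterative and exact
  paths agree to < 10⁻⁸ under the test tolerances.
* Problem sizes in the shipped tests and acceptance script (2,000-protein
  benchmark, 100 random solver instances ≤ 200 proteins, 200 calibration
  replicates at 199 null draws) were chosen so the whole suite completes in
  a couple of minutes on one CPU while keeping every statistical check
  well-powered.

## Known limitations

* The likelihood score's reliability mixture is one defensible reading of a
  "noisy observation" integration; alternatives (e.g. explicit
  false-positive/false-negative rates) would change absolute scores but not
  the ranking behavior the tests pin down.
* CIPHER-DN is quadratic in (candidates × diseases) per query and slows on
  large cross-validations.
* `tune_beta_to_size` is a grid search; on data sets whose score
  distribution varies strongly across diseases a per-disease `β` may be more
  appropriate.
* The propagation model assumes association evidence is binary per
  (disease, protein); graded evidence would enter naturally through `Y` but
  no loader for it is provided.
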