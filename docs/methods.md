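# Methods

This note records the models implemented in `kinnet`, the assumptions
behind them, the parameter defaults and why they were chosen, and the
design decisions taken where the underlying procedure left room for
interpretation. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The network model

A kinase interaction network is a directed bipartite graph with kinase
nodes and phosphosite nodes and two edge classes: kinase→site
("k phosphorylates s") and site→kinase ("s is a phosphosite located on
the protein of kinase k"). Site identifiers are canonical strings
`ACCESSION_<residue><position>` (e.g. `Q9UNZ2_S176`); positions are
1-based protein residue numbering. A parser also accepts
`ACCESSION_<position>` and takes the residue from the flank's center.
Kinases come in two specificity classes — serine/threonine and tyrosine —
and kinase→site edges must respect class/residue compatibility.
Site→kinase edges are created only within the matching class (an S/T
site on a tyrosine-kinase protein contributes none). Kinase names are
matched to site accessions by identity unless a two-column mapping table
is supplied. Nodes of total degree zero carry no information in an
interaction network, so every filter ends with singleton pruning; as a
consequence the edge-list serialization (which cannot represent isolated
nodes) is lossless exactly on the networks the pipeline produces.

## Baseline construction

The raw motif score of site s for kinase k is the product of the
kinase's PSSM weights at each covered flank offset, `r(k,s) = Π_o
w_k(o, aa_o)`. Ser/Thr matrices cover offsets −5…+4, Tyr matrices
−5…+5 (the phosphoacceptor itself is excluded). Offsets falling on `_`
padding (protein termini) contribute a neutral factor 1 — the least
informative choice for positions that do not exist. A flank consisting
entirely of padding is scored (neutrally) but flagged.

Raw scores are not comparable between kinases, so each is calibrated to
a percentile against that kinase's score distribution over a curated
background site set supplied as input: `p(k,s) = |{b ∈ bg : b ≤ r}| /
|bg|`. The `≤` convention means a score equal to the background maximum
reaches percentile 1.0 exactly.

Per site and per specificity class, compatible kinases are sorted by
percentile (ties broken by raw score descending, then kinase id, so
results are deterministic), truncated to the top `n`, and thresholded at
`p ≥ α`. Defaults `n = 15`, `α = 0.9` follow the recommendation of the
groups that curated the kinome-wide PSSMs. Raising `α` or lowering `n`
can only remove edges (monotonicity, covered by tests). Backgrounds are
consumed as data, never recomputed from reference phosphoproteomes.

## Fold changes

With paired samples (row i of both matrices is the same biological
replicate), `f_s = mean_i log2(x1[i,s] / x0[i,s])` over the complete
pairs; otherwise `f_s = log2(mean_i x1[i,s] / mean_i x0[i,s])` with
means over present values. The two coincide for a single sample per
condition; swapping the conditions negates every value; scaling one
condition by 2 shifts every value by exactly 1 (all asserted in tests).
Zero or negative intensities are treated as missing rather than
imputed — no pseudocount is applied, because a pseudocount would shift
`f_s` silently. Sites with no usable observation are dropped with a
warning. User-supplied fold-change vectors are validated instead:
entries for unmeasured sites are dropped (warned), non-finite values are
an error.

## Filters

All four filters map a network to a subnetwork of itself, are
idempotent, and end with singleton pruning. The two node filters act on
substrate nodes only (kinases leave only by pruning) and therefore
commute.

**FS** keeps sites with functional score `g(s) ≥ β`, default `β = 0.4`
(the threshold recommended for the score's published calibration).
Sites missing from the score table are removed by default — they cannot
demonstrate functional relevance — with a `keep_unscored` escape hatch.

**DIFF** keeps sites with `|f_s| ≥ γ`, default `γ = 1` (a two-fold
intensity change). Sites without a fold change are removed.

**CORR** examines only kinase→site edges whose target site lies on a
kinase present in the network; edges onto non-kinase proteins are never
touched, and site→kinase edges are never removed. An eligible edge
(k, s) survives if some target s′ of the host kinase k(s) shows
`|r(X_s, X_s′)| ≥ δ` with adjusted `P < ε` (defaults 0.8, 0.05) — the
co-phosphorylation evidence that phosphorylation of s modulates k(s)'s
activity. All pairs tested in one invocation form a single
multiple-testing family (the most conservative reproducible choice;
per-host families would make significance depend on network
decomposition). Pairs with fewer than 3 complete observations or a
constant column are skipped. Correlations are computed once; removal
then iterates to a fixed point, because a witness s′ is only credible
while the edge k(s)→s′ itself survives. The fixed point is unique
(removal is monotone) and makes the filter idempotent; a single
simultaneous pass would not be, since it can leave edges whose only
witnesses it just removed. Autophosphorylation edges (the host kinase
targeting its own site) are tested like any other by default;
`exclude_self` exempts them. With two condition matrices the filter runs
per condition and returns one network per condition.

**PCST** casts subnetwork extraction as a prize-collecting Steiner tree:
drop edge directions (both orientations map to one undirected edge),
prize substrate nodes with `|f_s|` (0 with a log message when `f_s` is
missing), prize kinase nodes with `γ` so that collecting a kinase is
worth exactly as much as a minimally differential substrate, and set all
edge costs to 1 so the optimizer favors few edges. The solution tree,
with directions restored, is the filtered network; its undirected
projection is connected and acyclic by construction. On disconnected
inputs the best tree across components (by collected prize minus edge
cost) is returned; `forest=True` keeps one tree per component.

## The PCST solver

No suitable solver library is part of the dependency set, so the solver
is implemented in `kinnet.pcst`: the classic moat-growing (dual growth)
scheme in its unrooted prize-collecting form — every node starts as an
active cluster whose budget is its prize; active clusters grow uniform
duals, merge when an edge becomes tight, and deactivate when their
budget is spent — followed by strong pruning of the growth forest
(bottom-up removal of branches whose collected prize does not pay for
their connecting edge, evaluated from every root). This scheme carries
the known approximation guarantee of 2 and in practice is usually
optimal; the test suite and the acceptance script verify the factor on
hundreds of random instances against an exhaustive oracle that
enumerates all connected node subsets and costs them with minimum
spanning trees.

Determinism and ties: events are processed in (time, kind, index) order
over sorted nodes and edges, so results are reproducible. At equal
objective the solver and the oracle both prefer higher net worth, then
the larger node set, then the lexicographically smallest one. Preferring
the larger set matters: with `γ` equal to the unit edge cost, attaching
a kinase to a profitable substrate is exactly net-neutral, and the
kinase prize exists precisely to make that attachment happen rather
than returning a bare substrate singleton.

Numerical tolerances: 1e-12 for tightness/tie comparisons; all weights
are 1 and prizes are O(1–10) in pipeline use, so no scaling issues
arise.

## Evaluation

The observed statistic is `|E*_KS ∩ reference|` — site→kinase edges are
never counted. Matching is site-level (kinase, protein, position); a
protein-level relaxation exists for sparse references.

*Random filtering*: draw as many kinase→site edges as the filtered
network kept, uniformly without replacement from the baseline, 1000
times by default. The replicate mean provably equals the hypergeometric
expectation `target · |E_KS ∩ ref| / |E_KS|`; the test suite checks this
within 3 standard errors.

*Degree-preserving rewiring*: double-edge swaps on the kinase→site edges
only — swap targets of two random edges unless a duplicate would arise —
preserving every kinase's out-degree, every site's in-degree, and the
kinase→substrate direction. 100 attempted swaps per edge per replicate
(the customary multiple for mixing double-edge-swap chains; the value is
logged and configurable). Graphs admitting no valid swap (single edge,
complete bipartite) reproduce the original overlap.

*Z-test*: `z = (observed − mean)/sd` with the sample (n−1) standard
deviation — pinned for bit-reproducibility, numerically irrelevant at
1000 replicates — and one-sided `P = 1 − Φ(z)`. A degenerate null
(sd = 0) yields P ∈ {0, 0.5, 1} by sign and is flagged. All stochastic
routines take explicit seeds and are bit-reproducible.

*Sweep*: rebuilds the baseline and reruns the filters over a grid of
{α, n, β, γ}, evaluates each point against both nulls, and adjusts the
P-values per null kind with Benjamini–Hochberg across the grid.

*PubMed coverage*: distinct PubMed IDs per target protein from a
user-supplied gene→PubMed snapshot (never fetched), as a literature-bias
profile of a network.

## Synthetic studies

The generator emulates the statistical structure the pipeline assumes,
with planted ground truth throughout. Every site is assigned exactly one
true regulating kinase; only *regulated* ("planted") sites carry that
kinase's motif in their flank. This separation is deliberate: the
truth's site coverage is uniform, so all recoverable signal flows
through the kinome, and at motif strength 1 the pipeline's overlap with
the truth is indistinguishable from random filtering by construction —
the calibration limit the tests exercise. PSSMs put weight
`motif_strength` on one preferred residue per offset with mild
log-normal jitter (sd 0.1) on all entries so scores are continuous;
percentile backgrounds are scored on random flanks.

Defaults, chosen once as a realistic scaled-down study: 24 Ser/Thr + 8
Tyr kinases and 160 sites, a quarter of them regulated — mirroring the
regime of real baselines where profiled-kinome motifs explain a minority
of measured sites and reference databases annotate a small fraction of
edges; 200 background sites per class; motif strength 10 (a strong PSPA
motif); 6 samples per condition (a typical perturbation-screen replicate
count); log2 effect size 2 on 40 regulated sites with log-normal noise
of sd 0.25; 4 co-phosphorylation chains in which the phosphosite on a
kinase protein drives that kinase's motif-backed targets through a
shared per-sample latent factor (residual sd 0.05, giving within-
condition correlations near 1); 5% missing values. Functional scores are
drawn U(0.5, 1) for regulated and U(0, 0.35) for other sites, i.e. the
score separates regulated biology cleanly — real functional scores are
noisier, so passing these tests demonstrates mechanism, not real-data
effect sizes. All randomness flows from one root seed through separate
documented child streams per artifact, making emitted files
byte-identical across runs.

What the generator does not emulate: peptide-level ambiguity, TMT ratio
compression and other acquisition artifacts, shared sites between
proteins, multi-kinase regulation of one site, and realistic overlap
between functional and differential site sets.

## Problem sizes in the shipped checks

The acceptance checks run the solver-versus-oracle comparison on 200
instances of ≤10 nodes, the filter-algebra properties on 100 random
networks, null-model checks at 1000 replicates, and the
recovery/calibration studies on 5 and 50 generator seeds at the default
study size (about 380 baseline edges) with 1000- and 200-replicate
nulls respectively. Recovery evidence is combined across the 5 seeds
with Stouffer's method: single small studies sit near the significance
boundary by design, and the claim under test is about the method, not
one realization. The calibration check asserts a central mean and a
near-nominal small-P rate rather than exact uniformity, because overlap
counts in the null regime are small integers and the one-sided Z-test on
them is discrete and slightly conservative.

## Known limitations

- Kinases absent from the PSSM collection cannot be predicted; motifs
  with interpositional dependencies are not modeled (the PSSM is
  position-independent by construction).
- The CORR filter captures linear co-phosphorylation only, and with
  typical phosphoproteomics sample sizes (≤10) its power is low; edges
  surviving it do so mostly through near-perfect correlations.
- The PCST filter returns a single tree by default; biology is not a
  tree, and the output should be read as a parsimonious summary of the
  densest differential region, not as the complete set of active links.
- The moat-growing solver is a 2-approximation; optimality on any given
  instance is not guaranteed (the shipped measurements observe worst
  ratios around 1.2 on random small instances).
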