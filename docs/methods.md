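# Methods

## Model

`causaltf` treats causal-regulator inference as a gene-set overlap problem.
A regulatory network supplies two kinds of directed edges over proteins and
genes: *transcription* edges (a TF binds and transcribes a gene, optionally
weighted by a log-likelihood score, LLS) and *modification* edges (a kinase
or phosphatase modifies a substrate protein, or a "modulator" protein
alters a TF's activity post-translationally). TF-coding genes carry a
single identifier serving as both the gene and its protein product, so a
transcription target can itself be a TF and chains can be followed without
an identifier-mapping layer.

For each TF six downstream gene-set models are constructed by progressively
adding regulation layers (direct; + PTM-mediated TFs; + transcribed TFs and
their PTM analogue; their union; + a third transcription layer). The chain
from the focal TF to the last mediating TF is bounded at length 2: the
admissible mediator paths are focal→C→F (transcription-transcription),
focal→B→D (PTM-transcription) and focal→X→E (transcription-modulator), plus
their prefixes. Longer chains make the downstream sets of distinct TFs
converge and are not built. Mediator roles B, C, D, E and F must be
rostered TFs; X may be any transcribed protein with an outgoing modulator
edge. Three traversal rules keep the sets well defined: the focal TF never
fills a mediator role for itself, a protein fills at most one role per path
(no revisits), and self-edges are stored but never traversed — though a
TF's own gene remains a downstream gene whenever a model TF transcribes it.
Mediators reached only through modification edges (B, E) contribute their
targets without themselves entering the set; mediators reached by
transcription are already members as direct targets.

Scoring uses the hypergeometric upper tail P(X ≥ k) for the overlap k
between a model set (size K within the universe) and the DEG set (size n)
drawn from a universe of N genes. The universe is the measured-gene
universe of the expression experiment when known, otherwise the union of
all transcription targets in the network; the choice is recorded in the
output provenance. The implementation delegates the tail to
`scipy.stats.hypergeom.sf` and clamps the result into (0, 1].

The acceptability filter compares, for each model m ≠ I, the vector of
p-values {p_m} across all candidate TFs with {p_I} by an unpaired
two-sample Wilcoxon rank-sum test; m is acceptable when the test p-value
exceeds `alpha` (default 0.005), and Model I is always acceptable. The
test is two-sided by default (any distributional difference disqualifies);
a one-sided variant (only a shift toward smaller p-values disqualifies) is
exposed because the filter's purpose is to catch models that make *many*
TFs look more significant. Small tie-free samples use the exact null
distribution; otherwise mid-ranks with the normal approximation and tie
correction are used. When the pooled samples are completely tied the test
p-value is defined as 1 (no evidence of a shift), a case the asymptotic
formula cannot express (zero variance).

Each TF's reported p-value is the minimum over acceptable models; the
best model is the argmin with ties resolved to the lower-numbered (simpler)
model. The ranking sorts by ascending minimum p, breaking ties by larger
overlap count at the best model and then lexicographically by TF
identifier — an arbitrary but deterministic order. A TF is a valid finding
at min p ≤ 0.01, and a perturbed TF counts as correctly identified when it
is valid and ranked in the top 20. No multiple-testing correction is
applied anywhere; all thresholds compare inclusively against raw p-values.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lls_threshold` | 4 | keep TF-DNA edges with score strictly > 4 (skipped when the table has no score column) |
| `min_set_size` | 4 | candidate TFs need ≥ 4 downstream genes in some model |
| DEG criterion | p ≤ 0.01 / \|z\| ≥ 2 / \|fc\| ≥ 2 | inclusive thresholds on the chosen statistic |
| `ranksum_alpha` | 0.005 | acceptability cut on the rank-sum test p |
| `valid_p` | 0.01 | valid-finding threshold on the minimum p |
| `top_k` | 20 | rank window for correct identification |

Fold changes are signed ratios (−3.3 means 3.3-fold down); log2 input is
supported behind an explicit flag. Identifiers are matched exactly and
case-sensitively.

## Synthetic data

The generator draws a layered network: each of `n_tfs` TFs receives a
Poisson(`mean_out_degree`) number of transcription targets, each target
being TF-coding with probability `tf_target_fraction` (sampled without
replacement from the other TFs) and a plain gene otherwise; `n_kinases`
TFs get kinase/phosphatase edges to other TFs; `n_modulators` genes become
modulators, each guaranteed to be transcribed by some TF and modifying one
TF. A perturbation of a chosen TF acting through a chosen model puts each
gene of that model's set into the DEG list with probability `tpr` and every
other universe gene with probability `fpr`. Defaults (140 TFs, 6000 genes,
tpr 0.8, fpr 0.02) match the method's intended operating band of ~140
candidate TFs over a genome-scale universe; mean out-degree 20 with 8%
TF-coding targets was chosen once as a realistic density for a confidence-
thresholded TF-DNA network with occasional cascades. Network generation,
true-TF choice and each replicate's DEG draw use separate seed-derived
streams, so all outputs are pure functions of (parameters, seed) and
changing the noise rates never changes the network.

The generator emulates DEG *membership* only: no expression magnitudes, no
signed (activation vs repression) regulation, no feedback dynamics, no
correlated measurement noise, and no backup/redundant TF pairs. Passing
recovery tests therefore demonstrates that the inference machinery works
when its model of the world holds; it says nothing about robustness to the
biological complications above.

When a recovery experiment must also identify the *acting model*, the true
TF is drawn only from candidates whose true-model set differs from every
lower-numbered model's set: identical sets give identical p-values and the
tie deterministically resolves to the simpler model, so the richer model
would be unrecoverable by construction. The noiseless model-identification
test runs on sparse networks (mean out-degree 8, 4% TF-coding targets)
where downstream sets of distinct TFs share few genes. In dense regimes a
noiseless cascade perturbation makes many background TFs' cascade-model
p-values drop in unison, and the acceptability filter then (correctly, by
its own logic) rejects the cascade model — the true TF still ranks first,
but the reported model falls back to a simpler acceptable one. This is an
inherent trade-off of distribution-based model filtering, not an
implementation artefact.

## Numerical and degenerate-input choices

- Empty DEG sets score p = 1 for every model with a logged warning rather
  than raising, so batch runs survive empty contrasts; an empty universe is
  an error.
- An overlap of k = 0 returns p = 1 exactly; tail probabilities are clamped
  to (0, 1] against round-off.
- Duplicate edge rows are dropped on load (first occurrence wins); records
  with the same endpoints but different modification subkinds are distinct
  edges. Score thresholding is strict (>), DEG thresholds inclusive (≤/≥).
- Acceptability requires ≥ 2 scored candidate TFs; fewer is an error rather
  than a silently trivial filter.
- The further-PTM-extended variant of Model II (a second modification
  layer) is deliberately not built: it targets kinases rather than TFs and
  adds no downstream genes for TF-centred rosters.

## Limitations

- Cooperative/competitive TF complexes and functionally redundant paralogs
  are not modelled; a knocked-out TF whose role is covered by a partner
  will not be recovered.
- The method needs the perturbation to affect a sizeable fraction of a
  model set; TFs responsible for only a small subset of a large DEG list
  are missed by design.
- Results inherit the completeness and quality of the supplied TF-DNA and
  PTM edge tables; no attempt is made to infer missing edges.
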