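# Methods

## Problem setting

Given `N` lncRNAs, a disease ontology with `D` terms, and sparse evidence
(lncRNA–disease associations, lncRNA GO annotations, lncRNA–miRNA
interactions, miRNA–disease associations), score every lncRNA × disease
pair so that true-but-unobserved associations rank high.  The key modelling
commitments are:

1. diseases are not exchangeable points but nodes of a DAG, and newly
   discovered associations of an lncRNA tend to be *descendants* of its
   known diseases — so the disease-side walk is directed parent→child;
2. the lncRNA similarity network must be built *independently* of the
   association labels, otherwise cross-validation rewards leakage — so
   similarity uses only GO annotations and miRNA evidence;
3. the two subnetworks are structurally different (undirected weighted vs
   directed hierarchical), so each gets its own walker with its own step
   cap rather than one global walk on the merged network.

## Disease side

Wang-style contributions: `S_d(d) = 1`, and for a proper ancestor `d'`,
`S_d(d') = max over children d'' of d' that are ancestors of d (or d) of
w_e * S_d(d'')`.  The max runs only over within-ancestor-set children; the
recursion is evaluated once per term in reverse topological order of the
ancestor-induced subgraph, so it is exact and linear in the subgraph size.
Equivalently `S_d(d') = w_e^dist(d',d)` with `dist` the shortest directed
path; the test suite checks the recursion against exhaustive path
enumeration.  Pairwise similarity `DS` and the semantic values follow the
standard shared-ancestor form.  The matrix builder vectorises all pairs as
`S B^T + B S^T` over the full term space, where `B` is the ancestor
indicator, divided by the outer sum of semantic values.

`w_e` (default 0.9) is the per-edge semantic decay: 0 isolates every term,
1 makes each parent–child link contribute fully.  Note `DS` is *not*
monotone in `w_e` for non-adjacent pairs (on the 3-chain the root–leaf
similarity dips near `w_e = 0.5`), because the semantic values in the
denominator grow faster than the shared mass; only parent–child
similarities grow monotonically.

`W_DD(d', d) = DS(d', d)` on parent→child edges and 0 elsewhere.  It is
deliberately **not** column-normalised: the restart weight and finite step
caps bound the scores, and renormalising would erase the meaningful
difference between strong and weak parent–child links.  A
`column_normalize` option (CLI `--normalize-dd`) exists for
experimentation.  Multi-rooted forests are allowed; cross-root pairs get
similarity 0.

## lncRNA side

`FS(l1, l2) = |T(l1) ∩ T(l2)| / |T(l1)|` is asymmetric as defined; the
stored network averages the two directions because the subnetwork is
undirected (a raw-directed option exists for inspection).  `MS(m1, m2)`
is the raw shared-disease count — intentionally unscaled, since the final
symmetric degree normalisation absorbs the scale.  `MDS` is the two-sided
best-match average; a best match against an empty partner set counts 0,
and a pair with no partners at all scores 0.  `LS = FS + MDS`; supplying
an empty annotation (or interaction) file yields the single-source
variants of the network.  The diagonal is computed by the same formulas
(self-FS is 1 for any annotated lncRNA) and is kept — the walk's sum over
neighbours includes the lncRNA itself, and the diagonal participates in
the degree sums of the normalisation.  Zero-degree rows normalise to zero
rows, never NaN.

## The walk

Both walkers start at the expanded association matrix `A`.  Per step `t`:
the disease walker advances if `t <= t_d` (else carries its state), the
lncRNA walker advances if `t <= t_l`, then `F = (F_D + F_L)/2` and *both*
states are reset to `F` — the walks interact every step.  Iteration runs
to `max(t_l, t_d)` with no convergence tolerance; scores are reported raw
because only the induced ranking matters.  An independent-walks variant
(`combine_at_end`) is provided but is not the default: the per-step reset
is the reference semantics of the combination rule.  `alpha = 0` (or
`t_l = t_d = 0`) returns `A` exactly; every known association keeps a
score of at least `1 - alpha` at every combined step.

Defaults `alpha = 0.3`, `t_l = t_d = 4`, `w_e = 0.9`.

## Evaluation protocols

All protocols rebuild the walk input from the *direct* associations after
hiding, and re-derive the ancestor expansion from what remains — hidden
pairs and expansion entries only they supported are provably absent
(`loocv(..., audit=True)` verifies this per fold by brute force).

**LOOCV.**  One fold per direct association; pooled scores/labels over all
folds give a single ROC (midrank/trapezoidal AUC, equal to the
Mann–Whitney statistic; cross-checked against an exhaustive pairwise
oracle).  Candidates are the diseases (lncRNA orientation) or lncRNAs
(disease orientation) unassociated in the reduced expanded matrix; other
known positives are excluded (an `include_known` option reverses this).
A held-out pair that the remaining direct associations still imply through
the hierarchy is *skipped*: it is still associated in the reduced matrix,
so it has no candidate set — it was never genuinely hidden, and scoring it
would reward the expansion identity rather than the method.  Skipped folds
are reported (`n_skipped`).

**Leaf masking.**  Per round and per lncRNA, the DAG induced by the
lncRNA's own direct diseases is masked leaf-by-leaf (a leaf is a disease
with no strict descendant among the lncRNA's diseases; masking can expose
new leaves), uniformly at random, up to `k` masks, always keeping at least
one disease.  One walk per round; AUC pools all masked pairs against all
never-associated pairs.  Bit-reproducible given the seed (per-round
generators are spawned from one seed sequence).

**Novel disease.**  All lncRNAs carrying the disease in the expanded
matrix are the removed set; the disease's direct column is dropped, the
expansion re-derived, and the column forced to zero so no support path
through the disease survives.  Recovery is the overlap of the removed set
with the top `k = |removed|` ranks (ties break lexicographically, making
rankings deterministic).

**Parameter-sensitivity aggregate.**  Where a single number per setting is
needed (the step-cap trends), the package averages the AUCs of the two
LOOCV orientations.  Per orientation, freezing the walker on the *same*
side as the ranked axis can slightly help that orientation while freezing
the cross-side walker clearly hurts; the orientation mean reflects the
method's overall behaviour across both use cases and shows both `t_l = 0`
and `t_d = 0` below the full walk on the standard benchmark.

## Synthetic data

The generator emulates the joint structure the method exploits, not any
real corpus:

* layered DAG: 1 root + 4 layers × 10 terms, each term with 1–2 parents in
  the previous layer (41 terms; the scale check uses 13 × 31 = 404 terms
  and 240 lncRNAs, the size of a realistic curated corpus);
* 6 functional modules anchored at distinct first-layer subtrees; 60
  lncRNAs and 40 miRNAs assigned round-robin; module members share a
  contiguous pool of 10 of the 60 GO terms;
* per lncRNA: 5 GO draws from the module pool, 3 miRNA partners from the
  module's miRNAs; per miRNA: 3 disease links from the module subtree;
* per lncRNA 4 planted associations from the module subtree
  (`assoc_per_lncrna = 4`, matching the ~3.5 direct diseases per lncRNA of
  real curated association corpora), each subsequent draw being, with
  probability `descendant_bias = 0.7`, a strict descendant of an earlier
  one — the temporal refinement pattern of real curation;
* every single draw above falls back to the global pool with probability
  `noise_rate` (default 0.1).  At `noise_rate = 1` the module structure —
  including the association placement — is gone, and LOOCV sits at chance
  (mean 0.50 over 10 seeds).  The noise branch applies to association
  draws too; if associations stayed subtree-anchored, the hierarchy signal
  would survive in the "null" and it would not be a null.

What passing on this generator does **not** show: robustness to the
identifier noise, annotation biases, literature-coverage confounders and
scale-free degree distributions of real resources; the generator's modules
are cleaner and its DAG more regular than the real disease ontology.

## Numerical and degenerate-input choices

* Similarity matrices are symmetrised exactly (`(M + M^T)/2`) and clipped
  to `[0, 1]` to remove floating-point dust; all division guards map 0/0
  to 0.
* Tie-breaks in every ranking are lexicographic on identifiers —
  deterministic output for deterministic input.
* `roc_auc` refuses single-class inputs; LOOCV requires ≥ 2 direct
  associations; masking with nothing maskable is an error, and `k` larger
  than an lncRNA's degree − 1 masks as much as the keep-one rule allows.
* All randomness flows through `numpy` generators seeded explicitly;
  per-round/per-purpose streams are spawned via `SeedSequence`.

## Known limitations

* The OBO reader keeps `is_a` only; `part_of` and cross-ontology mappings
  are out of scope, as are information-content similarities.
* The walk is step-capped, not convergence-checked, by design; very deep
  ontologies may need `t_d` raised to reach distant descendants.
* Scores are comparable within a run but are not probabilities.
* Comparison methods from the literature (global-walk and regression
  baselines) are not reimplemented here; the degenerate settings
  (`alpha = 0`, zero step caps, single-source similarity) serve as the
  built-in baselines.
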