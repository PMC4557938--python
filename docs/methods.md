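# Methods

## Function profiles

A genome's profile is the count of genes assigned to each function id.
Assignment takes, per query protein, the single best hit with e-value
*strictly* below the cutoff (default 1e-10). The best hit is defined by the
total order (min e-value, max bitscore, min subject id), so assignment is
deterministic and independent of the order of rows in the hit table.
Malformed hit rows are logged with their line number and skipped — one
corrupt line should not abort a whole-genome run. Function ids are read
either from a subject→function sidecar table or parsed from a configurable
delimited field of the subject identifier, since reference-set header
conventions vary. Enzyme (EC) and transporter (KO) profiles are built
independently; a protein present in both reference sets contributes to
both, and the two namespaces are never merged. Id *format* is not policed:
the semantics live in which reference set a function came from, and toy
data legitimately uses ids like `e1`/`t1`.

## Interaction matrices

`build_ein` encodes each reaction as +1 per product and −1 per substrate in
the column of its enzyme function, summed over the function's reactions.
There is no stoichiometry, flux, or mass balance; a compound on both sides
of one reaction nets zero. Two policies are deliberately configurable
because the numeric scheme of stoichiometry-free interaction networks is
not standardised:

- **Reversibility** (`reversible_mode`): default `forward` counts every
  reaction once in its annotated direction; `both` adds the mirrored
  direction for reversible reactions (whose own contribution then cancels).
- **Normalisation** (`normalize`): default `none`; `per_function` divides
  each column by its number of nonzero entries so promiscuous enzymes do
  not dominate scores purely by touching many compounds.

The sign convention makes a positive score mean "greater relative capacity
to synthesize/transport", matching the interpretation of the scores below.
The transportome matrix is binary and validated strictly (a non-binary cell
is fatal, reported with its row/column ids); all-zero columns only warn, so
matrices built against a larger function catalogue than the cohort uses
remain loadable. No currency-metabolite filtering is applied by default; a
user exclusion list can be passed to `subset_network`.

## Scoring

`score` computes, per genome *g*, `M · (log2(c_g + p) − log2(r + p))` where
`r` is the reference count vector and `p` the pseudocount (default 1, so an
absent function maps to log-count 0, preserving "no capacity"). The
reference is the arithmetic mean of **raw** counts across the cohort,
log-transformed afterwards — not the mean of logs. Functions present in the
matrix but absent from every genome are kept as zero counts (warned), so a
matrix derived from one annotation snapshot works with profiles from
another. PRTT is the same code path with a binary matrix; the test-suite
asserts the identity. Pairwise scoring (`score_pair`) is antisymmetric by
construction; with the average reference, scores do not sum to zero across
genomes because log of a mean is not the mean of logs.

## Classification

One binary linear SVM per niche (one-vs-rest; niche labels are
non-exclusive), leave-one-out validated. Choices where the procedure was
genuinely open:

- **Feature filter**: keep features non-zero in *more than* half the
  genomes and with sample SD *strictly greater than* 0.2, applied to the
  feature values as fed to the SVM for each type (counts for profiles,
  scores for the model outputs). Default is a single global filter over all
  genomes; `filter_per_fold=True` refits it inside every LOOV round on the
  training genomes only, removing the mild selection leakage of global
  filtering. The planted-signal recovery tests pass in either mode.
- **Cost parameter**: C ∈ {0.01, 0.1, 1, 10, 100}, chosen by internal
  stratified 10-fold CV accuracy on the training split, ties to the
  smallest C (deterministic). Fold assignment is seeded and stratified;
  when a class has fewer members than folds, the fold count drops to the
  class size, and below 2 the smallest C is used with a warning.
- **Confidence**: `1 − (Φ(z) − ½)` with `z = |d| / σ₊`, σ₊ the sample SD of
  the absolute decision values of the training positives; ≥ 0.95 is flagged
  significant. Taken literally this is maximal *at* the hyperplane, which is
  counter-intuitive; `confidence_mode="centered"` instead measures the
  decision value's deviation from the mean positive training distance.
  The literal form is the default; neither is asserted as "right".
  σ₊ = 0 (identical positive distances) is an error, not a silent 1.0.
- **F-score**: `2PR/(P+R)`. A zero denominator (no predicted positives or
  no actual positives) is not-computable (NaN) for the standalone function;
  within a LOOV report, tp = 0 with positives present is reported as F = 0,
  since recall is genuinely zero there.
- **High-weight features**: |w − mean(w)| > 2·SD(w) on the weights of a
  final model trained on *all* genomes with its own CV-selected C — one
  canonical weight vector per niche; per-round weight vectors are kept in
  the report for inspection. Sample (n−1) SD is used everywhere (filter,
  confidence, high-weight).
- **Class weighting**: none by default; `class_weight="balanced"` available
  because niche prevalences are uneven.

`niche_overlap` tallies, for every subset of niches, the high-weight
features exclusive to exactly that subset, as counts and percentages of the
union (they sum to 100).

The hierarchical-clustering baseline uses Bray–Curtis dissimilarity with
group-average (UPGMA) linkage — the canonical pairing for count-profile
community data — both configurable. Dendrograms export to newick.

## Synthetic cohorts

The generator emulates the statistical shape of genome-annotation studies
so the whole pipeline is testable without databases or downloads:

- counts ~ negative binomial (default mean 1.5, dispersion 2): gene-family
  counts are overdispersed, and these parameters give a realistic zero
  fraction for the majority-presence filter to bite on;
- transporter–ligand matrix: sparse binary, ≥ 1 ligand per transporter
  (~2 on average);
- reaction network: ~2 reactions per enzyme function, 1–2 substrates and
  products drawn disjointly per reaction, ~20% flagged reversible;
- labels: independent Bernoulli per niche at prevalence 0.4 (non-exclusive
  roles), nudged so every niche keeps ≥ 2 positives and ≥ 2 negatives;
- planted signal: per niche, a disjoint block of feature ids (default 5
  transporter functions) shifted additively (default +4 counts) in the
  genomes positive for that niche; the ground-truth manifest records the
  planted ids and labels.

Default study conditions: 60 genomes, 120 enzyme functions, 60
transporters, 90 metabolites, 40 ligands, four niches, signal planted only
in transporter counts. All randomness flows from one seed; regeneration is
bit-identical.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: phylogenetic correlation among genomes (real
strains are not i.i.d.; relatedness inflates apparent signal), correlated
gene-family counts (operons, co-evolving pathways), annotation error and
incomplete reference coverage, and any mechanistic link between the random
reaction network and the planted labels (only the transportome route
carries true signal by design). Recovery results therefore demonstrate that
the machinery detects the signal it is pointed at, not that any particular
real cohort is this easy.

## Numerical and I/O choices

- log2 with pseudocount; `count + pseudocount == 0` is fatal rather than
  silently −inf.
- Strict inequalities where the rules say "more than" / "greater than" /
  "< cutoff".
- All flat files are tab-separated text (wide matrices with a header row of
  function/compound ids; reactions with ;-joined metabolite sets); readers
  use exact (`round_trip`) float parsing so write→read→write is
  byte-identical.
- Pipeline provenance: each run writes `manifest.json` with the
  configuration (and its SHA-256 hash), the seed, the C selected per
  niche/feature type, and SHA-256 digests of every output file. The
  top-level run seed overrides the per-component seeds so one integer
  reproduces the run.
- Problem sizes in the test-suite: oracle equivalence on ≤10×20×15 random
  instances; signal recovery on the 60-genome default cohort; pipeline
  plumbing on an 18-genome cohort with a 3-point C grid and 5 internal
  folds (a smoke-scale configuration choice — completeness and determinism
  do not depend on the grid).

## Known limitations

Scores are relative capacities with no flux, kinetics or regulation;
mixed feature-type SVMs, nonlinear kernels and probability calibration
beyond the confidence statistic above are out of scope; running the
aligner itself is not part of the package (it consumes standard hit
tables); the confidence statistic's literal form should be interpreted
with the caveat discussed above.
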