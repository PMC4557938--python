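# nichecast

Predict the ecological niche of a bacterium from its genome content.

Rhizosphere bacteria such as Pseudomonads fill several non-exclusive
ecological roles — biocontrol agent, biofilm former, plant growth promoter,
plant pathogen — and most genomes recovered from soil metagenomes will never
be characterised in the laboratory. `nichecast` infers those roles from
annotation alone: it turns per-genome enzyme (EC) and transmembrane
transporter (KO) function counts into system-scale *relative capacity*
scores and feeds them to per-niche linear support-vector machines.

## The models

**Function profiles.** Each predicted protein is assigned the annotation of
its single best alignment hit with e-value < 1e-10; a genome's profile is
the count vector over all functions.

**PRMT** (Predicted Relative Metabolic Turnover) compares genome *x* to a
reference *y* through the Enzyme Interaction Network **M**, a metabolite ×
enzyme-function matrix built from a reaction list without flux or mass
balance (+1 where a function produces a compound, −1 where it consumes it):

```
PRMT = M (e_x − e_y)
```

with `e = log2(counts + 1)`. A positive entry means genome *x* has a
greater relative capacity to *synthesize* that metabolite than the
reference; negative, to consume it. Scores are relative capacities, not
rates or concentrations. The reference is the per-function arithmetic mean
of raw counts over the cohort. A *secondary metabolism* model is the same
construction restricted to a secondary-metabolite biosynthesis enzyme set.

**PRTT** (Predicted Relative Transmembrane Transport) is the exact special
case using the binary ligand × transporter matrix **T** and transporter
counts: `PRTT = T (k_x − k_y)`, positive meaning greater relative capacity
to transport a ligand.

**Classification.** One binary linear SVM per niche (one-vs-rest), features
pre-filtered to those non-zero in more than half the genomes with standard
deviation > 0.2, validated leave-one-out with the cost parameter chosen by
internal stratified 10-fold CV. Each held-out prediction gets a confidence
`1.5 − Φ(|d| / σ₊)` (σ₊ = SD of the training positives' absolute hyperplane
distances; ≥ 0.95 flagged significant), each niche an F-score, and each
feature a weight — features more than 2 SD from the mean weight are the
"high-weight" mechanisms most predictive of the niche.

## Worked example

A six-compound toy cell: ligands A, B, C enter via transporters t1 (A, B),
t2 (C), t3 (B, C); inside, enzymes e1–e4 run A → D → E → F → B. Duplicating
t1 raises relative transport capacity for exactly its ligands:

```python
from nichecast import generate_worked_example, score_pair

ex = generate_worked_example()
print(score_pair(ex.transportome, ex.transporter_profiles, "toy_t1dup", "toy_base"))
```

```
compound
A    0.584963
B    0.584963
C    0.000000
Name: toy_t1dup, dtype: float64
```

The 0.585 is log2(3) − log2(2): one extra t1 copy on top of the baseline
single copy, propagated to ligands A and B only (C is moved by t2/t3, whose
counts did not change).

On a synthetic cohort with planted transporter signal, the niche SVM
recovers the labels essentially perfectly from transporter counts:

```python
from nichecast import SyntheticSpec, SVMConfig, generate, loov_ovr_svm

bundle = generate(SyntheticSpec(seed=0))  # 60 genomes, 4 niches, planted signal
report = loov_ovr_svm(bundle.transporter_profiles.astype(float),
                      bundle.labels[["biocontrol"]], SVMConfig(seed=0))
print(report.f_scores())
```

```
biocontrol    1.0
Name: f_score, dtype: float64
```

## Command line

```
nichecast synth   --spec spec.yaml -o cohort/          # synthetic cohort
nichecast profile --hits hits.tsv --kind enzyme -o profile.tsv
nichecast ein     --reactions cohort/reactions.tsv -o ein.txt
nichecast score   --matrix ein.txt --profiles cohort/enzyme_profiles.tsv -o prmt.tsv
nichecast predict --features prtt.tsv --labels cohort/labels.tsv -o report/
nichecast cluster --features cohort/enzyme_profiles.tsv -o tree.nwk
nichecast run     --config config.yaml                 # full factorial pipeline
```

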