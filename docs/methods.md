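# Methods

`nephromine` reimplements, as a tested pipeline over synthetic inputs, a
strategy for finding kidney-origin proteins in urine. The biological idea:
urine collected from an isolated kidney perfused with a blood-free medium
contains only proteins the kidney itself secretes, sheds or leaks — not the
plasma ultrafiltrate that dominates ordinary urine. Profiling that
perfusion-driven urine, mapping the (rat) proteins to human ortholog genes,
and cross-referencing them against human kidney expression, normal-urine,
urinary-exosome and plasma compendia yields a prioritized list of candidate
urinary biomarkers of kidney disease.

## Pipeline stages and their models

### Identification filtering and intersection

Each deep-profiled perfusion sample is an identification table (protein
accession, distinct peptide count, spectral count). Records with fewer than
`min_distinct` distinct peptides are discarded (default 2; the conventional
"more than two distinct peptides" reporting phrase is ambiguous between >=2
and >=3, so the threshold is a parameter). Only proteins identified in
*every* profiling sample — here, two samples run on different instrument
platforms — proceed, which trades sensitivity for identification confidence.

### Ortholog consensus

Orthology databases disagree, so rat-protein -> human-gene pairs are merged
across K mapping tables (default 5) and a pair is kept only when at least
`min_support` (default 2) distinct databases report it. Support counts
databases, not rows. Pairs stay many-to-many; no attempt is made to
collapse co-orthologs to one-to-one, so N proteins can map to more than N
genes. A rat protein whose candidate genes each have single-database
support contributes nothing: the >=2 rule is applied per pair.

### Tier classification

Comparisons are done at the gene level after pooling the normal-urine and
urinary-exosome reference lists into one set. For the kidney-expressed
orthologs (`kidney-origin` genes):

* `zero_background` = absent from pooled urine+exosome — any detection in a
  patient sample is signal;
* `kidney_specific` = absent from plasma — not confounded by other organs;
* `sensitive` = both at once.

With a four-way urine/plasma Venn partition (both, urine-only, plasma-only,
neither), `zero_background` = plasma-only + neither and `kidney_specific` =
urine-only + neither; the classifier reports the partition alongside the
tier counts so this arithmetic is checkable from the output.

### emPAI quantitation

Abundance is the exponentially modified protein abundance index

    emPAI = 10^(N_observed / N_observable) − 1,

where `N_observed` is the distinct peptides matched to the protein and
`N_observable` the tryptic peptides the instrument could detect in
principle. Observability here is: fully tryptic peptides (cleavage
C-terminal to K or R, not before P) at 0 missed cleavages, length >= 6,
whose monoisotopic m/z at charge 2 or 3 falls in the 300–2000 survey-scan
window, with fixed cysteine carbamidomethylation (+57.02146 Da). Distinct
peptide sequences count once. These choices are a defined, reproducible
convention — search engines differ in how they count modified peptides, and
no single convention is canonical. `N_observed` is clamped to the protein's
distinct digest products at the search-engine setting of 2 missed
cleavages, with a warning, so coverage cannot exceed what digestion can
produce. A protein with no observable peptide cannot receive an emPAI and
is excluded with a warning.

Ranking is descending emPAI; ties break by ascending identifier so runs are
reproducible. Universe members never observed all share the terminal rank
m+1 (m = number ranked): the data give no reason to order unobserved
proteins among themselves. Gene-level emPAI is the maximum over a gene's
mapped proteins.

### Rank shift

For each kidney-origin gene, rank change = reference rank − perfusion rank,
so positive means the gene moved toward the top of the abundance list in
perfusion-driven urine. A gene is flagged only when its change meets the
threshold in **every** perfusion sample. The threshold defaults to the
fixed value 300; alternatively it is calibrated as the smallest positive
integer T such that at least a `coverage` fraction (default 0.94) of
|rank changes| between replicate perfusion samples falls strictly below T —
replicate changes reflect pure measurement noise, so a shift clearing
essentially all of them is meaningful. Calibration uses absolute changes;
significance uses signed positive changes (increases only). On a synthetic
universe of a few hundred genes the fixed 300 is unreachable by
construction, so the synthetic end-to-end configuration uses calibration.

### Differential abundance (hypoxia)

Four rats each contribute one oxygen-supplemented and one oxygen-deprived
perfusion sample. Spectral counts are normalized so every sample total
equals the mean of the raw totals (the quantitation used originally is
proprietary and undocumented, so a stated substitute is required for
reproducibility). Per protein: a Welch two-sample, two-sided t-test of
no-oxygen vs oxygen, combined with a within-rat direction rule — the
normalized count must be higher without oxygen in all four rats. A protein
is significant iff p < alpha (default 0.05) **and** the direction rule
holds; proteins with zero variance in both groups get p = 1. No
multiple-testing correction is applied at this stage, matching the original
single-stage p<0.05 + all-samples design; the direction rule is the de
facto guard against false positives. Whether the original test was paired
or unpaired, one- or two-sided, is unknown; the defaults above are the
package's documented choice and all variants are configurable.

### Candidate pooling and prior-biomarker overlap

The candidate pool is kidney-origin genes ∪ hypoxia-increased genes. The
high-quality subset is any candidate that is zero-background,
kidney-specific, hypoxia-increased or rank-shifted; each candidate row
lists its qualifying reasons. Overlap with a user-supplied prior biomarker
gene list splits candidates into already-studied and novel.

### Enrichment

Annotations are gene->term pairs plus a term parent-edge table (a DAG;
ontology file parsing is out of scope — the edge table is the interface).
True-path propagation annotates every gene to all ancestors of its terms.
Each term with at least one study gene gets an exact upper-tail
hypergeometric p-value against the universe (default: all genes in the
annotation file); only those tested terms form the Benjamini–Hochberg
family, and significance thresholds the *adjusted* value at alpha = 0.001.

## The synthetic-data generator

No raw identifications or database snapshots accompany the original study,
so `synthio` generates all inputs with the statistical structure the
analysis assumes, plus a truth table for recovery testing.

* **Proteome** — `n_proteins` (default 1000) random sequences over the 20
  standard residues (no ambiguity codes, keeping digestion deterministic),
  lengths uniform on 100–600 aa.
* **Abundance** — per-protein reference-urine baselines are log-normal,
  median 50 spectral counts, sigma 1 (a typical several-decade dynamic
  range). Counts are negative-binomial with variance mu + alpha*mu^2,
  alpha = 0.05 — i.e. 20–30% CV at moderate abundance, the usual
  overdispersed model for replicate spectral counting. The original study
  reports no inter-rat variance, so alpha is a free parameter, not an
  inference.
* **Distinct peptides** — a coverage model: at spectral count s each of the
  protein's instrument-observable peptides is covered with probability
  s/(s+100) (distinct = 1 + Binomial(capacity−1, p) for identified
  proteins). Coverage saturating with abundance and scaling with protein
  size is precisely the relationship emPAI exploits; modelling distinct
  counts independently of protein size would put small proteins at the top
  of every ranking as an artifact.
* **Reference urine** — one sample drawn at `reference_depth_factor` (5x)
  the baselines, emulating a deep pooled normal-urine compendium; uniform
  scaling preserves the abundance ordering while reducing dropout.
* **Planted effects** — exactly round(fraction x n) proteins per effect,
  hypoxia and rank-shift sets disjoint. Hypoxia: no-oxygen expected counts
  x `hypoxia_fold_change` (default 3) in every rat. Rank shift: perfusion
  baseline x `rankshift_multiplier` (default 30), planted on proteins below
  the `rankshift_low_quantile` (default 0.5) of reference abundance — a
  protein already at the top has no headroom, and the method targets
  proteins scarce in normal urine.
* **Ortholog maps** — a true pairing (1:1 plus a 3% second-gene fraction,
  echoing real co-ortholog expansion); each of 5 databases reports each
  true pair with probability 0.8 and adds a spurious random pair per
  protein with probability 0.01.
* **Reference sets** — a configurable urine/plasma Venn partition (default
  613/240/71/57) is imposed exactly on a random kidney-expressed subset of
  the gene universe; urine-side members are split between whole-urine and
  exosome lists (pooling recovers the partition), and background gene ids
  pad every compendium. `build_paper_venn_fixture` builds the partition
  deterministically without any simulation.
* **Annotations / prior biomarkers** — a 40-term random DAG with 1–3 terms
  per gene, and a random 7% slice of the gene universe.

What the generator does **not** emulate: raw spectra, retention times,
search-engine scoring, correlated protein abundances, shared-peptide
ambiguity, contamination, or any real biological covariance between the
reference compendia. Passing recovery tests therefore demonstrates that
the pipeline's logic and statistics behave as specified under the assumed
generative model — not that the thresholds transfer to any particular real
dataset.

## Numerical and scale choices

* All generators are pure functions of (config, seed); per-stage substreams
  come from `numpy.random.SeedSequence(seed, stage)`, so adding a stage
  never perturbs another stage's draws.
* Test and demonstration runs use 120–1000 proteins, 2 profiling samples,
  4 rats x 2 conditions — sizes at which every stage completes in seconds
  while leaving planted/null separations that are not trivially wide.
* The null calibration of the differential test (fraction of p < 0.05
  within three binomial standard errors of 0.05 over 1000 proteins) and its
  power (recall >= 0.8 of 3-fold effects at 4 rats) are checked at fixed
  seeds in the acceptance suite.
* The rank-shift recovery check constructs the clean-separation scenario
  its property presumes: planting on the lowest abundance decile with a
  1000x multiplier, dispersion 0.01 and proteins >= 300 aa, where planted
  changes exceed 300 and null changes stay below ~220 in a 400-gene
  universe; threshold 250 sits in the gap.
* Ties, absent proteins and degenerate inputs are all resolved
  deterministically (accession-order ties, shared terminal rank, p = 1 for
  zero-variance proteins, warnings plus exclusion for degenerate proteins).

## Known limitations

* emPAI is an order-of-magnitude abundance proxy; rank comparisons across
  species rest on the untested assumption that orthologous protein
  abundances correlate.
* The fixed rank-shift threshold of 300 is only meaningful at the original
  ~981-gene scale; use calibration elsewhere.
* Welch's t-test at n = 4 per group has limited power for overdispersed
  low-count proteins; counts-based models (e.g. negative-binomial GLMs)
  would be more powerful but are outside the scope of reproducing the
  original design.
* The enrichment stage treats the term DAG as opaque edges; ontology
  namespaces and evidence codes are out of scope.
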