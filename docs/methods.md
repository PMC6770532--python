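# Methods

## Problem and model

`lncstack` treats lncRNA identification as binary classification of
transcript sequences (positive class: lncRNA, label 1). The model
assumes transcripts are supplied in mRNA sense (forward strand only)
over the DNA alphabet, typically 200–3000 nt: lncRNAs are by definition
longer than 200 nt and the feature statistics are tuned to that window.
The pipeline has three stages — feature extraction, GA-RF feature
selection, stacked-ensemble classification — each usable on its own.

## Sequence handling

Input is folded to uppercase DNA (U→T). Residual non-ACGT characters
are kept as the sentinel `N` provided they make up at most 10% of the
sequence (otherwise the record is rejected); k-mer, hexamer and EDP
windows containing `N` are skipped and excluded from denominators, and
codons containing `N` translate to nothing. The length filter is strict
on both bounds (keeps 200 < L < 3000 by default) because a lncRNA must
*exceed* 200 nt. Redundancy removal (e.g. CD-HIT clustering at 80%
identity) is a recommended upstream step for real training sets but is
not part of this package.

## ORF conventions

ORFs are ATG-initiated in-frame codon runs. The first in-frame stop
codon terminates the ORF and is *included* in its length, so a
transcript that is exactly one complete CDS has ORF coverage 1.0; with
no in-frame stop the ORF extends to the last complete codon and is
flagged incomplete. Ties are broken deterministically: the *first* ORF
is the smallest start (preferring stop-terminated, then longer); the
*longest* ORF is the maximum length (ties: smallest start, then
stop-terminated). ORF integrity is coded {+1, −1}. Every "frame score"
in the package is the population variance (divide by 3) of a per-frame
statistic over the three forward frames.

## Feature blocks

* **Fickett TESTCODE** uses the published 1982 position/content lookup
  tables and weights; position parameters are max/(min+1) of per-base
  codon-position counts over frame-0 complete codons.
* **Hexamer score** is the mean log ratio of in-frame (step 3) hexamer
  frequencies under coding vs. noncoding tables. Tables are trained on
  the longest ORFs of coding sequences and the raw noncoding sequences,
  with add-one smoothing (pseudocount configurable) so unseen hexamers
  never produce infinities. A transcript whose longest ORF has no
  complete hexamer scores 0.
* **EDP** (entropy density profile) of a count vector is
  s_i = −p_i·log p_i / H (natural log; one-hot profiles are returned
  unchanged since H = 0). It is applied to the 16 dinucleotide counts
  of the longest ORF and to the 20 amino-acid counts of the frame-0
  translation with stops skipped.
* **SNR** sums the power spectra of the four base-indicator sequences
  and divides the power at bin round(N/3) (codon periodicity) by the
  mean non-DC power; degenerate spectra give 0.
* **CTD** is reduced to the 20 distribution descriptors (relative
  positions of the first/25%/50%/75%/last occurrence of each base):
  the composition and transition components are numerically identical
  to the k=1 and k=2 k-mer blocks already present, and only the
  20-descriptor reading is consistent with the 260-dimension budget.
* **CDS block**: the most-likely CDS is the longest ORF, scored by the
  transparent surrogate `len·(1+max(0,hexamer)) + 50·[stop] + 50·[ATG]`
  — monotone in ORF length, completeness and coding-like composition.
  Externally computed CDS calls (UCSC txCdsPredict TSV) can override it.
* **Structure block**: the longest-ORF peptide's average molecular
  weight (ExPASy convention), theoretical pI (Bjellqvist pKa set,
  bisection on [0,14] to 1e-3 pH), log10(pI/Mw) with a 0 guard for
  empty/degenerate peptides, Kyte–Doolittle GRAVY, and the Guruprasad
  instability index (DIWV weights). Transcripts without an ORF get
  zeros throughout.

Degenerate-input rules are chosen so the assembled 260-vector is always
finite. One naming note: the whole-transcript GC content is called
`GC_content` because the bare string `GC` names the dinucleotide
frequency in the k-mer block.

## GA-RF feature selection

Chromosomes are 260-bit masks initialized i.i.d. Bernoulli(0.5).
Fitness is the mean AUC of a seeded *stratified* k-fold CV of a random
forest on the masked columns (stratification stabilizes the AUC
estimate); the all-zero mask scores 0, and fitness values are cached by
gene bits so re-evaluations are exact repeats. Defaults follow the
full-scale profile (population 500, 50 generations, tournament size 3,
crossover 0.5, per-gene flip 0.05, per-individual mutation 0.2, 100
trees, 10 folds); `DESK_PROFILE` (population 60, 25 generations, 5
folds, 50 trees) is the interactive/test profile. The loop stops early
when the best-ever fitness fails to improve by more than 1e-4 for 5
consecutive generations — a concrete reading of "stop when the maximum
fitness is stable". The returned "top 10" is a hall of fame over *all*
distinct chromosomes ever evaluated (not just the final population),
ranked by fitness with byte-order tie-breaking for determinism.

## Stacked ensemble

One random forest per optimal subset (10 members by default; member
seeds derive from `random_state + member index`), averaged
positive-class probability as the output layer, threshold 0.5 with ties
called lncRNA. RF hyperparameters beyond tree count stay at library
defaults. Model archives embed the feature-schema hash, the masks and
the seed; loading verifies the hash so a model can never be applied to
a differently ordered feature table.

## Metrics

ACC, SN, SP, PRE, F1 from confusion counts with zero-denominator
metrics reported as NaN ("undefined") rather than 0; AUC is the
tie-averaged ROC area (equivalently the normalized Mann–Whitney U,
which the tests verify by brute-force pair counting). Cross-validation
is seeded stratified k-fold; SN is lncRNA recall since lncRNA is the
positive class.

## Synthetic data

The generator emulates the two statistical signatures the classifier
exploits. *Coding-like*: random-background 5'UTR + ATG + codons drawn
from a per-dataset Dirichlet-sharpened sense-codon distribution
(sharpness = `codon_bias_strength`, default 0.75) + stop + 3'UTR, with
the ORF covering at least 60% of the transcript (draws violating the
complete-dominant-ORF contract are resampled). *Noncoding-like*: an
order-2 Markov background whose transition rows are mild Dirichlet
perturbations around the GC-target base distribution (default GC 0.5).
Lengths are uniform strictly inside [len_min, len_max] = [200, 3000].

`codon_bias_strength = 0` is the designed null control: the "coding"
class is then drawn from the same background process as the noncoding
class (the ORF scaffold is dropped, since an enforced 60%-coverage ORF
alone would separate the classes), making the two labels exchangeable.

What the synthetic benchmarks show — and do not: they verify that the
pipeline recovers strong, known signal (near-perfect AUC on separable
data; every planted informative feature recovered by the GA) and
manufactures none under the null (AUC ≈ 0.5). Real transcriptomes have
weaker, correlated signals (splice isoforms, pseudogenes, short CDSs,
biased GC) that the generator does not emulate, so synthetic AUCs do
not predict real-data accuracy; training on curated labelled sets
(e.g. GENCODE-derived) is required for production use.

## Benchmark problem sizes and leakage control

The GA recovery benchmark uses 400 samples with 20 standard-normal
features, label = 1[(X1+..+X5)/√5 + 0.6·ε > 0], desk GA profile: the
noise level makes each informative feature individually necessary for
top fitness while keeping CV noise small enough that all ten
hall-of-fame masks contain all five.

The end-to-end benchmark uses 500+500 transcripts. The hexamer table is
trained on a *disjoint* 200+200 batch generated with an offset seed:
scoring sequences against a table trained on themselves leaks label
information (we measured null-calibration AUC ≈ 0.94 with in-sample
tables vs. ≈ 0.52 with disjoint tables). GA selection runs on a
stratified 200-sample split — the analogue of selecting features on a
separate independent set — and the stacked ensemble is evaluated by
10-fold CV on the full 1000.

## Known limitations

Forward-strand ATG-initiated ORFs only; no secondary-structure or
conservation features; the CDS score is a surrogate, not a
reimplementation of txCdsPredict; pI/Mw constants follow the ExPASy
conventions and may differ in the second decimal from other tools'
tables; the GA is single-objective with no explicit elitism inside the
population (the hall of fame preserves the best solutions instead).
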