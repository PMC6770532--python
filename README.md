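# lncstack

Distinguishing long non-coding RNAs (lncRNAs) from protein-coding
transcripts is a routine first step after transcript assembly: a
lncRNA is longer than 200 nt and lacks protein-coding capacity, but at
the sequence level the two classes differ only statistically. `lncstack`
is an alignment-free classifier for this task, built for
bioinformaticians who have transcript FASTA files and want calibrated
lncRNA probabilities plus an auditable feature pipeline.

## Method

Every transcript (DNA alphabet, intended range 200–3000 nt) is mapped
to a **260-dimension global feature vector** drawn from six categories:

| category | dims | contents |
|---|---|---|
| codon | 9 | stop-codon count/frequency and their across-frame variances, Fickett position parameters, Fickett TESTCODE score |
| ORF | 22 | first/longest ORF lengths and coverages, ORF integrity, ORF frame score, dinucleotide entropy density profile (EDP) of the longest ORF |
| GC | 7 | GC content, GC1–GC3 of the longest ORF, their variance, UTR GC |
| CDS | 3 | CDS length, percentage, and a deterministic coding-likelihood score |
| transcript | 213 | transcript length, k-mer frequencies (k=1..3, transcript and ORF), CTD distribution descriptors, in-frame hexamer score, DFT codon-periodicity SNR, UTR coverage, amino-acid EDP |
| structure | 6 | Mw, pI, log10(pI/Mw) and its frame score, GRAVY, instability index of the predicted peptide |

Feature selection is a **GA-RF wrapper**: a genetic algorithm over
binary feature masks (tournament selection of size 3, single-point
crossover with probability 0.5, flip-bit mutation with per-gene
probability 0.05 and per-individual probability 0.2, population 500,
up to 50 generations) whose fitness is the 10-fold cross-validated AUC
of a 100-tree random forest restricted to the mask. The ten best
distinct masks ever evaluated form the optimal subsets.

The classifier is a **two-layer stacked ensemble**: one random forest
per optimal subset (10 members), with the output layer averaging the
members' lncRNA probabilities:

    score(x) = (1/10) * sum_m P_m(lncRNA | x_masked_m),   call lncRNA iff score >= 0.5

## Worked example

```bash
lncstack synth --seed 7 --n-coding 100 --n-noncoding 100 --out data/
lncstack train-hexamer data/coding.fa data/noncoding.fa --out hex.tsv
lncstack extract data/coding.fa    --hexamer hex.tsv --label 0 --out coding.tsv
lncstack extract data/noncoding.fa --hexamer hex.tsv --label 1 --out noncoding.tsv
# concatenate the two labelled tables, then:
lncstack select features.tsv --seed 7 --out subsets.json
lncstack train features.tsv --subsets subsets.json --hexamer hex.tsv --out model.joblib
lncstack predict data/noncoding.fa --model model.joblib --out scores.tsv
lncstack evaluate --scores scores.tsv --truth data/labels.tsv --out metrics.json
```

The same pipeline through the Python API:

```python
from lncstack.workflow import synthetic_end_to_end
result = synthetic_end_to_end(seed=1, codon_bias_strength=0.75)
print(round(result["cv"]["pooled"].auc, 4), len(result["masks"]))
```

prints

```
1.0 10
```

i.e. on the default synthetic benchmark (500 coding-like + 500
noncoding-like transcripts) the 10-member stacked ensemble separates
the classes essentially perfectly under 10-fold cross-validation, using
the 10 feature subsets selected by the GA. The matching null control
(`codon_bias_strength=0.0`, GC matched: both classes drawn from the
same background process) gives an AUC near 0.5, confirming that the
pipeline does not manufacture signal where none exists.

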