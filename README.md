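# barcodekit

Analysis toolkit for DNA barcoding surveys: given aligned barcode sequences
(typically the 5′ ~652 bp of mitochondrial COI) and a five-rank specimen
taxonomy, it quantifies how well genetic distance separates species — the
"barcode gap" — and provides the character-based alternative for markers too
conserved for distance-based identification.

It is written for researchers assembling or auditing barcode reference
libraries (e.g. FISH-BOL-style fish surveys) who want the standard battery
of analyses reproducible from the command line or from Python.

## What it computes

**Distances.** Pairwise Kimura 2-parameter distances with pairwise deletion
of gaps and ambiguity codes:

```
d = −½ · ln[(1 − 2P − Q) · √(1 − 2Q)]
```

where *P* and *Q* are the proportions of transitions (A↔G, C↔T) and
transversions among compared sites. Saturated pairs (log argument ≤ 0) are
masked explicitly, never silently dropped. Uncorrected *p*-distances are
available as a baseline.

**Barcode-gap statistics.** Every specimen pair falls in exactly one
comparison class — within species, within genus (different species), within
family (different genera), within order, within class — and per-class
summaries (mean/min/max/SE, in %) reproduce the classic rank-divergence
table. Congeneric distances are banded (<5%, 5–10%, >10%) per family;
per-species nearest-neighbor distances (NND), threshold fractions ("x% of
intraspecific distances below 1%"), Tukey boxplot statistics, and
barcode-gap flags (deep intraspecific splits, NND below the 1% filter)
complete the picture.

**Numt screening.** Protein-coding sequences are translated with the
vertebrate mitochondrial code; stop codons, internal gaps, and lengths not
congruent mod 3 with the dataset mode mark suspected nuclear pseudogene
(numt) co-amplifications.

**Trees.** A deterministic neighbor-joining implementation (lexicographic
tie-breaking, negative branch lengths clamped and logged) builds the
unrooted tree from the K2P matrix; a bipartition test reports, per species,
whether one edge cut separates exactly its specimens ("forms a species
cluster").

**Diagnostic characters.** For conserved markers (18S), pure simple
diagnostic sites: alignment columns where a species' observed states are
disjoint from all other species, plus a query scorer ranking species by the
fraction of diagnostic states matched.

**Synthetic data.** A Kimura-process simulator generates study-shaped
datasets — nested taxonomy, rank-ordered divergence targets (defaults 0.2% /
13.5% / 19.7% / 24%), transition bias κ, optional planted numts, deep
intraspecific splits and diagnostic columns — with ground truth serialized
alongside, so the whole pipeline is testable without downloads.

## Worked example

```sh
barcodekit simulate --seed 42 --out-dir demo/data
barcodekit run-all --fasta demo/data/sequences.fasta \
    --taxonomy demo/data/taxonomy.tsv --out-dir demo/out
```

`demo/out/rank_summaries.tsv` (this exact output, seed 42):

```
comparisons_within	taxa	n_comparisons	mean	minimum	maximum	se
species	8	24	0.26	0.00	0.46	0.03
genus	4	36	13.10	11.77	14.38	0.17
family	2	72	19.92	16.47	22.95	0.22
order	1	144	24.57	21.02	29.25	0.15
```

Read it as: 8 species (24 conspecific pairs) diverge 0.26% on average while
congeneric species diverge 13.10% — a ~50-fold gap for this draw, echoing
the pattern real COI surveys report. The bundle also contains the QC report
(here: 24/24 pass, frame 0), the PHYLIP distance matrix, the per-family band
table (all 36 congeneric distances in the >10% band), per-species NNDs
(e.g. `Genus1A_sp1 → Genus1A_sp2, 11.77%`), the newick NJ tree, the species
cluster report (8/8 species form clusters), the diagnostic-site library, and
a run log with versions and parameters.

Each stage is also exposed alone (`barcodekit qc|distances|summarize|nnd|
tree|clusters|diagnose`), and everything is importable:

```python
from barcodekit import load_dataset, pairwise_matrix
from barcodekit.gap_analysis import rank_summaries

ds = load_dataset("demo/data/sequences.fasta", "demo/data/taxonomy.tsv", "COI")
summaries = rank_summaries(pairwise_matrix(ds), ds.taxonomy)
```

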