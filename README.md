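# barcodegap

Evaluation of single and combined DNA barcodes for species identification,
built around the two criteria recommended by the CBOL Plant Working Group:
the **barcoding gap** (PWG-distance) test and **tree-based monophyly** with
bootstrap support. The package targets multilocus studies of the kind used
for fungal species delimitation — several nuclear markers (e.g. ITS,
*EF1-α*, *RPB1*, *RPB2*) sequenced for tens of species with a handful of
individuals each — and answers the question: *which marker, or combination
of markers, identifies the most species?*

## What it computes

Given pre-aligned per-marker FASTA files and a sample → species table:

- **Marker variability** — per-marker SNP and indel site counts, their
  percentages of the aligned length, and mean intra-/interspecific
  divergence.
- **Pairwise distances** — uncorrected *p*-distance and the Kimura
  2-parameter distance under pairwise deletion of gaps/ambiguities:

  d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

  with *P* and *Q* the transition (A↔G, C↔T) and transversion proportions
  over comparable sites.
- **PWG-distance criterion** — species *s* is identified when
  min(interspecific distances of *s*) > max(intraspecific distances of *s*),
  strictly. The identification rate is the percentage of species that
  succeed (half-up, two decimals).
- **NJ-tree criterion** — a Saitou–Nei neighbour-joining tree with
  nonparametric bootstrap; species *s* is identified when its individuals
  are monophyletic and the subtending edge has support strictly above 50%.
- **The sweep** — every non-empty marker combination (4 single + 11
  combined for a four-marker study) × both methods × both models, with all
  per-species records, trees, divergence histograms and rate tables written
  as TSV/Newick.

A synthetic-data module generates multilocus datasets with known species
structure (species tree, marker-specific rates, within-species
lineage-joining model that can produce incomplete lineage sorting, optional
indels and label contamination) so the whole pipeline is testable without
any sequence download.

## Worked example

The analysis scripts run the whole study on generated data:

```sh
python analysis/01_simulate_dataset.py --seed 1 --out results/data
python analysis/02_marker_variability.py --data results/data --out results
python analysis/03_discrimination_sweep.py --data results/data \
    --out results/evaluation --seed 1 --bootstrap 50
```

The first script prints the realized design —

```
dataset: 260 individuals, 45 species (per-species n: 2-10)
marker      bp mean intra % mean inter %
ITS        452       0.0884        13.49
EF1a       312       0.0441         7.77
RPB1       420       0.0442         6.72
RPB2       391       0.0087         0.42
```

— four markers spanning a fast ribosomal spacer (ITS-like, mean
interspecific K2P divergence ≈ 13%) down to a strongly conserved
protein-coding gene (RPB2-like, ≈ 0.4%), with within-species divergence two
orders of magnitude smaller. The sweep then reports, per marker set:

```
single markers (K2P):
  EF1a     PWG  97.78%   NJ  93.33%
  ITS      PWG 100.00%   NJ 100.00%
  RPB1     PWG  97.78%   NJ  88.89%
  RPB2     PWG  28.89%   NJ  26.67%

four-marker concatenation:
  PWG K2P 100.00%   NJ K2P 100.00%   NJ p-distance 100.00%
```

Reading: the conserved marker alone identifies only a quarter of the
species (its divergences sit below the noise of the gap test and its trees
lack supported species clades), while variable markers and any combination
containing one identify essentially all species in this high-signal
simulation. `results/evaluation/` holds `rates.tsv`, `rates_wide.tsv`,
`variability.tsv`, per-species `gap_records/`, bootstrap-annotated
`trees/*.nwk` and `histograms/` of the intra/inter divergence
distributions; every rate is re-derivable from the persisted records
(`barcodegap.verify_output_dir`).

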