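# Methods

## Distances and site statistics

Distances are computed under **pairwise deletion**: any site where either
sequence has a gap (`-`), `N`, or an IUPAC ambiguity code is excluded for
that pair (the default behaviour of the common desktop phylogenetics tools
for these analyses). The uncorrected distance is *p* = mismatches /
comparable sites. The Kimura 2-parameter distance is
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), with transitions A↔G and C↔T and all
other nucleotide mismatches transversions. When the logarithm argument is
non-positive (saturation) the pair raises an error by default; an optional
cap mode substitutes a configurable `d_max` for exploratory sweeps.
Internally all-pairs counts come from one-hot encodings and matrix
products, which makes bootstrap loops cheap; counts are exact (small
integers in float arithmetic).

Site classification assigns every alignment column: a column containing any
gap is an **indel site**; a column whose gap-free rows show two or more
distinct unambiguous nucleotides is a **SNP site**. A gapped column with
residual nucleotide polymorphism counts in *both* tallies (toggleable via
`count_gapped_polymorphic_as_snp`), so the variable-site percentage — 100 ×
(SNPs + indels) / aligned length — matches the additive definition used in
marker variability tables. Columns varying only in ambiguity codes are
monomorphic. Reported percentages are rounded half-up to two decimals;
half-up is applied uniformly even though one published marker table appears
to truncate a single value (22.85 where half-up gives 22.86).

## Discrimination criteria

**PWG-distance**: species *s* succeeds iff min(inter(*s*)) > max(intra(*s*))
with strict inequality; ties fail. Both sides are evaluated under one model
(default K2P) for internal consistency; the criterion is per-species only —
no additional pooled-overlap veto is applied, since no quantitative
"obvious overlap" threshold exists. Singleton species (no conspecific
pairs) succeed when their nearest heterospecific distance is positive
(`count_success_if_positive_inter`, the default, keeps the denominator at
the full species count); an `exclude` policy drops them. The
identification rate is 100 × successes / evaluated species, half-up to two
decimals. Divergence histograms use half-open bins of width 0.005
substitutions/site by default and record the overlap interval
[min inter, max intra] when the pooled distributions overlap.

**NJ-tree**: neighbour joining follows the Saitou–Nei agglomeration with
the Q-criterion; ties are broken by the lowest (row, column) index pair in
the current matrix ordering, making the algorithm deterministic. Negative
branch-length estimates are clamped to zero with the deficit transferred to
the sister edge. Bootstrap resamples alignment columns with replacement;
replicate *r*'s resample depends only on (seed, *r*), so supports are
reproducible and invariant to tip order (absent exact distance ties).
Resamples that leave a pair without comparable sites or saturated are
redrawn (counted, logged; abandoned after 10 × replicates redraws).
Supports are mapped onto the reference tree built from the full alignment,
not onto a consensus. A species is identified when some edge's bipartition
equals exactly its set of individuals and (for multi-individual species)
that edge's support strictly exceeds the threshold (default 50). Singletons
are monophyletic by convention; a tree without support annotations falls
back to topology-only scoring with a warning.

Combined barcodes are column-wise concatenations; the default
`intersect` policy keeps only samples present in every selected marker
(matching how combined matrices are usually assembled), with
`pad_with_gaps` available for exploratory union analyses.

## Synthetic data generator

The generator emulates a multi-marker fungal barcoding study: 45 species,
260 individuals (1–20 per species, drawn once per seed), four markers of
452/312/420/391 aligned bp whose relative substitution rates (1.9, 1.05,
0.85, 0.085) span a fast ribosomal spacer to a strongly conserved
protein-coding gene. With the default interspecific depth of 0.05
substitutions/site this realizes mean interspecific K2P divergences of
roughly 0.4–13.5% and mean intraspecific divergences of roughly
0.01–0.09% across markers, the ranges such studies report.

*Species tree.* Topology is built by uniformly random pair joins; every
edge gets equal length and the tree is rescaled so the mean root-to-tip
path equals `interspecific_depth`. Equal edges are a deliberate
curated-taxonomy geometry: a set of *recognized* species contains no pair
separated by a vanishing fraction of tree height, unlike a Kingman
coalescent draw whose first split is O(1/n²) of the height. This keeps the
minimum species divergence predictable, which is what makes the
discrimination analyses interpretable.

*Within-species model.* Each individual's lineage joins its species'
ancestral (root-ward) lineage at a depth drawn uniformly from
[0, `intraspecific_depth`] (clamped at the root, shared across markers —
one organismal history per individual) and evolves independently down to
the present, so tips are contemporaneous. When the joining depth is small
relative to the species' terminal branch this behaves like a
within-species star. When it rivals species divergence times, lineages
join *above* speciation events — incomplete lineage sorting — and
conspecific individuals genuinely cease to be a clade. A pure star
attached at the species tip cannot represent that regime: the true species
clade persists at any intraspecific depth, so tree-based discrimination
never collapses no matter how noisy the data. The lineage-joining model was
chosen for exactly this reason; ILS is also the standard explanation for
confounded species in real multilocus fungal data. Expected conspecific
divergence is (4/3) × `intraspecific_depth`; heterospecific divergence is
unaffected by the joining depth while joins stay below the speciation node.

*Substitution model.* Sites evolve i.i.d. under K80 with
transition/transversion rate ratio κ (default 2), total rate normalised so
branch lengths are expected substitutions/site; site change probabilities
use the closed-form K80 transition matrix. No rate heterogeneity across
sites is simulated — consequently simulated alignments spread variation
over many more columns than real markers of equal mean divergence (SNP
percentages come out high), while pairwise divergences match. Indels are
single-column deletions applied per column with probability `indel_rate`
(default 0.02) to all individuals of the species descending from a
uniformly chosen species-tree edge; there are no insertions, so columns
stay homologous. An optional label-swap mode reassigns a fraction of
individuals to wrong species as a contamination negative control.

All randomness derives from the config seed through fixed
`numpy.random.SeedSequence` streams (tree, counts, per-marker evolution,
per-marker indels, label swaps, joining depths), so datasets are
bit-reproducible.

What passing tests on these data do and do not show: they verify the
arithmetic, algorithms and end-to-end wiring of the pipeline, and the
qualitative behaviours (variable markers and combinations discriminate
better; signal collapses when within-species depth rivals the species
tree). They do not show that real studies achieve any particular rate —
real data add alignment error, rate heterogeneity, introgression and
unbalanced sampling that the generator deliberately omits.

## Numerical and design choices

- Rounding of reported percentages: half-up to two decimals, computed in
  exact decimal arithmetic from the integer counts.
- Newick round-trips preserve branch lengths to 10 significant digits;
  bootstrap supports are written as internal-node labels and keyed
  internally by canonical bipartition (the side excluding the
  lexicographically smallest tip), which makes them invariant to rooting.
- The evaluation sweep reports tree rates separately under p-distance and
  K2P; PWG is evaluated per requested model (K2P by default). Every rate
  row in `rates.tsv` is re-derivable from the persisted per-species
  records, and `verify_output_dir` performs that check.
- Sweep outputs contain no timestamps, so a rerun with the same config and
  seed is byte-identical.
- Problem sizes in tests and the acceptance script are chosen for a
  desk-scale run: simulation checks use 20 species × 5 individuals × 4 ×
  500 bp with 200 bootstrap replicates across 10 seeds, and the full-study
  sweep uses the 45-species / 260-individual design with 50 bootstrap
  replicates per tree (a published analysis would use 1000; support
  estimates at 50 replicates are coarser but the >50% criterion is stable
  for well-supported clades).

## Known limitations

- Only the K2P and p-distance models are implemented (no JC69/TN93/GTR,
  no codon-aware distances, no among-site rate variation).
- The monophyly criterion is all-or-nothing per species; partially
  supported subclades of a non-monophyletic species are not scored.
- The generator does not fit its parameters to real data and omits
  recombination, introgression and within-species population structure
  beyond the lineage-joining depth.
- Inputs must be pre-aligned; the package never aligns sequences.
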