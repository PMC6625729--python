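# Methods

## Motif definition and scanning

A SECReTE motif is an uninterrupted run of nucleotide triplets with a fixed
checked position carrying a pyrimidine (or, for the generalized NNX family,
any of the two-letter IUPAC classes R, K, M, S, W). For phase *p* the checked
bases of a region-local sequence are positions *p*, *p*+3, *p*+6, …; a run is
a maximal stretch of consecutive checked bases inside the class, and only
runs of at least `min_triplets` triplets (default 10) are reported. Key
conventions:

- **Maximality.** Sub-runs are never reported: a 25-triplet run at threshold
  10 is one motif, not sixteen. The base one triplet before the run start and
  one triplet after the run end is either out of bounds or out of class.
- **Phases and regions.** The CDS is scanned in the reading frame, so phases
  0/1/2 are codon positions YNN/NYN/NNY. UTRs have no frame; each UTR is
  scanned at all three offsets from its own 5′ end, and a poly-Y stretch
  therefore yields a hit at every offset — these are counted separately,
  mirroring the per-frame CDS counting. A `FULL` mode concatenates
  5′UTR + CDS + 3′UTR with offsets anchored at the transcript 5′ end for
  whole-gene profiles; in the default region modes runs never cross region
  boundaries.
- **Ambiguity codes.** Sequences are uppercased and U→T at ingest; ambiguity
  codes other than N are collapsed to N. An N at a checked position breaks a
  run (conservative choice); N at an unchecked position is irrelevant to run
  membership but counts in the denominator of pyrimidine content.
- **Coordinates.** 0-based half-open internally; all emitted tables are
  1-based inclusive and their headers say so. `start_nt` is the start of the
  run's first triplet, so the first checked base sits at `start_nt + phase`.
  The motif sequence string spans complete triplets from `start_nt`,
  truncated at the region end if fewer than 3 nt remain after the last
  checked base.
- **Stop codon.** Included in CDS scanning (the CDS is taken start codon
  through stop codon). Genes whose CDS length is not a multiple of 3 are
  excluded at assembly and counted, since per-codon-position analysis is
  undefined for them.

The RRY score separates genuinely purine-purine-pyrimidine patterned motifs
from merely pyrimidine-rich ones: each base scores 1 if it matches the cyclic
R,R,Y template letter at its position, the mean is taken over the motif, and
the maximum over the three template offsets is returned. Poly-Y scores
exactly 1/3; a perfect RRY repeat scores 1.0.

## TMD / SSCR excision

Transmembrane domains are encoded by hydrophobic codons with pyrimidine
second bases, so NYN enrichment could be a protein-level artefact. Excision
removes whole codons by 1-based protein coordinates (overlapping intervals
merged), concatenates the flanks, and rescans. Runs newly created across the
junction are reported as-is — whether concatenation creates motifs *de novo*
is an empirical question the analysis should be able to ask, not a rule to
suppress. Hits on excised sequences carry a region tag (`CDS-TMD`,
`CDS-SSCR`, `CDS-both`) and excised-space coordinates.

## Statistics

- **Fractions and chi-squared.** The per-set fraction of genes with ≥1 motif
  feeds a 2×2 presence/absence table; Pearson chi-squared with df = 1 and no
  continuity correction (gene sets here are large enough that the Yates
  correction would only bias the statistic downward). Zero marginals are an
  error in `chi2_enrichment`; the threshold sweep tolerates them (NaN) since
  extreme thresholds legitimately saturate presence. BH step-up FDR is
  applied across the NNX family of tests.
- **ROC/AUC.** Scores are per-gene motif counts at the evaluated threshold
  (binary presence is a degenerate case of counts; counts preserve the
  ordering information the figure-level analyses use). AUC is computed as
  the area under the empirical ROC, identical to the tie-corrected
  normalized Mann–Whitney U; a pairwise-enumeration oracle verifies this to
  1e-12 in the tests.
- **Permutation test.** Codon order is shuffled with the codon multiset
  (hence codon usage and GC) unchanged. Because shuffling codons merely
  permutes the per-codon class flags at each codon position, the shuffle
  statistic is evaluated on permuted boolean arrays — exactly equivalent to
  scanning the shuffled string (asserted in a test) and an order of magnitude
  faster. The default per-gene statistic is the longest run length in
  triplets per phase; the motif count at the threshold is available as an
  alternative, since either reading is defensible and they answer slightly
  different questions (strength vs multiplicity). Degenerate genes (all
  shuffles identical, SD = 0) get Z = 0 with a flag and are excluded from
  significant-fraction denominators by default.
- **ECDF comparisons.** For external per-gene values (e.g. ER-enrichment
  ratios), ECDFs of motif-bearing vs motif-lacking genes are computed on the
  union grid, with the two-sample Kolmogorov–Smirnov statistic as the
  numeric summary accompanying the plots.
- **Distributions.** Region densities divide motif counts by the mean length
  of that region over the genes that have it — genes lacking an annotated
  UTR do not enter that UTR's denominator. Positional histograms place each
  hit at its start position within the 5′UTR+CDS+3′UTR concatenation,
  normalized by transcript length.
- **Reproducibility.** All stochastic operations consume a seed; per-gene
  RNG streams are derived from (seed, CRC32(gene_id)) so results are
  independent of gene order and of which other genes are processed.

## Recoding and CAI

(+)SECReTE substitutes third-codon-position A→T and G→C, (−)SECReTE the
mirror T→A and C→G, in each case only when the substituted codon encodes the
same amino acid (this automatically protects stop codons and leaves Met/Trp
untouched). Blocked substitutions are counted. Consequences asserted as
invariants: the protein is identical, only third positions change, both
directions are idempotent, and the phase-2 motif count moves monotonically
in the stated direction at every threshold. Some runs can survive (−)
recoding where synonymy blocks the edit. For UTRs, where no reading frame
constrains the sequence, recoding substitutes unconditionally.

CAI follows the Sharp & Li convention: geometric mean of relative
adaptiveness w(c) = f(c)/max f among synonyms, excluding ATG, TGG and stops.
The built-in usage table carries standard budding-yeast frequencies per
1,000 codons; any table can be supplied as TSV (codon, frequency).

## Synthetic data generator

The generator defines the study conditions under which the statistics are
validated. Defaults: 400 "secretome" genes each carrying one planted NNY run
of 10–14 triplets and 400 "non-secretome" genes each carrying one 5–9-triplet
decoy, CDS lengths 150–600 codons composed from the yeast usage table (ATG
start, single terminal stop, no internal stops), AT-rich UTRs of 30–150 /
50–300 nt. The 10–14 vs 5–9 contrast brackets the threshold of interest so
that the sweep's argmax is informative; 400 + 400 genes give chi-squared and
AUC estimates with negligible Monte-Carlo noise at these effect sizes.

Two design choices make the truth table exact rather than approximate:

- **Flank enforcement.** The checked base immediately before and after each
  planted run is forced to a purine, so the scanner reports exactly the
  planted coordinates and triplet count.
- **Background capping.** Accidental in-class runs longer than 4 triplets
  (any phase or UTR offset, outside planted structure) are broken by
  resampling one codon/base under the existing per-position constraints.
  Planted runs are thereby the only runs at or above the decoy threshold.

CDS planting at the third position draws window codons from those whose
synonymous third-position edit yields a pyrimidine and applies that edit —
the same substitution logic the recoder uses — so planted windows remain
plausible proteins. TMD planting replaces an interior codon stretch with
hydrophobic codons having pyrimidine second and purine third bases (Leu,
Val, Ile subsets), producing an NYN run without an NNY run, and records the
protein interval. `null_transcriptome` permutes the class labels after
generation, giving the calibration null (AUC ≈ 0.5, uniform chi-squared p).

What the generator deliberately does **not** emulate: codon-usage-driven
pyrimidine runs in the background (capped away), introns/isoforms,
correlated gene families, and realistic length–count correlation structure.
Passing tests therefore demonstrate correctness of the detection and
statistical machinery under controlled truth, not biological effect sizes on
real transcriptomes.

## Numerical choices and problem sizes

- Scanner/oracle agreement is checked exactly (integer coordinates) on
  10,000 random sequences of 30–3,000 nt against an exhaustive
  (start, length) window oracle.
- Permutation calibration uses 500 shuffle-null genes at 200 shuffles per
  gene (the acceptance script uses 300, which keeps its full run under a
  minute while leaving the rate estimate's MC error ≈ 0.012); the observed
  one-sided rate P(Z ≥ 1.96) ≈ 0.04 sits between the normal 2.5% and 5%
  because the longest-run statistic is discrete and right-skewed.
- Recoding invariants run on 1,000 random CDSs of 20–200 codons.
- CAI hand-computations are compared in the log domain to 1e-12; AUC to the
  pairwise oracle at 1e-12.
- Chi-squared on the hand-checkable table [[90,10],[50,50]] equals the
  closed form Σ(O−E)²/E = 38.095…; with the Yates correction it would be
  36.2, which is why the correction is disabled rather than silently mixed.

## Known limitations

- The scanner treats N conservatively; data with many ambiguity codes will
  under-report runs.
- The per-gene permutation statistic ("longest run" vs "motif count") is a
  genuine modelling fork; both are exposed and the default is documented,
  but results are not interchangeable between them.
- UTR scanning at all three offsets triple-counts poly-Y stretches by
  design; users comparing against single-offset conventions should restrict
  to one offset downstream.
- mRNA secondary-structure free energy is not computed; externally computed
  ΔG values can be carried through reports but are never derived here.
- The GFF3 reader handles the common single-isoform CDS/UTR layout; exotic
  multi-parent features are out of scope.
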