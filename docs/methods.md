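# Methods

`bescreen` re-implements, as a tested library, the computational workflow of
a genome-wide CRISPR base-editor (BE3) screen for regulators of protein
abundance in budding yeast: guide library design with predicted mutational
consequences, sort-seq screen quantification from barcoded reads, per-guide
and per-gene effect statistics, fitness-screen analysis, amplicon
editing-outcome quantification, and a sequence-context model of editing
efficiency. A synthetic-data generator makes every stage testable without
external downloads. This note records the models, the parameters that
matter, and the design choices that were genuinely open.

## Guide design

Guides are all 20-nt protospacers 5' of an NGG PAM, on both strands, with
5-nt genomic flanks (30-nt context total). The editing model is
deterministic and all-or-nothing: every C at protospacer positions 4–8
(13–17 bp upstream of the PAM) is converted to T; partial and off-window
editing exist only in the simulators, because the all-or-nothing window
model is the design-time assumption the library was built on.

Consequences are predicted by applying all substitutions of a guide
simultaneously to the genome, re-extracting and re-translating every CDS
that overlaps a substitution, and diffing the proteins. Classification
priority is nonsense > missense > synonymous; substitutions touching no CDS
are noncoding. Internal stop codons are retained during translation — a
truncating edit must stay visible in the protein diff. Genes whose spliced
CDS length is not a multiple of 3 are excluded at annotation load rather
than truncated; silent truncation would corrupt consequence calls
downstream.

Three library filters run in order, and a guide failing several is
attributed to the first: (i) protospacer contains TTTT (RNA Pol III
terminator); (ii) the protospacer's genomic span overlaps two or more
annotated genes; (iii) the PAM-proximal 12-nt seed followed by NGG matches
more than one genomic site. "Target region" for (ii)/(iii) is interpreted
as the protospacer span — it is the bound and edited sequence — and the
seed-homology criterion counts the guide's own site, so uniqueness means a
count of exactly 1. Filter (i) checks the protospacer only (the transcribed
guide), not the flanks.

Missense guides are split by conservation: a guide is "highly conserved" if
the maximal absolute substitution-impact score (e.g. PROVEAN) over its
amino-acid changes is strictly greater than 5. Scores are consumed from a
user-supplied table keyed by (gene, ref-aa, position, alt-aa); the package
never computes them.

Sublibraries: ES takes every nonsense-in-essential guide; NS/EP/NP are
uniform samples without replacement from nonsense-in-nonessential and
conserved-missense pools; controls are synonymous-only guides, guides with
no window C, and random 20-mers resampled until their seed+NGG is absent
from the genome. All sampling is deterministic given a seed, and all
outputs are sorted (chromosome, start, strand) so runs are byte-identical.

## Sort-seq quantification

The 20-nt guide and 20-nt barcode are extracted positionally from a read
pair. A guide must match a library protospacer exactly; mismatching pairs
are discarded and ledgered (kept + discarded = total, checked). When the
layout declares a stagger range, each offset is tried and the first exact
library match wins — the library itself is the anchor. Barcodes are taken
verbatim; their sequencing errors are handled by the collapse step.

Barcode collapse is a greedy directional merge, per guide, pooled across
all samples of a strain: barcodes ranked by descending pooled read count
(ties lexicographic); each barcode merges into the *first* already-accepted
barcode within Hamming distance ≤ 4 ("difference of less than five
nucleotides"), else becomes an acceptor. Hamming rather than edit distance
because barcodes are fixed-length and positionally extracted. Pooling
across samples before ranking reflects that a plasmid barcode is shared by
every sample of a strain; per-sample collapsing would split true barcodes.
An exhaustive reference implementation of the same rule is kept in the test
suite and the two are compared exactly on random barcode sets.

Support filters: drop (sample, guide, barcode) entries with fewer than 2
reads (applied per sample — the stricter reading), then drop guides lacking
≥ 2 barcodes in ≥ 4 control samples. The quantitative measure is the number
of unique barcodes per (guide, sample); size factors are each sample's
unique-barcode total divided by the across-sample mean. Fitness samples use
read counts with control-guide normalization (sample scaled so control
totals are constant), falling back to total-count normalization with a
warning when controls are absent.

## Screen statistics

Per-guide differential abundance between the GFP-high and GFP-low pools is
a two-group Poisson GLM with log link and log-size-factor offset. For this
saturated two-group model the MLE has a closed form,

    beta = ln((sum H / sum s_H) / (sum L / sum s_L)),   se = sqrt(1/sum H + 1/sum L),

which the package computes exactly; the iterative GLM fit (statsmodels)
serves as an independent cross-check in the tests. The p-value is a
two-sided Wald test on the group coefficient — the default behaviour of
standard GLM summaries — and the estimate is reported as log2FC. When one
group's total is zero (complete separation) the estimate is replaced by ±3
on the log2 scale, flagged as degenerate, with a continuity-corrected p
(0.5 added to both totals); the replacement detects separation directly
rather than reproducing any solver's overflow value.

Multiple testing uses Storey q-values: π0 is estimated by smoothing
#{p>λ}/(m(1−λ)) over λ ∈ {0.05, …, 0.95} with a cubic spline evaluated at
λ = 0.95, clipped to (0, 1] with fallback to 1; with π0 = 1 the procedure
reduces exactly to Benjamini–Hochberg (tested). Gene-level aggregation
takes (a) the log2FC and q of the guide with the largest absolute fold
change (ties: smaller q, then guide id), and (b) Fisher's method
(−2·Σ ln p against χ² with 2k df) over the gene's guides, re-controlled
across genes; the final per-gene q is the minimum of the two. By
construction this calls at least as many genes as the best-guide rule
alone.

Fitness log2 fold changes are log2((c_t + 0.5)/(c_ref + 0.5)) on normalized
counts, averaged over replicates, with the gene level again the max-|FC|
guide. The 0.5 pseudocount is a configurable package choice for zero
counts. Depletion significance is a control-based empirical null — one-sided
p = (1 + #{controls ≤ observed})/(n + 1) with Storey q-values — and is a
documented reconstruction: it is the package's own procedure, flagged as
such, for a screen quantity whose exact recipe is a free choice here.
Summary tests are the exact two-sided binomial direction test, Pearson
chi-square without continuity correction, and the pooled-variance Student
t-test.

## Sequence-context model

The 30-nt guide context is featurized as position-specific k-mer
indicators, k ≤ 4: each (position, k) window contributes exactly one active
feature, 114 per guide, out of a catalogue of 30·4 + 29·16 + 28·64 + 27·256
= 9288 features. Indicators rather than counts because each
position-specific window admits exactly one k-mer, making indicators
lossless. Two L1-penalized models are exposed: an ordinary lasso on the
quantitative log2FC and a logistic lasso on the dropout label (log2FC <
−0.5, strict). Regularization strength is chosen by 10-fold
cross-validation with the 1-SE rule (the selection criterion was an open
choice; 1-SE favours sparser, more interpretable models). Evaluation is the
squared Pearson correlation between the linear predictor and the held-out
response — not the coefficient of determination.

## Synthetic data

The generator emulates the study conditions rather than idealized inputs:

- **Toy genomes.** Random intergenic sequence with embedded single-exon
  ORFs on both strands, plus a deliberately overlapping annotation pair and
  a planted seed+PAM duplicate so every design filter fires on the fixture.
- **Editing efficiency.** Logistic in an intercept plus a weight for the
  base preceding the first window C (T, C ≫ A > G), defaults intercept −0.5
  and weights {T: 1, C: 1, A: 0, G: −1.5}, giving efficiencies of roughly
  0.12–0.62 across contexts — the observed per-guide range in this system
  is wide (single-digit to >60%), and the preceding-base ordering is the
  documented context effect. Guides without a window C have efficiency 0.
- **Sorted pools.** Each cell draws a guide (uniform), a plasmid barcode
  from its guide's pool, an edited state ~ Bernoulli(efficiency), and
  log-GFP = baseline + effect·edited + N(0, 1). The top and bottom 5% tails
  are sorted exactly (order statistics); unsorted controls are random draws
  of the same size. Defaults: 4,000,000 cells per population, so a 5% tail
  is the study's 200,000 sorted cells; 8 sorted replicate pairs plus 8
  controls; 500 barcodes per guide; reads per (guide, barcode) ~
  Poisson(20). Editing is a single Bernoulli "fully edited vs not" at the
  design-predicted genotype; partial and off-window patterns appear only in
  the amplicon simulator.
- **Fitness.** A guide's relative abundance after g generations is the
  mosaic mixture (1 − eff) + eff·2^(−cost·g) — only edited cells pay the
  cost — which reduces to pure exponential depletion at efficiency 1.
  Sampling times pre/0 h/8 h/24 h map to 0/0/4/12 generations (2 h doubling);
  reads are multinomial per sample.
- **Amplicon reads.** Complete (all window Cs→T), partial (random nonempty
  proper subset), off-window (one C→T outside the window) and unedited
  classes at configured probabilities.
- **FASTQ.** Reads carry guide/barcode at declared layout positions with
  iid substitution errors; barcode pools are disjoint by construction, so
  collapse on error-free data is the identity (collisions are injected only
  in dedicated collapse tests).

What the simulator does *not* model: fluorescence realism
(autofluorescence, doublets, sorting impurity), PCR jackpots beyond the
reads-per-barcode distribution, cell-to-cell editing mosaicism beyond the
single Bernoulli, or indels. Passing tests therefore demonstrate
correctness of the analysis pipeline under these generative assumptions,
not robustness to every artefact of real sequencing data.

## Numerical choices and problem sizes

- Coordinates are 1-based inclusive internally (GFF3 convention);
  conversion to 0-based happens only at string-indexing boundaries.
- Degenerate IUPAC bases are normalized to N at FASTA load; candidate sites
  containing N anywhere in their 30-nt context are never emitted.
- The q-value spline fallback (π0 = 1) makes the procedure conservative on
  degenerate p-value distributions.
- Fisher combination clamps p = 0 to the smallest positive double, with a
  warning.
- Calibration and recovery runs in the test suite and the reproduction
  script use scaled-down screens chosen to keep each run in minutes on one
  core: null calibration uses 2000 guides, 1,000,000 cells per population
  and 1500 barcodes per guide across 10 seeds; planted-effect recovery uses
  1000 guides (200 planted, balanced in sign, magnitudes 1–2, efficiency
  ≥ 0.5) with 100 barcodes per guide and 200,000 cells; context-model
  recovery trains on 1500 guides and evaluates on 600, with the generative
  R² set near 0.4 via noise sd 0.75. Planted protein effects are balanced
  in sign because sorted tails have fixed size: a one-directional effect
  class shifts the tail composition of every null guide, which is a real
  compositional property of sort-seq, not an analysis artefact.
- The context-recovery simulation fixes the single window C at protospacer
  position 4 so the preceding base (position 3) is a free base shared
  across all guides; this isolates the preceding-base effect as a single
  feature column.

## Known limitations

- Consequence calling handles plain CDS concatenation only: no
  non-canonical splice phase bookkeeping, no alternative codon tables.
- The amplicon module performs ungapped placement and rejects
  length-mismatched reads; indel quantification is out of scope.
- Guide matching is exact-only (no 1-mismatch rescue), matching the
  screen's own counting rule.
- The Poisson model is deliberately not over-dispersion-corrected and fold
  changes are not shrunk; the goal is fidelity to the original analysis,
  not a re-design of it.
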