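# bescreen

Design and analysis toolkit for CRISPR base-editor sort-seq screens in
budding yeast.

Cytosine base editors (BE3: Cas9 fused to a cytidine deaminase) introduce
C→T substitutions in a window 13–17 bp upstream of the PAM without
double-strand breaks. Tiling a genome with such guides and sorting cells by
the abundance of a GFP-tagged protein turns FACS + sequencing into a
genome-scale mutational scan for regulators of protein abundance. This
package implements the full computational path of such a screen, for people
who design the libraries and analyze the reads:

- **Guide design** — enumerate all NGG protospacers, predict the C→T
  outcome in the editing window (protospacer positions 4–8), classify the
  protein-level consequence (nonsense / missense / synonymous / noncoding)
  by re-translating every affected CDS, filter on poly-T, gene overlap and
  seed uniqueness, and assemble sublibraries (stop-in-essential,
  stop-in-nonessential, conserved-missense sets, and three control sets).
- **Screen quantification** — extract guide + barcode from paired reads
  (exact protospacer match only), collapse barcode sequencing errors with a
  greedy directional Hamming-distance merge (< 5 nt difference), apply
  read/barcode support filters, and count unique barcodes per guide.
- **Screen statistics** — per-guide high-vs-low effects from a two-group
  Poisson GLM with log link and size-factor offset

      log2FC = log2( (ΣH/Σs_H) / (ΣL/Σs_L) ),  Wald p on the group coefficient,

  with ±3 replacement under complete separation; Storey q-values; gene-level
  aggregation via the max-|FC| guide and Fisher's method (−2Σln p ~ χ²_2k),
  taking the lower of the two q-values; fitness log2FC time courses and a
  control-based empirical depletion FDR.
- **Amplicon editing outcomes** — per-position nucleotide frequencies in a
  20-nt quantification window, an allele table classified by editing
  pattern (complete / partial / off-window), and the substitution spectrum.
- **Sequence-context model** — position-specific k-mer features (k ≤ 4,
  9288-feature catalogue over the 30-nt context) with ordinary and logistic
  lasso models of editing-driven dropout, evaluated by squared Pearson
  correlation.
- **Synthetic data** — toy genomes with embedded ORFs, context-driven
  editing efficiencies (the preceding-base effect: T, C ≫ A > G), sorted
  GFP pools, fitness time courses, amplicon read sets and paired FASTQ,
  all bit-reproducible given a seed.

See `docs/methods.md` for the models, assumptions and parameter choices.

## Worked example

Design a library on a simulated genome, then run and analyze a simulated
sort-seq screen end to end:

```python
import numpy as np
from collections import Counter
from bescreen import design, simulate, workflows
from bescreen.reference import standard_codon_table

cfg = simulate.SimConfig()
genome, annotations, essential = simulate.build_toy_genome(cfg, seed=11)
candidates = design.enumerate_guides(genome)
kept, report = design.apply_filters(candidates, genome, annotations)
print(f"candidates: {len(candidates)}, kept: {len(kept)}, removed: {report}")

table = standard_codon_table()
cons = Counter()
for cand in kept:
    edits = design.predict_edits(cand, genome)
    cons[design.annotate_consequence(cand, edits, genome, annotations, table, {}).cls] += 1
print("consequences:", dict(cons))

eff = workflows.planted_recovery_screen(n_guides=400, n_planted=60, seed=3)
planted = eff[eff.true_effect != 0]
hits = planted[(planted.q < 0.05) & (np.sign(planted.log2fc) == np.sign(planted.true_effect))]
print(f"planted guides recovered at q<0.05 with correct sign: {len(hits)}/{len(planted)}")
```

Output:

```
candidates: 996, kept: 944, removed: {'polyT': 42, 'overlapping_genes': 8, 'multi_site_seed': 2}
consequences: {'no_edit': 238, 'noncoding': 167, 'missense': 386, 'synonymous': 113, 'nonsense': 40}
planted guides recovered at q<0.05 with correct sign: 60/60
```

The 996 candidates are every NGG site with full context on both strands of
the toy genome; the three removal counts are the poly-T, gene-overlap and
seed-homology filters. The consequence classes drive sublibrary assembly.
In the simulated screen, all 60 guides with a planted protein effect
(|log2 effect| ≥ 1 on guides with editing efficiency ≥ 0.5) are recovered
at q < 0.05 with the correct sign by the Poisson-GLM + q-value pipeline.

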