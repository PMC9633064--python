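"""Synthetic screen data generator.

Builds toy genomes with embedded ORFs, assigns ground-truth editing
efficiencies from local sequence context (the preceding-base effect), and
simulates the three read-level experiments the analysis modules consume:
sorted GFP-high/low/control pools, fitness time courses with exponential
depletion of deleterious guides, and amplicon read sets with
complete/partial/off-window editing patterns.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import GeneAnnotation, Genome, reverse_complement

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class EffParams:
    """Sequence-context model of editing efficiency.

    Logistic in an intercept plus a weight for the base preceding the first
    editing-window C; T and C contexts edit well, A intermediate, G poorly.
    An optional weight on the window C count is available.
    """

    intercept: float = -0.5
    preceding_base_weights: dict[str, float] = field(
        default_factory=lambda: {"T": 1.0, "C": 1.0, "A": 0.0, "G": -1.5}
    )
    c_count_weight: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for the simulated screens.

    Defaults mirror the screen design: the 5% GFP tails are sorted, eight
    sorted replicate cultures plus unsorted controls, guides carry a pool of
    plasmid barcodes, and fitness cultures are sampled at 0/8/24 h.
    """

    n_genes: int = 12
    gene_length: tuple[int, int] = (300, 600)
    n_chromosomes: int = 2
    intergenic_length: int = 120
    essential_fraction: float = 0.4

    baseline_log_gfp: float = 10.0
    gfp_noise_sd: float = 1.0
    sort_fraction: float = 0.05
    n_cells: int = 4_000_000
    n_replicates: int = 8
    n_control_replicates: int = 8

    barcodes_per_guide: int = 500
    barcode_len: int = 20
    mean_reads_per_barcode: float = 20.0
    seq_error_rate: float = 0.0

    fitness_replicates: int = 2
    fitness_generations: dict[str, float] = field(
        default_factory=lambda: {"pre": 0.0, "t0": 0.0, "t8": 4.0, "t24": 12.0}
    )
    fitness_reads_per_sample: int = 500_000

    eff: EffParams = field(default_factory=EffParams)

    def __post_init__(self) -> None:
        if not (0 < self.sort_fraction < 0.5):
            raise ValueError("sort_fraction must be in (0, 0.5)")
        if not (0 <= self.seq_error_rate <= 1):
            raise ValueError("seq_error_rate must be in [0,1]")


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    efficiency: pd.Series  # guide -> editing probability
    protein_effect: pd.Series  # guide -> true log2 GFP effect when edited
    fitness_cost: pd.Series  # guide -> cost per generation when edited
    barcode_pools: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class ReadLayout:
    """Where the guide and barcode sit in a read pair."""

    guide_mate: int = 1
    barcode_mate: int = 2
    guide_offset: int = 0
    guide_len: int = 20
    barcode_offset: int = 0
    barcode_len: int = 20
    stagger_range: tuple[int, int] | None = None  # inclusive, on the guide mate
    read_len: int = 50


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """ATG + random non-stop codons + stop; length must be a multiple of 3."""
    assert length % 3 == 0 and length >= 9
    codons = ["ATG"]
    n_internal = length // 3 - 2
    while len(codons) < n_internal + 1:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(codons)


def build_toy_genome(
    config: SimConfig, seed: int
) -> tuple[Genome, list[GeneAnnotation], set[str]]:
    """A multi-gene toy genome with planted design-filter structure.

    ORFs (single-exon, both strands) are separated by random intergenic
    sequence; one chromosome additionally carries a deliberately overlapping
    annotation pair and a planted duplicate of one guide's seed+PAM so the
    overlap and homology filters are exercised.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.gene_length
    genes_per_chrom = [
        len(chunk)
        for chunk in np.array_split(np.arange(config.n_genes), config.n_chromosomes)
    ]
    if min(genes_per_chrom) < 1:
        raise ValueError("fewer genes than chromosomes")

    records: dict[str, str] = {}
    annotations: list[GeneAnnotation] = []
    gidx = 0
    for ci, n_on_chrom in enumerate(genes_per_chrom):
        chrom = f"chr{ci + 1}"
        parts = []
        pos = 0
        for _ in range(n_on_chrom):
            gap = "".join(rng.choice(_BASES, size=config.intergenic_length))
            parts.append(gap)
            pos += len(gap)
            length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
            orf = _random_orf(rng, length)
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(orf if strand == "+" else reverse_complement(orf))
            annotations.append(
                GeneAnnotation(
                    gene_id=f"gene{gidx:03d}",
                    chrom=chrom,
                    strand=strand,
                    cds_intervals=[(pos + 1, pos + length)],
                )
            )
            pos += length
            gidx += 1
        parts.append("".join(rng.choice(_BASES, size=config.intergenic_length)))
        records[chrom] = "".join(parts)

    # planted overlapping annotation pair on chr1 (valid %3 lengths, shared span)
    chrom = "chr1"
    tail = len(records[chrom])
    pad = "".join(rng.choice(_BASES, size=200))
    records[chrom] += pad
    s = tail + 20
    annotations.append(
        GeneAnnotation("ovlA", chrom, "+", cds_intervals=[(s, s + 98)])
    )
    annotations.append(
        GeneAnnotation("ovlB", chrom, "+", cds_intervals=[(s + 51, s + 149)])
    )

    # planted seed duplicate: copy a seed+NGG 15-mer into distant sequence
    seq = records[chrom]
    planted = False
    for i in range(30, len(seq) - 3):
        if seq[i + 1 : i + 3] == "GG" and i >= 12:
            site = seq[i - 12 : i + 3]  # 12-nt seed + NGG
            if "N" in site:
                continue
            records[chrom] = seq + "".join(rng.choice(_BASES, size=30)) + site + "".join(
                rng.choice(_BASES, size=30)
            )
            planted = True
            break
    if not planted:
        raise ValueError("infeasible config: no PAM site to duplicate")

    n_ess = int(round(config.essential_fraction * config.n_genes))
    order = rng.permutation(config.n_genes)
    essential = {f"gene{g:03d}" for g in order[:n_ess]}
    for ann in annotations:
        ann.essential = ann.gene_id in essential
    return Genome(records), annotations, essential


def true_efficiency(context30: str, params: EffParams, window: tuple[int, int] = (4, 8)) -> float:
    """Editing probability of a guide from its 30-nt context.

    Logistic in the intercept plus the weight of the base preceding the first
    editing-window C (plus an optional window-C-count term). Guides without a
    window C cannot be edited and get probability 0.
    """
    proto = context30[5:25]
    lo, hi = window
    cs = [p for p in range(lo, hi + 1) if proto[p - 1] == "C"]
    if not cs:
        return 0.0
    first = cs[0]
    preceding = context30[5 + first - 2]  # base 5' of the first window C
    z = (
        params.intercept
        + params.preceding_base_weights.get(preceding, 0.0)
        + params.c_count_weight * len(cs)
    )
    return 1.0 / (1.0 + math.exp(-z))


def make_truth(
    library: pd.DataFrame,
    config: SimConfig,
    seed: int,
    protein_effects: dict[str, float] | None = None,
    fitness_costs: dict[str, float] | None = None,
) -> SimTruth:
    """Ground truth for a library: efficiencies from context, effects supplied.

    ``protein_effects``/``fitness_costs`` map guide ids to true values; guides
    not listed get 0. Barcode pools are disjoint random 20-mers per guide.
    """
    rng = np.random.default_rng(seed)
    guides = library["guide_id"].tolist()
    eff = pd.Series(
        [true_efficiency(c, config.eff) for c in library["context30"]],
        index=guides,
        name="efficiency",
    )
    pe = pd.Series(0.0, index=guides, name="protein_effect")
    if protein_effects:
        pe.update(pd.Series(protein_effects))
    fc = pd.Series(0.0, index=guides, name="fitness_cost")
    if fitness_costs:
        fc.update(pd.Series(fitness_costs))

    nb, bl = config.barcodes_per_guide, config.barcode_len
    needed = len(guides) * nb
    if bl > 31:
        raise ValueError("barcode_len > 31 unsupported by the pool generator")
    # draw 2-bit-packed barcodes, deduplicate as integers, decode vectorized
    codes = np.empty(0, dtype=np.uint64)
    while codes.size < needed:
        batch = rng.integers(0, 1 << (2 * bl), size=needed - codes.size, dtype=np.uint64)
        merged = np.sort(np.concatenate([codes, batch]))
        codes = merged[np.concatenate([[True], np.diff(merged) != 0])]
    rng.shuffle(codes)
    codes = codes[:needed]
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    chars = np.empty((codes.size, bl), dtype=np.uint8)
    for j in range(bl):
        shift = np.uint64(2 * (bl - 1 - j))
        chars[:, j] = lut[(codes >> shift) & np.uint64(3)]
    text = chars.tobytes().decode()
    flat = [text[i * bl : (i + 1) * bl] for i in range(needed)]
    pools = {g: flat[i * nb : (i + 1) * nb] for i, g in enumerate(guides)}
    return SimTruth(efficiency=eff, protein_effect=pe, fitness_cost=fc, barcode_pools=pools)


def _sample_counts(
    rng: np.random.Generator,
    guide_idx: np.ndarray,
    n_guides: int,
    nb: int,
    mean_reads: float,
) -> dict[int, dict[int, int]]:
    """Assign each selected cell a barcode; Poisson reads per (guide,barcode)."""
    bc_idx = rng.integers(0, nb, size=guide_idx.size)
    codes = guide_idx.astype(np.int64) * nb + bc_idx
    uniq = np.unique(codes)
    reads = rng.poisson(mean_reads, size=uniq.size)
    out: dict[int, dict[int, int]] = {}
    keep = reads > 0
    for code, r in zip(uniq[keep], reads[keep]):
        g, b = divmod(int(code), nb)
        out.setdefault(g, {})[b] = int(r)
    return out


def simulate_protein_screen(
    library: pd.DataFrame, truth: SimTruth, config: SimConfig, seed: int
) -> dict[str, dict[str, dict[str, int]]]:
    """Sorted-pool screen: sample -> guide -> barcode -> read count.

    Per replicate a fresh cell population is drawn: each cell carries a
    uniformly chosen guide and one of its plasmid barcodes, is edited with the
    guide's efficiency, and its log-GFP is baseline + effect(if edited) +
    Gaussian noise. The top and bottom ``sort_fraction`` tails become the
    high/low samples; control replicates are unsorted draws of the same size.
    """
    rng = np.random.default_rng(seed)
    guides = library["guide_id"].tolist()
    n_guides = len(guides)
    nb = config.barcodes_per_guide
    eff = truth.efficiency.loc[guides].to_numpy()
    effect = truth.protein_effect.loc[guides].to_numpy()
    k = int(config.sort_fraction * config.n_cells)

    samples: dict[str, dict[str, dict[str, int]]] = {}

    def finalize(name: str, cell_guides: np.ndarray) -> None:
        counts = _sample_counts(rng, cell_guides, n_guides, nb, config.mean_reads_per_barcode)
        samples[name] = {
            guides[g]: {truth.barcode_pools[guides[g]][b]: r for b, r in bcs.items()}
            for g, bcs in counts.items()
        }

    for rep in range(1, config.n_replicates + 1):
        gidx = rng.integers(0, n_guides, size=config.n_cells)
        edited = rng.random(config.n_cells) < eff[gidx]
        gfp = (
            config.baseline_log_gfp
            + effect[gidx] * edited
            + rng.normal(0.0, config.gfp_noise_sd, size=config.n_cells)
        )
        order = np.argsort(gfp, kind="stable")
        finalize(f"low_r{rep}", gidx[order[:k]])
        finalize(f"high_r{rep}", gidx[order[-k:]])

    for rep in range(1, config.n_control_replicates + 1):
        gidx = rng.integers(0, n_guides, size=config.n_cells)
        pick = rng.choice(config.n_cells, size=k, replace=False)
        finalize(f"ctrl_r{rep}", gidx[pick])

    return samples


def simulate_fitness_screen(
    library: pd.DataFrame, truth: SimTruth, config: SimConfig, seed: int
) -> pd.DataFrame:
    """Fitness time course: guide x sample read-count matrix.

    A guide's relative abundance after g generations is the mosaic mixture
    (1 - eff) + eff * 2^(-cost * g): only edited cells pay the fitness cost.
    Reads per sample are multinomial at the configured depth. Columns are
    named ``{timepoint}_r{replicate}``.
    """
    rng = np.random.default_rng(seed)
    guides = library["guide_id"].tolist()
    eff = truth.efficiency.loc[guides].to_numpy()
    cost = truth.fitness_cost.loc[guides].to_numpy()
    cols = {}
    for rep in range(1, config.fitness_replicates + 1):
        for tp, gen in config.fitness_generations.items():
            w = (1.0 - eff) + eff * np.power(2.0, -cost * gen)
            p = w / w.sum()
            cols[f"{tp}_r{rep}"] = rng.multinomial(config.fitness_reads_per_sample, p)
    return pd.DataFrame(cols, index=pd.Index(guides, name="guide_id"))


def _mutate_reads(reads: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    if error_rate <= 0:
        return reads
    out = []
    for r in reads:
        arr = np.frombuffer(r.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
        for i in hits:
            choices = [b for b in b"ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
        out.append(arr.tobytes().decode())
    return out


def emit_fastq(
    sample_counts: dict[str, dict[str, int]],
    layout: ReadLayout,
    error_rate: float,
    seed: int,
    r1_path,
    r2_path,
    sample_name: str = "sample",
) -> int:
    """Write a sample's (guide, barcode) read counts as a paired gzipped FASTQ.

    Mate 1 carries the protospacer (after an optional stagger), mate 2 the
    barcode; remaining positions are random filler. Substitution errors are
    iid at ``error_rate``; qualities are constant. Returns read pairs written.
    """
    rng = np.random.default_rng(seed)
    n_written = 0
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for guide_seq, bcs in sorted(sample_counts.items()):
            for bc, n_reads in sorted(bcs.items()):
                for _ in range(n_reads):
                    if layout.stagger_range is not None:
                        slo, shi = layout.stagger_range
                        stag = int(rng.integers(slo, shi + 1))
                    else:
                        stag = 0
                    r1 = list(rng.choice(_BASES, size=layout.read_len))
                    off = layout.guide_offset + stag
                    r1[off : off + layout.guide_len] = list(guide_seq)
                    r2 = list(rng.choice(_BASES, size=layout.read_len))
                    r2[layout.barcode_offset : layout.barcode_offset + layout.barcode_len] = list(bc)
                    s1, s2 = _mutate_reads(["".join(r1), "".join(r2)], error_rate, rng)
                    name = f"@{sample_name}:{n_written}"
                    qual = "I" * layout.read_len
                    f1.write(f"{name}/1\n{s1}\n+\n{qual}\n")
                    f2.write(f"{name}/2\n{s2}\n+\n{qual}\n")
                    n_written += 1
    return n_written


def simulate_amplicon(
    reference: str,
    protospacer_start: int,
    profile: dict[str, float],
    n_reads: int,
    seed: int,
    window: tuple[int, int] = (4, 8),
) -> list[str]:
    """Amplicon reads with complete/partial/off-window editing patterns.

    ``protospacer_start`` is the 0-based offset of the protospacer in the
    (plus-strand) reference. ``profile`` gives p_complete / p_partial /
    p_offwindow; the remaining mass is unedited. Partial reads edit a random
    nonempty proper subset of window Cs; off-window reads edit one C outside
    the window.
    """
    rng = np.random.default_rng(seed)
    p_c = profile.get("p_complete", 0.0)
    p_p = profile.get("p_partial", 0.0)
    p_o = profile.get("p_offwindow", 0.0)
    if p_c + p_p + p_o > 1 + 1e-12:
        raise ValueError("editing profile probabilities sum to more than 1")

    lo, hi = window
    win_c = [
        protospacer_start + p - 1
        for p in range(lo, hi + 1)
        if reference[protospacer_start + p - 1] == "C"
    ]
    off_c = [i for i, b in enumerate(reference) if b == "C" and i not in set(win_c)]
    if p_p > 0 and len(win_c) < 2:
        raise ValueError("partial editing needs at least two window Cs")
    if p_o > 0 and not off_c:
        raise ValueError("off-window editing needs a C outside the window")

    reads = []
    choices = rng.choice(
        4, size=n_reads, p=[p_c, p_p, p_o, 1.0 - p_c - p_p - p_o]
    )
    for c in choices:
        seq = list(reference)
        if c == 0:
            for i in win_c:
                seq[i] = "T"
        elif c == 1:
            n_edit = int(rng.integers(1, len(win_c)))
            for i in rng.choice(win_c, size=n_edit, replace=False):
                seq[i] = "T"
        elif c == 2:
            seq[int(rng.choice(off_c))] = "T"
        reads.append("".join(seq))
    return reads


def simulate_context_dataset(
    n: int,
    eff_params: EffParams,
    effect_scale: float,
    noise_sd: float,
    seed: int,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Guide contexts with a preceding-base-driven quantitative response.

    Contexts are random 30-mers constrained to carry exactly one editing-window
    C, at protospacer position 4, so the base at context position 8 (1-based;
    protospacer position 3, outside the window) is the preceding base for
    every guide — isolating the preceding-base effect for model-recovery
    tests. Returns (contexts, y, signal) where y = signal + Gaussian noise
    and signal = -effect_scale * efficiency.
    """
    rng = np.random.default_rng(seed)
    contexts = []
    non_c = np.array(list("AGT"))
    for _ in range(n):
        ctx = list(rng.choice(_BASES, size=30))
        # protospacer positions 4-8 = context indices 8-12 (0-based)
        for i in range(9, 13):
            ctx[i] = str(rng.choice(non_c))
        ctx[8] = "C"  # protospacer position 4
        contexts.append("".join(ctx))
    signal = np.array(
        [-effect_scale * true_efficiency(c, eff_params) for c in contexts]
    )
    y = signal + rng.normal(0.0, noise_sd, size=n)
    return contexts, y, signal
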