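"""BE3 guide library design.

Enumerates every NGG-PAM protospacer on both strands of a genome, predicts
the C-to-T editing outcome assuming complete conversion in the editing window
(protospacer positions 4-8, i.e. 13-17 bp upstream of the PAM), classifies
the protein-level consequence of the predicted edits, applies the library
filters (poly-T terminator, overlapping genes, non-unique seed), classifies
missense guides by conservation, and assembles the screen sublibraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import (
    GeneAnnotation,
    Genome,
    coding_sequence,
    genes_overlapping,
    reverse_complement,
    standard_codon_table,
    translate_cds,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignParams:
    """Library-design parameters.

    The editing window is given in protospacer coordinates (1 = PAM-distal
    end); positions 4-8 correspond to 13-17 bp upstream of the PAM. The seed
    is the PAM-proximal 12 nt governing target recognition.
    """

    protospacer_len: int = 20
    pam_pattern: str = "NGG"
    window: tuple[int, int] = (4, 8)
    seed_len: int = 12
    polyt_motif: str = "TTTT"
    conservation_threshold: float = 5.0
    flank: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.protospacer_len):
            raise ValueError("editing window outside protospacer")
        if self.seed_len > self.protospacer_len:
            raise ValueError("seed longer than protospacer")


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer+PAM site in guide-strand orientation (5'->3')."""

    guide_id: str
    chrom: str
    strand: str
    protospacer: str
    pam: str
    genomic_span: tuple[int, int]  # protospacer on + strand, 1-based inclusive
    context30: str  # protospacer with 5-nt flanks, guide orientation

    @property
    def seed(self) -> str:
        return self.protospacer[-12:]


@dataclass
class EditSet:
    """Predicted C->T edits of one guide (complete window conversion)."""

    window_positions_edited: list[int]  # protospacer positions with a C
    genomic_substitutions: list[tuple[str, int, str, str]]  # + strand

    @property
    def empty(self) -> bool:
        return not self.genomic_substitutions


@dataclass
class Consequence:
    cls: str  # nonsense | missense | synonymous | noncoding | no_edit
    affected_genes: list[str] = field(default_factory=list)
    aa_changes: list[tuple[str, str, int, str]] = field(default_factory=list)
    representative_score: float | None = None


def enumerate_guides(genome: Genome, params: DesignParams | None = None) -> list[GuideCandidate]:
    """All protospacer-NGG sites on both strands with full 5-nt flanks.

    Sites whose 30-nt context would run off the chromosome, or that contain an
    ambiguous base, are dropped (counted in the log). Output order is
    deterministic: (chrom, start, strand).
    """
    params = params or DesignParams()
    plen, fl = params.protospacer_len, params.flank
    dropped = 0
    out: list[GuideCandidate] = []
    for chrom in sorted(genome.records):
        seq = genome.records[chrom]
        n = len(seq)
        rc = reverse_complement(seq)
        for strand, s in (("+", seq), ("-", rc)):
            for i in range(n - plen - 2):
                # PAM = s[i+plen : i+plen+3], require NGG
                if s[i + plen + 1] != "G" or s[i + plen + 2] != "G":
                    continue
                if i < fl or i + plen + fl > n:
                    dropped += 1
                    continue
                context = s[i - fl : i + plen + fl]
                if "N" in context:
                    dropped += 1
                    continue
                proto = s[i : i + plen]
                pam = s[i + plen : i + plen + 3]
                if strand == "+":
                    start, end = i + 1, i + plen
                else:
                    start, end = n - (i + plen) + 1, n - i
                out.append(
                    GuideCandidate(
                        guide_id=f"{chrom}:{start}-{end}:{strand}",
                        chrom=chrom,
                        strand=strand,
                        protospacer=proto,
                        pam=pam,
                        genomic_span=(start, end),
                        context30=context,
                    )
                )
    if dropped:
        logger.info("enumerate_guides: dropped %d short-context/ambiguous sites", dropped)
    out.sort(key=lambda c: (c.chrom, c.genomic_span[0], c.strand))
    return out


def predict_edits(
    candidate: GuideCandidate, genome: Genome, params: DesignParams | None = None
) -> EditSet:
    """Complete C->T conversion at every window C (all-or-nothing model).

    Substitutions are reported on the + genomic strand: C->T for + guides,
    G->A for - guides.
    """
    params = params or DesignParams()
    lo, hi = params.window
    start, end = candidate.genomic_span
    positions = [p for p in range(lo, hi + 1) if candidate.protospacer[p - 1] == "C"]
    subs = []
    for p in positions:
        if candidate.strand == "+":
            gpos, ref, alt = start + p - 1, "C", "T"
        else:
            gpos, ref, alt = end - p + 1, "G", "A"
        actual = genome.fetch(candidate.chrom, gpos, gpos)
        if actual != ref:
            raise ValueError(
                f"stale candidate {candidate.guide_id}: genome has {actual} at "
                f"{candidate.chrom}:{gpos}, expected {ref}"
            )
        subs.append((candidate.chrom, gpos, ref, alt))
    return EditSet(window_positions_edited=positions, genomic_substitutions=subs)


ScoreTable = dict[tuple[str, str, int, str], float]


def annotate_consequence(
    candidate: GuideCandidate,
    edits: EditSet,
    genome: Genome,
    annotations: list[GeneAnnotation],
    table: dict[str, str] | None = None,
    scores: ScoreTable | None = None,
) -> Consequence:
    """Protein-level consequence of applying all predicted edits at once.

    All substitutions are introduced simultaneously; every CDS overlapping a
    substitution is re-extracted and re-translated and the proteins diffed.
    Priority: nonsense > missense > synonymous; substitutions touching no CDS
    are noncoding.
    """
    if edits.empty:
        return Consequence(cls="no_edit")
    table = table if table is not None else standard_codon_table()
    scores = scores or {}

    sub_pos = {(c, p): alt for c, p, _ref, alt in edits.genomic_substitutions}
    # genes whose CDS intervals (not just span) contain a substitution
    hit_genes = []
    for ann in annotations:
        for s, e in ann.cds_intervals:
            if any(c == ann.chrom and s <= p <= e for (c, p) in sub_pos):
                hit_genes.append(ann)
                break
    if not hit_genes:
        return Consequence(cls="noncoding")

    chroms = {c for c, _ in sub_pos}
    mutated = Genome(
        {
            cid: (
                "".join(
                    sub_pos.get((cid, i + 1), base) for i, base in enumerate(seq)
                )
                if cid in chroms
                else seq
            )
            for cid, seq in genome.records.items()
        }
    )

    aa_changes: list[tuple[str, str, int, str]] = []
    for ann in hit_genes:
        before = translate_cds(coding_sequence(genome, ann), table)
        after = translate_cds(coding_sequence(mutated, ann), table)
        for i, (a, b) in enumerate(zip(before, after), start=1):
            if a != b:
                aa_changes.append((ann.gene_id, a, i, b))

    if any(b == "*" and a != "*" for _, a, _, b in aa_changes):
        cls = "nonsense"
    elif aa_changes:
        cls = "missense"
    else:
        cls = "synonymous"

    avail = [abs(scores[key]) for key in aa_changes if key in scores]
    rep = max(avail) if avail else None
    return Consequence(
        cls=cls,
        affected_genes=[a.gene_id for a in hit_genes],
        aa_changes=aa_changes,
        representative_score=rep,
    )


def _count_pattern_sites(seq: str, seed: str) -> int:
    """Occurrences of seed immediately followed by NGG, overlapping allowed."""
    count = 0
    k = len(seed)
    i = seq.find(seed)
    while i != -1:
        if i + k + 3 <= len(seq) and seq[i + k + 1] == "G" and seq[i + k + 2] == "G":
            count += 1
        i = seq.find(seed, i + 1)
    return count


def count_seed_sites(
    genome: Genome, candidate: GuideCandidate, params: DesignParams | None = None
) -> int:
    """Genomic sites (both strands) matching the guide's 12-nt seed + NGG."""
    params = params or DesignParams()
    seed = candidate.protospacer[-params.seed_len :]
    total = 0
    for seq in genome.records.values():
        total += _count_pattern_sites(seq, seed)
        total += _count_pattern_sites(reverse_complement(seq), seed)
    return total


def count_spacer_sites(genome: Genome, protospacer: str, seed_len: int = 12) -> int:
    """Seed+NGG site count for an arbitrary 20-mer (library controls)."""
    seed = protospacer[-seed_len:]
    return sum(
        _count_pattern_sites(seq, seed) + _count_pattern_sites(reverse_complement(seq), seed)
        for seq in genome.records.values()
    )


def apply_filters(
    candidates: list[GuideCandidate],
    genome: Genome,
    annotations: list[GeneAnnotation],
    params: DesignParams | None = None,
) -> tuple[list[GuideCandidate], dict[str, int]]:
    """The three library filters, applied in order.

    (i) protospacer contains TTTT (Pol III terminator);
    (ii) protospacer span overlaps two or more annotated genes;
    (iii) seed+NGG matches more than one genomic site.
    A guide failing several filters is attributed to the first.
    """
    params = params or DesignParams()
    kept = []
    report = {"polyT": 0, "overlapping_genes": 0, "multi_site_seed": 0}
    ann_chroms = {a.chrom for a in annotations}
    for cand in candidates:
        if params.polyt_motif in cand.protospacer:
            report["polyT"] += 1
            continue
        if cand.chrom in ann_chroms:
            genes = genes_overlapping(annotations, cand.chrom, cand.genomic_span)
        else:
            genes = []
        if len(genes) >= 2:
            report["overlapping_genes"] += 1
            continue
        if count_seed_sites(genome, cand, params) > 1:
            report["multi_site_seed"] += 1
            continue
        kept.append(cand)
    return kept, report


def conservation_class(consequence: Consequence, params: DesignParams | None = None) -> bool:
    """True iff a missense consequence hits a highly conserved residue.

    "Highly conserved" means the maximal absolute conservation score over the
    guide's amino-acid changes is strictly greater than the threshold.
    """
    params = params or DesignParams()
    if consequence.cls != "missense":
        raise ValueError(f"conservation_class requires a missense consequence, got {consequence.cls}")
    if consequence.representative_score is None:
        return False
    return consequence.representative_score > params.conservation_threshold


DEFAULT_SET_SIZES = {
    "NS": 5500,
    "EP": 5500,
    "NP": 5500,
    "ctrl_synonymous": 500,
    "ctrl_noC": 500,
    "ctrl_nontargeting": 500,
}

_BASES = np.array(list("ACGT"))


def assemble_library(
    records: list[tuple[GuideCandidate, Consequence]],
    annotations: list[GeneAnnotation],
    set_sizes: dict[str, int],
    rng_seed: int,
    genome: Genome | None = None,
    params: DesignParams | None = None,
) -> pd.DataFrame:
    """Assemble the screen sublibraries into a library table.

    ES takes *all* nonsense guides in essential genes; NS/EP/NP are uniform
    random samples without replacement from their eligibility classes; the
    control sets are synonymous-only guides, guides with no window C, and
    random 20-mers whose seed+NGG is verified absent from the genome.
    """
    params = params or DesignParams()
    rng = np.random.default_rng(rng_seed)
    essential = {a.gene_id for a in annotations if a.essential}

    pools: dict[str, list[tuple[GuideCandidate, Consequence]]] = {
        "ES": [], "NS": [], "EP": [], "NP": [],
        "ctrl_synonymous": [], "ctrl_noC": [],
    }
    for cand, cons in records:
        if cons.cls == "no_edit":
            pools["ctrl_noC"].append((cand, cons))
        elif cons.cls == "synonymous":
            pools["ctrl_synonymous"].append((cand, cons))
        elif cons.cls == "nonsense":
            in_ess = any(g in essential for g in cons.affected_genes)
            pools["ES" if in_ess else "NS"].append((cand, cons))
        elif cons.cls == "missense":
            if conservation_class(cons, params):
                in_ess = any(g in essential for g in cons.affected_genes)
                pools["EP" if in_ess else "NP"].append((cand, cons))

    rows = []

    def emit(cand: GuideCandidate, cons: Consequence, label: str) -> None:
        rows.append(
            {
                "guide_id": cand.guide_id,
                "set_label": label,
                "protospacer": cand.protospacer,
                "context30": cand.context30,
                "target_gene": cons.affected_genes[0] if cons.affected_genes else "",
                "consequence": cons.cls,
                "n_aa_changes": len(cons.aa_changes),
                "representative_score": cons.representative_score,
            }
        )

    for cand, cons in pools["ES"]:
        emit(cand, cons, "ES")
    for label in ("NS", "EP", "NP", "ctrl_synonymous", "ctrl_noC"):
        pool = sorted(pools[label], key=lambda r: r[0].guide_id)
        want = set_sizes.get(label, 0)
        if want > len(pool):
            raise ValueError(
                f"set {label}: requested {want} guides but only {len(pool)} eligible"
            )
        idx = rng.choice(len(pool), size=want, replace=False) if pool else []
        for i in sorted(idx):
            emit(*pool[i], label)

    n_nt = set_sizes.get("ctrl_nontargeting", 0)
    if n_nt and genome is None:
        raise ValueError("genome required to verify nontargeting controls")
    made = 0
    while made < n_nt:
        context = "".join(rng.choice(_BASES, size=30))
        proto = context[params.flank : params.flank + params.protospacer_len]
        if "TTTT" in proto:
            continue
        if count_spacer_sites(genome, proto, params.seed_len) > 0:
            continue
        rows.append(
            {
                "guide_id": f"nontarget_{made:04d}",
                "set_label": "ctrl_nontargeting",
                "protospacer": proto,
                "context30": context,
                "target_gene": "",
                "consequence": "none",
                "n_aa_changes": 0,
                "representative_score": None,
            }
        )
        made += 1

    df = pd.DataFrame(rows)
    if not df.empty and df["guide_id"].duplicated().any():
        # a guide can be eligible for at most one set by construction, but a
        # duplicated genomic site would be a design bug
        dups = df.loc[df["guide_id"].duplicated(), "guide_id"].tolist()
        raise ValueError(f"duplicate guide ids in library: {dups[:5]}")
    return df


def read_score_table(path) -> ScoreTable:
    """Conservation scores TSV: gene, ref_aa, pos, alt_aa, score."""
    df = pd.read_csv(path, sep="\t")
    return {
        (r.gene, r.ref_aa, int(r.pos), r.alt_aa): float(r.score)
        for r in df.itertuples()
    }
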