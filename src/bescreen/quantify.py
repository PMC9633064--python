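"""Screen read quantification.

Turns paired reads into a guide x sample count matrix: extract the 20-nt
guide and 20-nt barcode from a read pair, keep only guides perfectly matching
the library, collapse barcode sequencing errors with a greedy directional
merge (Hamming distance <= 4), apply the read/barcode support filters, and
count unique barcodes per guide (or raw reads, for fitness samples).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .simulate import ReadLayout

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantParams:
    barcode_merge_max_dist: int = 4  # merge when difference < 5 nt
    min_reads_per_barcode: int = 2
    min_barcodes_per_guide: int = 2
    min_control_samples: int = 4


@dataclass
class GuideBarcodeCounts:
    """sample -> guide -> barcode -> read count, plus a discard ledger."""

    counts: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    discards: dict[str, dict[str, int]] = field(default_factory=dict)

    def total_kept(self, sample: str) -> int:
        return sum(
            r for bcs in self.counts.get(sample, {}).values() for r in bcs.values()
        )


@dataclass
class CountMatrix:
    """Guide x sample counts with per-sample size factors."""

    counts: pd.DataFrame
    size_factors: pd.Series
    unit: str  # unique_barcodes | reads


def _open_maybe_gzip(path):
    p = str(path)
    return gzip.open(p, "rt") if p.endswith(".gz") else open(p)


def parse_reads(
    fastq_r1,
    fastq_r2,
    layout: ReadLayout,
    library: pd.DataFrame,
    sample: str = "sample",
    counts: GuideBarcodeCounts | None = None,
) -> GuideBarcodeCounts:
    """Extract (guide, barcode) pairs from a paired FASTQ sample.

    The guide must match a library protospacer exactly; otherwise the read
    pair is discarded and ledgered. When the layout declares a stagger range,
    each offset in the range is tried and the first exact library match wins.
    The barcode is taken verbatim — sequencing errors there are handled by
    :func:`collapse_barcodes`.
    """
    gbc = counts if counts is not None else GuideBarcodeCounts()
    lib = set(library["protospacer"])
    proto_by_seq = dict(zip(library["protospacer"], library["guide_id"]))
    sample_counts = gbc.counts.setdefault(sample, {})
    ledger = gbc.discards.setdefault(sample, {"guide_mismatch": 0, "layout_fail": 0, "kept": 0})

    if layout.stagger_range is not None:
        offsets = [
            layout.guide_offset + s
            for s in range(layout.stagger_range[0], layout.stagger_range[1] + 1)
        ]
    else:
        offsets = [layout.guide_offset]

    with _open_maybe_gzip(fastq_r1) as f1, _open_maybe_gzip(fastq_r2) as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for rec1, rec2 in zip(it1, it2):
            guide_read = str(rec1.seq) if layout.guide_mate == 1 else str(rec2.seq)
            bc_read = str(rec2.seq) if layout.barcode_mate == 2 else str(rec1.seq)
            if (
                layout.barcode_offset + layout.barcode_len > len(bc_read)
                or max(offsets) + layout.guide_len > len(guide_read)
            ):
                ledger["layout_fail"] += 1
                continue
            guide_seq = None
            for off in offsets:
                cand = guide_read[off : off + layout.guide_len]
                if cand in lib:
                    guide_seq = cand
                    break
            if guide_seq is None:
                ledger["guide_mismatch"] += 1
                continue
            barcode = bc_read[layout.barcode_offset : layout.barcode_offset + layout.barcode_len]
            gid = proto_by_seq[guide_seq]
            bcs = sample_counts.setdefault(gid, {})
            bcs[barcode] = bcs.get(barcode, 0) + 1
            ledger["kept"] += 1
    return gbc


def _encode_barcodes(barcodes: list[str]) -> np.ndarray:
    return np.frombuffer("".join(barcodes).encode(), dtype=np.uint8).reshape(
        len(barcodes), -1
    )


def collapse_barcodes(
    per_sample: dict[str, dict[str, int]], params: QuantParams | None = None
) -> dict[str, dict[str, int]]:
    """Greedy directional barcode merge for one guide, pooled across samples.

    Barcodes are ranked by descending pooled read count (ties lexicographic);
    each barcode merges into the first already-accepted barcode within
    Hamming distance <= 4, else is accepted itself. Per-sample counts of
    merged barcodes are added to the acceptor; total reads are conserved.
    """
    params = params or QuantParams()
    pooled: dict[str, int] = {}
    for bcs in per_sample.values():
        for bc, r in bcs.items():
            pooled[bc] = pooled.get(bc, 0) + r
    if not pooled:
        return {s: {} for s in per_sample}
    lengths = {len(bc) for bc in pooled}
    if len(lengths) != 1:
        raise ValueError(f"barcode length mismatch: {sorted(lengths)}")

    ranked = sorted(pooled, key=lambda bc: (-pooled[bc], bc))
    enc = _encode_barcodes(ranked)
    acceptor_rows: list[int] = []
    assign: dict[str, str] = {}
    for i, bc in enumerate(ranked):
        if acceptor_rows:
            dists = (enc[acceptor_rows] != enc[i]).sum(axis=1)
            hits = np.nonzero(dists <= params.barcode_merge_max_dist)[0]
            if hits.size:  # first acceptor in rank order wins
                assign[bc] = ranked[acceptor_rows[int(hits[0])]]
                continue
        acceptor_rows.append(i)
        assign[bc] = bc

    out: dict[str, dict[str, int]] = {}
    for sample, bcs in per_sample.items():
        merged: dict[str, int] = {}
        for bc, r in bcs.items():
            tgt = assign[bc]
            merged[tgt] = merged.get(tgt, 0) + r
        out[sample] = merged
    return out


def collapse_all(
    gbc: GuideBarcodeCounts, params: QuantParams | None = None
) -> GuideBarcodeCounts:
    """Apply :func:`collapse_barcodes` to every guide across all samples."""
    params = params or QuantParams()
    guides = sorted({g for s in gbc.counts.values() for g in s})
    out = GuideBarcodeCounts(discards=gbc.discards)
    for s in gbc.counts:
        out.counts[s] = {}
    for g in guides:
        per_sample = {s: gbc.counts[s].get(g, {}) for s in gbc.counts}
        collapsed = collapse_barcodes(per_sample, params)
        for s, bcs in collapsed.items():
            if bcs:
                out.counts[s][g] = bcs
    return out


def apply_count_filters(
    collapsed: GuideBarcodeCounts,
    control_samples: list[str],
    params: QuantParams | None = None,
) -> tuple[GuideBarcodeCounts, dict[str, int]]:
    """Support filters: drop barcodes with < 2 reads in a sample, then drop
    guides lacking >= 2 barcodes in >= 4 of the control samples."""
    params = params or QuantParams()
    if len(control_samples) < params.min_control_samples:
        raise ValueError(
            f"need at least {params.min_control_samples} control samples, "
            f"got {len(control_samples)}"
        )
    report = {"low_read_barcodes": 0, "dropped_guides": 0}
    stage1 = GuideBarcodeCounts(discards=collapsed.discards)
    for s, guides in collapsed.counts.items():
        stage1.counts[s] = {}
        for g, bcs in guides.items():
            kept = {bc: r for bc, r in bcs.items() if r >= params.min_reads_per_barcode}
            report["low_read_barcodes"] += len(bcs) - len(kept)
            if kept:
                stage1.counts[s][g] = kept

    all_guides = sorted({g for s in stage1.counts.values() for g in s})
    keep_guides = set()
    for g in all_guides:
        ok = sum(
            1
            for cs in control_samples
            if len(stage1.counts.get(cs, {}).get(g, {})) >= params.min_barcodes_per_guide
        )
        if ok >= params.min_control_samples:
            keep_guides.add(g)
    report["dropped_guides"] = len(all_guides) - len(keep_guides)

    out = GuideBarcodeCounts(discards=stage1.discards)
    for s, guides in stage1.counts.items():
        out.counts[s] = {g: bcs for g, bcs in guides.items() if g in keep_guides}
    return out, report


def barcode_count_matrix(filtered: GuideBarcodeCounts) -> CountMatrix:
    """Unique-barcode counts per (guide, sample), with mean-scaled size factors."""
    samples = sorted(filtered.counts)
    guides = sorted({g for s in filtered.counts.values() for g in s})
    mat = pd.DataFrame(0, index=pd.Index(guides, name="guide_id"), columns=samples)
    for s in samples:
        for g, bcs in filtered.counts[s].items():
            mat.loc[g, s] = len(bcs)
    totals = mat.sum(axis=0).astype(float)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"empty sample(s) after filtering: {empty}")
    sf = totals / totals.mean()
    return CountMatrix(counts=mat, size_factors=sf, unit="unique_barcodes")


def control_normalized_read_matrix(
    read_counts: pd.DataFrame, control_guide_ids: list[str]
) -> CountMatrix:
    """Scale samples so control-guide read totals are constant across samples.

    Falls back to total-count normalization (with a warning) for samples with
    zero control reads.
    """
    present = [g for g in control_guide_ids if g in read_counts.index]
    ctrl_totals = (
        read_counts.loc[present].sum(axis=0).astype(float)
        if present
        else pd.Series(0.0, index=read_counts.columns)
    )
    if (ctrl_totals > 0).all() and present:
        sf = ctrl_totals / ctrl_totals.mean()
    else:
        logger.warning(
            "control guides missing or zero in some samples; "
            "falling back to total-count normalization"
        )
        totals = read_counts.sum(axis=0).astype(float)
        sf = totals / totals.mean()
    return CountMatrix(counts=read_counts, size_factors=sf, unit="reads")
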