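"""Amplicon editing-outcome quantification.

A lite analysis of base-editing amplicon reads: ungapped placement against
the amplicon reference, per-position nucleotide frequencies in a
quantification window spanning the protospacer, an allele table classified
by editing pattern, and the substitution spectrum. Indel-containing reads
are rejected rather than realigned — BE3 outcomes are substitutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AmpliconParams:
    """Quantification window: size 20 centered at -10 from the 3' protospacer
    end, i.e. spanning the protospacer; alleles at or below ``min_allele_freq``
    are aggregated as unclassified."""

    quantification_window_size: int = 20
    quantification_window_center: int = -10
    min_allele_freq: float = 0.01
    edit_window: tuple[int, int] = (4, 8)  # protospacer positions


@dataclass
class MappedRead:
    substitutions: list[tuple[int, str, str]]  # (0-based pos, ref, alt)
    rejected: str | None = None


def map_read(read: str, amplicon_reference: str) -> MappedRead:
    """Ungapped placement at the known amplicon offset.

    Reads whose length does not match the reference cannot be placed without
    gaps and are rejected with reason ``indel_or_unmapped``.
    """
    if len(read) != len(amplicon_reference):
        return MappedRead(substitutions=[], rejected="indel_or_unmapped")
    subs = [
        (i, r, a)
        for i, (r, a) in enumerate(zip(amplicon_reference, read))
        if r != a
    ]
    return MappedRead(substitutions=subs)


def _window_bounds(protospacer_start: int, params: AmpliconParams) -> tuple[int, int]:
    """0-based half-open window bounds in the reference.

    The window of ``quantification_window_size`` centered at
    ``quantification_window_center`` relative to the 3' protospacer end spans
    the protospacer for the default (20, -10) geometry.
    """
    proto_end = protospacer_start + 20  # 0-based, exclusive
    center = proto_end + params.quantification_window_center
    half = params.quantification_window_size // 2
    return center - half, center - half + params.quantification_window_size


def nucleotide_frequency_table(
    profiles: list[MappedRead],
    reference: str,
    protospacer_start: int,
    params: AmpliconParams | None = None,
) -> pd.DataFrame:
    """Per-position A/C/G/T/other frequencies over accepted reads.

    One row per window position (0-based reference coordinate in ``pos``),
    with the reference base and coverage.
    """
    params = params or AmpliconParams()
    accepted = [p for p in profiles if p.rejected is None]
    if not accepted:
        raise ValueError("no accepted reads")
    lo, hi = _window_bounds(protospacer_start, params)
    lo, hi = max(lo, 0), min(hi, len(reference))
    n = len(accepted)
    counts = {b: np.zeros(hi - lo) for b in "ACGT"}
    other = np.zeros(hi - lo)
    ref_count = {i: n for i in range(lo, hi)}
    for prof in accepted:
        for pos, _ref, alt in prof.substitutions:
            if lo <= pos < hi:
                ref_count[pos] -= 1
                if alt in counts:
                    counts[alt][pos - lo] += 1
                else:
                    other[pos - lo] += 1
    rows = []
    for i in range(lo, hi):
        refb = reference[i]
        freqs = {b: counts[b][i - lo] / n for b in "ACGT"}
        freqs[refb] += ref_count[i] / n
        rows.append(
            {
                "pos": i,
                "ref": refb,
                **{b: freqs[b] for b in "ACGT"},
                "other": other[i - lo] / n,
                "coverage": n,
            }
        )
    return pd.DataFrame(rows)


def allele_table(
    profiles: list[MappedRead],
    reference: str,
    protospacer_start: int,
    params: AmpliconParams | None = None,
) -> pd.DataFrame:
    """Alleles over the quantification window, classified by editing pattern.

    Classes: ``unedited``; ``complete_window_edit`` (every editing-window
    reference C read as T, nothing else); ``partial_window_edit`` (some but
    not all window Cs edited, nothing else); ``edit_outside_window`` (edits
    only outside the editing window); ``other`` (window and non-window edits
    combined, or any non-C>T change). Alleles at frequency <= min_allele_freq
    contribute to a single ``unclassified`` row.
    """
    params = params or AmpliconParams()
    accepted = [p for p in profiles if p.rejected is None]
    if not accepted:
        raise ValueError("no accepted reads")
    qlo, qhi = _window_bounds(protospacer_start, params)
    qlo, qhi = max(qlo, 0), min(qhi, len(reference))
    elo, ehi = params.edit_window
    win_pos = set(range(protospacer_start + elo - 1, protospacer_start + ehi))
    win_c = {i for i in win_pos if reference[i] == "C"}

    def allele_key(prof: MappedRead) -> tuple[str, tuple]:
        window_seq = list(reference[qlo:qhi])
        for pos, _r, a in prof.substitutions:
            if qlo <= pos < qhi:
                window_seq[pos - qlo] = a
        return "".join(window_seq), tuple(sorted(prof.substitutions))

    groups: dict[tuple[str, tuple], int] = {}
    for prof in accepted:
        key = allele_key(prof)
        groups[key] = groups.get(key, 0) + 1
    n = len(accepted)

    def classify(subs: tuple) -> str:
        if not subs:
            return "unedited"
        in_win = [s for s in subs if s[0] in win_pos]
        out_win = [s for s in subs if s[0] not in win_pos]
        clean_ct = all(r == "C" and a == "T" for _, r, a in subs)
        if not clean_ct:
            return "other"
        if in_win and out_win:
            return "other"
        if out_win:
            return "edit_outside_window"
        edited_c = {s[0] for s in in_win}
        if edited_c == win_c:
            return "complete_window_edit"
        return "partial_window_edit"

    rows = []
    unclassified = 0.0
    for (window_seq, subs), count in sorted(groups.items(), key=lambda kv: -kv[1]):
        freq = count / n
        if freq <= params.min_allele_freq:
            unclassified += freq
            continue
        rows.append(
            {
                "allele": window_seq,
                "count": count,
                "frequency": freq,
                "class": classify(subs),
            }
        )
    if unclassified > 0:
        rows.append(
            {"allele": "", "count": int(round(unclassified * n)),
             "frequency": unclassified, "class": "unclassified"}
        )
    return pd.DataFrame(rows)


def edit_spectrum(position_matrix: pd.DataFrame) -> pd.Series:
    """Fraction of non-reference base mass per substitution type (e.g. C>T)."""
    totals: dict[str, float] = {}
    for row in position_matrix.itertuples():
        ref = row.ref
        for b in "ACGT":
            if b == ref:
                continue
            mass = getattr(row, b)
            if mass > 0:
                totals[f"{ref}>{b}"] = totals.get(f"{ref}>{b}", 0.0) + mass
    total = sum(totals.values())
    if total == 0:
        return pd.Series(dtype=float)
    return pd.Series({k: v / total for k, v in sorted(totals.items())})
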