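import re

import numpy as np
import pytest

from bescreen.design import (
    Consequence,
    DesignParams,
    annotate_consequence,
    apply_filters,
    assemble_library,
    conservation_class,
    count_seed_sites,
    count_spacer_sites,
    enumerate_guides,
    predict_edits,
)
from bescreen.reference import (
    GeneAnnotation,
    Genome,
    coding_sequence,
    reverse_complement,
    translate_cds,
)


def brute_force_sites(seq: str):
    """Independent regex scan for 20-mer + NGG with 5-nt flanks, both strands."""
    found = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for m in re.finditer(r"(?=([ACGT]{25})[ACGT]GG)", s):
            i = m.start()
            if i + 25 + 3 + 2 > n:  # flank after PAM
                continue
            proto = s[i + 5 : i + 25]
            if strand == "+":
                span = (i + 6, i + 25)
            else:
                span = (n - (i + 25) + 1, n - (i + 5))
            found.add((strand, span, proto))
    return found


class TestEnumerate:
    def test_no_pam_no_guides(self):
        assert enumerate_guides(Genome({"c": "A" * 50})) == []

    def test_single_forced_candidate(self):
        # 5-nt flank + 20-nt protospacer + AGG PAM + 2 more flank = 30 nt
        proto = "ATATATATATATATATATAT"
        seq = "CATCA" + proto + "AGGTA"
        cands = enumerate_guides(Genome({"c": seq}))
        assert len(cands) == 1
        c = cands[0]
        assert (c.strand, c.protospacer, c.pam) == ("+", proto, "AGG")
        assert c.genomic_span == (6, 25)
        assert c.context30 == seq

    def test_matches_brute_force_regex_scan(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 500))
        cands = enumerate_guides(Genome({"c": seq}))
        ours = {(c.strand, c.genomic_span, c.protospacer) for c in cands}
        assert ours == brute_force_sites(seq)

    def test_emitted_guides_well_formed(self, toy_guides):
        records, _ = toy_guides
        for cand, _ in records[:200]:
            assert len(cand.protospacer) == 20
            assert len(cand.context30) == 30
            assert cand.pam[1:] == "GG"
            assert cand.context30[5:25] == cand.protospacer


class TestPredictEdits:
    def _forced(self, proto):
        seq = "CATCA" + proto + "AGGTA"
        genome = Genome({"c": seq})
        (cand,) = enumerate_guides(genome)
        return cand, genome

    def test_all_window_cs_convert(self):
        cand, genome = self._forced("AAACCCCCAAAAAAAAAAAA")
        edits = predict_edits(cand, genome)
        assert edits.window_positions_edited == [4, 5, 6, 7, 8]
        assert [e[3] for e in edits.genomic_substitutions] == ["T"] * 5

    def test_c_outside_window_untouched(self):
        cand, genome = self._forced("AAAAAAAACAAAAAAAAAAA")  # C at position 9
        assert predict_edits(cand, genome).empty

    def test_minus_strand_substitutions_are_g_to_a(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 400))
        genome = Genome({"c": seq})
        minus = [c for c in enumerate_guides(genome) if c.strand == "-"]
        rc_genome = Genome({"c": reverse_complement(seq)})
        n = len(seq)
        checked = 0
        for cand in minus[:20]:
            edits = predict_edits(cand, genome)
            for chrom, pos, ref, alt in edits.genomic_substitutions:
                assert (ref, alt) == ("G", "A")
                # same site on the reverse-complemented genome reads as C
                assert rc_genome.fetch("c", n - pos + 1, n - pos + 1) == "C"
                checked += 1
        assert checked > 0

    def test_stale_candidate_is_error(self):
        cand, genome = self._forced("AAACCCCCAAAAAAAAAAAA")
        other = Genome({"c": "A" * len(genome["c"])})
        with pytest.raises(ValueError, match="stale"):
            predict_edits(cand, other)


def _genome_with_gene(cds: str, upstream: str = "GATTC", downstream: str = "CCAGGTTAAG"):
    seq = upstream + cds + downstream
    genome = Genome({"c": seq})
    ann = GeneAnnotation("g1", "c", "+", [(len(upstream) + 1, len(upstream) + len(cds))])
    return genome, [ann]


class TestConsequence:
    def _consequence_for_substitution(self, cds, genome, anns, pos, codon_table):
        """Minimal edit set hitting one genomic position with C->T."""
        from bescreen.design import EditSet

        ref = genome.fetch("c", pos, pos)
        edits = EditSet(window_positions_edited=[4], genomic_substitutions=[("c", pos, ref, "T")])
        cand = _FakeCand()
        return annotate_consequence(cand, edits, genome, anns, codon_table, {})

    def test_nonsense_from_caa_to_taa(self, codon_table):
        genome, anns = _genome_with_gene("ATGCAATAA")
        cons = self._consequence_for_substitution("ATGCAATAA", genome, anns, 9, codon_table)
        assert cons.cls == "nonsense"
        assert cons.aa_changes == [("g1", "Q", 2, "*")]

    def test_missense_pro_to_leu(self, codon_table):
        genome, anns = _genome_with_gene("ATGCCATAA")
        from bescreen.design import EditSet

        edits = EditSet([4, 5], [("c", 9, "C", "T"), ("c", 10, "C", "T")])
        cons = annotate_consequence(_FakeCand(), edits, genome, anns, codon_table, {})
        assert cons.cls == "missense"
        assert cons.aa_changes == [("g1", "P", 2, "L")]

    def test_synonymous_wobble(self, codon_table):
        genome, anns = _genome_with_gene("ATGGCCTAA")  # GCC -> GCT still Ala
        cons = self._consequence_for_substitution("ATGGCCTAA", genome, anns, 11, codon_table)
        assert cons.cls == "synonymous"

    def test_minus_guide_trp_to_stop(self, codon_table):
        # + strand gene codon TGG; a - strand guide converts G->A on the
        # coding strand: TGG -> TGA (Trp -> stop)
        genome, anns = _genome_with_gene("ATGTGGTAA")
        from bescreen.design import EditSet

        edits = EditSet([5], [("c", 11, "G", "A")])
        cons = annotate_consequence(_FakeCand(), edits, genome, anns, codon_table, {})
        assert cons.cls == "nonsense"
        assert cons.aa_changes == [("g1", "W", 2, "*")]

    def test_noncoding_outside_cds(self, codon_table):
        genome, anns = _genome_with_gene("ATGCAATAA")
        cons = self._consequence_for_substitution("ATGCAATAA", genome, anns, 2, codon_table)
        assert cons.cls == "noncoding"

    def test_against_whole_genome_retranslation_oracle(self, toy, toy_guides, codon_table):
        """Every guide's class equals a from-scratch mutate-and-retranslate oracle."""
        genome, annotations, _ = toy
        records, _ = toy_guides
        rng = np.random.default_rng(9)
        idx = rng.choice(len(records), size=min(300, len(records)), replace=False)
        from bescreen.design import predict_edits

        for i in idx:
            cand, cons = records[i]
            edits = predict_edits(cand, genome)
            assert cons.cls == _oracle_class(genome, annotations, edits, codon_table)


class _FakeCand:
    guide_id = "fake"
    chrom = "c"


def _oracle_class(genome, annotations, edits, codon_table):
    """Independent oracle: rebuild every chromosome string with the edits,
    re-translate every annotated gene from scratch, and classify the diff."""
    if not edits.genomic_substitutions:
        return "no_edit"
    mutated = {}
    for cid, seq in genome.records.items():
        arr = list(seq)
        for c, p, ref, alt in edits.genomic_substitutions:
            if c == cid:
                assert arr[p - 1] == ref
                arr[p - 1] = alt
        mutated[cid] = "".join(arr)
    mgenome = Genome(mutated)
    changes = []
    touched = False
    for ann in annotations:
        before = translate_cds(coding_sequence(genome, ann), codon_table)
        after = translate_cds(coding_sequence(mgenome, ann), codon_table)
        if before != after:
            touched = True
            changes.extend(
                (a, b) for a, b in zip(before, after) if a != b
            )
        elif coding_sequence(genome, ann) != coding_sequence(mgenome, ann):
            touched = True  # silent nucleotide change inside a CDS
    if not touched:
        return "noncoding"
    if any(b == "*" and a != "*" for a, b in changes):
        return "nonsense"
    if changes:
        return "missense"
    return "synonymous"


class TestSeedSites:
    def test_own_site_counts(self):
        rng = np.random.default_rng(10)
        seq = "".join(rng.choice(list("ACGT"), 300))
        genome = Genome({"c": seq})
        cands = enumerate_guides(genome)
        assert cands, "fixture needs at least one candidate"
        assert all(count_seed_sites(genome, c) >= 1 for c in cands[:10])

    def test_planted_duplicate_counts_two(self):
        proto = "ATATATATATATGCGCGCGC"
        seq = "CATCA" + proto + "AGGTA"
        dup = proto[-12:] + "AGG"
        genome = Genome({"c": seq + "TTAAC" + dup})
        (cand,) = [c for c in enumerate_guides(genome) if c.protospacer == proto]
        assert count_seed_sites(genome, cand) == 2

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 600))
        genome = Genome({"c": seq})
        for cand in enumerate_guides(genome)[:15]:
            seed = cand.protospacer[-12:]
            brute = 0
            for s in (seq, reverse_complement(seq)):
                for i in range(len(s) - 14):
                    if s[i : i + 12] == seed and s[i + 13 : i + 15] == "GG":
                        brute += 1
            assert count_seed_sites(genome, cand) == brute


class TestFilters:
    def test_polyt_removed(self):
        proto = "GGTTTTAAGCGCGCGCATAT"
        seq = "CATCA" + proto + "AGGTA"
        genome = Genome({"c": seq})
        cands = [c for c in enumerate_guides(genome) if c.protospacer == proto]
        kept, report = apply_filters(cands, genome, [])
        assert kept == [] and report["polyT"] == 1

    def test_bookkeeping_conserves_counts(self, toy, toy_guides):
        genome, annotations, _ = toy
        cands = enumerate_guides(genome)
        kept, report = apply_filters(cands, genome, annotations)
        assert len(kept) + sum(report.values()) == len(cands)

    def test_planted_structure_triggers_every_filter(self, toy_guides):
        _, report = toy_guides
        assert all(v >= 1 for v in report.values()), report


class TestConservation:
    def test_above_threshold(self):
        c = Consequence(cls="missense", representative_score=7.2)
        assert conservation_class(c) is True

    def test_exact_threshold_is_not_conserved(self):
        c = Consequence(cls="missense", representative_score=5.0)
        assert conservation_class(c) is False

    def test_max_absolute_score(self, codon_table):
        genome, anns = _genome_with_gene("ATGCCATAA")
        from bescreen.design import EditSet

        edits = EditSet([4, 5], [("c", 9, "C", "T"), ("c", 10, "C", "T")])
        scores = {("g1", "P", 2, "L"): -6.0}
        cons = annotate_consequence(_FakeCand(), edits, genome, anns, codon_table, scores)
        assert cons.representative_score == 6.0
        assert conservation_class(cons) is True

    def test_non_missense_is_error(self):
        with pytest.raises(ValueError):
            conservation_class(Consequence(cls="nonsense"))


class TestAssembleLibrary:
    def _sizes(self, records, essential):
        pools = {"NS": 0, "ctrl_synonymous": 0, "ctrl_noC": 0}
        for _, cons in records:
            if cons.cls == "nonsense" and not any(g in essential for g in cons.affected_genes):
                pools["NS"] += 1
            elif cons.cls == "synonymous":
                pools["ctrl_synonymous"] += 1
            elif cons.cls == "no_edit":
                pools["ctrl_noC"] += 1
        return pools

    def test_exact_sizes_and_determinism(self, toy, toy_guides):
        genome, annotations, essential = toy
        records, _ = toy_guides
        pools = self._sizes(records, essential)
        sizes = {
            "NS": min(3, pools["NS"]),
            "ctrl_synonymous": min(5, pools["ctrl_synonymous"]),
            "ctrl_noC": min(5, pools["ctrl_noC"]),
            "ctrl_nontargeting": 4,
        }
        lib1 = assemble_library(records, annotations, sizes, 42, genome=genome)
        lib2 = assemble_library(records, annotations, sizes, 42, genome=genome)
        assert lib1.equals(lib2)
        for label, want in sizes.items():
            assert (lib1.set_label == label).sum() == want
        # ES takes every eligible guide, never sampled
        n_es = sum(
            1
            for _, cons in records
            if cons.cls == "nonsense" and any(g in essential for g in cons.affected_genes)
        )
        assert (lib1.set_label == "ES").sum() == n_es

    def test_oversized_request_is_error(self, toy, toy_guides):
        genome, annotations, _ = toy
        records, _ = toy_guides
        with pytest.raises(ValueError, match="NS"):
            assemble_library(records, annotations, {"NS": 10**6}, 0, genome=genome)

    def test_nontargeting_controls_absent_from_genome(self, toy, toy_guides):
        genome, annotations, _ = toy
        records, _ = toy_guides
        lib = assemble_library(
            records, annotations, {"ctrl_nontargeting": 5}, 7, genome=genome
        )
        nt = lib[lib.set_label == "ctrl_nontargeting"]
        assert len(nt) == 5
        for proto in nt.protospacer:
            assert count_spacer_sites(genome, proto) == 0


def test_strand_symmetry_of_design(toy):
    """Designing on the reverse-complemented genome yields the same multiset
    of (protospacer) sequences (coordinates mirror, content identical)."""
    genome, _, _ = toy
    sub = Genome({"chr1": genome["chr1"][:800]})
    rc = Genome({"chr1": reverse_complement(sub["chr1"])})
    fwd = sorted(c.protospacer for c in enumerate_guides(sub))
    rev = sorted(c.protospacer for c in enumerate_guides(rc))
    assert fwd == rev
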