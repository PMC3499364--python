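"""Local alignment, E-values, prefiltered search, six-frame ORFs and
BLAST-tabular I/O, each checked against an independent route."""

import math

import numpy as np
import pytest
from Bio.Data import CodonTable

from duoproteome import (InputError, ParseError, all_vs_all, evalue_of,
                         protein_vs_genome, read_hits, sixframe_orfs,
                         smith_waterman, write_hits)
from duoproteome.synthetic_data import (back_translate, mutate_to_identity,
                                        random_protein)

from _oracles import best_local_score, translate_regex_orf_count
from conftest import make_records


class TestSmithWaterman:
    def test_self_alignment_is_perfect(self, scheme):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        aln = smith_waterman(seq, seq, scheme)
        assert aln.percent_identity == 100.0
        assert aln.a_end - aln.a_start == len(seq)
        assert aln.columns == len(seq)

    def test_unrelated_short_sequences_best_single_residue(self, scheme):
        # no extension is worth a gap here, so the optimum is the best
        # positive single-residue pairing (E:K under BLOSUM62)
        a, b = "ACDE", "WYHK"
        best_single = max(scheme.matrix[x, y] for x in a for y in b)
        assert best_single > 0
        aln = smith_waterman(a, b, scheme)
        assert aln.score == best_single
        assert aln.score == best_local_score(a, b, scheme.matrix,
                                             scheme.gap_open, scheme.gap_extend)

    def test_score_matches_exhaustive_enumeration(self, scheme):
        """200 random short pairs: optimal score equals the exhaustive
        local-alignment search."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            la = int(rng.integers(1, 9))
            lb = int(rng.integers(1, 9))
            a = random_protein(la, rng)
            b = random_protein(lb, rng)
            expected = best_local_score(a, b, scheme.matrix,
                                        scheme.gap_open, scheme.gap_extend)
            aln = smith_waterman(a, b, scheme)
            got = 0.0 if aln is None else aln.score
            assert got == expected, (a, b)

    def test_score_symmetry(self, scheme):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = random_protein(int(rng.integers(10, 60)), rng)
            b = random_protein(int(rng.integers(10, 60)), rng)
            fwd = smith_waterman(a, b, scheme)
            rev = smith_waterman(b, a, scheme)
            assert (fwd is None) == (rev is None)
            if fwd is not None:
                assert fwd.score == rev.score

    def test_x_is_neutral(self, scheme):
        aln = smith_waterman("MKTAYIAK", "MKTXYIAK", scheme)
        assert aln is not None
        assert scheme.matrix["X", "W"] == 0.0

    def test_empty_sequence_rejected(self, scheme):
        with pytest.raises(InputError):
            smith_waterman("", "MKT", scheme)


class TestEvalue:
    def test_closed_form_at_zero_score(self, scheme):
        assert evalue_of(0.0, 250, scheme) == pytest.approx(
            scheme.k_param * 250 * scheme.db_letters)

    def test_linearity_in_search_space(self, scheme):
        import dataclasses
        doubled = dataclasses.replace(scheme, db_letters=2 * scheme.db_letters)
        assert evalue_of(80, 250, doubled) == pytest.approx(
            2 * evalue_of(80, 250, scheme))

    def test_independent_recomputation(self, scheme):
        for score in (10.0, 55.0, 123.0):
            direct = scheme.k_param * 300 * scheme.db_letters \
                * math.exp(-scheme.lam * score)
            assert abs(evalue_of(score, 300, scheme) - direct) \
                <= 1e-12 * direct

    def test_monotone_decreasing_in_score(self, scheme):
        evs = [evalue_of(s, 200, scheme) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))


class TestAllVsAll:
    def test_identical_proteomes_reciprocal_hits(self, scheme):
        rng = np.random.default_rng(31)
        seqs = [random_protein(120, rng) for _ in range(10)]
        a = make_records(seqs, "A", "a")
        b = make_records(seqs, "B", "b")
        hits = all_vs_all(a, b, scheme, evalue_max=1e-5)
        perfect = [h for h in hits if h.percent_identity == 100.0]
        assert len(perfect) == 20  # both directions of the 10 identical pairs
        assert {(h.query_id, h.subject_id) for h in perfect} == \
            {(f"a{i:03d}", f"b{i:03d}") for i in range(1, 11)} \
            | {(f"b{i:03d}", f"a{i:03d}") for i in range(1, 11)}

    def test_prefilter_loses_no_ortholog_pairs(self, scheme):
        """k-mer prefilter retains the same hit set as the exhaustive
        search on 80%-identity orthologs."""
        rng = np.random.default_rng(8)
        seqs = [random_protein(150, rng) for _ in range(50)]
        a = make_records(seqs, "A", "a")
        b = make_records([mutate_to_identity(s, 80.0, rng) for s in seqs],
                         "B", "b")
        fast = all_vs_all(a, b, scheme, prefilter=True, evalue_max=1e-5)
        slow = all_vs_all(a, b, scheme, prefilter=False, evalue_max=1e-5)
        key = lambda h: (h.query_id, h.subject_id)
        assert sorted(map(key, fast)) == sorted(map(key, slow))
        assert len(fast) >= 100  # all ortholog pairs, both directions

    def test_null_hit_rate_is_low(self, scheme):
        rng = np.random.default_rng(13)
        a = make_records([random_protein(200, rng) for _ in range(30)], "A", "a")
        b = make_records([random_protein(200, rng) for _ in range(30)], "B", "b")
        hits = all_vs_all(a, b, scheme, prefilter=False, evalue_max=1e-5)
        assert len(hits) <= 0.01 * 30 * 30 * 2

    def test_self_comparison_excludes_self_hits(self, scheme):
        rng = np.random.default_rng(5)
        a = make_records([random_protein(100, rng) for _ in range(5)], "A", "a")
        hits = all_vs_all(a, a, scheme)
        assert all(h.query_id != h.subject_id for h in hits)

    def test_sorted_by_query_then_evalue(self, scheme):
        rng = np.random.default_rng(6)
        seqs = [random_protein(100, rng) for _ in range(6)]
        a = make_records(seqs, "A", "a")
        b = make_records([mutate_to_identity(s, 85.0, rng) for s in seqs],
                         "B", "b")
        hits = all_vs_all(a, b, scheme, evalue_max=1e-3)
        keys = [(h.query_id, h.evalue) for h in hits]
        assert keys == sorted(keys)


class TestSixFrameOrfs:
    def test_embedded_cds_recovered(self):
        rng = np.random.default_rng(3)
        prot = random_protein(80, rng)
        cds = back_translate(prot, rng)
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        genome = spacer + cds + spacer
        orfs = sixframe_orfs(genome, min_aa=30)
        assert any(prot in o.peptide and o.strand == "+" for o in orfs)

    def test_reverse_complement_flips_strands(self):
        rng = np.random.default_rng(4)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
        from Bio.Seq import Seq
        rc = str(Seq(genome).reverse_complement())
        fwd = sixframe_orfs(genome, min_aa=25)
        rev = sixframe_orfs(rc, min_aa=25)
        assert sorted(o.peptide for o in fwd) == sorted(o.peptide for o in rev)
        by_pep_fwd = sorted((o.peptide, o.strand) for o in fwd)
        by_pep_rev = sorted((o.peptide, "+" if o.strand == "-" else "-")
                            for o in rev)
        assert by_pep_fwd == by_pep_rev

    def test_orf_count_matches_regex_oracle(self):
        rng = np.random.default_rng(11)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10000))
        table = CodonTable.unambiguous_dna_by_id[1]
        codon_to_aa = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_to_aa[stop] = "*"
        expected = translate_regex_orf_count(genome, 30, codon_to_aa)
        assert len(sixframe_orfs(genome, min_aa=30)) == expected

    def test_coordinates_are_consistent(self):
        rng = np.random.default_rng(14)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
        from Bio.Seq import Seq
        for o in sixframe_orfs(genome, min_aa=30):
            sub = genome[o.start - 1:o.end]
            if o.strand == "-":
                sub = str(Seq(sub).reverse_complement())
            assert str(Seq(sub).translate()) == o.peptide


class TestProteinVsGenome:
    def test_planted_hidden_gene_is_found(self, small_sim, scheme):
        intervals = small_sim.gene_intervals
        hidden = intervals[intervals.hidden]
        genome_sp = hidden.iloc[0]["genome_species"]
        targets = set(hidden[hidden.genome_species == genome_sp]["gene_id"])
        src_sp = "A" if genome_sp == "B" else "B"
        queries = [r for r in small_sim.proteomes[src_sp]
                   if r.gene_id in targets]
        hits = protein_vs_genome(queries, small_sim.genomes[genome_sp],
                                 scheme, evalue_max=1e-5)
        best = {}
        for h in hits:
            if h.query_id not in best or h.evalue < best[h.query_id].evalue:
                best[h.query_id] = h
        assert set(best) == targets
        for h in best.values():
            assert h.percent_identity >= 90.0
            assert h.query_coverage >= 0.9
            assert h.frame is not None

    def test_random_protein_rarely_hits_random_genome(self, scheme):
        rng = np.random.default_rng(17)
        no_hit = 0
        trials = 100
        for i in range(trials):
            prot = make_records([random_protein(150, rng)], "Q", f"q{i}")
            genome = "".join("ACGT"[k] for k in rng.integers(0, 4, size=5000))
            hits = protein_vs_genome(prot, ("chr", genome), scheme,
                                     evalue_max=1e-5)
            no_hit += not hits
        assert no_hit >= 0.99 * trials

    def test_stop_split_cds_caps_coverage(self, scheme):
        rng = np.random.default_rng(19)
        prot = random_protein(120, rng)
        cds = back_translate(prot, rng)
        # plant an in-frame stop at codon 60, splitting the ORF in two
        cds = cds[:180] + "TAA" + cds[183:]
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
        genome = spacer + cds + spacer
        hits = protein_vs_genome(make_records([prot], "Q", "q"),
                                 ("chr", genome), scheme, evalue_max=1e-5)
        assert hits
        assert max(h.query_coverage for h in hits) < 1.0


class TestHitIO:
    def _hits(self, scheme):
        rng = np.random.default_rng(23)
        seqs = [random_protein(100, rng) for _ in range(4)]
        a = make_records(seqs, "A", "a")
        b = make_records([mutate_to_identity(s, 85.0, rng) for s in seqs],
                         "B", "b")
        return all_vs_all(a, b, scheme, evalue_max=1e-3)

    def test_round_trip(self, tmp_path, scheme):
        hits = self._hits(scheme)
        path = tmp_path / "hits.tsv"
        write_hits(hits, path)
        assert read_hits(path) == hits

    def test_invalid_identity_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q\ts\t101.0\t50\t0\t0\t1\t50\t1\t50\t1e-20\t100.0\n")
        with pytest.raises(ParseError, match="line 1"):
            read_hits(path)

    def test_wrong_column_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q\ts\t90.0\t50\n")
        with pytest.raises(ParseError, match="columns"):
            read_hits(path)

    def test_coverage_recomputed_for_plain_12_columns(self, tmp_path):
        path = tmp_path / "plain.tsv"
        path.write_text("q\ts\t90.00\t50\t5\t0\t11\t60\t1\t50\t1e-20\t100.0\n")
        (hit,) = read_hits(path, query_lengths={"q": 100})
        assert hit.query_coverage == pytest.approx((60 - 11 + 1) / 100)
        (hit_nolen,) = read_hits(path)
        assert hit_nolen.query_coverage is None
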